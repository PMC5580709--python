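"""Barcoded strain catalogs.

The yeast knockout collection addresses each homozygous deletion strain with a
unique 20-base "uptag" barcode integrated next to the deletion cassette.  A
:class:`BarcodeCatalog` is the screen's address book: strain id, deleted yeast
gene, uptag sequence.  Barcodes are required to be mutually separated by a
Hamming distance of at least 3 so that single-mismatch assignment is always
unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
UPTAG_LENGTH = 20
MIN_PAIRWISE_DISTANCE = 3

#: byte -> base index (0..3), 255 for any non-ACGT byte
BASE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    BASE_LUT[_b] = _i


def _encode(seqs: list[str], length: int) -> np.ndarray:
    """Pack equal-length DNA strings into a (n, length) uint8 byte matrix."""
    joined = "".join(seqs).encode("ascii")
    arr = np.frombuffer(joined, dtype=np.uint8)
    return arr.reshape(len(seqs), length)


def min_pairwise_hamming(seqs: list[str]) -> int:
    """Minimum pairwise Hamming distance over a set of equal-length sequences.

    Chunked all-pairs comparison; O(n^2 * L) bytes touched.
    """
    if len(seqs) < 2:
        return len(seqs[0]) if seqs else 0
    mat = _encode(seqs, len(seqs[0]))
    n = mat.shape[0]
    best = mat.shape[1]
    chunk = max(1, 2_000_000 // max(n, 1))
    for start in range(0, n, chunk):
        block = mat[start : start + chunk]
        # distances of block rows against all later rows
        d = (block[:, None, :] != mat[None, :, :]).sum(axis=2)
        rows = np.arange(start, start + block.shape[0])
        mask = np.arange(n)[None, :] > rows[:, None]
        if mask.any():
            best = min(best, int(d[mask].min()))
    return best


@dataclass
class BarcodeCatalog:
    """Strain identities and their uptag barcodes."""

    strain_ids: list[str]
    yeast_genes: list[str]
    uptags: list[str]
    _matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.strain_ids)

    def validate(self, check_distance: bool = False) -> None:
        """Check catalog invariants.

        The pairwise-distance check is quadratic and is opt-in; it is
        guaranteed by construction for catalogs from :func:`bartox.simulate.build_library`.
        """
        n = len(self.strain_ids)
        if not (len(self.yeast_genes) == len(self.uptags) == n):
            raise ValueError("catalog columns have unequal lengths")
        if len(set(self.strain_ids)) != n:
            raise ValueError("strain_ids are not unique")
        if len(set(self.uptags)) != n:
            raise ValueError("uptag sequences are not unique")
        for tag in self.uptags:
            if len(tag) != UPTAG_LENGTH or any(c not in "ACGT" for c in tag):
                raise ValueError(f"invalid uptag {tag!r}: need {UPTAG_LENGTH} bases over ACGT")
        if check_distance and n >= 2:
            d = min_pairwise_hamming(self.uptags)
            if d < MIN_PAIRWISE_DISTANCE:
                raise ValueError(
                    f"minimum pairwise uptag Hamming distance {d} < {MIN_PAIRWISE_DISTANCE}"
                )

    def uptag_matrix(self) -> np.ndarray:
        """Uptags as a (n_strains, 20) uint8 byte matrix (cached)."""
        if self._matrix is None:
            self._matrix = _encode(self.uptags, UPTAG_LENGTH)
        return self._matrix

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strain_id": self.strain_ids,
                "yeast_gene": self.yeast_genes,
                "uptag": self.uptags,
            }
        )

    def gene_map(self) -> dict[str, str]:
        """strain_id -> yeast_gene."""
        return dict(zip(self.strain_ids, self.yeast_genes))

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "BarcodeCatalog":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"strain_id", "yeast_gene", "uptag"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"catalog {path} missing columns: {sorted(missing)}")
        return cls(
            strain_ids=df["strain_id"].tolist(),
            yeast_genes=df["yeast_gene"].tolist(),
            uptags=df["uptag"].tolist(),
        )


def random_codes(
    n: int,
    length: int,
    min_distance: int,
    rng: np.random.Generator,
    max_attempts: int = 1_000_000,
) -> list[str]:
    """Rejection-sample ``n`` DNA codes of ``length`` bases with minimum
    pairwise Hamming distance ``min_distance``.

    Raises RuntimeError when the attempt cap is hit, which signals that ``n``
    is too large for the requested code space.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    accepted = np.empty((n, length), dtype=np.uint8)
    k = 0
    attempts = 0
    while k < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} codes of length {length} at distance "
                f">= {min_distance} within {max_attempts} attempts"
            )
        batch = min(1024, max_attempts - attempts)
        candidates = BASES[rng.integers(0, 4, size=(batch, length))]
        attempts += batch
        for cand in candidates:
            if k == n:
                break
            if k > 0:
                dmin = (accepted[:k] != cand).sum(axis=1).min()
                if dmin < min_distance:
                    continue
            accepted[k] = cand
            k += 1
    return [bytes(row).decode("ascii") for row in accepted]
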