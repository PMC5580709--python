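"""Demultiplexing and barcode counting.

Multiplexed amplicon reads have a fixed structure set by the composite PCR
primers: one fixed base, a 6-mer inline index tag identifying the (query,
condition) sample, the 18-base common primer, then the strain's 20-mer uptag
barcode at positions 26–45 (1-based).  Assignment is Hamming-distance based
throughout: tags within ``tag_mismatch`` of a unique design tag, primer within
``primer_mismatch`` of the common sequence, barcodes matched exactly first and
then by unique best hit within ``barcode_mismatch``.  Because the barcode
window is fixed by the amplicon structure there is no sliding-window search.

Unassignable reads are a return category, never an exception; every read is
accounted for in the :class:`DemuxStats` ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .catalog import BarcodeCatalog
from .fastq import read_fastq_seqs
from .simulate import CONDITIONS, FIXED_PREFIX, FWD_COMMON, REV_COMMON, TAG_LENGTH

DESIGN_COLUMNS = ["query", "condition", "fwd_tag", "rev_tag", "fastq"]

# match_barcode sentinel results
UNMATCHED = "unmatched"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class ReadStructure:
    """Fixed amplicon layout of the sequenced (forward) read."""

    fixed_prefix: str = FIXED_PREFIX
    tag_len: int = TAG_LENGTH
    fwd_common: str = FWD_COMMON
    rev_common: str = REV_COMMON
    barcode_len: int = 20

    @property
    def tag_slice(self) -> slice:
        return slice(len(self.fixed_prefix), len(self.fixed_prefix) + self.tag_len)

    @property
    def primer_slice(self) -> slice:
        start = len(self.fixed_prefix) + self.tag_len
        return slice(start, start + len(self.fwd_common))

    @property
    def barcode_slice(self) -> slice:
        start = len(self.fixed_prefix) + self.tag_len + len(self.fwd_common)
        return slice(start, start + self.barcode_len)

    @property
    def min_length(self) -> int:
        return self.barcode_slice.stop


def parse_design(path) -> pd.DataFrame:
    """Load and validate a multiplex design sheet.

    TSV columns: query, condition, fwd_tag, rev_tag, fastq.  Tags must be
    exactly 6 bases over ACGT and every (fwd_tag, rev_tag) combination unique;
    a duplicate combination is a hard error naming the clash.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    return validate_design(df, origin=str(path))


def validate_design(df: pd.DataFrame, origin: str = "design") -> pd.DataFrame:
    missing = set(DESIGN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{origin}: missing columns {sorted(missing)}")
    df = df[DESIGN_COLUMNS].reset_index(drop=True)
    bad_cond = set(df["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ValueError(f"{origin}: unknown conditions {sorted(bad_cond)}")
    for col in ("fwd_tag", "rev_tag"):
        for tag in df[col]:
            if len(tag) != TAG_LENGTH or any(c not in "ACGT" for c in tag):
                raise ValueError(
                    f"{origin}: invalid {col} {tag!r}: need {TAG_LENGTH} bases over ACGT"
                )
    combos = list(zip(df["fwd_tag"], df["rev_tag"]))
    seen: dict[tuple, int] = {}
    for i, combo in enumerate(combos):
        if combo in seen:
            raise ValueError(
                f"{origin}: duplicate tag combination {combo} in rows "
                f"{seen[combo] + 2} and {i + 2}"
            )
        seen[combo] = i
    dup_sample = df.duplicated(subset=["query", "condition"])
    if dup_sample.any():
        raise ValueError(f"{origin}: duplicate (query, condition) sample entries")
    return df


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("length mismatch")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class DemuxResult:
    """Outcome of demultiplexing one read."""

    status: str  # assigned | too_short | unassigned_tag | unassigned_primer
    sample: Optional[tuple[str, str]] = None  # (query, condition)
    barcode: Optional[str] = None
    barcode_start: Optional[int] = None  # 1-based position of the barcode window


def demultiplex_read(
    read: str,
    structure: ReadStructure,
    design: pd.DataFrame,
    tag_mismatch: int = 1,
    primer_mismatch: int = 2,
) -> DemuxResult:
    """Assign a single read to a sample by its inline index tag.

    The tag window must have a unique best design tag within ``tag_mismatch``
    and the following 18 bases must match the common primer within
    ``primer_mismatch``.  The leading fixed base is part of the primer
    synthesis, not an informative position, and is not checked.
    """
    if len(read) < structure.min_length:
        return DemuxResult("too_short")
    tag = read[structure.tag_slice]
    best_d, best_idx, best_ties = None, None, 0
    for i, fwd in enumerate(design["fwd_tag"]):
        d = hamming(tag, fwd)
        if best_d is None or d < best_d:
            best_d, best_idx, best_ties = d, i, 1
        elif d == best_d:
            best_ties += 1
    if best_d is None or best_d > tag_mismatch or best_ties > 1:
        return DemuxResult("unassigned_tag")
    if hamming(read[structure.primer_slice], structure.fwd_common) > primer_mismatch:
        return DemuxResult("unassigned_primer")
    row = design.iloc[best_idx]
    return DemuxResult(
        "assigned",
        sample=(row["query"], row["condition"]),
        barcode=read[structure.barcode_slice],
        barcode_start=structure.barcode_slice.start + 1,
    )


def match_barcode(seq: str, catalog: BarcodeCatalog, max_mismatch: int = 2) -> str:
    """Assign a 20-base barcode to a strain.

    Exact match wins; otherwise the unique catalog entry within Hamming
    ``max_mismatch`` wins; two or more equidistant best hits give
    ``"ambiguous"``; no entry in range (or any non-ACGT character, e.g. N)
    gives ``"unmatched"``.
    """
    if len(seq) != catalog.uptag_matrix().shape[1]:
        raise ValueError("barcode length mismatch")
    idx = _match_barcode_batch(
        np.frombuffer(seq.encode("ascii"), dtype=np.uint8)[None, :], catalog, max_mismatch
    )[0]
    if idx == -1:
        return UNMATCHED
    if idx == -2:
        return AMBIGUOUS
    return catalog.strain_ids[idx]


def _match_barcode_batch(
    barcodes: np.ndarray, catalog: BarcodeCatalog, max_mismatch: int
) -> np.ndarray:
    """Vectorized barcode assignment.

    ``barcodes``: (m, 20) uint8.  Returns per-row strain index, -1 for
    unmatched (incl. non-ACGT), -2 for ambiguous.
    """
    cat = catalog.uptag_matrix()
    m = barcodes.shape[0]
    out = np.full(m, -1, dtype=np.int64)
    if m == 0:
        return out
    valid = np.isin(barcodes, np.frombuffer(b"ACGT", dtype=np.uint8)).all(axis=1)
    if valid.any():
        sub = barcodes[valid]
        # chunk to bound the (m, n_strains, 20) broadcast
        res = np.empty(sub.shape[0], dtype=np.int64)
        chunk = max(1, 20_000_000 // max(cat.shape[0] * cat.shape[1], 1))
        for s in range(0, sub.shape[0], chunk):
            block = sub[s : s + chunk]
            d = (block[:, None, :] != cat[None, :, :]).sum(axis=2)
            best = d.min(axis=1)
            ties = (d == best[:, None]).sum(axis=1)
            r = d.argmin(axis=1)
            r[best > max_mismatch] = -1
            r[(ties > 1) & (best <= max_mismatch)] = -2
            res[s : s + block.shape[0]] = r
        out[valid] = res
    return out


@dataclass
class DemuxStats:
    """Read-accounting ledger of a demultiplexing run.

    ``per_file``: one row per FASTQ with reads_total, reads_assigned and the
    unassigned categories (short / tag / primer); ``per_sample``: one row per
    (query, condition) with reads_assigned and the barcode fate tallies.
    """

    per_file: pd.DataFrame
    per_sample: pd.DataFrame

    def validate(self) -> None:
        pf = self.per_file
        lhs = pf["reads_total"]
        rhs = (
            pf["reads_assigned"]
            + pf["reads_unassigned_short"]
            + pf["reads_unassigned_tag"]
            + pf["reads_unassigned_primer"]
        )
        if not (lhs == rhs).all():
            raise ValueError("per-file read ledger does not balance")
        ps = self.per_sample
        ok = ps["reads_assigned"] == (
            ps["barcodes_matched"] + ps["barcodes_ambiguous"] + ps["barcodes_unmatched"]
        )
        if not ok.all():
            raise ValueError("per-sample barcode ledger does not balance")
        file_assigned = ps.groupby("fastq")["reads_assigned"].sum()
        for _, row in pf.iterrows():
            if file_assigned.get(row["fastq"], 0) != row["reads_assigned"]:
                raise ValueError("per-file and per-sample assigned counts disagree")

    def write(self, per_file_path, per_sample_path) -> None:
        self.per_file.to_csv(per_file_path, sep="\t", index=False)
        self.per_sample.to_csv(per_sample_path, sep="\t", index=False)


def _assign_tags(
    tag_windows: np.ndarray, file_tags: list[str], tag_mismatch: int
) -> np.ndarray:
    """Map each read's 6-mer tag window to a design-entry index (-1 = fail).

    Works on unique tag sequences, so cost scales with error diversity rather
    than read count.
    """
    tags_u8 = np.frombuffer("".join(file_tags).encode(), dtype=np.uint8).reshape(
        len(file_tags), TAG_LENGTH
    )
    uniq, inv = np.unique(tag_windows.view(f"S{TAG_LENGTH}").ravel(), return_inverse=True)
    uniq_u8 = np.frombuffer(uniq.tobytes(), dtype=np.uint8).reshape(len(uniq), TAG_LENGTH)
    d = (uniq_u8[:, None, :] != tags_u8[None, :, :]).sum(axis=2)
    best = d.min(axis=1)
    ties = (d == best[:, None]).sum(axis=1)
    lut = d.argmin(axis=1)
    lut[(best > tag_mismatch) | (ties > 1)] = -1
    return lut[inv]


def count_barcodes(
    design: pd.DataFrame,
    catalog: BarcodeCatalog,
    tag_mismatch: int = 1,
    primer_mismatch: int = 2,
    barcode_mismatch: int = 2,
    structure: ReadStructure | None = None,
) -> tuple[pd.DataFrame, DemuxStats]:
    """Demultiplex every design FASTQ and count barcodes per strain.

    Returns ``(counts, stats)``: ``counts`` is a strains × samples integer
    DataFrame (every catalog strain has a row, zero-filled if unobserved;
    columns named ``<query>_<condition>`` in design order) and ``stats`` the
    balanced read-accounting ledger.  Several samples may share one FASTQ as
    long as their forward tags differ.
    """
    structure = structure or ReadStructure()
    design = validate_design(design)
    n_strains = len(catalog)
    sample_ids = [f"{q}_{c}" for q, c in zip(design["query"], design["condition"])]
    counts = np.zeros((n_strains, len(design)), dtype=np.int64)

    file_rows = []
    sample_stats = {
        sid: {"reads_assigned": 0, "matched": 0, "ambiguous": 0, "unmatched": 0}
        for sid in sample_ids
    }
    exact = {u: i for i, u in enumerate(catalog.uptags)}

    for path, entries in design.groupby("fastq", sort=False):
        fwd_tags = entries["fwd_tag"].tolist()
        if len(set(fwd_tags)) != len(fwd_tags):
            raise ValueError(
                f"samples sharing FASTQ {path} must have distinct forward tags"
            )
        entry_positions = entries.index.to_numpy()
        seqs = read_fastq_seqs(path)
        total = len(seqs)
        min_len = structure.min_length
        kept = [s[:min_len] for s in seqs if len(s) >= min_len]
        n_short = total - len(kept)
        if kept:
            arr = np.frombuffer(b"".join(kept), dtype=np.uint8).reshape(
                len(kept), min_len
            )
            tag_win = np.ascontiguousarray(arr[:, structure.tag_slice])
            entry_of_read = _assign_tags(tag_win, fwd_tags, tag_mismatch)
            common = np.frombuffer(structure.fwd_common.encode(), dtype=np.uint8)
            primer_ok = (arr[:, structure.primer_slice] != common).sum(axis=1) <= (
                primer_mismatch
            )
            tag_ok = entry_of_read >= 0
            n_tag_fail = int((~tag_ok).sum())
            n_primer_fail = int((tag_ok & ~primer_ok).sum())
            assigned = tag_ok & primer_ok
        else:
            arr = None
            n_tag_fail = n_primer_fail = 0
            assigned = np.zeros(0, dtype=bool)
            entry_of_read = np.zeros(0, dtype=np.int64)

        n_assigned_file = int(assigned.sum())
        for local_i, design_pos in enumerate(entry_positions):
            sid = sample_ids[design_pos]
            mask = assigned & (entry_of_read == local_i)
            n_reads = int(mask.sum())
            sample_stats[sid]["reads_assigned"] += n_reads
            if n_reads == 0:
                continue
            bc = np.ascontiguousarray(arr[mask][:, structure.barcode_slice])
            uniq, ucounts = np.unique(
                bc.view(f"S{structure.barcode_len}").ravel(), return_counts=True
            )
            need_scan = []
            blen = structure.barcode_len
            for u, c in zip(uniq, ucounts):
                raw = bytes(u).ljust(blen, b"\x00")  # S-dtype strips trailing nulls
                hit = exact.get(raw.decode("ascii", "replace"))
                if hit is not None:
                    counts[hit, design_pos] += int(c)
                    sample_stats[sid]["matched"] += int(c)
                else:
                    need_scan.append((raw, int(c)))
            if need_scan:
                scan_u8 = np.frombuffer(
                    b"".join(u for u, _ in need_scan), dtype=np.uint8
                ).reshape(len(need_scan), blen)
                hits = _match_barcode_batch(scan_u8, catalog, barcode_mismatch)
                for (u, c), h in zip(need_scan, hits):
                    if h >= 0:
                        counts[h, design_pos] += c
                        sample_stats[sid]["matched"] += c
                    elif h == -2:
                        sample_stats[sid]["ambiguous"] += c
                    else:
                        sample_stats[sid]["unmatched"] += c

        file_rows.append(
            {
                "fastq": path,
                "reads_total": total,
                "reads_assigned": n_assigned_file,
                "reads_unassigned_short": n_short,
                "reads_unassigned_tag": n_tag_fail,
                "reads_unassigned_primer": n_primer_fail,
            }
        )

    count_df = pd.DataFrame(
        counts, index=pd.Index(catalog.strain_ids, name="strain_id"), columns=sample_ids
    )
    per_sample = pd.DataFrame(
        [
            {
                "sample_id": sid,
                "query": q,
                "condition": c,
                "fastq": f,
                "reads_assigned": sample_stats[sid]["reads_assigned"],
                "barcodes_matched": sample_stats[sid]["matched"],
                "barcodes_ambiguous": sample_stats[sid]["ambiguous"],
                "barcodes_unmatched": sample_stats[sid]["unmatched"],
            }
            for sid, q, c, f in zip(
                sample_ids, design["query"], design["condition"], design["fastq"]
            )
        ]
    )
    stats = DemuxStats(per_file=pd.DataFrame(file_rows), per_sample=per_sample)
    stats.validate()
    return count_df, stats


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t")


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="strain_id")
    if (df < 0).any().any():
        raise ValueError(f"negative counts in {path}")
    return df
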