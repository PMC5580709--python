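"""Minimal, fast FASTQ reading and writing.

Reads are fixed-structure amplicons, so the pipeline only ever needs the raw
sequence line of each record plus strict structural validation with
line-numbered errors.  Plain and gzip-compressed files are supported.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np


class FastqFormatError(ValueError):
    """Malformed FASTQ record; message carries the 1-based line number."""


def _open(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq_seqs(path) -> list[bytes]:
    """Return the sequence line of every record, validating record structure.

    Raises :class:`FastqFormatError` naming the offending line for truncated
    records, bad header/separator characters, or sequence/quality length
    mismatches.
    """
    with _open(path, "rb") as fh:
        data = fh.read()
    lines = data.split(b"\n")
    if lines and lines[-1] == b"":
        lines.pop()
    n = len(lines)
    if n % 4 != 0:
        raise FastqFormatError(
            f"{path}: truncated FASTQ record at line {n - n % 4 + 1}"
        )
    seqs: list[bytes] = []
    append = seqs.append
    for i in range(0, n, 4):
        if not lines[i].startswith(b"@"):
            raise FastqFormatError(f"{path}: line {i + 1}: header must start with '@'")
        if not lines[i + 2].startswith(b"+"):
            raise FastqFormatError(f"{path}: line {i + 3}: separator must start with '+'")
        seq = lines[i + 1]
        if len(seq) != len(lines[i + 3]):
            raise FastqFormatError(
                f"{path}: line {i + 4}: quality length != sequence length"
            )
        append(seq)
    return seqs


def write_fastq(path, reads: np.ndarray, name_prefix: str, qual_char: str = "I") -> None:
    """Write an (n_reads, read_length) uint8 byte matrix as FASTQ.

    Quality is constant ``qual_char`` (default 'I' = Q40, Phred+33); the
    pipeline never consumes qualities.  Record ids are ``name_prefix:i``.
    """
    reads = np.ascontiguousarray(reads, dtype=np.uint8)
    if reads.ndim != 2:
        raise ValueError("reads must be a 2-D byte matrix")
    n, length = reads.shape
    qual = qual_char.encode("ascii") * length
    prefix = name_prefix.encode("ascii")
    seq_view = reads.view(f"S{length}").ravel() if length else [b""] * n
    with _open(path, "wb") as fh:
        chunk = 100_000
        for start in range(0, n, chunk):
            parts = [
                b"@%s:%d\n%s\n+\n%s\n" % (prefix, i, seq_view[i], qual)
                for i in range(start, min(start + chunk, n))
            ]
            fh.write(b"".join(parts))
        if n == 0:
            fh.write(b"")
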