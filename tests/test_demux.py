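"""Demultiplexing, barcode matching and the read-accounting ledger."""

import gzip

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bartox.catalog import BarcodeCatalog
from bartox.demux import (
    AMBIGUOUS,
    UNMATCHED,
    ReadStructure,
    count_barcodes,
    demultiplex_read,
    match_barcode,
    parse_design,
    validate_design,
)
from bartox.fastq import FastqFormatError, read_fastq_seqs, write_fastq
from bartox.simulate import FWD_COMMON, build_library

from conftest import TOY_UPTAGS, make_read

STRUCT = ReadStructure()


def write_design(df, path):
    df.to_csv(path, sep="\t", index=False)
    return path


class TestParseDesign:
    def test_twenty_queries_two_conditions_accepted(self, tmp_path):
        from bartox.catalog import random_codes

        rng = np.random.default_rng(0)
        fwd = random_codes(40, 6, 3, rng)
        rows = []
        for qi in range(20):
            for ci, cond in enumerate(("GLU", "GAL")):
                rows.append({"query": f"OMIM{qi:02d}", "condition": cond,
                             "fwd_tag": fwd[2 * qi + ci], "rev_tag": "ACGTAC",
                             "fastq": "pool.fastq"})
        path = write_design(pd.DataFrame(rows), tmp_path / "design.tsv")
        design = parse_design(path)
        assert len(design) == 40

    def test_duplicate_tag_combination_rejected(self, toy_design, tmp_path):
        bad = toy_design.copy()
        bad.loc[1, ["fwd_tag", "rev_tag"]] = bad.loc[0, ["fwd_tag", "rev_tag"]]
        path = write_design(bad, tmp_path / "design.tsv")
        with pytest.raises(ValueError, match="duplicate tag combination"):
            parse_design(path)

    def test_short_tag_rejected(self, toy_design, tmp_path):
        bad = toy_design.copy()
        bad.loc[0, "fwd_tag"] = "AACCG"
        path = write_design(bad, tmp_path / "design.tsv")
        with pytest.raises(ValueError, match="6 bases"):
            parse_design(path)

    def test_unknown_condition_rejected(self, toy_design):
        bad = toy_design.copy()
        bad.loc[0, "condition"] = "RAF"
        with pytest.raises(ValueError, match="condition"):
            validate_design(bad)


class TestDemultiplexRead:
    def test_exact_read_assigned(self, toy_design):
        read = make_read("AACCGG", TOY_UPTAGS[0])
        res = demultiplex_read(read, STRUCT, toy_design)
        assert res.status == "assigned"
        assert res.sample == ("OPTN", "GLU")
        assert res.barcode == TOY_UPTAGS[0]
        assert res.barcode_start == 26  # 1-based window start

    def test_one_tag_mismatch_tolerated(self, toy_design):
        read = make_read("TACCGG", TOY_UPTAGS[1])
        res = demultiplex_read(read, STRUCT, toy_design, tag_mismatch=1)
        assert res.status == "assigned"
        assert res.sample == ("OPTN", "GLU")

    def test_three_primer_mismatches_rejected(self, toy_design):
        primer = list(FWD_COMMON)
        for i in (0, 5, 11):
            primer[i] = "A" if primer[i] != "A" else "C"
        read = "G" + "AACCGG" + "".join(primer) + TOY_UPTAGS[0]
        # brute-force oracle: the mutated primer differs at exactly 3 sites
        assert sum(a != b for a, b in zip("".join(primer), FWD_COMMON)) == 3
        res = demultiplex_read(read, STRUCT, toy_design, primer_mismatch=2)
        assert res.status == "unassigned_primer"

    def test_short_read_unassigned(self, toy_design):
        res = demultiplex_read("G" + "AACCGG" + FWD_COMMON[:5], STRUCT, toy_design)
        assert res.status == "too_short"

    def test_unknown_tag_unassigned(self, toy_design):
        read = make_read("CCTTAA", TOY_UPTAGS[0])
        res = demultiplex_read(read, STRUCT, toy_design, tag_mismatch=1)
        assert res.status == "unassigned_tag"


class TestMatchBarcode:
    def test_exact_match(self, toy_catalog):
        assert match_barcode(TOY_UPTAGS[2], toy_catalog) == "S3"

    def test_single_mismatch_unique_best(self, toy_catalog):
        probe = "C" + TOY_UPTAGS[0][1:]
        assert match_barcode(probe, toy_catalog, max_mismatch=2) == "S1"

    def test_equidistant_hits_ambiguous(self):
        cat = BarcodeCatalog(
            ["a", "b"], ["ga", "gb"],
            ["AAAAAAAAAAAAAAAAAAAA", "AAAACCCCAAAAAAAAAAAA"],  # distance 4
        )
        probe = "AAAACCAAAAAAAAAAAAAA"  # Hamming 2 from both
        assert match_barcode(probe, cat, max_mismatch=2) == AMBIGUOUS

    def test_beyond_tolerance_unmatched(self, toy_catalog):
        probe = TOY_UPTAGS[0][:17] + "CCC"  # Hamming 3 from nearest (S1)
        assert match_barcode(probe, toy_catalog, max_mismatch=2) == UNMATCHED

    def test_n_containing_barcode_unmatched(self, toy_catalog):
        probe = "N" + TOY_UPTAGS[0][1:]
        assert match_barcode(probe, toy_catalog, max_mismatch=2) == UNMATCHED

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_agrees_with_exhaustive_scan(self, seed):
        """Brute-force all-entries Hamming oracle on random probes."""
        rng = np.random.default_rng(seed)
        cat = build_library(50, seed=17)
        probes = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(30)]
        for probe in probes:
            dists = [sum(a != b for a, b in zip(probe, u)) for u in cat.uptags]
            best = min(dists)
            expected = (
                UNMATCHED if best > 2
                else AMBIGUOUS if dists.count(best) > 1
                else cat.strain_ids[dists.index(best)]
            )
            assert match_barcode(probe, cat, max_mismatch=2) == expected


class TestCountBarcodes:
    def test_shared_screen_ledger_balances(self, small_screen):
        counts, stats = count_barcodes(
            small_screen["design"], small_screen["catalog"]
        )
        # 0.1% per-base error: ledger must balance even when counts differ
        stats.validate()
        assert set(counts.index) == set(small_screen["catalog"].strain_ids)

    def test_zero_error_counts_equal_multinomial_draw(self, tmp_path):
        from bartox.simulate import SimulationConfig, simulate_screen

        cfg = SimulationConfig(n_strains=40, n_suppressors=4, n_enhancers=4,
                               depth=20_000, seq_error_rate=0.0, seed=3)
        catalog, design, _, true_counts = simulate_screen(cfg, tmp_path)
        counts, stats = count_barcodes(design, catalog)
        pd.testing.assert_frame_equal(
            counts, true_counts.astype(counts.dtypes.iloc[0]), check_names=False
        )
        pf = stats.per_file
        assert (pf["reads_assigned"] == pf["reads_total"]).all()

    def test_empty_fastq_gives_zero_column(self, toy_catalog, toy_design):
        for path in toy_design["fastq"]:
            open(path, "wb").close()
        counts, stats = count_barcodes(toy_design, toy_catalog)
        assert (counts == 0).all().all()
        assert (stats.per_file["reads_total"] == 0).all()
        stats.validate()

    def test_ledger_identity_with_noisy_reads(self, tmp_path):
        from bartox.simulate import SimulationConfig, simulate_screen

        cfg = SimulationConfig(n_strains=30, n_suppressors=3, n_enhancers=3,
                               depth=1000, seq_error_rate=0.01, seed=21)
        catalog, design, _, _ = simulate_screen(cfg, tmp_path)
        _, stats = count_barcodes(design, catalog)
        stats.validate()
        ps = stats.per_sample
        assert (
            ps["barcodes_matched"] + ps["barcodes_ambiguous"]
            + ps["barcodes_unmatched"]
        ).equals(ps["reads_assigned"])

    def test_order_independence(self, tmp_path, toy_catalog, toy_design):
        rng = np.random.default_rng(5)
        design = toy_design.iloc[:1].copy()
        reads = [make_read("AACCGG", TOY_UPTAGS[rng.integers(4)])
                 for _ in range(200)]
        for name, ordering in (("fwd.fastq", reads), ("rev.fastq", reads[::-1])):
            with open(tmp_path / name, "w") as fh:
                for i, r in enumerate(ordering):
                    fh.write(f"@r{i}\n{r}\n+\n{'I' * len(r)}\n")
        a = design.copy(); a["fastq"] = str(tmp_path / "fwd.fastq")
        b = design.copy(); b["fastq"] = str(tmp_path / "rev.fastq")
        ca, _ = count_barcodes(a, toy_catalog)
        cb, _ = count_barcodes(b, toy_catalog)
        assert (ca.to_numpy() == cb.to_numpy()).all()

    def test_vectorized_path_agrees_with_per_read_functions(
        self, tmp_path, toy_catalog, toy_design
    ):
        """Cross-check the batched counter against the scalar operations."""
        rng = np.random.default_rng(8)
        design = toy_design.copy()
        design["fastq"] = str(tmp_path / "pool.fastq")
        bases = np.array(list("ACGT"))
        reads = []
        for _ in range(500):
            tag = design["fwd_tag"].iloc[rng.integers(4)]
            read = list(make_read(tag, TOY_UPTAGS[rng.integers(4)]))
            for pos in rng.integers(0, len(read), rng.integers(0, 4)):
                read[pos] = bases[rng.integers(4)]
            reads.append("".join(read))
        with open(design["fastq"].iloc[0], "w") as fh:
            for i, r in enumerate(reads):
                fh.write(f"@r{i}\n{r}\n+\n{'I' * len(r)}\n")

        counts, stats = count_barcodes(design, toy_catalog)

        expected = counts.copy(); expected.loc[:, :] = 0
        for r in reads:
            res = demultiplex_read(r, STRUCT, design)
            if res.status != "assigned":
                continue
            hit = match_barcode(res.barcode, toy_catalog, max_mismatch=2)
            if hit not in (UNMATCHED, AMBIGUOUS):
                expected.loc[hit, f"{res.sample[0]}_{res.sample[1]}"] += 1
        assert (counts.to_numpy() == expected.to_numpy()).all()
        stats.validate()


class TestFastqIO:
    def test_round_trip_and_gzip(self, tmp_path, rng):
        mat = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), (10, 45))
        for name in ("r.fastq", "r.fastq.gz"):
            path = tmp_path / name
            write_fastq(path, mat, "s")
            seqs = read_fastq_seqs(path)
            assert len(seqs) == 10
            assert np.array_equal(
                np.frombuffer(b"".join(seqs), dtype=np.uint8).reshape(10, 45), mat
            )

    def test_matches_biopython_parse(self, tmp_path, rng):
        from Bio import SeqIO

        mat = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), (25, 45))
        path = tmp_path / "oracle.fastq"
        write_fastq(path, mat, "sample")
        records = list(SeqIO.parse(path, "fastq"))
        assert [str(r.seq).encode() for r in records] == read_fastq_seqs(path)
        assert all(
            q == 40 for r in records for q in r.letter_annotations["phred_quality"]
        )

    @pytest.mark.parametrize(
        "content, lineno",
        [
            ("@r0\nACGT\n+\nIIII\n@r1\nACGT\n", 5),        # truncated record
            ("r0\nACGT\n+\nIIII\n", 1),                     # bad header
            ("@r0\nACGT\nX\nIIII\n", 3),                    # bad separator
            ("@r0\nACGT\n+\nIII\n", 4),                     # qual length mismatch
        ],
    )
    def test_malformed_fastq_reports_line_number(self, tmp_path, content, lineno):
        path = tmp_path / "bad.fastq"
        path.write_text(content)
        with pytest.raises(FastqFormatError, match=f"line {lineno}"):
            read_fastq_seqs(path)
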