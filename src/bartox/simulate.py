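"""Synthetic pooled Bar-seq screen generator.

Emulates the pooled competition experiment: a barcoded homozygous-diploid
deletion library (default 4653 strains) carrying a galactose-inducible toxic
human "query" gene competes in glucose (query off, GLU) and galactose (query
on, GAL).  Strains deleted for a toxicity suppressor outgrow the pool under
induction; enhancer deletions fall behind.  Uptag amplicons are then
synthesized as multiplexed single-end reads with per-base substitution error,
alongside a ground-truth table for benchmarking the downstream caller.

Growth is deterministic exponential competition, a_i(t) ∝ a_i(0)·2^(f_i·t);
sequencing sampling (multinomial draw per sample) supplies the noise.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import BASES, BASE_LUT, BarcodeCatalog, random_codes

#: common primers flanking the uptag in the composite amplification primers;
#: reads carry the forward one, the reverse tag never appears in sequenced bases
FWD_COMMON = "GATGTCCACGAGGTCTCT"
REV_COMMON = "GTCGACCTGCAGCGTACG"
FIXED_PREFIX = "G"
TAG_LENGTH = 6
READ_LENGTH = 1 + TAG_LENGTH + len(FWD_COMMON) + 20  # 45

CONDITIONS = ("GLU", "GAL")
CLASSES = ("suppressor", "enhancer", "no_effect")


def fold_coverage(colonies: float, plated_fraction: float, library_size: int) -> float:
    """Library fold-coverage implied by a transformation-efficiency plating.

    Plating ``plated_fraction`` of the transformation mix and counting
    ``colonies`` implies ``colonies / plated_fraction`` total transformants;
    dividing by the library size gives how many independent transformants
    cover each strain on average.
    """
    if not 0 < plated_fraction <= 1:
        raise ValueError("plated_fraction must be in (0, 1]")
    if colonies < 0 or library_size <= 0:
        raise ValueError("colonies must be >= 0 and library_size positive")
    return colonies / plated_fraction / library_size


@dataclass
class SimulationConfig:
    """Knobs of the synthetic screen.

    Fitness values are relative growth rates (1.0 = wild-type-like);
    ``generations`` counts pool doublings during induction, standing in for the
    2-day galactose culture.  ``baseline_gal`` is the pool-wide rate under
    query toxicity; suppressor/enhancer effects are added/subtracted from it.
    """

    n_strains: int = 4653
    n_suppressors: int = 10
    n_enhancers: int = 10
    suppressor_effect: float = 0.3
    enhancer_effect: float = 0.3
    baseline_gal: float = 0.5
    generations: float = 10.0
    depth: int = 1_000_000
    seq_error_rate: float = 0.001
    seed: int = 0
    queries: tuple[str, ...] = ("QUERY1",)

    def validate(self) -> None:
        if self.n_strains < 1:
            raise ValueError("n_strains must be >= 1")
        if self.n_suppressors < 0 or self.n_enhancers < 0:
            raise ValueError("class counts must be non-negative")
        if self.n_suppressors + self.n_enhancers > self.n_strains:
            raise ValueError("n_suppressors + n_enhancers exceeds n_strains")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if not 0 <= self.seq_error_rate < 1:
            raise ValueError("seq_error_rate must be in [0, 1)")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.baseline_gal <= 0:
            raise ValueError("baseline_gal must be positive")
        if self.enhancer_effect >= self.baseline_gal:
            raise ValueError(
                "enhancer_effect >= baseline_gal would give non-positive fitness"
            )
        if self.suppressor_effect < 0 or self.enhancer_effect < 0:
            raise ValueError("effect sizes must be non-negative")
        if not self.queries:
            raise ValueError("at least one query gene required")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["queries"] = list(self.queries)
        return d


def build_library(n_strains: int, seed: int) -> BarcodeCatalog:
    """Generate a barcoded deletion library.

    Uptags are rejection-sampled 20-mers with pairwise Hamming distance >= 3,
    so single-mismatch barcode assignment is unambiguous.  Deterministic for a
    fixed seed; raises RuntimeError if the distance constraint cannot be met
    within the attempt cap.
    """
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    rng = np.random.default_rng(seed)
    uptags = random_codes(n_strains, 20, 3, rng)
    width = len(str(n_strains))
    strain_ids = [f"S{i + 1:0{width}d}" for i in range(n_strains)]
    yeast_genes = [f"Y{i + 1:0{width}d}" for i in range(n_strains)]
    return BarcodeCatalog(strain_ids, yeast_genes, uptags)


def assign_effects(catalog: BarcodeCatalog, config: SimulationConfig) -> pd.DataFrame:
    """Assign modifier classes and fitness values to the library.

    Returns the truth table: one row per strain with columns ``strain_id``,
    ``yeast_gene``, ``true_class``, ``fitness_glu``, ``fitness_gal``.  Control
    fitness is 1.0 for every strain; under induction, suppressor deletions run
    at baseline + suppressor_effect and enhancer deletions at
    baseline - enhancer_effect.
    """
    config.validate()
    n = len(catalog)
    if n != config.n_strains:
        raise ValueError("catalog size does not match config.n_strains")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    order = rng.permutation(n)
    classes = np.full(n, "no_effect", dtype=object)
    classes[order[: config.n_suppressors]] = "suppressor"
    classes[order[config.n_suppressors : config.n_suppressors + config.n_enhancers]] = (
        "enhancer"
    )
    fitness_gal = np.full(n, config.baseline_gal)
    fitness_gal[classes == "suppressor"] += config.suppressor_effect
    fitness_gal[classes == "enhancer"] -= config.enhancer_effect
    return pd.DataFrame(
        {
            "strain_id": catalog.strain_ids,
            "yeast_gene": catalog.yeast_genes,
            "true_class": classes,
            "fitness_glu": 1.0,
            "fitness_gal": fitness_gal,
        }
    )


def simulate_growth(
    effects: pd.DataFrame, generations: float, condition: str
) -> np.ndarray:
    """Relative abundances after pooled competition.

    All strains start at equal abundance; strain i ends proportional to
    2^(fitness_i * generations).  The returned fractions sum to 1.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    if len(effects) == 0:
        raise ValueError("empty effect table")
    if generations < 0:
        raise ValueError("generations must be >= 0")
    fitness = effects["fitness_glu" if condition == "GLU" else "fitness_gal"].to_numpy(
        dtype=float
    )
    log_w = fitness * generations
    log_w = log_w - log_w.max()  # stabilize before exponentiation
    w = np.exp2(log_w)
    a = w / w.sum()
    return a / a.sum()


def sample_reads(
    abundances: np.ndarray,
    catalog: BarcodeCatalog,
    fwd_tag: str,
    depth: int,
    seq_error_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize one sample's reads.

    Each read is the fixed base 'G' + the sample's forward 6-mer index tag +
    the 18-base common primer + the sampled strain's 20-mer uptag; the strain
    of each read is a multinomial draw from ``abundances`` and every base is
    substituted independently with probability ``seq_error_rate``.

    Returns ``(reads, true_counts)`` where ``reads`` is an
    (depth, 45) uint8 byte matrix in randomized order and ``true_counts`` the
    underlying per-strain multinomial draw.
    """
    n = len(catalog)
    if len(abundances) != n:
        raise ValueError("abundance vector does not match catalog size")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if len(fwd_tag) != TAG_LENGTH or any(c not in "ACGT" for c in fwd_tag):
        raise ValueError(f"fwd_tag must be {TAG_LENGTH} bases over ACGT")
    counts = rng.multinomial(depth, abundances)
    strain_idx = np.repeat(np.arange(n), counts)
    rng.shuffle(strain_idx)

    reads = np.empty((depth, READ_LENGTH), dtype=np.uint8)
    reads[:, 0] = ord(FIXED_PREFIX)
    reads[:, 1 : 1 + TAG_LENGTH] = np.frombuffer(fwd_tag.encode(), dtype=np.uint8)
    reads[:, 1 + TAG_LENGTH : 1 + TAG_LENGTH + len(FWD_COMMON)] = np.frombuffer(
        FWD_COMMON.encode(), dtype=np.uint8
    )
    reads[:, 25:] = catalog.uptag_matrix()[strain_idx]

    if seq_error_rate > 0 and depth > 0:
        mask = rng.random(reads.shape) < seq_error_rate
        n_err = int(mask.sum())
        if n_err:
            idx = BASE_LUT[reads[mask]].astype(np.int64)
            idx = (idx + rng.integers(1, 4, size=n_err)) % 4
            reads[mask] = BASES[idx]
    return reads, counts


def make_design(
    queries: tuple[str, ...], outdir: Path, seed: int
) -> pd.DataFrame:
    """Multiplex design sheet: one (fwd_tag, rev_tag) combination per sample.

    Forward tags are distinct per sample and mutually at Hamming >= 3 (so
    1-mismatch tag assignment stays unique); each query gets one reverse tag
    shared by its two conditions, mirroring the two-tag combination scheme.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    n_samples = len(queries) * 2
    fwd_tags = random_codes(n_samples, TAG_LENGTH, 3, rng)
    rev_tags = random_codes(len(queries), TAG_LENGTH, 3, rng)
    rows = []
    i = 0
    for qi, query in enumerate(queries):
        for condition in CONDITIONS:
            rows.append(
                {
                    "query": query,
                    "condition": condition,
                    "fwd_tag": fwd_tags[i],
                    "rev_tag": rev_tags[qi],
                    "fastq": str(Path(outdir) / f"{query}_{condition}.fastq"),
                }
            )
            i += 1
    return pd.DataFrame(rows)


def write_truth(effects: pd.DataFrame, path) -> None:
    """Write the ground-truth table as TSV (lossless round trip)."""
    if len(effects) == 0:
        raise ValueError("empty effect table")
    effects.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    bad = set(df["true_class"]) - set(CLASSES)
    if bad:
        raise ValueError(f"unknown true_class values in {path}: {sorted(bad)}")
    return df


def simulate_screen(
    config: SimulationConfig, outdir
) -> tuple[BarcodeCatalog, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the full generator and write all artifacts to ``outdir``.

    Writes ``catalog.tsv``, ``design.tsv``, ``truth.tsv`` and one FASTQ per
    (query, condition) sample.  Returns (catalog, design, truth, true_counts)
    where ``true_counts`` holds the per-sample multinomial draws — the counts
    a lossless demultiplexer must reproduce exactly at zero sequencing error.

    Identical config (including seed) gives byte-identical FASTQ output.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    catalog = build_library(config.n_strains, config.seed)
    truth = assign_effects(catalog, config)
    design = make_design(config.queries, outdir, config.seed)

    from .fastq import write_fastq  # local import to avoid cycle at module load

    true_counts = pd.DataFrame(index=pd.Index(catalog.strain_ids, name="strain_id"))
    for row_i, row in enumerate(design.itertuples(index=False)):
        abund = simulate_growth(truth, config.generations, row.condition)
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3, row_i]))
        reads, counts = sample_reads(
            abund, catalog, row.fwd_tag, config.depth, config.seq_error_rate, rng
        )
        sample_id = f"{row.query}_{row.condition}"
        write_fastq(row.fastq, reads, sample_id)
        true_counts[sample_id] = counts

    catalog.write_tsv(outdir / "catalog.tsv")
    design.to_csv(outdir / "design.tsv", sep="\t", index=False)
    write_truth(truth, outdir / "truth.tsv")
    return catalog, design, truth, true_counts
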