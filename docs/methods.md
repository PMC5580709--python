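# Methods

This note records the models, conventions and numerical choices behind
`bartox`, and what the synthetic benchmark does and does not establish.

## Screen model and statistic chain

**Base quantity.** The screen compares each strain's abundance between the
induced (GAL) and control (GLU) pools of the same query. Scores are computed
on the per-strain log2 GAL/GLU ratio of normalized counts rather than on the
GAL sample alone: the ratio cancels strain-intrinsic abundance differences
(pool composition, barcode amplification efficiency) that are constant across
conditions, which is exactly the nuisance a paired control condition exists
to remove.

**Normalization.** The default is the divide-by-average rule: each sample
column is divided by its mean barcode count, giving every sample mean 1. A
classical quantile-normalization mode (`method="quantile"`; sorted values
replaced by across-sample means of sorted values, ties averaged, rescaled to
mean 1) is available for comparison when library-size scaling alone is not
trusted; the two agree when count distributions differ only by scale.

**Pseudocount.** 0.5 is added to raw counts in the ratio and in the error
propagation, expressed on the normalized scale as `0.5 / (sample raw mean)`.
This keeps zero-count strains finite and strongly negative rather than
infinite. The cost is exact scale invariance: multiplying a sample's counts
by k perturbs z by O(pc/(k·n̄)) — about 10⁻³ at typical depths, zero when the
pseudocount is disabled.

**Standardization.** Plain mean and n−1 standard deviation across strains.
With many strong effects the sd is inflated by the tails, which makes the
default conservative; a median/MAD mode (`robust=True`, MAD scaled by 1.4826)
is available. The default matches the fixed ±1.96 decision rule the screen
uses; no multiple-testing correction is applied by default, though
Benjamini–Hochberg q-values on two-sided normal p-values can be appended
(`fdr=True`) for users who prefer an FDR view.

**Error propagation.** Barcode counting noise is modeled as Poisson: a count
n has relative error `1/sqrt(n + pc)`. By the delta method the absolute error
of the log2 ratio is `δ = (1/ln2)·sqrt(1/(n_GAL+pc) + 1/(n_GLU+pc))`, the
error of z is `δ/sd(L)`, and the error *rate* is that divided by |z| (defined
as 1 when z = 0 — a zero score is fully uncertain). The corrected score is
`(1 ± rate)·z`. The rate is stored uncapped so the upper bound faithfully
widens with noise, but the factor in the lower bound is capped at 1:
the toward-zero bound may shrink a score to zero, never flip its sign.
Classification uses the lower bound, so uncertainty can only remove hits.
This is one defensible realization of "error propagation from the counting
error"; the exact chain is an interpretation, recorded here as the package's
design choice.

**Thresholds.** ±1.96 — the two-sided 5% critical values of the standard
normal — with strict inequalities, so a corrected score exactly at the cut is
no-effect. Configurable via `Thresholds`.

## Demultiplexing conventions

Reads are fixed-structure amplicons; coordinates are fixed, not searched:
positions 2–7 (1-based) hold the index tag, 8–25 the common primer, 26–45 the
uptag. Defaults: tag Hamming ≤ 1 with a unique best design tag (the simulator
generates tags at pairwise distance ≥ 3, so one mismatch is always
unambiguous), primer Hamming ≤ 2 (18 anchored bases tolerate two errors
without risking misassignment), barcode exact match first, then unique best
hit within Hamming ≤ 2 (catalog minimum pairwise distance 3 guarantees
1-mismatch uniqueness; at distance 2 ties are declared ambiguous and excluded
from counts but tallied). Reads with any non-ACGT base in the barcode window
are unmatched, not error-corrected. The leading fixed 'G' is synthesis
scaffold, not an informative position, and is not checked. Only the forward
read is parsed; the reverse tag exists in the design sheet for sample
bookkeeping but never appears in sequenced bases. Every read lands in exactly
one ledger category (assigned / too short / tag fail / primer fail), and
assigned reads in exactly one barcode category (matched / ambiguous /
unmatched); the `DemuxStats` ledger is validated to balance.

## Synthetic-data generator

The generator emulates the pooled competition experiment so the whole
pipeline can be tested against known ground truth.

- **Library**: rejection-sampled 20-mer uptags with minimum pairwise Hamming
  distance 3 (attempt cap 10⁶), default 4653 strains.
- **Effects**: control fitness 1.0 for every strain. Under induction the pool
  baseline is 0.5 (the toxic query slows everyone); suppressor deletions run
  at baseline + 0.3, enhancers at baseline − 0.3. One effect table is shared
  across all simulated queries of a run.
- **Growth**: deterministic exponential competition,
  `a_i ∝ 2^(f_i·g)`, default g = 10 doublings standing in for the two-day
  induction culture. Growth is noiseless by design — the monotone
  fitness→abundance link is the assumption the statistic chain relies on, and
  sequencing sampling supplies the noise.
- **Sequencing**: per-sample multinomial draw of `depth` reads (default 10⁶),
  independent uniform base substitutions at `seq_error_rate` (default 0.001,
  a typical short-read figure), constant Q40 qualities (never consumed).
  No indels, PCR jackpots, paired ends or depth variation.
- **Determinism**: one seed, split per stage via `SeedSequence`; identical
  configs give byte-identical FASTQ.

Depth and generations are not experimentally reported quantities; the
defaults above are the package's own realistic choices and are configurable.

**What passing the benchmark shows — and does not.** With 200 strains,
10+10 planted modifiers, ±0.3 effects and 10⁶ reads, suppressor recall ≥ 0.9
at FDP ≤ 0.2 in ≥ 18/20 seeds demonstrates that the statistic chain recovers
the signal its own growth model plants, through the full FASTQ round trip.
It does not certify performance on real screens, where PCR bias,
transformation bottlenecks, growth stochasticity and strain-specific
amplification violate the generator's assumptions. Notably, the clean
generator recovers enhancers as well as suppressors; the empirical
unreliability of enhancer detection in real screens (baseline toxicity so
strong that further depletion saturates) is *not* reproduced, which is why
the benchmark constrains only the suppressor metrics and the interaction
network is built from suppressors alone.

## Network stage

Suppressor calls are joined to a user-supplied yeast→human ortholog table; a
yeast gene with k orthologs yields k candidate edges, each tagged with its
source (canonically `inparanoid`, `homologene` or `other`; other tokens are
accepted with a warning, and a source filter is available rather than
enforcing agreement between databases). Suppressors with no ortholog entry go
to an explicit unmapped report. Nodes are typed `disease_gene` /
`human_ortholog`, edges `genetic_suppression` / `imported` (imported edges —
e.g. literature protein–protein interactions — pass through untouched).
Duplicate interactions collapse onto one edge that accumulates its supporting
yeast genes. Exports (GraphML via networkx, SIF, TSV) are canonicalized —
nodes and edge endpoints sorted — so GraphML round-trips are byte-stable and
all formats carry identical node/edge sets.

Enrichment is a plain hypergeometric upper tail (`P(X ≥ hits)`) against a
user-supplied category→gene annotation and universe, with Benjamini–Hochberg
q-values across categories. It is generic plumbing, not a reimplementation of
any proprietary annotation service.

## Degenerate inputs and tie-breaking

- All-zero sample column: hard error naming the sample (normalization
  undefined).
- sd(log-ratio) = 0: hard error (a screen with no spread is degenerate).
- Fewer than 3 strains: rejected for standardization.
- Tag or barcode distance ties: unassigned / ambiguous, never arbitrary.
- `z = 0`: error rate 1 by convention; both corrected bounds are 0.
- Ambiguous barcodes are excluded from counts but appear in the ledger.

## Problem sizes

The test suite and the reproduction script run the benchmark at 200 strains
and 10⁶ reads per sample (20 seeds in the suite, 5 in the script), the demux
round-trip checks at 10⁵ reads, and the enrichment enumeration sweep at
universes up to 15 genes — sizes chosen so the full suite completes in a few
minutes on a single core while still exercising every code path at realistic
per-sample depth.

## Known limitations

- Single-end, fixed-structure reads only; no adapter trimming, quality
  filtering or indel tolerance.
- No replicate-aware variance model (the screen design has no replicates);
  the Poisson chain understates overdispersion of real amplicon counts.
- One effect table per run across queries; per-query modifier sets require
  separate runs.
- Gene identifiers are opaque case-sensitive strings; no symbol
  normalization is attempted (fully offline operation).
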