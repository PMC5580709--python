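"""Ground-truth benchmarking of the full screen pipeline.

Runs the generator's study conditions end to end — synthetic FASTQ through
demultiplexing and Z-scoring — and scores the calls against the generator's
truth table.  Used by the test suite and the reproduction script; useful for
gauging how parameter changes (depth, effect size, error rate) move recall.
"""

from __future__ import annotations

import shutil
import tempfile
from dataclasses import replace

from .demux import count_barcodes
from .simulate import SimulationConfig, simulate_screen
from .stats import Thresholds, score_screen

#: the benchmark's reference screen: 200 strains, 10 suppressors at +0.3 over
#: a 0.5 induced baseline, 10 enhancers at -0.3, 10 doublings, one million
#: reads per sample, 0.1% per-base error
RECOVERY_CONFIG = SimulationConfig(
    n_strains=200,
    n_suppressors=10,
    n_enhancers=10,
    suppressor_effect=0.3,
    enhancer_effect=0.3,
    baseline_gal=0.5,
    generations=10.0,
    depth=1_000_000,
    seq_error_rate=0.001,
)


def run_recovery_trial(
    seed: int,
    config: SimulationConfig = RECOVERY_CONFIG,
    thresholds: Thresholds | None = None,
    workdir=None,
) -> dict:
    """One simulate→demux→score round trip scored against the truth table.

    Returns per-class recall and the suppressor false-discovery proportion
    (FDP = false suppressor calls / all suppressor calls, 0 when nothing is
    called).  FASTQ intermediates go to ``workdir`` (a temporary directory by
    default, removed afterwards).
    """
    config = replace(config, seed=seed)
    tmp = None
    if workdir is None:
        tmp = workdir = tempfile.mkdtemp(prefix="bartox-recovery-")
    try:
        catalog, design, truth, _ = simulate_screen(config, workdir)
        counts, _ = count_barcodes(design, catalog)
        ztable = score_screen(
            counts, gene_map=catalog.gene_map(), thresholds=thresholds
        )
    finally:
        if tmp is not None:
            shutil.rmtree(tmp, ignore_errors=True)

    query = config.queries[0]
    calls = ztable[ztable["query"] == query].set_index("strain_id")["label"]
    truth_by_strain = truth.set_index("strain_id")["true_class"]

    def class_sets(name):
        true = set(truth_by_strain[truth_by_strain == name].index)
        called = set(calls[calls == name].index)
        return true, called

    sup_true, sup_called = class_sets("suppressor")
    enh_true, enh_called = class_sets("enhancer")
    return {
        "seed": seed,
        "suppressor_recall": (
            len(sup_true & sup_called) / len(sup_true) if sup_true else float("nan")
        ),
        "suppressor_fdp": (
            len(sup_called - sup_true) / len(sup_called) if sup_called else 0.0
        ),
        "enhancer_recall": (
            len(enh_true & enh_called) / len(enh_true) if enh_true else float("nan")
        ),
        "n_suppressor_calls": len(sup_called),
        "n_enhancer_calls": len(enh_called),
    }
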