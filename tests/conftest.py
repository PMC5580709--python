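"""Shared fixtures: small hand-built catalogs and one reusable synthetic screen."""

import numpy as np
import pandas as pd
import pytest

from bartox.catalog import BarcodeCatalog
from bartox.simulate import FWD_COMMON, SimulationConfig, simulate_screen

# four uptags mutually at Hamming distance >= 3 (prefix blocks differ)
TOY_UPTAGS = [
    "AAAAAAAAAAAAAAAAAAAA",
    "CCCCAAAAAAAAAAAAAAAA",
    "GGGGGGGGAAAAAAAAAAAA",
    "TTTTTTTTTTTTAAAAAAAA",
]


@pytest.fixture
def toy_catalog() -> BarcodeCatalog:
    return BarcodeCatalog(
        strain_ids=[f"S{i}" for i in range(1, 5)],
        yeast_genes=["MKK1", "CKB2", "YAP1801", "MDE1"],
        uptags=TOY_UPTAGS,
    )


@pytest.fixture
def toy_design(tmp_path) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "query": ["OPTN", "OPTN", "ANG", "ANG"],
            "condition": ["GLU", "GAL", "GLU", "GAL"],
            "fwd_tag": ["AACCGG", "TTGGCC", "ACACAC", "GTGTGT"],
            "rev_tag": ["CGCGCG", "CGCGCG", "ATATAT", "ATATAT"],
            "fastq": [str(tmp_path / f"{q}_{c}.fastq")
                      for q, c in zip(["OPTN", "OPTN", "ANG", "ANG"],
                                      ["GLU", "GAL", "GLU", "GAL"])],
        }
    )


def make_read(fwd_tag: str, uptag: str) -> str:
    """Well-formed amplicon read for the given tag and barcode."""
    return "G" + fwd_tag + FWD_COMMON + uptag


@pytest.fixture(scope="session")
def small_screen(tmp_path_factory):
    """A 50-strain simulated screen shared across read-only tests."""
    outdir = tmp_path_factory.mktemp("screen")
    config = SimulationConfig(
        n_strains=50, n_suppressors=5, n_enhancers=5, depth=50_000,
        seq_error_rate=0.001, seed=11,
    )
    catalog, design, truth, true_counts = simulate_screen(config, outdir)
    return {
        "config": config, "outdir": outdir, "catalog": catalog,
        "design": design, "truth": truth, "true_counts": true_counts,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
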