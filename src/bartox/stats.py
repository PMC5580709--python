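"""Per-strain modifier calling from barcode counts.

The screen's statistic chain, per query gene:

1. Normalize each sample column by its mean barcode count, so every sample is
   on a common scale with mean 1.
2. For each strain, take the log2 ratio of normalized GAL (query induced) over
   GLU (control) abundance, with a pseudocount guarding zero counts.
3. Standardize the log-ratios across strains into a Z-score.
4. Propagate Poisson counting error of the raw barcode numbers into a relative
   error of the Z-score, and form the corrected scores
   (1 ± error_rate) × Z.  The low (toward-zero) bound shrinks the score and
   never crosses zero; classification uses it, so uncertain counts can only
   remove hits, never add them.
5. Call suppressors (corrected Z > 1.96), enhancers (corrected Z < −1.96) and
   no-effect strains — the two-sided 5% standard-normal cuts.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import CLASSES, CONDITIONS

LN2 = math.log(2.0)


@dataclass
class Thresholds:
    """Classification cuts and the zero-count guard."""

    suppressor_cut: float = 1.96
    enhancer_cut: float = -1.96
    pseudocount: float = 0.5

    def validate(self) -> None:
        if not self.suppressor_cut > 0 > self.enhancer_cut:
            raise ValueError("need suppressor_cut > 0 > enhancer_cut")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


def normalize_counts(counts: pd.DataFrame, method: str = "mean") -> pd.DataFrame:
    """Normalize a strains × samples count matrix.

    ``method="mean"`` (default): divide each column by its mean barcode count,
    so every sample's normalized mean is exactly 1.  ``method="quantile"``:
    classical quantile normalization (each column's sorted values replaced by
    the across-sample mean of sorted values), then rescaled to mean 1 so both
    modes share the output convention.

    The raw column means are stashed in ``result.attrs["raw_mean"]`` — the
    downstream pseudocount must be expressed on the normalized scale.
    """
    if (counts < 0).any().any():
        raise ValueError("counts must be non-negative")
    col_means = counts.mean(axis=0)
    zero_cols = col_means[col_means == 0]
    if len(zero_cols):
        raise ValueError(f"all-zero sample column(s): {list(zero_cols.index)}")
    if method == "mean":
        norm = counts / col_means
    elif method == "quantile":
        ranked = counts.rank(method="average")
        sorted_mean = pd.DataFrame(
            np.sort(counts.to_numpy(dtype=float), axis=0), columns=counts.columns
        ).mean(axis=1)
        # interpolate rank -> reference quantile, averaging ties
        ref = sorted_mean.to_numpy()
        norm = ranked.apply(lambda r: np.interp(r, np.arange(1, len(ref) + 1), ref))
        norm = norm / norm.mean(axis=0)
        norm.index = counts.index
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    norm.attrs["raw_mean"] = col_means
    return norm


def _sample_cols(norm: pd.DataFrame, query: str) -> tuple[str, str]:
    glu, gal = f"{query}_GLU", f"{query}_GAL"
    for col in (glu, gal):
        if col not in norm.columns:
            raise ValueError(f"missing sample column {col!r}")
    return glu, gal


def compute_zscores(
    norm: pd.DataFrame,
    query: str,
    pseudocount: float = 0.5,
    robust: bool = False,
) -> pd.DataFrame:
    """Per-strain log-ratio and Z-score for one query gene.

    ``log_ratio = log2((v_GAL + pc_GAL) / (v_GLU + pc_GLU))`` where ``v`` is
    the normalized abundance and ``pc`` the pseudocount expressed on the
    normalized scale (raw pseudocount divided by the sample's raw mean count).
    ``z`` standardizes the log-ratios across strains with the plain mean and
    n−1 standard deviation; ``robust=True`` uses median and scaled MAD
    instead (effect-laden tails inflate the plain sd).

    The across-strain spread of the log-ratio is stashed in
    ``result.attrs["sd_logratio"]`` for error propagation.
    """
    if len(norm) < 3:
        raise ValueError("need at least 3 strains to standardize")
    glu, gal = _sample_cols(norm, query)
    raw_mean = norm.attrs.get("raw_mean")
    s_glu = pseudocount / raw_mean[glu] if raw_mean is not None else pseudocount
    s_gal = pseudocount / raw_mean[gal] if raw_mean is not None else pseudocount
    lr = np.log2((norm[gal] + s_gal) / (norm[glu] + s_glu))
    if robust:
        center = float(lr.median())
        sd = 1.4826 * float((lr - center).abs().median())
    else:
        center = float(lr.mean())
        sd = float(lr.std(ddof=1))
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"degenerate screen for query {query!r}: sd(log_ratio) = 0")
    out = pd.DataFrame({"log_ratio": lr, "z": (lr - center) / sd}, index=norm.index)
    out.attrs["sd_logratio"] = sd
    return out


def estimate_error_rate(
    n_glu, n_gal, z, sd_logratio: float, pseudocount: float = 0.5
):
    """Relative error of the Z-score, propagated from Poisson counting noise.

    A barcode number n has Poisson relative error 1/sqrt(n + pc); the absolute
    error of the log2 ratio is δ = (1/ln 2)·sqrt(1/(n_GAL+pc) + 1/(n_GLU+pc)),
    the error of z is δ/sd(log_ratio), and the relative error rate is that
    divided by |z|.  A z of exactly 0 is fully uncertain (error rate 1).
    The rate is returned uncapped; the toward-zero corrected bound applies the
    cap (see :func:`correct_zscores`).
    """
    n_glu = np.asarray(n_glu, dtype=float)
    n_gal = np.asarray(n_gal, dtype=float)
    z = np.asarray(z, dtype=float)
    if (n_glu < 0).any() or (n_gal < 0).any():
        raise ValueError("counts must be non-negative")
    if not sd_logratio > 0:
        raise ValueError("sd_logratio must be positive")
    delta = np.sqrt(1.0 / (n_gal + pseudocount) + 1.0 / (n_glu + pseudocount)) / LN2
    z_err = delta / sd_logratio
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(z != 0, z_err / np.abs(z), 1.0)
    return rate


def correct_zscores(z, error_rate):
    """Corrected Z-score bounds, (1 ± error rate) × Z.

    The low bound shrinks toward (at most to) zero — the error-rate factor is
    capped at 1 so the correction can never flip the sign; the high bound is
    uncapped.
    """
    z = np.asarray(z, dtype=float)
    error_rate = np.asarray(error_rate, dtype=float)
    if (error_rate < 0).any():
        raise ValueError("error_rate must be >= 0")
    low = (1.0 - np.minimum(error_rate, 1.0)) * z
    high = (1.0 + error_rate) * z
    return low, high


def classify_modifiers(
    records: pd.DataFrame, thresholds: Thresholds | None = None
) -> pd.DataFrame:
    """Label each strain from its conservative corrected Z-score.

    suppressor iff z_corrected_low > suppressor_cut, enhancer iff
    z_corrected_low < enhancer_cut (strict inequalities, so a score exactly at
    the cut is no_effect); everything else no_effect.  The labels partition
    the strains.
    """
    thresholds = thresholds or Thresholds()
    thresholds.validate()
    zlow = records["z_corrected_low"]
    label = np.where(
        zlow > thresholds.suppressor_cut,
        "suppressor",
        np.where(zlow < thresholds.enhancer_cut, "enhancer", "no_effect"),
    )
    out = records.copy()
    out["label"] = label
    return out


_SAMPLE_RE = re.compile(r"^(?P<query>.+)_(?P<condition>GLU|GAL)$")


def infer_queries(columns) -> list[str]:
    """Query genes present with both conditions among ``<query>_<condition>`` columns."""
    seen: dict[str, set[str]] = {}
    for col in columns:
        m = _SAMPLE_RE.match(col)
        if m:
            seen.setdefault(m.group("query"), set()).add(m.group("condition"))
    queries = [q for q, conds in seen.items() if conds == set(CONDITIONS)]
    if not queries:
        raise ValueError("no query with both GLU and GAL sample columns")
    return queries


ZTABLE_COLUMNS = [
    "strain_id",
    "yeast_gene",
    "query",
    "n_glu",
    "n_gal",
    "norm_glu",
    "norm_gal",
    "log_ratio",
    "z",
    "error_rate",
    "z_corrected_low",
    "z_corrected_high",
    "label",
]


def score_screen(
    counts: pd.DataFrame,
    gene_map: dict[str, str] | None = None,
    thresholds: Thresholds | None = None,
    robust: bool = False,
    method: str = "mean",
    fdr: bool = False,
) -> pd.DataFrame:
    """Run the whole statistic chain for every query in a count matrix.

    Returns the long-format Z-table (one row per strain per query).  With
    ``fdr=True``, two-sided normal p-values on the uncorrected z and their
    Benjamini–Hochberg q-values (per query) are appended as extra columns;
    labels are unaffected — the screen's fixed ±1.96 cut is the default
    decision rule.
    """
    thresholds = thresholds or Thresholds()
    thresholds.validate()
    norm = normalize_counts(counts, method=method)
    tables = []
    for query in infer_queries(counts.columns):
        glu, gal = f"{query}_GLU", f"{query}_GAL"
        zdf = compute_zscores(norm, query, thresholds.pseudocount, robust=robust)
        er = estimate_error_rate(
            counts[glu],
            counts[gal],
            zdf["z"],
            zdf.attrs["sd_logratio"],
            thresholds.pseudocount,
        )
        low, high = correct_zscores(zdf["z"].to_numpy(), er)
        table = pd.DataFrame(
            {
                "strain_id": counts.index,
                "yeast_gene": [
                    gene_map.get(s, s) if gene_map else s for s in counts.index
                ],
                "query": query,
                "n_glu": counts[glu].to_numpy(),
                "n_gal": counts[gal].to_numpy(),
                "norm_glu": norm[glu].to_numpy(),
                "norm_gal": norm[gal].to_numpy(),
                "log_ratio": zdf["log_ratio"].to_numpy(),
                "z": zdf["z"].to_numpy(),
                "error_rate": er,
                "z_corrected_low": low,
                "z_corrected_high": high,
            }
        )
        table = classify_modifiers(table, thresholds)
        if fdr:
            from statsmodels.stats.multitest import multipletests

            p = 2.0 * sps.norm.sf(np.abs(table["z"]))
            table["p_value"] = p
            table["q_value"] = multipletests(p, method="fdr_bh")[1]
        tables.append(table)
    out = pd.concat(tables, ignore_index=True)
    assert set(out["label"]) <= set(CLASSES)
    return out


def write_ztable(ztable: pd.DataFrame, path) -> None:
    ztable.to_csv(path, sep="\t", index=False)


def read_ztable(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(ZTABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Z-table {path} missing columns: {sorted(missing)}")
    return df
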