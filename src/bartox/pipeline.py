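"""One-config orchestration: simulate → demux → score → network.

A run takes either a simulation block (fully synthetic screen) or real FASTQ
inputs (design + catalog), never both.  Every stage writes its artifact under
the output directory and the run closes with a manifest recording the config
hash, seed, package version and a SHA-256 digest of every output, so identical
config + seed reruns are verifiably byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .catalog import BarcodeCatalog
from .demux import count_barcodes, parse_design, write_counts
from .network import (
    build_network,
    enrich_categories,
    export_network,
    load_ortholog_map,
    map_suppressors,
    read_annotation,
)
from .simulate import CLASSES, SimulationConfig, simulate_screen
from .stats import Thresholds, score_screen, write_ztable

logger = logging.getLogger(__name__)

_TOP_KEYS = {
    "seed", "outdir", "simulation", "inputs", "thresholds", "demux",
    "scoring", "network",
}
_SIM_KEYS = {
    "n_strains", "n_suppressors", "n_enhancers", "suppressor_effect",
    "enhancer_effect", "baseline_gal", "generations", "depth",
    "seq_error_rate", "queries",
}
_INPUT_KEYS = {"design", "catalog"}
_THRESH_KEYS = {"suppressor_cut", "enhancer_cut", "pseudocount"}
_DEMUX_KEYS = {"tag_mismatch", "primer_mismatch", "barcode_mismatch"}
_SCORING_KEYS = {"robust", "fdr", "quantile"}
_NETWORK_KEYS = {"orthologs", "annotation", "universe", "imported_edges", "format"}


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) in {where}: {sorted(unknown)}")


@dataclass
class PipelineConfig:
    """Validated run configuration with defaults filled."""

    seed: int
    outdir: Path
    simulation: SimulationConfig | None
    design_path: Path | None
    catalog_path: Path | None
    thresholds: Thresholds
    demux_params: dict
    scoring: dict
    network: dict
    raw: dict = field(default_factory=dict, repr=False)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()


def validate_config(path) -> PipelineConfig:
    """Parse and schema-check a YAML run config.

    Unknown keys anywhere are rejected; exactly one of the ``simulation`` and
    ``inputs`` blocks must be present; every referenced file must exist.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    _check_keys(raw, _TOP_KEYS, "top level")
    if "outdir" not in raw:
        raise ValueError(f"{path}: 'outdir' is required")
    has_sim = "simulation" in raw
    has_inputs = "inputs" in raw
    if has_sim == has_inputs:
        raise ValueError(
            f"{path}: exactly one of 'simulation' and 'inputs' must be given"
        )
    seed = int(raw.get("seed", 0))

    simulation = None
    design_path = catalog_path = None
    base = Path(path).parent
    if has_sim:
        block = raw["simulation"] or {}
        _check_keys(block, _SIM_KEYS, "simulation")
        if "queries" in block:
            block = dict(block, queries=tuple(block["queries"]))
        simulation = SimulationConfig(seed=seed, **block)
        simulation.validate()
    else:
        block = raw["inputs"] or {}
        _check_keys(block, _INPUT_KEYS, "inputs")
        for key in ("design", "catalog"):
            if key not in block:
                raise ValueError(f"{path}: inputs.{key} is required")
        design_path = (base / block["design"]).resolve()
        catalog_path = (base / block["catalog"]).resolve()
        for p in (design_path, catalog_path):
            if not p.exists():
                raise ValueError(f"{path}: missing input file {p}")
        # referenced FASTQs must exist at validation time
        design = parse_design(design_path)
        for fq in design["fastq"]:
            fq_path = Path(fq)
            if not fq_path.is_absolute():
                fq_path = design_path.parent / fq_path
            if not fq_path.exists():
                raise ValueError(f"{path}: missing FASTQ {fq_path}")

    tblock = raw.get("thresholds") or {}
    _check_keys(tblock, _THRESH_KEYS, "thresholds")
    thresholds = Thresholds(**tblock)
    thresholds.validate()

    dblock = raw.get("demux") or {}
    _check_keys(dblock, _DEMUX_KEYS, "demux")
    demux_params = {
        "tag_mismatch": 1, "primer_mismatch": 2, "barcode_mismatch": 2, **dblock,
    }

    sblock = raw.get("scoring") or {}
    _check_keys(sblock, _SCORING_KEYS, "scoring")
    scoring = {"robust": False, "fdr": False, "quantile": False, **sblock}

    nblock = raw.get("network") or {}
    _check_keys(nblock, _NETWORK_KEYS, "network")
    network = dict(nblock)
    for key in ("orthologs", "annotation", "universe", "imported_edges"):
        if key in network:
            p = (base / network[key]).resolve()
            if not p.exists():
                raise ValueError(f"{path}: missing network file {p}")
            network[key] = p

    return PipelineConfig(
        seed=seed,
        outdir=(base / raw["outdir"]).resolve(),
        simulation=simulation,
        design_path=design_path,
        catalog_path=catalog_path,
        thresholds=thresholds,
        demux_params=demux_params,
        scoring=scoring,
        network=network,
        raw=raw,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _confusion_report(truth: pd.DataFrame, ztable: pd.DataFrame) -> pd.DataFrame:
    """Truth-vs-called confusion counts, one row block per query."""
    rows = []
    for query, sub in ztable.groupby("query"):
        merged = truth.merge(sub[["strain_id", "label"]], on="strain_id")
        for true_class in CLASSES:
            row = {"query": query, "true_class": true_class}
            tsub = merged[merged["true_class"] == true_class]
            for called in CLASSES:
                row[f"called_{called}"] = int((tsub["label"] == called).sum())
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute every stage and return the artifact paths.

    Stage failures abort with the stage name; previously written outputs are
    left in place.  Identical config + seed produces byte-identical outputs.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    truth = None

    def stage(name):
        logger.info("stage=%s status=start", name)

    try:
        if config.simulation is not None:
            stage("simulate")
            sim_dir = out / "simulated"
            catalog, design, truth, _ = simulate_screen(config.simulation, sim_dir)
            artifacts["catalog"] = sim_dir / "catalog.tsv"
            artifacts["design"] = sim_dir / "design.tsv"
            artifacts["truth"] = sim_dir / "truth.tsv"
        else:
            catalog = BarcodeCatalog.read_tsv(config.catalog_path)
            design = parse_design(config.design_path)
            base = Path(config.design_path).parent
            design["fastq"] = [
                str(p if Path(p).is_absolute() else base / p) for p in design["fastq"]
            ]

        stage("demux")
        counts, stats = count_barcodes(design, catalog, **config.demux_params)
        artifacts["counts"] = out / "counts.tsv"
        write_counts(counts, artifacts["counts"])
        artifacts["demux_stats_per_file"] = out / "demux_stats_per_file.tsv"
        artifacts["demux_stats_per_sample"] = out / "demux_stats_per_sample.tsv"
        stats.write(
            artifacts["demux_stats_per_file"], artifacts["demux_stats_per_sample"]
        )

        stage("score")
        ztable = score_screen(
            counts,
            gene_map=catalog.gene_map(),
            thresholds=config.thresholds,
            robust=config.scoring["robust"],
            method="quantile" if config.scoring["quantile"] else "mean",
            fdr=config.scoring["fdr"],
        )
        artifacts["ztable"] = out / "ztable.tsv"
        write_ztable(ztable, artifacts["ztable"])

        if "orthologs" in config.network:
            stage("network")
            omap = load_ortholog_map(config.network["orthologs"])
            interactions, unmapped = map_suppressors(ztable, omap)
            imported = None
            if "imported_edges" in config.network:
                imported = pd.read_csv(
                    config.network["imported_edges"], sep="\t", dtype=str
                )
            graph = build_network(interactions, imported)
            fmt = config.network.get("format", "graphml")
            ext = {"graphml": "graphml", "sif": "sif", "tsv": "tsv"}[fmt]
            artifacts["network"] = out / f"network.{ext}"
            export_network(graph, artifacts["network"], fmt=fmt)
            artifacts["interactions"] = out / "interactions.tsv"
            interactions.to_csv(artifacts["interactions"], sep="\t", index=False)
            artifacts["unmapped"] = out / "unmapped_suppressors.tsv"
            unmapped.to_csv(artifacts["unmapped"], sep="\t", index=False)
            if "annotation" in config.network:
                annotation = read_annotation(config.network["annotation"])
                if "universe" in config.network:
                    universe = set(
                        Path(config.network["universe"]).read_text().split()
                    )
                else:
                    universe = set().union(*annotation.values())
                hit_genes = set(interactions["partner"]) & universe
                if hit_genes:
                    enr = enrich_categories(hit_genes, annotation, universe)
                    artifacts["enrichment"] = out / "enrichment.tsv"
                    enr.to_csv(artifacts["enrichment"], sep="\t", index=False)

        if truth is not None:
            stage("report")
            report = _confusion_report(truth, ztable)
            artifacts["confusion"] = out / "confusion.tsv"
            report.to_csv(artifacts["confusion"], sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "bartox_version": __version__,
        "outputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in artifacts.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    artifacts["manifest"] = manifest_path
    logger.info("stage=done outputs=%d", len(artifacts))
    return artifacts
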