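"""Ortholog mapping, interaction-network construction and export.

A genetic interaction between a human disease (query) gene and a human gene is
called when deleting the yeast ortholog of that human gene suppresses the
query's toxicity in the pooled screen.  Only suppressors generate edges —
enhancer calls proved unreliable in this screen design.  Yeast suppressors are
translated through a user-supplied yeast→human ortholog map (e.g. exported
from InParanoid or HomoloGene); a yeast gene with several human orthologs
contributes one edge per ortholog, each tagged with its source.

Networks are held as :mod:`networkx` graphs with typed nodes (``disease_gene``
/ ``human_ortholog``) and typed edges (``genetic_suppression`` / ``imported``)
and export to Cytoscape-readable GraphML, SIF and edge-list TSV.  A generic
hypergeometric category-enrichment utility is included for annotating hit
lists against any user-supplied gene-set table.
"""

from __future__ import annotations

import logging
import warnings

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

ORTHOLOG_COLUMNS = ["yeast_gene", "human_gene", "source"]
KNOWN_SOURCES = ("inparanoid", "homologene", "other")
EVIDENCE_SUPPRESSION = "genetic_suppression"
EVIDENCE_IMPORTED = "imported"


def load_ortholog_map(path) -> pd.DataFrame:
    """Load a yeast→human ortholog table (TSV, 3 columns, many-to-many).

    Duplicate (yeast_gene, human_gene, source) triples collapse to one with a
    warning; malformed rows are reported with their line number.  Gene symbols
    are opaque, case-preserved strings.
    """
    rows = []
    with open(path) as fh:
        header = fh.readline()
        if header and [c.strip() for c in header.rstrip("\n").split("\t")] != ORTHOLOG_COLUMNS:
            raise ValueError(
                f"{path}: line 1: expected header {ORTHOLOG_COLUMNS}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3 or not all(p.strip() for p in parts):
                raise ValueError(f"{path}: line {lineno}: need 3 non-empty columns")
            rows.append([p.strip() for p in parts])
    df = pd.DataFrame(rows, columns=ORTHOLOG_COLUMNS)
    n_before = len(df)
    df = df.drop_duplicates(ignore_index=True)
    if len(df) < n_before:
        logger.warning(
            "%s: collapsed %d duplicate ortholog triples", path, n_before - len(df)
        )
    unknown = set(df["source"]) - set(KNOWN_SOURCES)
    if unknown:
        logger.warning("%s: non-canonical ortholog sources %s", path, sorted(unknown))
    return df


def map_suppressors(
    ztable: pd.DataFrame,
    ortholog_map: pd.DataFrame,
    sources: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Translate suppressor calls into human-human interactions.

    Returns ``(interactions, unmapped)``: one interaction row per
    (query, yeast suppressor, human ortholog) triple with evidence
    ``genetic_suppression``; suppressors lacking any ortholog entry are listed
    in the ``unmapped`` side report (never dropped silently).  Enhancer and
    no-effect strains contribute nothing.  ``sources`` optionally restricts
    which ortholog sources may support an edge.
    """
    omap = ortholog_map
    if sources is not None:
        omap = omap[omap["source"].isin(sources)]
    sup = ztable[ztable["label"] == "suppressor"]
    merged = sup.merge(omap, on="yeast_gene", how="left")
    mapped = merged[merged["human_gene"].notna()]
    interactions = (
        pd.DataFrame(
            {
                "query_gene": mapped["query"],
                "partner": mapped["human_gene"],
                "evidence": EVIDENCE_SUPPRESSION,
                "yeast_gene": mapped["yeast_gene"],
                "source": mapped["source"],
            }
        )
        .drop_duplicates(ignore_index=True)
        .reset_index(drop=True)
    )
    unmapped = (
        merged[merged["human_gene"].isna()][["query", "yeast_gene"]]
        .drop_duplicates(ignore_index=True)
        .rename(columns={"query": "query_gene"})
    )
    return interactions, unmapped


def build_network(
    interactions: pd.DataFrame, imported_edges: pd.DataFrame | None = None
) -> nx.Graph:
    """Assemble the typed interaction graph.

    Query disease genes become ``disease_gene`` nodes, partners
    ``human_ortholog`` nodes (a gene that is both keeps the disease_gene
    type).  Duplicate interaction rows collapse onto a single edge whose
    ``yeast_gene`` attribute accumulates every supporting yeast deletion.
    Imported edges (e.g. literature protein–protein interactions) pass
    through with type ``imported``; an imported endpoint unknown to the screen
    is added as a ``human_ortholog`` node and logged.
    """
    g = nx.Graph()
    for row in interactions.itertuples(index=False):
        if row.query_gene == row.partner:
            continue  # suppression evidence cannot form a self-loop
        g.add_node(row.query_gene, node_type="disease_gene")
        if row.partner not in g:
            g.add_node(row.partner, node_type="human_ortholog")
        if g.has_edge(row.query_gene, row.partner):
            prov = set(g.edges[row.query_gene, row.partner]["yeast_gene"].split(";"))
            prov.add(row.yeast_gene)
            g.edges[row.query_gene, row.partner]["yeast_gene"] = ";".join(sorted(prov))
        else:
            g.add_edge(
                row.query_gene,
                row.partner,
                edge_type=EVIDENCE_SUPPRESSION,
                yeast_gene=row.yeast_gene,
            )
    if imported_edges is not None:
        for row in imported_edges.itertuples(index=False):
            for node in (row.source, row.target):
                if node not in g:
                    logger.info("imported edge adds unknown node %s", node)
                    g.add_node(node, node_type="human_ortholog")
            if not g.has_edge(row.source, row.target):
                g.add_edge(
                    row.source,
                    row.target,
                    edge_type=EVIDENCE_IMPORTED,
                    yeast_gene="",
                )
    return g


def _canonical(graph: nx.Graph) -> nx.Graph:
    """Copy with sorted node/edge insertion order for byte-stable export."""
    g = nx.Graph()
    for node in sorted(graph.nodes):
        g.add_node(node, **{k: str(v) for k, v in sorted(graph.nodes[node].items())})
    for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
        g.add_edge(u, v, **{k: str(x) for k, x in sorted(graph.edges[u, v].items())})
    return g


def export_network(graph: nx.Graph, path, fmt: str = "graphml") -> None:
    """Write the network as GraphML, SIF or edge-list TSV.

    All three formats carry the same node and edge sets; GraphML export is
    canonically ordered so an export→import→export cycle is byte-stable.
    """
    g = _canonical(graph)
    if fmt == "graphml":
        nx.write_graphml(g, path, infer_numeric_types=False)
    elif fmt == "sif":
        with open(path, "w") as fh:
            seen = set()
            for u, v, data in g.edges(data=True):
                fh.write(f"{u}\t{data.get('edge_type', EVIDENCE_SUPPRESSION)}\t{v}\n")
                seen.update((u, v))
            for node in g.nodes:
                if node not in seen:
                    fh.write(f"{node}\n")
    elif fmt == "tsv":
        rows = [
            {
                "source": u,
                "target": v,
                "type": data.get("edge_type", ""),
                "yeast_gene": data.get("yeast_gene", ""),
            }
            for u, v, data in g.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", "type", "yeast_gene"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def import_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


def enrich_categories(
    genes, annotation: dict[str, set], universe) -> pd.DataFrame:
    """Hypergeometric over-representation of gene categories in a hit list.

    For each category, the p-value is the upper-tail probability of drawing at
    least the observed overlap when ``len(genes)`` genes are sampled without
    replacement from the universe; q-values are Benjamini–Hochberg across
    categories.  Results are sorted by p.  Categories with no member in the
    universe are skipped with a warning.
    """
    from statsmodels.stats.multitest import multipletests

    genes = set(genes)
    universe = set(universe)
    if not genes:
        raise ValueError("empty gene list")
    if not genes <= universe:
        raise ValueError(f"genes outside universe: {sorted(genes - universe)[:5]}")
    rows = []
    for category, members in annotation.items():
        members = set(members) & universe
        if not members:
            warnings.warn(f"category {category!r} has no member in universe")
            continue
        hits = len(genes & members)
        p = float(hypergeom.sf(hits - 1, len(universe), len(members), len(genes)))
        rows.append(
            {
                "category": category,
                "hits": hits,
                "category_size": len(members),
                "universe_size": len(universe),
                "drawn": len(genes),
                "p_value": min(p, 1.0),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "category", "hits", "category_size", "universe_size",
                "drawn", "p_value", "q_value",
            ]
        )
    df = pd.DataFrame(rows)
    df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.sort_values("p_value", kind="stable", ignore_index=True)


def read_annotation(path) -> dict[str, set]:
    """Annotation TSV (`category<TAB>gene`) into a category → gene-set map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["category", "gene"]:
        raise ValueError(f"{path}: expected columns category, gene")
    return {c: set(sub["gene"]) for c, sub in df.groupby("category")}
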