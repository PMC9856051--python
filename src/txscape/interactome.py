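"""Ligand/receptor interactome overlay of differential-expression classes.

Builds a directed ligand→receptor graph from a curated pair table and
annotates each gene node, per comparison, with its shrunken fold change,
adjusted p-value and volcano class (``up`` / ``down`` /
``significant-only`` / ``ns``; ``no-data`` when the gene was not tested).
Pairs are then flagged for signalling-relevant patterns:

* ``receptor-only-activation`` — the receptor gene is upregulated while
  its ligand is not: the paracrine signature of a tissue responding to a
  cytokine it does not itself transcribe;
* ``autocrine-candidate`` — ligand and receptor both upregulated in the
  same tissue;
* ``no-data`` — neither endpoint tested in that comparison.

A curated human interleukin/interferon ligand→receptor table compiled
from HGNC gene families (interleukins, interleukin receptors,
interferons, cytokine receptors) and published pairing reviews ships with
the package (``data/interleukin_interactome.tsv``).
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

REQUIRED_COLUMNS = ("ligand", "receptor", "source")


@dataclass(frozen=True)
class InteractomePair:
    """One directed ligand→receptor relation with its provenance tag."""

    ligand: str
    receptor: str
    source: str = ""


@dataclass
class InteractomeGraph:
    """Pair graph plus per-gene, per-comparison expression overlay."""

    graph: nx.DiGraph
    comparisons: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)

    def pair_flags(self, comparison: str) -> pd.DataFrame:
        rows = [
            {
                "ligand": a,
                "receptor": b,
                "flag": d.get(f"flag__{comparison}", "no-data"),
            }
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["ligand", "receptor", "flag"])


def load_pairs(path) -> list[InteractomePair]:
    """Read and validate a pair table TSV (ligand, receptor, source).

    Duplicate (ligand, receptor) rows collapse to the first occurrence;
    ligand == receptor is unusual but legal (warned, kept).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pair table {path} lacks columns: {missing}")
    pairs: list[InteractomePair] = []
    seen: set[tuple[str, str]] = set()
    for row in df.itertuples(index=False):
        key = (row.ligand, row.receptor)
        if key in seen:
            continue
        seen.add(key)
        if row.ligand == row.receptor:
            warnings.warn(
                f"self-pairing {row.ligand!r} kept as-is", stacklevel=2
            )
        pairs.append(InteractomePair(row.ligand, row.receptor, row.source))
    return pairs


def bundled_interleukin_pairs() -> list[InteractomePair]:
    """The packaged curated interleukin/interferon ligand→receptor table."""
    ref = importlib.resources.files("txscape.data") / "interleukin_interactome.tsv"
    with importlib.resources.as_file(ref) as p:
        return load_pairs(p)


def write_pairs(pairs, path) -> None:
    pd.DataFrame(
        [(p.ligand, p.receptor, p.source) for p in pairs],
        columns=list(REQUIRED_COLUMNS),
    ).to_csv(path, sep="\t", index=False)


def overlay(pairs, stats_by_comparison: dict[str, pd.DataFrame]) -> InteractomeGraph:
    """Annotate the pair graph with per-comparison DE classes.

    ``stats_by_comparison`` maps a comparison label to a gene-indexed
    stats frame carrying ``slfc``, ``padj`` and ``class`` columns (the
    volcano classification is the single source of truth — it is read,
    never recomputed here).  Genes absent from a comparison are marked
    ``no-data``.  The node set is exactly the union of pair endpoints.
    """
    g = nx.DiGraph()
    for p in pairs:
        g.add_node(p.ligand, role="ligand")
    for p in pairs:
        if p.receptor in g:
            if g.nodes[p.receptor].get("role") != "receptor":
                g.nodes[p.receptor]["role"] = (
                    "both" if g.nodes[p.receptor].get("role") == "ligand" else "receptor"
                )
        else:
            g.add_node(p.receptor, role="receptor")
    for p in pairs:
        g.add_edge(p.ligand, p.receptor, source=p.source)

    comparisons = list(stats_by_comparison)
    for label, stats in stats_by_comparison.items():
        if "class" not in stats.columns:
            raise ValueError(f"stats for {label!r} lack a 'class' column")
        for v in g.nodes:
            if v in stats.index:
                g.nodes[v][f"slfc__{label}"] = float(stats.at[v, "slfc"])
                g.nodes[v][f"padj__{label}"] = float(stats.at[v, "padj"])
                g.nodes[v][f"class__{label}"] = str(stats.at[v, "class"])
            else:
                g.nodes[v][f"class__{label}"] = "no-data"
        for a, b in g.edges:
            ca = g.nodes[a].get(f"class__{label}", "no-data")
            cb = g.nodes[b].get(f"class__{label}", "no-data")
            if ca == "no-data" and cb == "no-data":
                flag = "no-data"
            elif cb == "up" and ca == "up":
                flag = "autocrine-candidate"
            elif cb == "up":
                flag = "receptor-only-activation"
            else:
                flag = "other"
            g.edges[a, b][f"flag__{label}"] = flag
    return InteractomeGraph(graph=g, comparisons=comparisons)


def export_interactome(graph: InteractomeGraph, prefix) -> dict[str, str]:
    """GraphML plus node/edge TSVs; attribute-preserving round trip."""
    prefix = str(prefix)
    paths = {
        "graphml": prefix + ".graphml",
        "nodes": prefix + ".nodes.tsv",
        "edges": prefix + ".edges.tsv",
    }
    nx.write_graphml(graph.graph, paths["graphml"], infer_numeric_types=False)
    node_rows = [
        {"gene": v, **{k: d[k] for k in sorted(d)}}
        for v, d in graph.graph.nodes(data=True)
    ]
    pd.DataFrame(node_rows).to_csv(paths["nodes"], sep="\t", index=False,
                                   float_format="%.6f")
    edge_rows = [
        {"ligand": a, "receptor": b, **{k: d[k] for k in sorted(d)}}
        for a, b, d in graph.graph.edges(data=True)
    ]
    pd.DataFrame(edge_rows).to_csv(paths["edges"], sep="\t", index=False,
                                   float_format="%.6f")
    return paths
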