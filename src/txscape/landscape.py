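"""Enrichment-map landscapes: node/edge rules, Markov clustering, projection.

A transcriptional landscape is a network over significantly altered gene
sets.  From an anchor comparison's enrichment table, any set with adjusted
p below a strict gate (default 0.001) whose leading edge covers at least a
third (33.34%) of its member genes in the ranked universe becomes a node;
enriched and depleted sets coexist in one map, with direction as a node
attribute.  An edge joins two nodes when their leading edges share at
least 5% of their member genes (relative to the smaller set); its weight
is the member-overlap coefficient
``|M_A ∩ M_B| / min(|M_A|, |M_B|)``, so redundant sets attract strongly.

The weighted graph is clustered with an implemented Markov Cluster
algorithm (MCL): the column-stochastic flow matrix is alternately squared
(expansion — flow spreads along walks) and raised entrywise to the
inflation power (flow concentrates on strong routes), with small entries
pruned, until the matrix stops changing; clusters are read off the
attractor structure of the limit.

Other comparisons are then *projected* onto the fixed scaffold: their
adjusted p-values, directions and significance tiers annotate the same
nodes without touching the topology, so maps for different contrasts are
directly comparable.  Per-cluster "theme" summaries report each member
set's signed log10 adjusted p (positive for enrichment, negative for
depletion) per comparison — the tidy input for violin-style theme plots.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import EnrichmentTable

PADJ_FLOOR = 1e-16  # underflow guard before log10
LOG10_CAP = 16.0


@dataclass
class LandscapeNetwork:
    """Gene-set network anchored on one comparison.

    ``graph`` nodes are set names with anchor statistics and, after
    projection, per-comparison annotations stored as
    ``padj__<label>``, ``direction__<label>``, ``tier__<label>``.
    """

    graph: nx.Graph
    anchor: str
    params: dict = field(default_factory=dict)
    clusters: dict[str, int] = field(default_factory=dict)
    comparisons: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def significance_tier(padj: float, tiers=(0.001, 0.01, 0.05)) -> str:
    """Map an adjusted p to its tier label ('<0.001', ..., 'ns')."""
    for t in sorted(tiers):
        if padj < t:
            return f"<{t:g}"
    return "ns"


def select_nodes(
    table: EnrichmentTable,
    padj_thr: float = 0.001,
    le_frac_thr: float = 0.3334,
):
    """Sets passing the node gates: padj < thr AND le_fraction >= thr.

    Both enriched and depleted sets are retained; direction is recorded,
    not filtered on.
    """
    return [
        r
        for r in table.results
        if r.padj < padj_thr and r.le_fraction >= le_frac_thr
    ]


def build_edges(nodes, le_gate: float = 0.05) -> list[tuple[str, str, float, float]]:
    """All node pairs whose leading edges overlap enough, with weights.

    For each unordered pair the gate statistic is the leading-edge
    intersection over the smaller member-set size,
    ``le_share = |LE_A ∩ LE_B| / min(|M_A|, |M_B|)``; an edge exists iff
    ``le_share >= le_gate``.  The edge weight is the full member-set
    overlap coefficient ``|M_A ∩ M_B| / min(|M_A|, |M_B|)`` (member sets
    taken within the ranked universe).  Returns
    ``(name_a, name_b, weight, le_share)`` tuples.
    """
    edges = []
    for i in range(len(nodes)):
        a = nodes[i]
        mem_a = frozenset(a.members_in_universe)
        le_a = frozenset(a.leading_edge)
        for jj in range(i + 1, len(nodes)):
            b = nodes[jj]
            mem_b = frozenset(b.members_in_universe)
            denom = min(len(mem_a), len(mem_b))
            if denom == 0:
                continue
            le_share = len(le_a & frozenset(b.leading_edge)) / denom
            if le_share < le_gate:
                continue
            weight = len(mem_a & mem_b) / denom
            if weight > 0:
                edges.append((a.name, b.name, weight, le_share))
    return edges


def build_network(
    table: EnrichmentTable,
    padj_thr: float = 0.001,
    le_frac_thr: float = 0.3334,
    le_gate: float = 0.05,
) -> LandscapeNetwork:
    """Select nodes and edges from the anchor comparison in one call."""
    nodes = select_nodes(table, padj_thr, le_frac_thr)
    g = nx.Graph()
    for r in nodes:
        g.add_node(
            r.name,
            size=r.size_in_universe,
            es=r.es,
            nes=r.nes,
            le_fraction=r.le_fraction,
            **{
                f"padj__{table.comparison}": r.padj,
                f"direction__{table.comparison}": r.direction,
                f"tier__{table.comparison}": significance_tier(r.padj),
            },
        )
    for a, b, w, s in build_edges(nodes, le_gate):
        g.add_edge(a, b, weight=w, le_share=s)
    return LandscapeNetwork(
        graph=g,
        anchor=table.comparison,
        params={
            "padj_thr": padj_thr,
            "le_frac_thr": le_frac_thr,
            "le_gate": le_gate,
            "edge_weight": "member_overlap_min",
            "edge_gate": "leading_edge_overlap_min",
        },
        comparisons=[table.comparison],
    )


# ---------------------------------------------------------------------------
# Markov clustering


def mcl_cluster(
    network,
    inflation: float = 2.0,
    expansion: int = 2,
    self_loops: bool = True,
    prune: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> dict:
    """Markov Cluster algorithm on the weighted landscape graph.

    Accepts a :class:`LandscapeNetwork` or a plain ``networkx.Graph``
    with ``weight`` edge attributes.  Flow is simulated on the
    column-stochastic adjacency (self-loops at each node's maximum
    incident weight, 1 for isolates): expansion = matrix power, inflation
    = entrywise power + renormalization, entries below ``prune`` dropped
    each round.  Iteration stops when the matrix changes by less than
    ``tol`` (max absolute entry) or at ``max_iter`` (flagged).

    Clusters are the connected components of the attractor structure of
    the limit matrix: rows with positive diagonal mass are attractors and
    every node joins the attractors it flows into; a node reachable from
    several attractor components is resolved to the lowest cluster index.
    Cluster ids are 1-based, ordered by each cluster's first node in the
    input node order.

    Returns ``{"clusters": {node: id}, "converged": bool,
    "iterations": int, "inflation": float}``.
    """
    graph = network.graph if isinstance(network, LandscapeNetwork) else network
    nodes = list(graph.nodes)
    if not nodes:
        raise ValueError("empty node set")
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        m[index[a], index[b]] = w
        m[index[b], index[a]] = w
    if self_loops:
        incident_max = m.max(axis=0)
        np.fill_diagonal(m, np.where(incident_max > 0, incident_max, 1.0))

    def normalize(mat: np.ndarray) -> np.ndarray:
        cols = mat.sum(axis=0)
        cols[cols == 0] = 1.0
        return mat / cols

    m = normalize(m)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        expanded = np.linalg.matrix_power(m, expansion)
        inflated = expanded**inflation
        inflated[inflated < prune] = 0.0
        new = normalize(inflated)
        if np.max(np.abs(new - m)) < tol:
            m = new
            converged = True
            break
        m = new
    if not converged:
        import warnings

        warnings.warn(
            f"MCL did not converge in {max_iter} iterations; "
            "returning the current partition",
            stacklevel=2,
        )

    # attractors: rows with positive diagonal mass
    attractors = [i for i in range(n) if m[i, i] > prune]
    if not attractors:  # numerically degenerate; everyone is their own
        attractors = list(range(n))
    # attractor systems: attractors flowing into each other form one cluster
    parent = {i: i for i in attractors}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for i in attractors:
        for i2 in attractors:
            if i2 > i and (m[i, i2] > prune or m[i2, i] > prune):
                union(i, i2)

    roots: dict[int, int] = {}
    next_id = 1
    for i in attractors:  # ids ordered by first attractor of each system
        r = find(i)
        if r not in roots:
            roots[r] = next_id
            next_id += 1

    clusters: dict[str, int] = {}
    extra_id = next_id
    for jcol in range(n):
        owners = sorted(roots[find(i)] for i in attractors if m[i, jcol] > prune)
        if owners:
            # a node supported by several attractor systems goes to the
            # lowest cluster index
            clusters[nodes[jcol]] = owners[0]
        else:
            clusters[nodes[jcol]] = extra_id  # no attractor mass: singleton
            extra_id += 1

    if isinstance(network, LandscapeNetwork):
        network.clusters = clusters
        for v, cid in clusters.items():
            network.graph.nodes[v]["cluster"] = cid
    return {
        "clusters": clusters,
        "converged": converged,
        "iterations": iterations,
        "inflation": inflation,
    }


# ---------------------------------------------------------------------------
# projection and summaries


def project_comparison(
    network: LandscapeNetwork,
    other_table: EnrichmentTable,
    tiers=(0.001, 0.01, 0.05),
) -> LandscapeNetwork:
    """Annotate scaffold nodes with another comparison's statistics.

    Topology is never altered: every scaffold node gains
    ``padj/direction/tier`` attributes for ``other_table.comparison``;
    sets absent from the other table are marked ``not-tested``.
    """
    label = other_table.comparison
    lookup = {r.name: r for r in other_table.results}
    for v in network.graph.nodes:
        r = lookup.get(v)
        if r is None:
            network.graph.nodes[v][f"padj__{label}"] = float("nan")
            network.graph.nodes[v][f"direction__{label}"] = "not-tested"
            network.graph.nodes[v][f"tier__{label}"] = "not-tested"
        else:
            network.graph.nodes[v][f"padj__{label}"] = r.padj
            network.graph.nodes[v][f"direction__{label}"] = r.direction
            network.graph.nodes[v][f"tier__{label}"] = significance_tier(
                r.padj, tiers
            )
    if label not in network.comparisons:
        network.comparisons.append(label)
    return network


def signed_log10(padj: float, direction: str) -> float:
    """Signed -log10(padj): positive for enrichment, negative for depletion."""
    v = -np.log10(max(float(padj), PADJ_FLOOR))
    v = min(v, LOG10_CAP)
    return float(v if direction == "enriched" else -v)


def theme_signed_pvalues(network: LandscapeNetwork) -> pd.DataFrame:
    """Tidy per-cluster, per-comparison signed log10 adjusted p-values.

    One row per (cluster, comparison, member set); ``value`` is
    ``sign(direction) * -log10(padj)`` capped at ±16, 0 at padj = 1, and
    NaN for not-tested sets.  Suitable directly for violin plots of theme
    behaviour across contrasts.
    """
    if not network.clusters:
        raise ValueError("run mcl_cluster before summarizing themes")
    rows = []
    for v in network.graph.nodes:
        cid = network.clusters[v]
        for comp in network.comparisons:
            padj = network.graph.nodes[v].get(f"padj__{comp}", float("nan"))
            direction = network.graph.nodes[v].get(f"direction__{comp}", "not-tested")
            if direction == "not-tested" or not np.isfinite(padj):
                value = float("nan")
            else:
                value = signed_log10(padj, direction)
            rows.append(
                {"cluster": cid, "comparison": comp, "set": v, "value": value}
            )
    df = pd.DataFrame(rows, columns=["cluster", "comparison", "set", "value"])
    return df.sort_values(["cluster", "comparison", "set"], ignore_index=True)


_STOPWORDS = frozenset(
    "of the to in and a an via by from with for or on at into".split()
)


def _tokenize(name: str) -> list[str]:
    import re

    raw = [t.lower() for t in re.split(r"[^0-9A-Za-z]+", name) if t]
    # re-attach trailing pure-number tokens (interleukin 7 -> interleukin_7)
    merged: list[str] = []
    for t in raw:
        if t.isdigit() and merged:
            merged[-1] = f"{merged[-1]}_{t}"
        else:
            merged.append(t)
    return [t for t in merged if t not in _STOPWORDS]


def suggest_labels(set_names, top: int = 5) -> list[str]:
    """Most frequent informative name tokens of a cluster, as label hints.

    Ties on frequency break lexicographically; curation of the final
    biological theme name remains a human task.
    """
    names = list(set_names)
    if not names:
        raise ValueError("empty cluster")
    counts = Counter(t for name in names for t in _tokenize(name))
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [t for t, _ in ordered[:top]]


def cluster_label_suggestions(network: LandscapeNetwork, top: int = 5) -> dict[int, list[str]]:
    out: dict[int, list[str]] = {}
    for cid in sorted(set(network.clusters.values())):
        members = [v for v, c in network.clusters.items() if c == cid]
        out[cid] = suggest_labels(members, top=top)
    return out


# ---------------------------------------------------------------------------
# export


def export_network(network: LandscapeNetwork, prefix) -> dict[str, str]:
    """Write GraphML plus node/edge TSV twins; returns the paths.

    GraphML carries every node attribute (per-comparison padj, direction,
    tier; anchor stats; cluster id) and edge weights/le_share, ready for
    any graph viewer; the TSVs are byte-stable flat twins of the same
    content.
    """
    prefix = str(prefix)
    paths = {
        "graphml": prefix + ".graphml",
        "nodes": prefix + ".nodes.tsv",
        "edges": prefix + ".edges.tsv",
    }
    g = nx.Graph()
    g.graph.update({k: str(v) for k, v in network.params.items()})
    g.graph["anchor"] = network.anchor
    for v, data in network.graph.nodes(data=True):
        g.add_node(v, **{k: _graphml_safe(x) for k, x in sorted(data.items())})
    for a, b, data in network.graph.edges(data=True):
        g.add_edge(a, b, **{k: float(x) for k, x in sorted(data.items())})
    nx.write_graphml(g, paths["graphml"], infer_numeric_types=False)

    node_rows = [
        {"set": v, **{k: data[k] for k in sorted(data)}}
        for v, data in network.graph.nodes(data=True)
    ]
    pd.DataFrame(node_rows).to_csv(
        paths["nodes"], sep="\t", index=False, float_format="%.6f"
    )
    edge_rows = [
        {"source": a, "target": b, "weight": d["weight"], "le_share": d["le_share"]}
        for a, b, d in network.graph.edges(data=True)
    ]
    pd.DataFrame(
        edge_rows, columns=["source", "target", "weight", "le_share"]
    ).to_csv(paths["edges"], sep="\t", index=False, float_format="%.6f")
    return paths


def _graphml_safe(x):
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.integer,)):
        return int(x)
    return x


def read_network_graphml(path) -> nx.Graph:
    """Re-read an exported landscape (attribute-preserving round trip)."""
    return nx.read_graphml(path)
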