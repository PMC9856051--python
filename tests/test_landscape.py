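"""Node/edge thresholds, Markov clustering, projection, themes, export."""

import networkx as nx
import numpy as np
import pytest

from txscape.enrichment import EnrichmentResult, EnrichmentTable
from txscape.landscape import (
    build_edges,
    build_network,
    cluster_label_suggestions,
    export_network,
    mcl_cluster,
    project_comparison,
    read_network_graphml,
    select_nodes,
    signed_log10,
    suggest_labels,
    theme_signed_pvalues,
)


def _result(name, padj=1e-4, le_n=20, size=40, es=0.5, members=None, le=None):
    members = members or tuple(f"{name}_m{i}" for i in range(size))
    le = le or members[:le_n]
    return EnrichmentResult(
        name=name, size_in_universe=len(members), es=es, nes=es * 2,
        pval=padj / 2, padj=padj, leading_edge=tuple(le),
        members_in_universe=tuple(members),
    )


def _table(results, label="A_vs_C"):
    return EnrichmentTable(comparison=label, results=results, nperm=100, seed=0)


# ---------------------------------------------------------------------------
# independent reference MCL used for cross-checking: a direct transcription
# of the expand/inflate/prune loop using scipy sparse matrices and an
# independent cluster extraction via connected components of the limit.


def reference_mcl(graph: nx.Graph, inflation=2.0, max_iter=300):
    nodes = list(graph.nodes)
    n = len(nodes)
    a = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    mx = a.max(axis=0)
    for i in range(n):
        a[i, i] = mx[i] if mx[i] > 0 else 1.0
    m = a / a.sum(axis=0)
    for _ in range(max_iter):
        prev = m
        m = (m @ m) ** inflation
        m[m < 1e-5] = 0.0
        m = m / m.sum(axis=0)
        if np.abs(m - prev).max() < 1e-8:
            break
    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(m > 1e-5)
    for i, j in zip(rows, cols):
        support.add_edge(int(i), int(j))
    comp = {
        v: ci
        for ci, c in enumerate(nx.connected_components(support))
        for v in c
    }
    return {nodes[i]: comp[i] for i in range(n)}


def partitions_equal(p1: dict, p2: dict) -> bool:
    by1, by2 = {}, {}
    for k, v in p1.items():
        by1.setdefault(v, set()).add(k)
    for k, v in p2.items():
        by2.setdefault(v, set()).add(k)
    return set(map(frozenset, by1.values())) == set(map(frozenset, by2.values()))


class TestSelectNodes:
    @pytest.mark.parametrize(
        "padj,le_frac,kept",
        [
            (0.0005, 0.50, True),
            (0.002, 0.90, False),   # fails the p gate
            (0.0001, 0.20, False),  # fails the leading-edge gate
            (0.001, 0.50, False),   # strict p inequality
        ],
    )
    def test_gates(self, padj, le_frac, kept):
        r = _result("S", padj=padj, le_n=int(round(le_frac * 40)))
        table = _table([r])
        assert (len(select_nodes(table)) == 1) is kept

    def test_leading_edge_threshold_is_inclusive(self):
        # le_fraction exactly at the gate (20/40 vs gate 0.5) is kept
        r = _result("S", padj=1e-4, le_n=20)
        assert len(select_nodes(_table([r]), le_frac_thr=0.5)) == 1
        assert len(select_nodes(_table([r]), le_frac_thr=0.5001)) == 0

    def test_both_directions_retained(self):
        rs = [
            _result("UP", es=0.6),
            _result("DOWN", es=-0.6),
        ]
        nodes = select_nodes(_table(rs))
        assert {r.name for r in nodes} == {"UP", "DOWN"}


class TestBuildEdges:
    def test_identical_sets_weight_one(self):
        m = tuple(f"m{i}" for i in range(30))
        a = _result("A", members=m, le=m[:15])
        b = _result("B", members=m, le=m[:15])
        edges = build_edges([a, b])
        assert len(edges) == 1
        assert edges[0][2] == pytest.approx(1.0)

    def test_disjoint_leading_edges_gate_out(self):
        m = tuple(f"m{i}" for i in range(30))
        a = _result("A", members=m, le=m[:10])
        b = _result("B", members=m, le=m[20:])
        assert build_edges([a, b]) == []

    def test_hand_computed_ratios(self):
        # |M_A|=40, |M_B|=60, overlap 20; |LE_A cap LE_B| = 4
        shared = tuple(f"s{i}" for i in range(20))
        m_a = shared + tuple(f"a{i}" for i in range(20))
        m_b = shared + tuple(f"b{i}" for i in range(40))
        le_a = shared[:4] + m_a[20:30]
        le_b = shared[:4] + m_b[30:40]
        a = _result("A", members=m_a, le=le_a)
        b = _result("B", members=m_b, le=le_b)
        edges = build_edges([a, b], le_gate=0.05)
        assert len(edges) == 1
        _, _, weight, le_share = edges[0]
        assert le_share == pytest.approx(4 / 40)
        assert weight == pytest.approx(20 / 40)

    def test_gate_threshold_is_sharp(self):
        # le_share exactly 2/40 = 0.05 passes; 1/40 fails
        m_a = tuple(f"a{i}" for i in range(40))
        m_b = m_a[:2] + tuple(f"b{i}" for i in range(38))
        a = _result("A", members=m_a, le=m_a[:20])
        b2 = _result("B", members=m_b, le=m_b[:2] + m_b[10:20])
        b1 = _result("B", members=m_b, le=m_b[:1] + m_b[10:20])
        assert len(build_edges([a, b2])) == 1
        assert len(build_edges([a, b1])) == 0


class TestMcl:
    def test_two_disjoint_triangles(self):
        g = nx.Graph()
        for base in (0, 3):
            for i in range(3):
                for j in range(i + 1, 3):
                    g.add_edge(base + i, base + j, weight=1.0)
        out = mcl_cluster(g)
        clusters = out["clusters"]
        assert out["converged"]
        groups = {}
        for v, c in clusters.items():
            groups.setdefault(c, set()).add(v)
        assert sorted(map(sorted, groups.values())) == [[0, 1, 2], [3, 4, 5]]

    def test_single_isolated_node(self):
        g = nx.Graph()
        g.add_node("solo")
        out = mcl_cluster(g)
        assert out["clusters"] == {"solo": 1}

    def test_weak_bridge_barbell_splits(self):
        g = nx.Graph()
        for base in (0, 4):
            for i in range(4):
                for j in range(i + 1, 4):
                    g.add_edge(base + i, base + j, weight=1.0)
        g.add_edge(3, 4, weight=0.01)
        out = mcl_cluster(g, inflation=2.0)
        ref = reference_mcl(g, inflation=2.0)
        assert partitions_equal(out["clusters"], ref)
        sizes = sorted(
            np.bincount(list(out["clusters"].values()))[1:].tolist()
        )
        assert sizes == [4, 4]

    def test_matches_reference_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(4, 15))
            g = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(1 << 30)))
            for a, b in g.edges:
                g[a][b]["weight"] = float(rng.uniform(0.1, 1.0))
            if g.number_of_nodes() == 0:
                continue
            out = mcl_cluster(g)
            ref = reference_mcl(g)
            assert partitions_equal(out["clusters"], ref)

    def test_partition_and_component_confinement(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(2, 20))
            g = nx.gnp_random_graph(n, 0.2, seed=int(rng.integers(1 << 30)))
            for a, b in g.edges:
                g[a][b]["weight"] = float(rng.uniform(0.05, 1.0))
            out = mcl_cluster(g)
            clusters = out["clusters"]
            # partition: every node exactly once
            assert set(clusters) == set(g.nodes)
            # confinement: no cluster spans two connected components
            comp_of = {
                v: ci
                for ci, comp in enumerate(nx.connected_components(g))
                for v in comp
            }
            by_cluster = {}
            for v, c in clusters.items():
                by_cluster.setdefault(c, set()).add(comp_of[v])
            assert all(len(s) == 1 for s in by_cluster.values())

    def test_inflation_monotone_on_barbell_family(self):
        g = nx.Graph()
        for base in (0, 5):
            for i in range(5):
                for j in range(i + 1, 5):
                    g.add_edge(base + i, base + j, weight=1.0)
        g.add_edge(4, 5, weight=0.5)
        counts = [
            len(set(mcl_cluster(g, inflation=r)["clusters"].values()))
            for r in (1.2, 2.0, 3.0, 5.0)
        ]
        assert counts == sorted(counts)

    def test_planted_family_recovery(self):
        """MCL recovers two disjoint overlapping-set families (ARI >= 0.9)."""
        from sklearn.metrics import adjusted_rand_score

        aris = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            results, truth = [], []
            for fam, offset in (("F1", 0), ("F2", 5000)):
                pool = [f"m{offset + i}" for i in range(120)]
                for s in range(4):
                    members = tuple(
                        rng.choice(pool, size=60, replace=False)
                    )
                    results.append(
                        _result(f"{fam}_S{s}", members=members,
                                le=members[:30])
                    )
                    truth.append(fam)
            nodes = select_nodes(_table(results))
            g = nx.Graph()
            for r in nodes:
                g.add_node(r.name)
            for a, b, w, s in build_edges(nodes):
                g.add_edge(a, b, weight=w, le_share=s)
            clusters = mcl_cluster(g)["clusters"]
            pred = [clusters[r.name] for r in results]
            aris.append(adjusted_rand_score(truth, pred))
        assert np.mean(np.array(aris) >= 0.9) == 1.0


class TestProjection:
    def _network(self):
        m = tuple(f"m{i}" for i in range(30))
        rs = [
            _result("S1", members=m, le=m[:15]),
            _result("S2", members=m[:20] + tuple(f"x{i}" for i in range(10)),
                    le=m[:15]),
        ]
        return build_network(_table(rs))

    def test_projection_adds_annotations_not_topology(self):
        net = self._network()
        before = (set(net.graph.nodes), set(net.graph.edges))
        other = _table([_result("S1", padj=0.2)], label="A_vs_B")
        project_comparison(net, other)
        assert (set(net.graph.nodes), set(net.graph.edges)) == before
        assert net.graph.nodes["S1"]["tier__A_vs_B"] == "ns"
        assert net.graph.nodes["S2"]["tier__A_vs_B"] == "not-tested"

    def test_projecting_anchor_onto_itself_is_idempotent(self):
        net = self._network()
        anchor_padj = net.graph.nodes["S1"]["padj__A_vs_C"]
        rs = [_result("S1"), _result("S2")]
        project_comparison(net, _table(rs, label="A_vs_C"))
        assert net.graph.nodes["S1"]["padj__A_vs_C"] == anchor_padj

    def test_empty_other_table_marks_all_not_tested(self):
        net = self._network()
        project_comparison(net, _table([], label="B_vs_C"))
        tiers = [net.graph.nodes[v]["tier__B_vs_C"] for v in net.graph.nodes]
        assert set(tiers) == {"not-tested"}


class TestThemes:
    @pytest.mark.parametrize(
        "padj,direction,expected",
        [
            (0.001, "enriched", 3.0),
            (0.01, "depleted", -2.0),
            (1.0, "enriched", 0.0),
            (1.0, "depleted", 0.0),
            (1e-30, "enriched", 16.0),  # underflow cap
        ],
    )
    def test_signed_log10(self, padj, direction, expected):
        assert signed_log10(padj, direction) == pytest.approx(expected)

    def test_tidy_table_shape(self):
        m = tuple(f"m{i}" for i in range(30))
        net = build_network(
            _table([_result("S1", members=m, le=m[:15])])
        )
        mcl_cluster(net)
        project_comparison(net, _table([_result("S1", padj=0.01, es=-0.4)],
                                       label="A_vs_B"))
        df = theme_signed_pvalues(net)
        assert list(df.columns) == ["cluster", "comparison", "set", "value"]
        assert len(df) == 2  # 1 node x 2 comparisons
        v = df.set_index("comparison")["value"]
        assert v["A_vs_B"] == pytest.approx(-2.0)


class TestLabels:
    def test_dominant_token_family(self):
        names = [
            "RESPONSE_TO_INTERLEUKIN_7",
            "INTERLEUKIN_7_SIGNALING",
            "REGULATION_OF_INTERLEUKIN_7_PRODUCTION",
        ]
        assert suggest_labels(names)[0] == "interleukin_7"

    def test_single_name_returns_its_tokens(self):
        assert suggest_labels(["ALPHA_BETA"]) == ["alpha", "beta"]

    def test_frequency_ties_break_lexicographically(self):
        assert suggest_labels(["D_C"], top=2) == ["c", "d"]

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            suggest_labels([])


class TestExport:
    def test_round_trip_preserves_attributes(self, tmp_path):
        m = tuple(f"m{i}" for i in range(30))
        rs = [
            _result("S1", members=m, le=m[:15]),
            _result("S2", members=m[:25] + tuple(f"y{i}" for i in range(5)),
                    le=m[:12]),
        ]
        net = build_network(_table(rs))
        mcl_cluster(net)
        paths = export_network(net, tmp_path / "land")
        back = read_network_graphml(paths["graphml"])
        assert set(back.nodes) == set(net.graph.nodes)
        assert set(map(frozenset, back.edges)) == set(
            map(frozenset, net.graph.edges)
        )
        for v in net.graph.nodes:
            assert back.nodes[v]["cluster"] == net.graph.nodes[v]["cluster"]
            assert back.nodes[v]["padj__A_vs_C"] == pytest.approx(
                net.graph.nodes[v]["padj__A_vs_C"]
            )
        for a, b in net.graph.edges:
            assert back.edges[a, b]["weight"] == pytest.approx(
                net.graph.edges[a, b]["weight"], abs=1e-6
            )

    def test_empty_network_exports_valid_graphml(self, tmp_path):
        net = build_network(_table([]))
        paths = export_network(net, tmp_path / "empty")
        back = read_network_graphml(paths["graphml"])
        assert back.number_of_nodes() == 0

    def test_edge_weights_in_tsv_match_computation(self, tmp_path):
        import pandas as pd

        m = tuple(f"m{i}" for i in range(30))
        rs = [_result("S1", members=m, le=m[:15]),
              _result("S2", members=m, le=m[:15])]
        net = build_network(_table(rs))
        mcl_cluster(net)
        paths = export_network(net, tmp_path / "x")
        edges = pd.read_csv(paths["edges"], sep="\t")
        assert edges["weight"].iloc[0] == pytest.approx(1.0, abs=1e-6)

    def test_labels_on_network(self):
        m = tuple(f"m{i}" for i in range(30))
        rs = [_result("IL7_PATH_A", members=m, le=m[:15]),
              _result("IL7_PATH_B", members=m, le=m[:15])]
        net = build_network(_table(rs))
        mcl_cluster(net)
        labels = cluster_label_suggestions(net)
        assert labels[1][0] in {"il7", "path"}
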