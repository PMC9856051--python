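"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately written from the contracts, not from the
package's code paths: a literal position-by-position running-sum walk for
the enrichment score, exhaustive subset enumeration for permutation
p-values, and closed-form step-up arithmetic for BH — so that agreement
with the package is evidence, not tautology.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from txscape.diffexpr import RankedList


# ---------------------------------------------------------------------------
# independent enrichment-score oracle (brute-force walk)


def walk_es_oracle(scores, hit_positions, weight_p=1.0):
    """Literal running-sum walk over every ranking position.

    Returns (es, peak_index, leading_edge_positions).  Hits add
    |score|^p / total, misses subtract 1/(N-k); the extremum of larger
    magnitude wins, ties to the earlier walk index.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    hits = set(int(h) for h in hit_positions)
    k = len(hits)
    assert 1 <= k < n
    absw = np.abs(scores) ** weight_p
    total = sum(absw[i] for i in hits)
    if total == 0:  # degenerate all-zero metric: unweighted walk
        absw = np.ones(n)
        total = float(k)
    tol = 1e-12
    running = 0.0
    trace = []
    for i in range(n):
        if i in hits:
            running += absw[i] / total
        else:
            running -= 1.0 / (n - k)
        trace.append(running)
    best_pos = max(0.0, max(trace))
    best_neg = min(0.0, min(trace))
    best_pos_idx = next(
        (i for i, v in enumerate(trace) if v >= best_pos - tol), -1
    )
    best_neg_idx = next(
        (i for i, v in enumerate(trace) if v <= best_neg + tol), -1
    )
    if best_pos - (-best_neg) > tol or (
        abs(best_pos + best_neg) <= tol
        and (best_neg_idx == -1 or best_pos_idx <= best_neg_idx)
    ):
        es, peak = best_pos, best_pos_idx
        le = sorted(h for h in hits if h <= peak)
    else:
        es, peak = best_neg, best_neg_idx
        # trough at a miss position: leading edge = hits strictly after it
        le = sorted(h for h in hits if h > peak)
        peak = le[0] if le else peak
    return es, peak, le


def enumerate_null_es(scores, set_size, weight_p=1.0):
    """ES of every possible member subset of the given size (exhaustive)."""
    n = len(scores)
    return np.array(
        [
            walk_es_oracle(scores, combo, weight_p)[0]
            for combo in itertools.combinations(range(n), set_size)
        ]
    )


def enumeration_pvalue(es_obs, null_es):
    """Exact sign-partitioned tail probability under full enumeration."""
    null_es = np.asarray(null_es, dtype=float)
    same = null_es[null_es >= 0] if es_obs >= 0 else null_es[null_es < 0]
    if same.size == 0:
        return 1.0
    # 1e-12 tie tolerance mirrors the sampled estimator: enumerated
    # subsets equal to the observed one must count as at-least-as-extreme
    return float(np.mean(np.abs(same) >= abs(es_obs) - 1e-12))


def bh_oracle(pvals):
    """Closed-form step-up: padj_i = min_{j>=rank_i} p_(j) * n / j, <= 1."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    out = np.empty(n)
    running_min = 1.0
    for pos in range(n - 1, -1, -1):
        idx = order[pos]
        running_min = min(running_min, p[idx] * n / (pos + 1))
        out[idx] = running_min
    return out


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def toy_ranking():
    """Six genes with distinct symmetric scores (3, 2, 1, -1, -2, -3)."""
    return RankedList(
        genes=[f"g{i}" for i in range(1, 7)],
        scores=np.array([3.0, 2.0, 1.0, -1.0, -2.0, -3.0]),
        comparison="toy",
    )


@pytest.fixture(scope="session")
def demo_study():
    """The packaged demo study (seed 0), shared across the session."""
    from txscape.synthetic import fixture_config, simulate_counts

    return simulate_counts(fixture_config(0))


@pytest.fixture(scope="session")
def demo_stats(demo_study):
    """Gene statistics with slfc and class for the demo anchor contrast."""
    from txscape import diffexpr as de

    stats = de.shrink_lfc(de.gene_stats(demo_study.counts, ("A", "C")))
    stats["class"] = de.classify_volcano(stats)
    return stats


@pytest.fixture(scope="session")
def demo_ranked(demo_stats):
    from txscape.diffexpr import rank_genes

    return rank_genes(demo_stats, comparison="A_vs_C")
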