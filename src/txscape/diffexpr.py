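"""Differential expression for multi-group count studies.

Turns a gene-by-sample integer count matrix plus a sample design into
per-gene statistics for a two-group contrast — normalized baseline mean,
log2 fold change (lfc), its standard error, a p-value, a
Benjamini–Hochberg adjusted p-value, and a shrunken log2 fold change
(slfc) — and into the slfc-ranked gene list that seeds preranked
enrichment.

The estimator is deliberately simple and fully documented rather than a
replication of any particular DE engine:

* library-size normalization by median-of-ratios size factors (CPM offered
  separately for inspection);
* per-gene effect: lfc of pseudocounted group means of normalized counts;
* inference: Welch's unequal-variance test on ``log2(normalized + c)``
  (default), or a negative-binomial Wald test with moment-estimated
  dispersion (``method="nb-wald"``);
* shrinkage: a normal-prior ridge, ``slfc = lfc * tau2 / (tau2 + se^2)``,
  with the prior variance ``tau2`` estimated by moment matching across
  genes.  Shrinkage never amplifies and never flips sign.

An optional known batch column in the design is removed as an additive
log-scale offset before testing (``adjust_batch=True``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_PSEUDOCOUNT = 0.5


# ---------------------------------------------------------------------------
# containers


@dataclass
class CountMatrix:
    """Integer counts (genes x samples) plus the sample design.

    ``design`` is indexed by sample id and must carry a ``group`` column;
    an optional ``batch`` column enables known-covariate adjustment.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids in count matrix")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids in count matrix")
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("negative counts")
        if "group" not in self.design.columns:
            raise ValueError("design must have a 'group' column")
        missing = set(self.counts.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)[:5]}")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def group_samples(self, group: str) -> list[str]:
        sel = self.design.index[self.design["group"] == group]
        return [s for s in self.counts.columns if s in set(sel)]

    def to_tsv(self, counts_path, design_path) -> None:
        out = self.counts.copy()
        out.index.name = "gene"
        out.to_csv(counts_path, sep="\t")
        d = self.design.copy()
        d.index.name = "sample"
        d.to_csv(design_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, design_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        design = pd.read_csv(design_path, sep="\t", index_col=0, dtype=str)
        counts.index.name = None
        design.index.name = None
        return cls(counts=counts, design=design)


@dataclass
class RankedList:
    """Genes in a strict total order, descending by the ranking metric.

    The metric is the shrunken log2 fold change; ties are broken by the
    test statistic (descending) and then by gene id, so the order is
    deterministic on any input.
    """

    genes: list[str]
    scores: np.ndarray
    comparison: str

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list has duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def positions(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def to_rnk(self, path) -> None:
        """Write the two-column RNK format (gene TAB score)."""
        with open(path, "wt", encoding="utf-8") as fh:
            for g, s in zip(self.genes, self.scores):
                fh.write(f"{g}\t{s:.10g}\n")

    @classmethod
    def from_rnk(cls, path, comparison: str = "") -> "RankedList":
        df = pd.read_csv(path, sep="\t", header=None, names=["gene", "score"])
        return cls(list(df["gene"]), df["score"].to_numpy(float), comparison)


# ---------------------------------------------------------------------------
# normalization


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    The reference profile is the gene-wise geometric mean over samples,
    restricted to genes positive in every sample; each sample's factor is
    the median of its count/reference ratios.  If no gene is positive in
    all samples the total-count (CPM-style) fallback is used, with a
    warning.
    """
    mat = np.asarray(counts, dtype=float)
    if (mat.sum(axis=0) <= 0).any():
        raise ValueError("every sample needs at least one nonzero count")
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        warnings.warn(
            "no gene is positive in all samples; falling back to "
            "total-count size factors",
            stacklevel=2,
        )
        tot = mat.sum(axis=0)
        sf = tot / np.exp(np.mean(np.log(tot)))
        return pd.Series(sf, index=counts.columns, name="size_factor")
    ref = np.exp(np.mean(np.log(mat[allpos]), axis=1))
    ratios = mat[allpos] / ref[:, None]
    sf = np.median(ratios, axis=0)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: ``count / library_size * 1e6`` per sample."""
    lib = np.asarray(counts, dtype=float).sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    return counts / lib * 1e6


def _normalized(counts: pd.DataFrame, sf: pd.Series) -> pd.DataFrame:
    return counts / sf


def _batch_adjust_log(logmat: np.ndarray, batches: np.ndarray) -> np.ndarray:
    """Remove per-batch additive offsets on the log scale (centered)."""
    out = logmat.copy()
    grand = logmat.mean(axis=1, keepdims=True)
    for b in np.unique(batches):
        sel = batches == b
        out[:, sel] -= logmat[:, sel].mean(axis=1, keepdims=True) - grand
    return out


# ---------------------------------------------------------------------------
# per-gene statistics


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    ``padj = min_{j >= rank} p_(j) * n / j``, clipped to 1; monotone
    non-decreasing in the p-value rank and never below the raw p.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def _welch_on_log(
    norm_a: np.ndarray, norm_b: np.ndarray, pseudocount: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Welch test on log2(normalized + c); returns (se, stat, p)."""
    la = np.log2(norm_a + pseudocount)
    lb = np.log2(norm_b + pseudocount)
    na, nb = la.shape[1], lb.shape[1]
    ma, mb = la.mean(axis=1), lb.mean(axis=1)
    va = la.var(axis=1, ddof=1) / na
    vb = lb.var(axis=1, ddof=1) / nb
    se = np.sqrt(va + vb)
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, diff / se, 0.0)
        df_num = (va + vb) ** 2
        df_den = va**2 / (na - 1) + vb**2 / (nb - 1)
        df = np.where(df_den > 0, df_num / df_den, na + nb - 2)
    p = 2.0 * sps.t.sf(np.abs(stat), df)
    # constant-in-both-groups genes carry no evidence
    p = np.where(se > 0, p, 1.0)
    return se, stat, np.clip(p, 0.0, 1.0)


def _nb_wald(
    raw_a: np.ndarray,
    raw_b: np.ndarray,
    sf_a: np.ndarray,
    sf_b: np.ndarray,
    max_iter: int = 25,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Negative-binomial Wald test for a two-group contrast.

    Per gene, a log-link NB model with group-wise intercepts and
    log-size-factor offsets is fitted by Newton iteration (the two groups
    decouple, so each group mean is a scalar root-finding problem).  The
    dispersion is a per-gene method-of-moments estimate on normalized
    counts, floored at 1e-8.  The Wald statistic is the difference of the
    fitted log2 means over its Fisher standard error.
    """
    norm = np.concatenate([raw_a / sf_a, raw_b / sf_b], axis=1)
    mu_hat = norm.mean(axis=1)
    var_hat = norm.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (var_hat - mu_hat) / np.maximum(mu_hat, 1e-12) ** 2
    phi = np.clip(np.nan_to_num(phi, nan=1e-8), 1e-8, 10.0)

    def fit_group(raw: np.ndarray, sfv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # Newton on beta = log mean; mu_i = exp(beta) * sf_i
        base = np.maximum(raw.mean(axis=1) / sfv.mean(), 1e-8)
        beta = np.log(base)
        for _ in range(max_iter):
            mu = np.exp(beta)[:, None] * sfv[None, :]
            w = mu / (1.0 + phi[:, None] * mu)
            score = ((raw - mu) / (1.0 + phi[:, None] * mu)).sum(axis=1)
            info = w.sum(axis=1)
            step = score / np.maximum(info, 1e-12)
            step = np.clip(step, -2.0, 2.0)
            beta = beta + step
            if np.max(np.abs(step)) < tol:
                break
        mu = np.exp(beta)[:, None] * sfv[None, :]
        info = (mu / (1.0 + phi[:, None] * mu)).sum(axis=1)
        return beta, 1.0 / np.maximum(info, 1e-12)

    beta_a, var_a = fit_group(raw_a, sf_a)
    beta_b, var_b = fit_group(raw_b, sf_b)
    ln2 = np.log(2.0)
    se = np.sqrt(var_a + var_b) / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, (beta_a - beta_b) / ln2 / se, 0.0)
    p = 2.0 * sps.norm.sf(np.abs(stat))
    return se, stat, np.clip(p, 0.0, 1.0)


def gene_stats(
    cm: CountMatrix,
    contrast: tuple[str, str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    method: str = "welch-log",
    adjust_batch: bool = False,
) -> pd.DataFrame:
    """Per-gene statistics for ``contrast = (group_A, group_B)``.

    Returns a DataFrame indexed by gene with columns ``baseMean``, ``lfc``,
    ``se``, ``stat``, ``pvalue``, ``padj``.  The fold change is
    ``log2((mean_A + c) / (mean_B + c))`` on size-factor-normalized counts.
    Genes with zero counts in every sample of both contrast groups are
    dropped before testing.
    """
    group_a, group_b = contrast
    samples_a = cm.group_samples(group_a)
    samples_b = cm.group_samples(group_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError(
            f"contrast {group_a} vs {group_b} needs >=2 samples per group"
        )
    sub = cm.counts[samples_a + samples_b]
    keep = np.asarray(sub).sum(axis=1) > 0
    sub = sub.loc[keep]

    sf = size_factors(cm.counts)
    norm = _normalized(sub, sf[samples_a + samples_b])
    norm_a = np.asarray(norm[samples_a], dtype=float)
    norm_b = np.asarray(norm[samples_b], dtype=float)

    if adjust_batch:
        if "batch" not in cm.design.columns:
            raise ValueError("adjust_batch=True requires a 'batch' design column")
        allmat = np.log2(np.concatenate([norm_a, norm_b], axis=1) + pseudocount)
        batches = cm.design.loc[samples_a + samples_b, "batch"].to_numpy()
        adj = _batch_adjust_log(allmat, batches)
        resc = np.maximum(2.0**adj - pseudocount, 0.0)
        norm_a, norm_b = resc[:, : len(samples_a)], resc[:, len(samples_a):]

    mean_a = norm_a.mean(axis=1)
    mean_b = norm_b.mean(axis=1)
    base_mean = np.concatenate([norm_a, norm_b], axis=1).mean(axis=1)
    lfc = np.log2(mean_a + pseudocount) - np.log2(mean_b + pseudocount)

    if method == "welch-log":
        se, stat, p = _welch_on_log(norm_a, norm_b, pseudocount)
    elif method == "nb-wald":
        raw_a = np.asarray(sub[samples_a], dtype=float)
        raw_b = np.asarray(sub[samples_b], dtype=float)
        se, stat, p = _nb_wald(
            raw_a, raw_b,
            sf[samples_a].to_numpy(), sf[samples_b].to_numpy(),
        )
    else:
        raise ValueError(f"unknown method {method!r}")

    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "lfc": lfc,
            "se": se,
            "stat": stat,
            "pvalue": p,
            "padj": bh_adjust(p),
        },
        index=sub.index,
    )


def shrink_lfc(stats: pd.DataFrame, min_genes: int = 10) -> pd.DataFrame:
    """Add a shrunken log2 fold change column ``slfc``.

    A normal-prior ridge: ``slfc = lfc * tau2 / (tau2 + se^2)`` with the
    prior variance estimated by moment matching,
    ``tau2 = max(0, var(lfc) - mean(se^2))``.  With too few genes the
    moment estimate is unstable; shrinkage is then skipped (slfc = lfc)
    with a warning.  ``se = 0`` genes keep their raw lfc; ``tau2 = 0``
    (pure-noise fold changes) shrinks everything to zero.
    """
    out = stats.copy()
    lfc = out["lfc"].to_numpy(float)
    se = out["se"].to_numpy(float)
    if len(out) < min_genes:
        warnings.warn(
            f"fewer than {min_genes} genes: prior variance undefined, "
            "shrinkage skipped",
            stacklevel=2,
        )
        out["slfc"] = lfc
        return out
    tau2 = max(0.0, float(np.var(lfc, ddof=1) - np.mean(se**2)))
    denom = tau2 + se**2
    with np.errstate(divide="ignore", invalid="ignore"):
        shrunk = np.where(denom > 0, lfc * tau2 / denom, lfc)
    out["slfc"] = shrunk
    return out


def rank_genes(stats: pd.DataFrame, comparison: str = "") -> RankedList:
    """Rank genes descending by slfc with a deterministic tie-break.

    Ties on slfc are broken by the test statistic (descending), then by
    gene id (ascending lexicographic), giving a strict total order.
    """
    if "slfc" not in stats.columns:
        raise ValueError("run shrink_lfc first: 'slfc' column missing")
    df = stats.reset_index(names="gene")
    df = df.sort_values(
        ["slfc", "stat", "gene"], ascending=[False, False, True], kind="stable"
    )
    return RankedList(
        genes=list(df["gene"]),
        scores=df["slfc"].to_numpy(float),
        comparison=comparison,
    )


def classify_volcano(
    stats: pd.DataFrame,
    padj_thr: float = 0.05,
    fc_thr: float = 2.0,
    fc_scale: str = "linear",
) -> pd.Series:
    """Classify genes as ``up`` / ``down`` / ``significant-only`` / ``ns``.

    ``up`` requires ``padj < padj_thr`` together with the fold-change gate;
    ``down`` is symmetric.  ``significant-only`` marks genes that pass the
    adjusted-p criterion but not the fold-change one.  The fold-change gate
    on slfc reads ``fc_thr`` on the linear scale by default (2-fold, i.e.
    |slfc| >= log2(fc_thr)); ``fc_scale="log2"`` instead requires
    |slfc| > fc_thr in log2 units.
    """
    if fc_scale == "linear":
        cut = np.log2(fc_thr)
        hi = stats["slfc"] >= cut
        lo = stats["slfc"] <= -cut
    elif fc_scale == "log2":
        hi = stats["slfc"] > fc_thr
        lo = stats["slfc"] < -fc_thr
    else:
        raise ValueError(f"unknown fc_scale {fc_scale!r}")
    sig = stats["padj"] < padj_thr
    cls = np.where(
        sig & hi, "up",
        np.where(sig & lo, "down", np.where(sig, "significant-only", "ns")),
    )
    return pd.Series(cls, index=stats.index, name="class")


def write_gene_stats(stats: pd.DataFrame, path) -> None:
    out = stats.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.10g")
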