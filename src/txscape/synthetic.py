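"""Synthetic three-group RNA-seq studies with planted pathway signals.

Generates everything a landscape run consumes — a negative-binomial
gene-by-sample count matrix with a group design, a gene-set collection in
which chosen sets carry known coordinated expression shifts, and a small
ligand/receptor pair table — so that every downstream stage (differential
expression, enrichment, network construction, clustering, projection,
interactome overlay) can be exercised and validated against ground truth
without any external data.

The generative model
--------------------
Gene baseline means are log-normal: ``log mu_g ~ Normal(mean_log_mu,
sd_log_mu)`` (natural log).  Counts are negative-binomial with
``Var = mu + phi * mu^2`` and a decreasing mean–dispersion trend
``phi_g = phi0 + a / mu_g``, the shape commonly fitted to bulk RNA-seq.
Per-sample library-size factors are drawn log-uniformly within
``library_size_range`` and scale every gene mean of that sample.

A planted signal names a gene set, the pairwise comparisons it should
affect, a direction, a log2 effect size, and the fraction of member genes
("responders") that actually shift.  For an affected comparison
``X_vs_Y``, responder means in group ``X`` are multiplied by
``2**member_effect_lfc`` (divided, for a depleted signal).  Because
signals act through group means, a signal planted for ``A_vs_C`` and
``B_vs_C`` (a "shared" signal) is by construction null in ``A_vs_B``,
while an ``A_vs_C``-specific signal also separates ``A`` from ``B`` —
exactly the dichotomy the projection stage is designed to expose.

Three groups default to ``A`` and ``B`` (two disease-like groups) versus
``C`` (control); comparisons are labelled ``A_vs_C``, ``B_vs_C``,
``A_vs_B``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .diffexpr import CountMatrix
from .genesets import GeneSet, GeneSetCollection

VALID_COMPARISONS = ("A_vs_C", "B_vs_C", "A_vs_B")


@dataclass(frozen=True)
class PlantedSignal:
    """Ground truth for one gene set's planted expression shift.

    Signals sharing a non-empty ``family`` label draw their members from
    one common gene pool, so family members overlap — the redundancy that
    enrichment-map edges and Markov clusters are designed to expose.
    Signals within a family must agree on direction, effect size,
    responder fraction and affected comparisons.
    """

    set_id: str
    affected_comparisons: tuple[str, ...]
    direction: str = "enriched"  # or "depleted"
    member_effect_lfc: float = 1.0
    responder_fraction: float = 0.5
    family: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("enriched", "depleted"):
            raise ValueError(f"bad direction {self.direction!r}")
        if not 0.0 < self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must be in (0, 1]")
        if self.member_effect_lfc <= 0:
            raise ValueError("member_effect_lfc must be positive")
        bad = set(self.affected_comparisons) - set(VALID_COMPARISONS)
        if bad:
            raise ValueError(f"unknown comparisons: {sorted(bad)}")
        if not self.affected_comparisons:
            raise ValueError("a planted signal must affect >=1 comparison")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe a moderate-depth bulk study of well-expressed genes:
    baseline means around e^5 ~ 150 counts with a 1.2 natural-log spread,
    dispersion ``phi = 0.05 + 1/mu`` (shot noise dominating weak genes,
    ~5% overdispersion CV^2 for strong ones), eight samples per group, and
    up to two-fold library-depth variation.
    """

    n_genes: int = 5000
    groups: tuple[str, ...] = ("A", "B", "C")
    n_per_group: int = 8
    mean_log_mu: float = 5.0
    sd_log_mu: float = 1.2
    dispersion_intercept: float = 0.05
    dispersion_slope: float = 1.0
    n_sets: int = 200
    set_size_range: tuple[int, int] = (15, 100)
    planted_sets: tuple[PlantedSignal, ...] = ()
    library_size_range: tuple[float, float] = (0.6, 1.6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if len(self.groups) != 3:
            raise ValueError("exactly three groups are modelled")
        lo, hi = self.set_size_range
        if lo < 2 or hi < lo:
            raise ValueError("set sizes must be >= 2 with min <= max")
        if hi > self.n_genes:
            raise ValueError("set size exceeds gene universe")
        if self.dispersion_intercept <= 0 or self.dispersion_slope < 0:
            raise ValueError("dispersion parameters out of range")
        if self.mean_log_mu is None or self.sd_log_mu < 0:
            raise ValueError("bad log-mean parameters")
        llo, lhi = self.library_size_range
        if llo <= 0 or lhi < llo:
            raise ValueError("library size factors must be positive")
        names = [p.set_id for p in self.planted_sets]
        if len(set(names)) != len(names):
            raise ValueError("duplicate planted set ids")
        fams: dict[str, PlantedSignal] = {}
        for p in self.planted_sets:
            if not p.family:
                continue
            ref = fams.setdefault(p.family, p)
            if (
                p.direction != ref.direction
                or p.member_effect_lfc != ref.member_effect_lfc
                or p.responder_fraction != ref.responder_fraction
                or p.affected_comparisons != ref.affected_comparisons
            ):
                raise ValueError(
                    f"family {p.family!r} mixes incompatible signals"
                )


@dataclass
class SyntheticStudy:
    """A complete simulated study with its ground truth."""

    counts: CountMatrix
    collection: GeneSetCollection
    truth: tuple[PlantedSignal, ...]
    interactome: pd.DataFrame
    responders: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def write(self, outdir) -> dict[str, str]:
        """Write counts/design/GMT/pairs/truth as plain-text files."""
        import os

        from .genesets import write_gmt

        os.makedirs(outdir, exist_ok=True)
        paths = {
            "counts": os.path.join(outdir, "counts.tsv"),
            "design": os.path.join(outdir, "design.tsv"),
            "gmt": os.path.join(outdir, "sets.gmt"),
            "pairs": os.path.join(outdir, "pairs.tsv"),
            "truth": os.path.join(outdir, "truth.tsv"),
        }
        self.counts.to_tsv(paths["counts"], paths["design"])
        write_gmt(self.collection, paths["gmt"])
        self.interactome.to_csv(paths["pairs"], sep="\t", index=False)
        rows = [
            {
                "set_id": p.set_id,
                "affected_comparisons": ",".join(p.affected_comparisons),
                "direction": p.direction,
                "member_effect_lfc": p.member_effect_lfc,
                "responder_fraction": p.responder_fraction,
                "responder_genes": "|".join(self.responders.get(p.set_id, ())),
            }
            for p in self.truth
        ]
        pd.DataFrame(
            rows,
            columns=[
                "set_id", "affected_comparisons", "direction",
                "member_effect_lfc", "responder_fraction", "responder_genes",
            ],
        ).to_csv(paths["truth"], sep="\t", index=False)
        return paths


# ---------------------------------------------------------------------------
# deterministic sub-streams: one child seed per concern so that e.g. the
# collection is identical whether or not counts were drawn first


def _child_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(5)
    names = ("members", "counts", "collection", "interactome", "library")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"G{i:0{width}d}" for i in range(n)]


def _planted_assignment(
    config: SimulationConfig,
) -> tuple[
    dict[str, tuple[str, ...]],
    dict[str, tuple[str, ...]],
    dict[str, tuple[PlantedSignal, tuple[str, ...]]],
]:
    """Members and responder genes per planted set (seed-deterministic).

    Families draw from disjoint gene pools so that each family carries an
    unambiguous ground truth.  A singleton family's pool is exactly its
    set: members are the pool, responders the first ``round(f * k)`` of
    the drawn order (at least one).  A multi-set family shares a pool of
    roughly 70% of the summed set sizes; each set samples its members
    from the pool, so family members overlap, and a set's responders are
    its members that fall into the family-level responder slice — per-set
    responder counts then hold in expectation rather than exactly.

    Returns (members per set, responders per set, family truth:
    representative signal + family responder genes).
    """
    rng = _child_rngs(config.seed)["members"]
    genes = _gene_ids(config.n_genes)
    pool = list(rng.permutation(genes))
    lo, hi = config.set_size_range
    members: dict[str, tuple[str, ...]] = {}
    responders: dict[str, tuple[str, ...]] = {}
    family_truth: dict[str, tuple[PlantedSignal, tuple[str, ...]]] = {}

    families: dict[str, list[PlantedSignal]] = {}
    for sig in config.planted_sets:
        families.setdefault(sig.family or sig.set_id, []).append(sig)

    for fam, sigs in families.items():
        sizes = [int(rng.integers(lo, hi + 1)) for _ in sigs]
        if len(sigs) == 1:
            pool_size = sizes[0]
        else:
            pool_size = max(max(sizes), int(round(0.7 * sum(sizes))))
        if pool_size > len(pool):
            raise ValueError("gene universe exhausted by planted sets")
        fam_pool = pool[:pool_size]
        pool = pool[pool_size:]
        frac = sigs[0].responder_fraction
        fam_resp = tuple(fam_pool[: max(1, int(round(frac * pool_size)))])
        family_truth[fam] = (sigs[0], fam_resp)
        resp_set = set(fam_resp)
        for sig, size in zip(sigs, sizes):
            if len(sigs) == 1:
                chosen = tuple(fam_pool)
            else:
                idx = sorted(rng.choice(pool_size, size=size, replace=False))
                chosen = tuple(fam_pool[i] for i in idx)
            members[sig.set_id] = chosen
            responders[sig.set_id] = tuple(g for g in chosen if g in resp_set)
    return members, responders, family_truth


def _group_log2_offsets(
    config: SimulationConfig,
    family_truth: dict[str, tuple[PlantedSignal, tuple[str, ...]]],
) -> pd.DataFrame:
    """Per-gene, per-group log2 mean offsets implied by the planted truth.

    Offsets accumulate per family, so a gene shared by two sets of one
    family shifts once; distinct families occupy disjoint gene pools.
    """
    genes = _gene_ids(config.n_genes)
    off = pd.DataFrame(0.0, index=genes, columns=list(config.groups))
    short = {"A": config.groups[0], "B": config.groups[1], "C": config.groups[2]}
    for sig, resp in family_truth.values():
        sign = 1.0 if sig.direction == "enriched" else -1.0
        for comp in sig.affected_comparisons:
            first = short[comp.split("_vs_")[0]]
            for g in resp:
                off.loc[g, first] += sign * sig.member_effect_lfc
    return off


def simulate_counts(config: SimulationConfig) -> SyntheticStudy:
    """Draw the full synthetic study: counts, collection, truth, pairs.

    Counts are gene-wise negative binomial with the configured
    mean–dispersion trend, sample library factors, and planted group
    effects.  Identical configs (including seed) give byte-identical
    output.
    """
    rngs = _child_rngs(config.seed)
    genes = _gene_ids(config.n_genes)
    _, responders, family_truth = _planted_assignment(config)

    mu = np.exp(
        rngs["counts"].normal(config.mean_log_mu, config.sd_log_mu, config.n_genes)
    )
    phi = config.dispersion_intercept + config.dispersion_slope / mu

    n_samples = config.n_per_group * len(config.groups)
    llo, lhi = config.library_size_range
    lib = np.exp(rngs["library"].uniform(np.log(llo), np.log(lhi), n_samples))

    sample_ids, sample_groups = [], []
    for g in config.groups:
        for i in range(config.n_per_group):
            sample_ids.append(f"{g}_{i + 1:02d}")
            sample_groups.append(g)

    offsets = _group_log2_offsets(config, family_truth)
    off_mat = offsets[sample_groups].to_numpy()  # genes x samples

    mean_mat = mu[:, None] * lib[None, :] * (2.0**off_mat)
    r = (1.0 / phi)[:, None]  # NB shape; Var = mu + phi mu^2
    p_nb = r / (r + mean_mat)
    counts = rngs["counts"].negative_binomial(r, p_nb)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=sample_ids),
        design=pd.DataFrame({"group": sample_groups}, index=sample_ids),
    )
    collection = simulate_collection(config)
    interactome = simulate_interactome(config)
    return SyntheticStudy(
        counts=cm,
        collection=collection,
        truth=tuple(config.planted_sets),
        interactome=interactome,
        responders=responders,
    )


def simulate_collection(config: SimulationConfig) -> GeneSetCollection:
    """Gene-set collection with the planted sets plus uniform null sets.

    Null-set sizes are uniform in ``set_size_range``; members are drawn
    without replacement from the whole gene universe.  Planted sets use
    their designated members, so the collection is consistent with the
    count matrix drawn from the same config.
    """
    rng = _child_rngs(config.seed)["collection"]
    genes = np.array(_gene_ids(config.n_genes))
    members, _, _ = _planted_assignment(config)
    lo, hi = config.set_size_range
    sets: list[GeneSet] = []
    for sig in config.planted_sets:
        sets.append(
            GeneSet(sig.set_id, f"planted_{sig.direction}", members[sig.set_id])
        )
    n_null = config.n_sets - len(sets)
    if n_null < 0:
        raise ValueError("n_sets smaller than the number of planted sets")
    for i in range(n_null):
        size = int(rng.integers(lo, hi + 1))
        chosen = tuple(rng.choice(genes, size=size, replace=False))
        sets.append(GeneSet(f"NULL_{i:04d}", "random", chosen))
    return GeneSetCollection(sets, source=f"synthetic(seed={config.seed})")


def simulate_interactome(
    config: SimulationConfig, n_pairs: int = 30
) -> pd.DataFrame:
    """A synthetic directed ligand→receptor pair table (unique pairs)."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = _child_rngs(config.seed)["interactome"]
    genes = np.array(_gene_ids(config.n_genes))
    pairs: set[tuple[str, str]] = set()
    rows = []
    while len(rows) < n_pairs:
        lig, rec = rng.choice(genes, size=2, replace=False)
        if (lig, rec) in pairs:
            continue
        pairs.add((lig, rec))
        rows.append({"ligand": lig, "receptor": rec, "source": "synthetic"})
    return pd.DataFrame(rows, columns=["ligand", "receptor", "source"])


# ---------------------------------------------------------------------------
# canonical demo studies


def default_planted_signals() -> tuple[PlantedSignal, ...]:
    """The documented demo truth: shared, specific, and depleted themes.

    Mirrors the structure of a two-disease-versus-control design, with
    each theme planted as a small family of overlapping sets so the
    landscape stage has redundancy to cluster: one family shared by both
    disease groups, one enriched family and one depleted family specific
    to the first disease group, and one singleton specific to the second.
    """
    shared = ("A_vs_C", "B_vs_C")
    return (
        PlantedSignal("PLANT_SHARED_UP_1", shared, "enriched", 1.0, 0.6, "fam_shared"),
        PlantedSignal("PLANT_SHARED_UP_2", shared, "enriched", 1.0, 0.6, "fam_shared"),
        PlantedSignal("PLANT_SHARED_UP_3", shared, "enriched", 1.0, 0.6, "fam_shared"),
        PlantedSignal("PLANT_A_UP_1", ("A_vs_C",), "enriched", 1.0, 0.6, "fam_a_up"),
        PlantedSignal("PLANT_A_UP_2", ("A_vs_C",), "enriched", 1.0, 0.6, "fam_a_up"),
        PlantedSignal("PLANT_A_UP_3", ("A_vs_C",), "enriched", 1.0, 0.6, "fam_a_up"),
        PlantedSignal("PLANT_A_DOWN_1", ("A_vs_C",), "depleted", 1.0, 0.6, "fam_a_dn"),
        PlantedSignal("PLANT_A_DOWN_2", ("A_vs_C",), "depleted", 1.0, 0.6, "fam_a_dn"),
        PlantedSignal("PLANT_B_UP_1", ("B_vs_C",), "enriched", 1.0, 0.6),
    )


def fixture_config(seed: int = 0) -> SimulationConfig:
    """Desk-scale demo study used by the examples and the packaged fixture."""
    return SimulationConfig(
        n_genes=2000,
        n_per_group=8,
        n_sets=100,
        set_size_range=(15, 80),
        planted_sets=default_planted_signals(),
        seed=seed,
    )


def null_config(seed: int = 0, n_genes: int = 5000) -> SimulationConfig:
    """A no-signal study: every downstream p-value should be uniform."""
    return SimulationConfig(n_genes=n_genes, planted_sets=(), seed=seed)


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=seed)
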