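"""End-to-end orchestration: config, staged runs, manifests, fixtures.

A run starts from four plain-text inputs — counts TSV, design TSV, a GMT
collection and a ligand/receptor pair TSV — and produces, per the
configured comparisons: gene statistics and RNK ranked lists, enrichment
tables, the anchor-comparison landscape network (GraphML + TSVs) with MCL
clusters and projected annotations, tidy theme summaries, the interactome
overlay, and a JSON manifest recording every parameter and the SHA-256 of
every input and output.  Identical config + seed reproduce every artifact
byte for byte; the manifest is the reproducibility receipt.

Comparisons are computed pairwise (no joint model); the first-listed
comparison is the anchor whose network topology all others are projected
onto.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import yaml

from . import diffexpr, enrichment, genesets, interactome, landscape
from .synthetic import fixture_config, simulate_counts

log = logging.getLogger("txscape")


@dataclass
class PipelineConfig:
    """Every knob of a landscape run, serializable to YAML."""

    counts: str = "counts.tsv"
    design: str = "design.tsv"
    gmt: str = "sets.gmt"
    pairs: str = "pairs.tsv"
    outdir: str = "landscape_out"
    # comparisons as "GROUP1_vs_GROUP2"; the first is the anchor scaffold
    comparisons: tuple[str, ...] = ("A_vs_C", "B_vs_C", "A_vs_B")
    seed: int = 0
    pseudocount: float = diffexpr.DEFAULT_PSEUDOCOUNT
    de_method: str = "welch-log"
    adjust_batch: bool = False
    fc_thr: float = 2.0
    fc_scale: str = "linear"
    gene_padj_thr: float = 0.05
    min_set_size_exclusive: int = 10
    max_set_size_exclusive: int = 500
    nperm: int = enrichment.DEFAULT_NPERM
    weight_p: float = 1.0
    node_padj_thr: float = 0.001
    node_le_frac_thr: float = 0.3334
    edge_le_gate: float = 0.05
    inflation: float = 2.0
    tiers: tuple[float, ...] = (0.001, 0.01, 0.05)

    def __post_init__(self) -> None:
        for name in ("node_padj_thr", "gene_padj_thr", "edge_le_gate"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for comp in self.comparisons:
            if "_vs_" not in comp:
                raise ValueError(f"comparison {comp!r} must be 'X_vs_Y'")

    @property
    def anchor(self) -> str:
        return self.comparisons[0]

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["comparisons"] = list(self.comparisons)
        d["tiers"] = list(self.tiers)
        with open(path, "wt", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        if "comparisons" in d:
            d["comparisons"] = tuple(d["comparisons"])
        if "tiers" in d:
            d["tiers"] = tuple(d["tiers"])
        return cls(**d)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _contrast(comp: str) -> tuple[str, str]:
    a, b = comp.split("_vs_", 1)
    return a, b


@dataclass
class RunResult:
    """Handles to everything a finished run produced."""

    config: PipelineConfig
    stats: dict = field(default_factory=dict)
    ranked: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)
    network: landscape.LandscapeNetwork | None = None
    clustering: dict = field(default_factory=dict)
    themes: object = None
    overlay: interactome.InteractomeGraph | None = None
    manifest_path: str = ""


def run_all(config: PipelineConfig) -> RunResult:
    """Execute the whole pipeline; see the module docstring for outputs."""
    for name in ("counts", "design", "gmt", "pairs"):
        path = getattr(config, name)
        if not os.path.exists(path):
            raise FileNotFoundError(f"[input] missing {name} file: {path}")
    os.makedirs(config.outdir, exist_ok=True)
    out = config.outdir
    manifest: dict = {
        "config": {**asdict(config),
                   "comparisons": list(config.comparisons),
                   "tiers": list(config.tiers)},
        "inputs": {
            name: {"path": getattr(config, name), "sha256": _sha256(getattr(config, name))}
            for name in ("counts", "design", "gmt", "pairs")
        },
        "outputs": {},
    }
    result = RunResult(config=config)

    def record(key: str, path: str) -> None:
        manifest["outputs"][key] = {
            "path": os.path.relpath(path, out),
            "sha256": _sha256(path),
        }

    # ---- stage: load -----------------------------------------------------
    log.info("stage=load counts=%s design=%s", config.counts, config.design)
    cm = diffexpr.CountMatrix.from_tsv(config.counts, config.design)
    collection = genesets.read_gmt(config.gmt)
    filtered = genesets.filter_by_size(
        collection, config.min_set_size_exclusive, config.max_set_size_exclusive
    )
    log.info(
        "stage=genesets %s", genesets.size_filter_report(collection, filtered)
    )
    pairs = interactome.load_pairs(config.pairs)

    # ---- stage: differential expression ----------------------------------
    stats_for_overlay = {}
    for comp in config.comparisons:
        try:
            stats = diffexpr.gene_stats(
                cm, _contrast(comp),
                pseudocount=config.pseudocount,
                method=config.de_method,
                adjust_batch=config.adjust_batch,
            )
        except Exception as exc:
            raise RuntimeError(f"[diffexpr] {comp}: {exc}") from exc
        stats = diffexpr.shrink_lfc(stats)
        stats["class"] = diffexpr.classify_volcano(
            stats, config.gene_padj_thr, config.fc_thr, config.fc_scale
        )
        ranked = diffexpr.rank_genes(stats, comparison=comp)
        result.stats[comp] = stats
        result.ranked[comp] = ranked
        stats_for_overlay[comp] = stats
        spath = os.path.join(out, f"gene_stats.{comp}.tsv")
        rpath = os.path.join(out, f"ranked.{comp}.rnk")
        diffexpr.write_gene_stats(stats, spath)
        ranked.to_rnk(rpath)
        record(f"gene_stats.{comp}", spath)
        record(f"ranked.{comp}", rpath)
        log.info("stage=diffexpr comparison=%s genes=%d", comp, len(ranked))

    # ---- stage: enrichment ------------------------------------------------
    seeds = _comparison_seeds(config.seed, config.comparisons)
    for comp in config.comparisons:
        try:
            table = enrichment.run_enrichment(
                result.ranked[comp], filtered,
                nperm=config.nperm, seed=seeds[comp], weight_p=config.weight_p,
            )
        except Exception as exc:
            raise RuntimeError(f"[enrichment] {comp}: {exc}") from exc
        result.tables[comp] = table
        epath = os.path.join(out, f"enrichment.{comp}.tsv")
        table.write_tsv(epath)
        record(f"enrichment.{comp}", epath)
        log.info("stage=enrichment comparison=%s sets=%d", comp, len(table))

    # ---- stage: landscape network ------------------------------------------
    anchor = config.anchor
    net = landscape.build_network(
        result.tables[anchor],
        padj_thr=config.node_padj_thr,
        le_frac_thr=config.node_le_frac_thr,
        le_gate=config.edge_le_gate,
    )
    if net.n_nodes > 0:
        clustering = landscape.mcl_cluster(net, inflation=config.inflation)
    else:
        clustering = {"clusters": {}, "converged": True, "iterations": 0,
                      "inflation": config.inflation}
    for comp in config.comparisons[1:]:
        landscape.project_comparison(net, result.tables[comp], config.tiers)
    result.network = net
    result.clustering = clustering
    log.info(
        "stage=landscape nodes=%d edges=%d clusters=%d",
        net.n_nodes, net.n_edges, len(set(clustering["clusters"].values())),
    )
    paths = landscape.export_network(net, os.path.join(out, "landscape"))
    for key, p in paths.items():
        record(f"landscape.{key}", p)

    if net.n_nodes > 0:
        themes = landscape.theme_signed_pvalues(net)
        labels = landscape.cluster_label_suggestions(net)
    else:
        import pandas as pd

        themes = pd.DataFrame(columns=["cluster", "comparison", "set", "value"])
        labels = {}
    result.themes = themes
    tpath = os.path.join(out, "theme_summary.tsv")
    themes.to_csv(tpath, sep="\t", index=False, float_format="%.6f")
    record("theme_summary", tpath)
    lpath = os.path.join(out, "cluster_labels.tsv")
    with open(lpath, "wt", encoding="utf-8") as fh:
        fh.write("cluster\ttokens\n")
        for cid in sorted(labels):
            fh.write(f"{cid}\t{'|'.join(labels[cid])}\n")
    record("cluster_labels", lpath)

    # ---- stage: interactome overlay ----------------------------------------
    ig = interactome.overlay(pairs, stats_for_overlay)
    result.overlay = ig
    ipaths = interactome.export_interactome(ig, os.path.join(out, "interactome"))
    for key, p in ipaths.items():
        record(f"interactome.{key}", p)
    log.info("stage=interactome genes=%d pairs=%d",
             len(ig.genes), len(ig.pairs))

    # ---- manifest ----------------------------------------------------------
    mpath = os.path.join(out, "manifest.json")
    with open(mpath, "wt", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    result.manifest_path = mpath
    log.info("stage=done manifest=%s", mpath)
    return result


def _comparison_seeds(seed: int, comparisons) -> dict[str, int]:
    """Stable per-comparison enrichment seeds derived from the run seed."""
    import numpy as np

    children = np.random.SeedSequence(seed).spawn(len(comparisons))
    return {
        comp: int(c.generate_state(1)[0] % (2**31))
        for comp, c in zip(comparisons, children)
    }


def make_fixture(outdir, seed: int = 0) -> PipelineConfig:
    """Write the documented demo study and a ready-to-run config.

    A desk-scale three-group study (two disease-like groups A and B versus
    control C) with shared and group-specific planted signals; the truth
    sidecar lists every planted set.  Regeneration with the same seed is
    byte-identical.
    """
    os.makedirs(outdir, exist_ok=True)
    study = simulate_counts(fixture_config(seed))
    paths = study.write(outdir)
    config = PipelineConfig(
        counts=paths["counts"],
        design=paths["design"],
        gmt=paths["gmt"],
        pairs=paths["pairs"],
        outdir=os.path.join(outdir, "results"),
        seed=seed,
    )
    config.to_yaml(os.path.join(outdir, "config.yaml"))
    return config
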