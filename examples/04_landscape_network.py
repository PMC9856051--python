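"""Build, cluster and project the transcriptional landscape network.

Anchors the network on A vs C (nodes: padj<0.001 and leading edge >=
33.34% of members; edges: leading edges sharing >=5% of the smaller
member set), clusters it with Markov clustering, then projects the
A-vs-B comparison onto the fixed scaffold. Shared themes go quiet in
A-vs-B; A-specific themes stay significant — the specificity dichotomy.
"""

from txscape import diffexpr as de
from txscape import landscape as ls
from txscape.enrichment import run_enrichment
from txscape.genesets import filter_by_size
from txscape.synthetic import fixture_config, simulate_counts

study = simulate_counts(fixture_config(seed=0))
collection = filter_by_size(study.collection)

tables = {}
for comp, contrast in (("A_vs_C", ("A", "C")), ("A_vs_B", ("A", "B")),
                       ("B_vs_C", ("B", "C"))):
    stats = de.shrink_lfc(de.gene_stats(study.counts, contrast))
    ranked = de.rank_genes(stats, comparison=comp)
    tables[comp] = run_enrichment(ranked, collection, seed=0)

net = ls.build_network(tables["A_vs_C"])
clustering = ls.mcl_cluster(net)
for comp in ("A_vs_B", "B_vs_C"):
    ls.project_comparison(net, tables[comp])

print(f"scaffold (A_vs_C): {net.n_nodes} nodes, {net.n_edges} edges")
print(f"MCL: {len(set(clustering['clusters'].values()))} clusters, "
      f"converged in {clustering['iterations']} iterations")
for cid, tokens in ls.cluster_label_suggestions(net, top=3).items():
    members = sorted(v for v, c in net.clusters.items() if c == cid)
    print(f"  cluster {cid}: {members}  label hints: {tokens}")

themes = ls.theme_signed_pvalues(net)
piv = themes.pivot_table(index="set", columns="comparison", values="value")
print("\nsigned -log10 adjusted p per node (+enriched / -depleted):")
print(piv.round(2).to_string())
print(
    "\nreading: A-specific themes keep |value| > 1.3 (padj<0.05) in "
    "A_vs_B, shared themes drop to ~0 there — specificity made visible "
    "on one fixed scaffold"
)
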