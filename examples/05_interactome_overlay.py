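"""Overlay differential-expression classes on a ligand/receptor graph.

Uses the packaged curated interleukin/interferon pair table with a small
hand-made stats frame to show the two signalling-relevant pair flags:
receptor-only activation (paracrine signature: the tissue upregulates a
receptor without its ligand) and autocrine candidates (both up).
"""

import pandas as pd

from txscape.interactome import bundled_interleukin_pairs, overlay

pairs = bundled_interleukin_pairs()
print(f"curated pair table: {len(pairs)} ligand->receptor relations")
print("examples:", [(p.ligand, p.receptor) for p in pairs[:4]])

# a miniature stats frame: IL7R up without IL7; IL33 and IL1RL1 both up
stats = pd.DataFrame(
    {
        "slfc": [0.2, 2.1, 1.6, 1.8, -0.1],
        "padj": [0.60, 0.001, 0.01, 0.02, 0.90],
        "class": ["ns", "up", "up", "up", "ns"],
    },
    index=["IL7", "IL7R", "IL33", "IL1RL1", "IL12B"],
)

graph = overlay(pairs, {"disease_vs_control": stats})
flags = graph.pair_flags("disease_vs_control")
interesting = flags[flags["flag"].isin(
    ["receptor-only-activation", "autocrine-candidate"]
)]
print("\nflagged pairs:")
print(interesting.to_string(index=False))
print(
    "\nreceptor-only-activation marks receptors upregulated without "
    "their ligand (response to a distantly produced cytokine); "
    "autocrine-candidate marks ligand+receptor co-upregulation"
)
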