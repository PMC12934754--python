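"""Detect a clone that biologically expresses three TCR chains.

Simulates a sample with dual-α clones planted (10% of clones), detects them
from repeated chain-triple co-observation, and shows how cells carrying only
two of the three chains are joined back to the full clonotype.
"""

from eclipse_tcr import EclipseConfig, SimConfig, run_eclipse, simulate
from eclipse_tcr.special_clones import classify_cell_in_special_clone

sim = simulate(SimConfig(n_clones=60, seed=8, frac_triple_alpha=0.1))
result = run_eclipse(sim.contigs, sim.cells, EclipseConfig())
res = result.samples["S1"]

truth = {c["label"] for c in sim.truth["clones"] if c["triple"]}
print(f"planted dual-chain clones: {len(truth)}, detected: {len(res.special)}")
for sp in res.special:
    print(
        f"  rule {sp.rule}: monotypic {sp.monotypic_cdr3[:10]}…, "
        f"major {sp.bitypic_major[:10]}… ({sp.stats['n_cells_major']} cells), "
        f"minor {sp.bitypic_minor[:10]}… ({sp.stats['n_cells_minor']} cells)"
    )

sp = res.special[0]
members = [c for c in res.cells if result.annotations.set_index("barcode")
           .loc[c.barcode, "final_clonotype"] == sp.label]
classes = {}
for cell in members:
    classes.setdefault(classify_cell_in_special_clone(cell, sp), []).append(cell.barcode)
print(f"\ncells of clone {sp.label[:24]}… by detected bitypic chains:")
for name, barcodes in sorted(classes.items()):
    print(f"  {name:<15s} {len(barcodes)} cells")
print(
    "\nAll of these cells share one final 3-chain clonotype; without the"
    "\ndetection step the EM would have split them across 2-chain labels."
)
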