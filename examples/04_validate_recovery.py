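"""Validate clonotype recovery with chain removal/addition simulations.

Deletes (or grafts) one chain in 200 cells with a ground-truth 1α:1β
clonotype, re-runs the pipeline, and classifies each perturbed cell's fate:
same call recovered, a different (incorrect) confident call, or no
prediction. Unperturbed cells act as a stability control.
"""

from eclipse_tcr import SimConfig, io_contigs, run_eclipse, simulate, validation

sim = simulate(SimConfig(seed=3))
filtered = io_contigs.filter_contigs(sim.contigs, set(sim.cells["barcode"]))
before = run_eclipse(sim.contigs, sim.cells)

for name, perturb in (("removal", validation.perturb_remove),
                      ("addition", validation.perturb_add)):
    perturbed, record = perturb(filtered, 200, seed=99)
    after = run_eclipse(perturbed, sim.cells)
    outcome = validation.classify_outcomes(before.annotations, after.annotations, record)
    c = outcome.counts
    print(f"chain {name}: {c['n_affected']} perturbed cells")
    print(f"  same call recovered : {c['same_call']} ({100 * c['same_call'] / c['n_affected']:.1f}%)")
    print(f"  new (wrong) clone   : {c['new_clonotype']}")
    print(f"  no prediction       : {c['no_prediction']}")
    unchanged = 100 * (1 - c["unaffected_changed"] / c["n_unaffected"])
    print(f"  unperturbed cells with identical calls: {unchanged:.2f}%\n")

print(
    "A high same-call rate with near-zero wrong calls means the EM recovers"
    "\ndropped chains and ignores grafted ones rather than inventing clones."
)
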