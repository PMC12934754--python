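"""Resolve clonally ambiguous cells with the EM assignment.

Builds a tiny sample in which three cells carry the full (α1, β1) pair, one
cell carries (α2, β1), and one cell lost its α chain to dropout, then shows
how the β-only cell's posterior follows the sample-wide clonotype
frequencies rather than an arbitrary choice.
"""

from eclipse_tcr import build_universe, compatibility, run_em
from eclipse_tcr.io_contigs import CellChainSet

cells = [CellChainSet(f"cell{i}", "S1", {"CAVRDNF"}, {"CASSLGF"}) for i in range(3)]
cells.append(CellChainSet("cell3", "S1", {"CAGPFQF"}, {"CASSLGF"}))
cells.append(CellChainSet("cell4", "S1", set(), {"CASSLGF"}))  # ambiguous: β only

universe, chain_index = build_universe(cells)
records = [compatibility(c, universe, chain_index) for c in cells]
result = run_em(records, len(universe))

print("clonotype universe and converged marginal distribution θ:")
for clonotype, theta in zip(universe, result.theta):
    print(f"  {clonotype.label:<20s} θ = {theta:.4f}")

posterior = result.assignment.getrow(4).toarray().ravel()
print("\nposterior for the β-only cell (cell4):")
for clonotype in universe:
    print(f"  P({clonotype.label}) = {posterior[clonotype.id]:.4f}")

print(
    "\nThe ambiguous cell is assigned 3:1 odds matching the sample's pairing"
    "\nevidence — the fixed point of θ = (3+θ₁)/5 — instead of being dropped."
)
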