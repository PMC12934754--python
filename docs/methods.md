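# Methods

## Model

Each cell of a sample carries a latent clonotype Z drawn i.i.d. from a
marginal clonotype distribution θ over a finite universe. A clonotype is an
identity of 2 chains (1 TCRα + 1 TCRβ) or, for dual-chain clones, 3 chains
(2α+1β or 1α+2β); a chain's identity is its CDR3 amino-acid sequence plus
chain type. Nucleotide CDR3 and V/D/J/C segments are carried as metadata but
never enter identity — two clones with identical CDR3-aa pairs are
indistinguishable (a rare but real collision mode; see Limitations).

What is observed per cell is a chain set corrupted by dropout and possibly
augmented by contamination. The observation model is pure censoring: the
likelihood of a cell is `Σ_{k ∈ cand(i)} θ_k`, where `cand(i)` is the set of
clonotypes consistent with the observed chains. The EM algorithm maximizes
the observed-data likelihood: the E-step assigns responsibilities
`a_ik = θ_k / Σ_{k'∈cand(i)} θ_k'`; the M-step sets `θ_k = Σ_i a_ik / N`.
Initialization splits each cell's mass evenly over its candidates (i.e. the
first M-step is taken from uniform responsibilities). Iteration stops when
`max_k |θ_k(t+1) − θ_k(t)| < ε`; the observed-data log-likelihood is
recorded per iteration and asserted non-decreasing in the tests.

### Candidate universe

The universe is built from within-cell co-observation only: every (α, β)
pair seen together inside one cell, plus every detected 3-chain clonotype.
A pairing never co-observed in a single cell is not a candidate — this keeps
the universe finite and grounded in pairing evidence. A 2-chain pair whose
only supporting cells are fully contained in a 3-chain clone's chain set is
treated as explained by that clone and not emitted separately; independent
evidence keeps both entries alive and the EM arbitrates.

### Compatibility

* Cell with both chain types: candidates are the clonotypes containing
  **all** observed chains (this is how a 1α:1β cell can also be a candidate
  member of a 3-chain clone).
* If none exists (an extra chain not part of any dual-chain clone), the
  true clonotype must be composed of observed chains with the surplus
  explained by contamination, so candidates are the clonotypes whose chains
  are a **subset** of the observed set. A union-over-chains rule is kept
  only as a last resort. This choice is load-bearing: under a plain union
  rule a contaminating chain makes its donor clone a candidate, and in the
  chain-addition validation ~27% of perturbed cells were confidently
  reassigned to the donor clone; under the subset rule that rate is ~1%,
  consistent with contamination being ignorable noise.
* Cell with one chain type: candidates are all clonotypes containing at
  least one observed chain.
* Cells with no candidate bypass the EM and keep their observed chains.

## Dual-chain (3-chain) clone detection

A candidate triple {b1, b2, m} (two bitypic chains of one type, one
monotypic chain of the other) is called when either ≥3 cells show exactly
that chain set (rule A), or one cell shows all three and one cell each
shows {b1, m} and {b2, m} exactly (rule B). Exact-set counting is
deliberate: a 4-chain cell is not evidence for a 3-chain clone. Two
artifact filters follow: ≥10% (inclusive) of the sample's cells containing
m must carry both b1 and b2, and m must be the strictly modal opposite-type
partner of b1 and of b2 (per-cell co-occurrence; ties fail, conservatively).
The bitypic chain observed in more cells is the major chain; an exact tie
is broken toward the lexicographically smaller CDR3, which is deterministic
and biologically neutral. Detection runs per sample, dual-α mode before
dual-β, non-destructively — a chain consumed by a dual-α call remains
visible to dual-β detection.

When ≥80% of cells carrying any of a clone's bitypic chains have chain sets
consistent with the clone, cells holding 1–2 bitypic chains and no
monotypic-type chain are given the full bitypic pair before the EM, so the
3-chain clonotype is considered for them.

## Calling thresholds

With p1 the top posterior, p2 the runner-up and r = p1/p2 (r = +∞ when
p2 = 0), a cell is assigned iff `p1 ≥ 0.8`, or `p1 ≥ 0.7 and r > 5`, or
`p1 > 0.5 and r > 10`. Bounds follow the printed inequalities exactly:
the first two p1 bounds inclusive, everything else strict. A cell whose
only observed chain occurs in no other cell is never assigned (a single
private contig cannot be distinguished from an artifact). After
thresholding, any final 1α:1β call matching one bitypic + the monotypic
chain of exactly one detected 3-chain clone is joined to the full clone; a
pair matching two clones is logged and left unchanged. An optional doublet
filter removes cells with >4 chains total or >2 of a type (chains under a
UMI floor optionally ignored); removed cells stay in the export with a
reason column but are excluded from clone sizes and diversity.

MAIT/iNKT flags use the canonical human semi-invariant segments
(TRAV1-2 with TRAJ33/20/12; TRAV10 with TRAJ18), allele suffixes ignored,
MAIT taking precedence.

## Comparators, clone statistics, diversity

`keep_all` labels every cell by its full observed chain set; `top_umi_pair`
keeps the highest-UMI chain of each type (ties: reads, then lexicographic
CDR3) and drops single-chain-type cells; `strict_1to1` keeps only exact
1α:1β cells. The EM pipeline counts a cell annotated when its final label
is a complete clonotype (≥1α and ≥1β). Clone proportions and diversity are
computed over annotated cells only, which is what makes values comparable
across methods. Diversity indices are the plug-in closed forms
(shannon = −Σ p ln p, inv_simpson = 1/Σp², gini_simpson = 1−Σp²,
norm_entropy = shannon/ln S, defined 0 for S = 1); bootstrap resampling of
the clone distribution is available behind an explicit seed but off by
default. Relative clone-size bins use right-closed cuts at
10⁻⁴/10⁻³/10⁻²/10⁻¹ (Rare → Hyperexpanded), configurable. Method
comparisons use two-sided Wilcoxon signed-rank tests with
Benjamini–Hochberg correction (scipy/statsmodels).

## Validation machinery

Chain removal deletes one chain (α or β, uniformly) from n distinct cells
with a ground-truth 1α:1β clonotype; chain addition grafts one contig from
n distinct *other* ground-truth cells onto n targets, rewriting barcode and
contig id, re-drawing a donor whose chain collides with an identical chain
already present. Outcomes per perturbed cell: same call, new (confidently
wrong) clonotype, or no prediction; unperturbed cells are a stability
control. All perturbation records are seeded and serializable.

Phenotypic consistency is quantified by the total variation distance
`dTV(A,B) = ½ Σ_x |A(x) − B(x)|` between the cluster-usage distributions of
two cell groups of a clone (bitypic major- vs minor-expressing, or
complete vs chain-missing). The null replicates pair random same-donor
1α:1β clones (as many pairs as test clones, drawn without replacement
within a pair) and average their dTV. The p-value is the standard
one-sided permutation estimator `p = (1 + #{permuted ≤ observed})/(1 + n_perm)`
— the count direction that makes small p mean "observed groups are more
similar than random clone pairings". Group sizes below 4 cells are
excluded from the observed set in the acceptance analysis because the
empirical distribution of 2–3 cells over 8–13 clusters is noise-dominated.

## Synthetic data generator

The generator emulates the statistical structure the method assumes:

* clone sizes geometric (default mean 8) or Zipf, with a configurable
  number of expanded clones inflated so that a target fraction of cells
  (default 20%) sits in them;
* unique random CDR3s (length 8–20, C…F convention; collisions only in an
  explicit stress mode), random V/J segments drawn from pools that exclude
  the MAIT/iNKT segments so invariant-T flags never fire by accident;
* dual-chain clones at configurable α/β fractions, forced to ≥3 cells
  because the detection rule needs 3 supporting cells — a smaller planted
  triple is undetectable by design, not an algorithmic failure;
* per-chain dropout (defaults 0.15 α / 0.10 β), ambient contamination
  drawn from the sample's own chain pool proportional to clone size
  (default rate 0.02/cell), and doublets merging two cells' chains under
  one barcode (default 0.005);
* per-clone cluster-usage distributions from a Dirichlet (concentration
  0.5 over 8 clusters) linking clones to phenotype labels;
* UMIs from a shifted negative binomial (min 1, mean 4), reads a noisy
  multiple of UMIs.

It does **not** simulate nucleotide-level V(D)J recombination, sequencing
reads, expression matrices, batch effects, or clone-correlated dropout.
Passing tests on this generator therefore demonstrate correctness of the
inference machinery under the stated noise model, not performance on any
particular real dataset.

## Numerical choices and problem sizes

ε = 1e-6 and max_iter = 10 000 for the EM (non-convergence warns and
returns); θ normalization asserted to 1e-9; posterior row sums to 1e-9.
Zero candidate mass in an E-step re-splits evenly (cannot arise from the
stated initialization; guarded anyway). Duplicate-contig winners are chosen
by UMIs, then reads, then lexicographic contig id. The test-bench and
acceptance analyses run at 200 clones (~2 000 cells) per sample, 5 seeds,
200 perturbed cells per simulation, and 5 000 permutations — sizes chosen
so the full analysis reruns in seconds while keeping every directional
result stable across seeds.

The perturbation stability control deserves one caveat: the fraction of
unperturbed cells whose call changes scales with the fraction of the
sample perturbed, because removing the sole pairing cell of a small clone
removes that clone's pair from the candidate universe and reverts its
dropout siblings to observed-chain labels. At 200 of ~2 000 cells (10%)
this is ~0.2–0.4%; at a 1% perturbation density the same mechanism yields
~0.03%.

## Limitations

CDR3-aa identity collapses clones that share amino-acid CDR3s; samples are
assumed independent (no cross-sample chain borrowing); the EM cannot rescue
clones whose pairing was never observed in any single cell (e.g. a clone
present only as α-only and β-only cells); heavily singleton-dominated
repertoires (naïve blood) leave most ambiguous cells below the confidence
thresholds by construction.
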