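# Methods

## The three-taxon model

The analytic component computes the joint probabilities that a binary
trait shared (derived) by the two non-sister taxa B and C of a species
tree ((A,B),C) arose by hemiplasy versus homoplasy, under the
multispecies network coalescent.

**Histories.**  Speciation times are `t1` (A/B) and `t2` (AB/C), in
coalescent units of 2N generations.  A single instantaneous introgression
pulse between B and C at time `tm < t1` assigns each locus to one of
three parent trees: the species history with probability `1 − (δ2 + δ3)`;
the C→B history (B and C sister from `tm`, A joining at `t2`) with
probability `δ2`; the B→C history (B and C sister from `tm`, A joining at
`t1`, since B's ancestry lets C coalesce with A earlier) with probability
`δ3`.  A locus cannot take both directions at once.  Within a parent tree
with internal interval `(lo, hi)` the sister pair coalesces before `hi`
with probability `1 − e^{−(hi−lo)}` (lineage sorting, first coalescence
at `lo + TruncExp(1)`), otherwise all three lineages enter the ancestral
population and the first coalescing pair is uniform over the three
possibilities (first coalescence at `hi + Exp(3)`, second `+ Exp(1)`).
That yields four genealogy classes per parent tree, twelve in all; tips
end at the first coalescence involving them, the internal branch spans
the two coalescences.

**Mutations.**  The trait mutates as a symmetric two-state Poisson
process.  The population-scaled rate `θ` is accepted as conventionally
printed; the per-lineage event rate per 2N generations is `θ/2`.
Hemiplasy is at least one mutation on the internal branch `λ4` of a
((B,C),A) genealogy and none elsewhere; homoplasy is either parallel
mutations on both derived tips (`λ2`, `λ3`) or a mutation on the
ancestral branch `λ5` reversed on the outgroup tip `λ1`, on any
genealogy, weighted by class probability.

**The ancestral branch and `root_depth`.**  The reversal path requires an
ancestral reference point above the genealogy's root at which the trait
is known to be ancestral (conceptually, the divergence of a distant
outgroup).  The branch `λ5` runs from the gene-tree root at `T2` up to
that depth, `λ5 = max(0, root_depth − T2)`.  The published equations do
not pin this extent down, so it is a model parameter; its default,
`root_depth = t2 + 13.4525`, is calibrated once so that the ILS-only
model at the reference parameterization (`t1 = 1`, `t2 = 3.5`,
`θ = 0.002`) reproduces the published baseline ratio `P_e/P_o = 0.818`,
which also fixes the rate convention above.  The simulation pipeline
anchors the trait's root state at the same depth whenever it is asked to
emulate the analytic model, so the two components are mutually
consistent by construction.

**Exact joint expectations.**  Within a genealogy class all five branch
lengths are functions of the two coalescence times `(T1, T2)`, so they
are correlated: the sister tips share `T1`, and `λ5` shrinks as `T2`
grows.  Configuration probabilities are therefore computed as exact joint
expectations `E[∏_{i∈S} e^{−rλ_i}]` over the coalescent law of
`(T1, T2)`, expanded by inclusion–exclusion; every term reduces to a
closed form in exponentials (including the kink at `λ5 = 0`).  The
per-branch marginal probabilities `ν(λ_i, τ)` are still exposed (they are
the quantities usually quoted), but multiplying them would ignore the
correlations, which matters at the percent level once `θ` approaches
0.01.  The simulation oracle in the test suite arbitrates: the joint form
agrees with simulated configuration counts to Monte-Carlo precision.

Because `ν` counts *at least one* event per branch, the analytic
probabilities slightly exceed what an event-counting pipeline measures
(a branch hit twice changes nothing).  The shortfall is concentrated on
the long ancestral branch, grows with `θ`, and is negligible at realistic
trait rates — the test suite verifies both the direction and the
`θ`-dependence of this gap.

**Grid scan.**  The introgression grid evaluates `P_e/P_o` over pulse
timings `tm ∈ [0.01, 0.99]` (99 steps) and total admixture
`δ ∈ [0, 0.1]` (101 steps) for three direction configurations: C→B only
(`δ2 = δ`), B→C only (`δ3 = δ`), and equal rates in both directions,
interpreted as the total split evenly (`δ2 = δ3 = δ/2`) so the three
panels share an x-axis scale.  At `δ = 0.05` the computed ratios span
roughly 1.30 (B→C, pulse just below `t1`) to 5.8 (C→B, very recent
pulse).  The B→C floor is structural: as `tm → t1` the B→C parent tree
degenerates to pure lineage sorting entered at `t1`, so its hemiplasy
probability exceeds the baseline class by exactly `e^{t2−t1}` (the
internal branch of every post-entry genealogy is `Exp(1)` regardless of
entry time), capping the column minimum near 1.35 at these parameters
for any choice of the ancestral-branch extent or rate convention.

## The simulation pipeline

**Engine.**  Backwards-in-time structured coalescent with one haploid
sample per species: within a population, `k` lineages coalesce at rate
`k(k−1)/2` per 2N generations; at a pulse time each lineage currently in
the recipient population independently jumps to the donor population with
the pulse probability (matching the per-locus parent-tree draw when there
is one sample per species); populations merge at species-tree nodes.
Each locus records the set of pulses taken.  Population size is constant
and equal across branches.  Two simultaneous pulses in opposite
directions differ from the analytic decomposition at order `δ2·δ3`
(a locus can take both); the oracle tests therefore use one direction per
pulse time.  The per-locus loop is a numba kernel (~1 µs per three-taxon
genealogy), and runs stream in chunks of 200,000 loci so memory use is
constant in the number of trees; larger-than-memory campaigns are run as
repeated invocations with distinct seeds and merged summaries.

**Trait overlay.**  Mutations are Poisson on each branch at a constant
symmetric rate per 2N generations, each event flipping the state; the
root state is 0.  Events are explicit, so mutation counts, tip-versus-
internal placement, and forward-versus-reversal direction are exact
rather than inferred from simulated sequence — multiple hits on one
branch are therefore counted as multiple events even though only their
parity shows at the tips.

**Inference.**  A locus is focal when its derived set equals the observed
pattern exactly (back-mutation routes included; the outgroup must be
ancestral, consistent with root-state-0 polarization).  Focal loci are
classified against the Fitch parsimony score of the (optionally pruned)
species tree: one mutation is hemiplasy-only, fewer than the Fitch score
is a hemiplasy/homoplasy mixture, at or above it is parsimony-equivalent.
For non-monophyletic derived sets the pipeline reports mutation counts
and the number of maximal derived clades without attributing individual
mutations to hemiplasy or homoplasy, since that attribution depends on
the genealogy.  Input pruning keeps the smallest clade containing all
derived taxa plus the outgroup re-grafted at its original divergence
time.

## Benchmark conditions

All benchmark conditions use the four-taxon topology (((4,3),2),1) with
the derived state in species 4 and 2, the root at 8N generations, the
second split held at 4N, and a default trait rate of 0.05 per 2N
generations.  Times stated in N generations are divided by two once, at
construction.  ILS1–ILS3 shrink the (4,3) internal branch (2N, 1.5N, N);
INT1–INT3 add a 2→4 pulse at 0.6N with probability 0.01/0.05/0.1;
INT4–INT6 hold the probability at 0.1 and move the pulse to 0.4N/0.2N/
0.1N; CGF1–CGF5 trade a longer internal branch (2N…2.8N) against more and
more recent introgression so the discordant-genealogy frequency stays
approximately constant while its expected internal branch grows.  The
total height is held at 8N across all conditions by moving only the
(4,3) split; the choice of 4N for the second split is this package's
(the published description fixes the root and the internal branch but not
that node).  Default benchmark scale is 10 replicates of 100,000 trees
per condition, which separates the condition medians cleanly.

## Synthetic empirical fixtures

The published input files for the two case studies (a 15-taxon New
Guinea lizard clade with six green-blooded species; a *Heliconius
erato/sara*-like clade whose chromosomal inversion is shared by four taxa
in two subclades, connected by two introgression pulses with total
probability 0.201) are not redistributed here.  The package instead ships
*synthetic reconstructions* built from their published descriptions: the
trait placements reproduce the published parsimony baselines exactly
(four transitions for the lizards, two for the butterflies) because those
depend only on topology and state placement, while branch lengths are
plausible round values in coalescent units.  Quantities that depend on
the exact branch lengths (conditional mutation-count probabilities,
introgressed-origin fractions) are therefore qualitative on these
fixtures: tests assert the robust statements — one- and two-mutation
histories dominate focal loci, three-plus-mutation histories are
essentially absent, introgressed histories are over-represented among
focal loci — not the published percentages.

What the generator does not emulate: estimation error in topologies,
branch lengths or concordance factors; rate variation among lineages;
selection on trait loci; multiple samples per species.  Passing tests
show the machinery is self-consistent under the model, not that any
particular empirical dataset satisfies the model.

## subs2coal

Internal branches convert through `T = −ln((3/2)(1 − CF))`, the inverse
of the quartet expectation `CF(T) = 1 − (2/3)e^{−T}`; values above 1 are
treated as percentages, values at or above 1 after normalization are
clamped just below 1, and branches with `CF ≤ 1/3` are excluded from the
regression (a star tree carries no length information).  Tips are
predicted from an OLS fit of `T` on substitutions/site length (response
and predictor in that orientation, matching the printed line formats),
with t-based 95% prediction intervals available as conservative/liberal
tip lengths; predictions outside the fitted range are flagged as
extrapolations and non-positive predictions floored at 1e-6.  Smoothing
is either `redistribute` (each edge below a node receives the node's
remaining depth divided by one plus the maximum number of edges left to
a leaf, so every root-to-tip span is spread evenly along its path) or
`extend` (tips lengthened to the maximum depth, internal branches
untouched).  An outgroup can be excluded before smoothing and re-grafted
at a depth equal to its original substitutions/site branch length times
the fitted slope — one concrete reading of "proportional to the original
tree" — with a warning and a 5% margin if that depth fails to clear the
ingroup.

Round-trip precision: recovering `T` from a double-precision CF is
limited by the subtraction `1 − CF` to about `e^T · 2e-16`; the API
accepts the discordance complement `1 − CF` directly where full
precision over long branches matters.

## Numerical and interface choices

* Exponential-integral closed forms are used everywhere in the analytic
  model; no quadrature, so grid scans are cheap and exact to float
  precision.  Degenerate exponent differences cannot occur (they are
  bounded away from zero by the coalescent rates).
* Mutation probabilities are clipped to [0, 1] to absorb float
  cancellation at extreme rates.
* Seeds: user-facing entry points take a single integer seed; internal
  chunks and replicates derive child seeds via `numpy.random.SeedSequence`.
  Identical seed and configuration give byte-identical Newick streams.
* The introgression input dialect is one directive per line
  (`introgression <donor> <recipient> <time> <probability>`, forward-time
  direction) alongside the Newick tree, `derived`, `outgroup` and `rate`
  lines.

## Known limitations

* The analytic model is exact only for three taxa and a single pulse per
  locus; simultaneous opposite-direction pulses differ at `O(δ2δ3)`.
* The ancestral-branch extent is calibrated, not derived; ratios of
  `P_e` to `P_o` depend on it through the reversal path, and users whose
  system pins the outgroup divergence should set `root_depth` explicitly.
* At trait rates approaching 0.05 per 2N generations the at-least-one-
  event convention visibly overstates configuration probabilities
  relative to explicit event counting (the direction is conservative for
  hemiplasy inference).
* `derived_clade_count` and the monophyly fraction are reported per focal
  tree; no multiple-testing machinery is provided for scanning many
  patterns.
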