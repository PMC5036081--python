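# Methods

This note records the models, conventions and numerical choices behind
`cladistron`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the genuinely open design decisions fell.

## Characters and the matrix model

A cell holds a *state set*: a singleton observation, a multi-element set for
a polymorphic coding (interpreted as "the tip may take any member state at
zero cost" during optimisation, the PAUP* convention for parsimony length),
or the empty set for missing data. The gap symbol `-` is read as missing;
morphological matrices in this literature do not code inapplicability
separately. Each character belongs to one of three classes: binary,
ordered (additive; a change from state *i* to *j* costs |i−j|, appropriate
when states form a morphocline) or unordered (any change costs 1). The
class is part of the character's *declaration* — read from NEXUS
`ASSUMPTIONS`/`TYPESET` or TNT `ccode` directives and written back the same
way — and survives even when a matrix happens to realise only two states of
a declared multistate character. Character indices are 1-based in files and
reports, 0-based internally.

## Parsimony scoring

Unordered characters are scored by the Fitch pass; ordered characters by
their exact decomposition into "state ≥ k" threshold binary factors
(additive binary coding), which lets every character ride a single packed
bitwise Fitch traversal — one 8-bit lane per factor inside a big integer, so
a 34-taxon, 51-character tree scores in well under a millisecond. The
decomposition requires contiguous tip state sets; the rare ordered character
with a non-contiguous polymorphic observation falls back to a full Sankoff
dynamic programme, as does any multifurcating topology (where pairwise
Fitch folding is not exact). The packed pass is cross-checked in the test
suite against an independent generic Sankoff implementation and against
brute-force enumeration of all internal state assignments on small trees.

Step bounds: `m` (minimum over all trees) is one less than the smallest
number of states accounting for every observation (a tiny exact set-cover
for unordered characters; the shortest interval meeting every observation
for ordered ones); `g` (maximum) is the star-tree score — `n` minus the
largest achievable modal count for unordered characters, the minimised sum
of absolute deviations from a single state for ordered ones.

Ensemble indices: CI is taken over all characters, RI over
parsimony-informative characters only (`g > m`; the others contribute 0/0 to
RI). Published ensemble values do not always state their convention, so
both (`ci`/`ci_informative_only`, `ri`/`ri_all_chars`) are reported and a
consumer can match whichever a source printed.

Implied weighting uses the concave fit `f_i = K/(K + es_i)` and reports the
total with a negative sign, matching the convention of the programs this
field publishes with. Internally searches minimise the distortion
`Σ w_i es_i/(K + es_i)`; optima and ties are decided in exact rational
arithmetic (`fractions.Fraction`), because floating-point near-ties would
otherwise make MPC *sets* irreproducible across platforms. K defaults to 3,
the value this literature standardised on.

## Tree search

*Exhaustive* enumeration visits all (2n−5)!! unrooted binary topologies via
stepwise addition (guarded to ≤ 10 taxa) and is the oracle for everything
else. *Branch and bound* uses the same enumeration with pruning by an
admissible lower bound: the partial tree's score plus, per character, steps
it must still gain — the number of states only unplaced taxa force (for
unordered characters) or the ordered-range extension beyond the placed
hull. Per-character steps never decrease under taxon addition, so pruning
is exact; the equivalence of the two modes (identical MPC sets under both
criteria) is asserted over hundreds of random matrices. The addition order
places data-rich, informative taxa first and the initial upper bound comes
from a quick greedy search. *Heuristic* search runs seeded random-addition
greedy starts followed by first-improvement hill climbing over a chosen
neighbourhood (NNI, SPR or TBR) and then a closure sweep that keeps swapping
from every optimum found, absorbing equal-score neighbours until the MPC
set stops growing. The sweep has an expansion budget (default 2000 tree
expansions) because equal-score plateaus on low-signal matrices can be
enormous; the search log records whether closure completed.

Condensation: under the default `min_length_zero` rule an internal branch is
collapsed when its minimum optimised length is zero — per character, the
minimum change cost on that edge over all most-parsimonious reconstructions,
computed from the subtree ("down") and rest-of-tree ("up") cost tables.
Each batch of zero-length edges is contracted simultaneously (making the
result independent of edge order) and minimum lengths are recomputed on the
contracted tree until none remain, so condensation is idempotent by
construction. MPC counts are sensitive to this convention, which is why the
`none` rule (keep all distinct binary optima) also ships.

## Resampling support and MPC selection

GC support of a group is its recovery frequency minus the frequency of its
best-supported incompatible rival, both in percent. The default scheme is
symmetric resampling (each character's weight doubled or zeroed with equal
probability p/2, p = 0.33), preferred over the plain character bootstrap
when differential character weights are in play; the bootstrap is also
available. Each replicate reruns a deliberately light heuristic search
(two random-addition starts, NNI, small closure budget) and contributes the
splits of the strict consensus of its optima once; per-replicate search
intensity trades against replicate count, and both are configurable. All
replicate seeds derive from the top-level seed, so runs are reproducible
bit for bit.

When several K values each yield equally optimal cladograms, candidates are
ranked by the summed GC of their nodes against one *shared* resampling run
(so the comparison is like for like), with ties going to the better-resolved
tree, then to the higher (less negative) reported fit, then to the smallest
K.

## Stratigraphic calibration

Inputs are tabular: tip ranges (oldest, youngest occurrence in Ma; extant
tips at 0) and node constraints (clade membership plus an age range; a
`stem` constraint applies to the parent of the named clade). A tip's point
age is the young end of its range; the full range is kept as the plotted
bar. A node's age is the maximum of its constraint under the chosen policy
(`range_top` = old bound, `range_mid` = midpoint), each child node's age
plus a minimal internode ε (default 0.1 Ma, so branches are drawable), each
child tip's point age plus ε, and the first-appearance datum of any
confidently dated descendant — a clade is at least as old as its oldest
member, with *no* ε padding above that datum (padding there would push a
node off the calibration its own member defines). Tips whose range comes
from a coarse epoch-level default (fossils known only as "Neogene" or
"probably middle Miocene–Pliocene"; the epoch lookup ships in
`chronostrat.EPOCH_RANGES`) are flagged low-confidence and do not push
ancestor ages — otherwise a single phosphorite-deposit taxon with a
15.97 Ma epoch top would drag every containing clade to ≥ 16 Ma. The
validator reports negative branches, binding versus dominated constraints,
and tips whose entire range predates their parent node; calibration is
idempotent and monotone in the constraints.

The bundled working tree (`data/study_tree_synthetic.nwk`) is a synthetic
stand-in assembled from relationships described in prose, shipped so the
calibration and mapping layers run end-to-end; it is not a published
machine-readable topology, and any conclusions drawn from it are about the
software, not about whale phylogeny.

## Trait mapping

Discrete traits are optimised by unordered parsimony with full MPR sets per
node (down/up cost tables; exact on polytomies); the change count equals the
Fitch steps of the same column, which the tests assert. Missing tips take
the full alphabet with a warning. "Cosmopolitan" is coded as its own area
rather than as a polymorphic union — a deliberate choice, editable in the
shipped area table. Continuous traits use squared-change parsimony:
internal values solve the linear system placing every internal node at the
mean of its neighbours (tips fixed, polytomies allowed), which keeps
ancestral values inside the tip span; the objective value is checked against
a black-box optimiser to 1e-8. Body-length proxies apply a user-supplied
linear transform to postorbital skull width; published regression
coefficients belong to their sources and are consumed as configuration, with
the identity (the width itself) as the default. Morphometric ratios round
half-up to two decimals to match printed tables, and `verify_ratios`
recomputes printed claims from their own printed inputs without reconciling
discrepancies (one such discrepancy in the bundled tables — a ratio printed
0.82 whose inputs give 0.83 — is deliberately left visible).

## The simulator

`simulate_tree` draws a Yule-shape rooted binary tree with unit branch
lengths; `simulate_matrix` evolves each character down it under a per-branch
Poisson(rate) change process — unordered characters jump to a uniformly
chosen different state, ordered characters random-walk ±1 with reflecting
bounds — then injects missing and polymorphic cells at exact counts.
Defaults mirror a mid-sized fossil-cetacean dataset: 34 taxa; 51 characters
declared 28 binary / 19 ordered (4 states) / 4 unordered; 15% missing
cells, 1% polymorphic; rate 0.05 per branch. At these defaults the ensemble
indices of the best tree land near the values real matrices of this shape
print (CI ≈ 0.4–0.5), which is what motivated the rate choice. The
generator records the realised number of changes per character, so tests can
assert that parsimony steps on the true tree never exceed the ledger.

What the simulator does *not* emulate: correlated character evolution,
heterotachy, non-uniform state frequencies, and phylogenetically structured
missingness (real fossil matrices lose whole anatomical regions per taxon,
not random cells). Passing recovery tests therefore demonstrate the
correctness of the inference machinery under the model's own assumptions,
not the reliability of parsimony on real morphological data.

`recovery_experiment` measures *exact-optimality* recovery: the fraction of
replicates in which no topology scores strictly better than the generating
tree (decided by a pruned search without enumerating ties, validated against
full branch and bound). This is a demanding criterion. With unit branches a
10-taxon tree has 18 edges, so even rate 0.05 means ~0.9 expected changes
per character and a substantial homoplastic fraction; single-rearrangement
neighbours then beat the truth by one step in a sizeable minority of
replicates, and measured recovery at rate 0.05 sits near 0.6, rising toward
1.0 only for rates an order of magnitude smaller (the acceptance script
computes both ends). Exact-optimality recovery under a per-branch change
process should not be expected to approach certainty at rates that leave
many characters multiply hit.

## Pipeline and reproducibility

`run_full_analysis` chains matrix loading (or simulation), equal-weights
search, an implied-weights K sweep with stability intervals, one shared
resampling run, summed-GC MPC selection, optional outgroup rooting,
calibration and trait maps, and writes a JSON report plus NEXUS/newick/TSV
artifacts that the package's own readers reload. The report embeds the full
configuration and every derived seed; reruns are byte-identical. The
default profile uses deliberately modest search and resampling settings
(heuristic NNI starts, a few hundred replicates) chosen to keep a full
34×51 analysis interactive on one core; publication-grade settings (SPR/TBR,
tens of thousands of replicates) are a configuration change, not a code
change.
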