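# Methods

## Data model

A character matrix is a taxa × characters table of small integer state
codes with `?` for missing cells.  All characters are unordered
(Fitch) and equally weighted: a change between any two states costs
one step, and no ordering or step-matrix structure is imposed.  Cells
are sets internally, so polymorphic observations (`{01}`) are
representable in all dialects, though the packaged matrix contains
none.  Character indices are 1-based everywhere a user sees them,
matching the `char. 30:1` citation style of the systematics
literature; the packaged matrix stores the original 8 × 5 block layout
but the blocks carry no meaning.  A SHA-256 digest over the normalized
rows guards the fixture against accidental edits.

Missing cells behave as the full observed alphabet of their column in
every optimization: they never force a step and never contribute to
the per-column maxima *g*.  State codes above 9 are rejected at the
serialization boundary (no dialect here can express them); in
practice morphological matrices use 0–2.

## Scoring

Fitch scoring roots the unrooted tree arbitrarily on a leaf edge and
runs the set intersection/union pass; the count is root-invariant, a
property the tests exercise directly.  Scoring is vectorized across
characters as uint8 bitmasks.  For search, columns are restricted to
parsimony-informative ones, duplicate column patterns are merged with
multiplicities, and the topology-independent contribution of
uninformative variable characters (each always costs exactly its
minimum) is added back as a constant.

Per-character bounds follow the standard unordered-character formulas:
*m* = observed states − 1, *g* = observed taxa − largest single-state
class.  Both are validated in the tests against exhaustive
minimization/maximization over every topology on subsampled columns.
On the packaged matrix Σm = 42 and Σg = 199, giving CI 42/57 = 0.7368
→ 74 and RI 142/157 = 0.9045 → 90 on the optimal tree.  Reported CI/RI
are ×100, rounded half away from zero.  The ensemble sums include all
variable characters, parsimony-uninformative ones included (on this
matrix all 40 characters happen to be informative, so the distinction
is moot here); an `informative_only` flag computes the stricter
convention.  When Σg = Σm there is no potential homoplasy and RI is
reported as undefined (`None`/`NA`), never as 0.

## Exact search

Branch-and-bound adds taxa one at a time on every edge of every
partial tree.  Two ingredients keep the 20-taxon search to a few
seconds on one core:

* **Exact insertion costs.**  For each edge of the current partial
  tree, the set of states assignable to a point subdividing it in some
  most-parsimonious labeling (its "midpoint set") comes from one
  down-pass + up-pass over directed Fitch sets.  Attaching a leaf with
  state set X to that edge costs exactly one extra step for the
  characters where X misses the midpoint set, and zero otherwise —
  so a whole level of the enumeration is priced from one O(nodes ×
  characters) sweep.  The same identity drives stepwise addition and
  subtree (SPR) reinsertion.
* **Admissible lower bound.**  A definite state occurring among
  not-yet-placed taxa but in no placed cell must eventually cost at
  least one step per character.  The bound is the weighted popcount of
  (suffix-OR of unplaced definite states) AND NOT (OR of placed
  cells), maintained incrementally along the addition order.  Taxa are
  ordered by decreasing distinctness (greedily maximizing characters
  whose placed cells share no state with the candidate), which makes
  the bound bite early.  Missing and polymorphic cells contribute
  nothing to the bound, keeping it admissible.

The incumbent comes from seeded random-addition stepwise starts plus
branch swapping.  Partial trees are pruned only when cost strictly
exceeds the incumbent, so the full optimum *set* is returned;
equivalence with exhaustive enumeration (complete optimum-set
equality) is tested on dozens of random sub-matrices up to 8 taxa.

On the packaged matrix the optimum is 57 steps, attained by 27 binary
topologies.  The ties come from three independent indifferences: the
arrangement of the four outgroup taxa, the internal resolution of
three species with identical character rows, and the position of
*S. gravis* within its species group.  Collapsing every branch with
minimum length zero (no character changes on it in at least one
most-parsimonious reconstruction) maps all 27 to a single condensed
cladogram — the sense in which the analysis yields one most
parsimonious tree.  Length and CI/RI are reported from the binary
optima: a hard polytomy is a stronger claim than an unresolved one,
and optimizing on the condensed tree directly would cost one extra
step.

## Branch swapping

NNI, SPR and TBR hill-climbers are provided.  SPR evaluates all
prune/regraft moves from one directed-set sweep per pruned subtree and
is the default inside resampling; TBR (bisect and reconnect across
both halves) rescores candidates naively and serves as the
thorough finisher for incumbents.  All tie-breaking is seeded, so
every heuristic result is a pure function of (matrix, config, seed).

## Jackknife

Each pseudoreplicate deletes every character independently with
probability 0.36 and re-searches with 5 random-addition starts + SPR
swapping; the replicate contributes the splits common to all best
trees it found (its strict consensus), and support is the percentage
of replicates containing a split ("absolute frequency").  SPR rather
than TBR per replicate keeps the full 2000-replicate run to a few
minutes at an accuracy well inside the jackknife's own sampling noise
(two master seeds agree to a few points on well-supported clades, and
the four-species clade tracked in the study lands within two points of
its published 91).  Replicates drawing zero characters are redrawn and
logged (at p = 0.36 and 40 characters this is a ~10⁻⁸ event).  Each
replicate runs on its own substream derived from the master seed, so
runs are bit-for-bit reproducible and any single replicate can be
re-examined in isolation.

## Character mapping

All mapping questions go through a unit-cost dynamic program (Sankoff
with 0/1 costs) on the tree rooted with the outgroup sister to
everything else: down-tables give the cost of each subtree per root
state, rest-tables the cost of the remainder per node state, and their
combination prices every (branch, endpoint-state-pair) exactly — also
on multifurcating trees, where the pairwise Fitch pass does not apply.
From these tables:

* a node's ancestral set is the states attaining the optimum there in
  some reconstruction (verified against brute-force enumeration of all
  minimal assignments on small instances);
* a branch carries an **unambiguous** change for a character iff no
  optimal reconstruction assigns equal endpoint states; from/to states
  are reported when unique;
* a change is a **synapomorphy** iff its character attains its minimum
  steps on the tree (single origin), otherwise a homoplasy — a
  character-level predicate applied to all of that character's
  changes;
* a clade's diagnosis lists the unambiguous changes on its stem
  branch.  Asking about a leaf set that is not a branch of the tree is
  an error, distinct from an empty diagnosis.

The primary view reports unambiguous changes only (plus flagged
ambiguous candidates); ACCTRAN and DELTRAN single-reconstruction
mappings are available behind a flag, with ties resolved toward or
away from early changes and then by smallest state code.  On the
packaged matrix the computed diagnoses reproduce the published
per-clade lists, with two matrix-vs-prose divergences reported as the
matrix implies: the four-species clade inside the modestus group is
diagnosed by 3:1 and 9:1 plus homoplasious 5:1 (character 6 does not
vary across that clade), and the gravis-sister arrangement inside the
convexipennis group is not forced by the data at all (both
resolutions cost 57 steps), so the condensed cladogram shows a
trichotomy there.

## Synthetic data

The generator emulates the fixture's shape — defaults of 20 taxa, 40
characters, up to 3 states, an all-ancestral outgroup, optionally one
fragmentary taxon.  The clean regime writes each character as one
change on one internal branch (the first n−3 characters cover every
internal branch once, so any matrix with at least that many characters
pins the topology); recovery must then be unique with CI = RI = 100,
which the tests assert across 100 seeds.  The mk regime draws
1 + Poisson(mean − 1) changes per character on uniform branches,
applied root-to-tip with later changes overwriting inside their
subtree; at the default mean of 1.5 the generating-tree CI falls in
the 0.6–0.9 band typical of real morphological matrices.  Change
counts rather than rates-on-lengths are used deliberately: the targets
are cladograms and parsimony is length-blind.  What the simulator does
not emulate: character correlation, state-frequency asymmetries, and
non-random missingness patterns — so passing recovery tests certifies
the machinery, not the adequacy of parsimony for any particular real
data set.

## Problem sizes and determinism

Test-suite searches run exact comparisons at ≤ 8 taxa (exhaustive
enumeration tops out at 10395 topologies there) and statistical checks
at 120–400 jackknife replicates; the acceptance script runs the full
2000.  Exhaustive enumeration refuses more than 10 leaves, the guard
the oracle tests rely on.  Every stochastic component takes an
explicit seed; nothing reads global RNG state.

## Known limitations

* Unordered, equally weighted characters only — no additive
  characters, step matrices, or implied weighting.
* State alphabet capped at 8 by the bitmask encoding (0–9 by the
  serialization formats); morphological practice uses far fewer.
* Branch-and-bound is exponential in the worst case; matrices much
  larger or noisier than ~25 taxa may need the heuristic engine.
* Jackknife support uses per-replicate heuristics; in principle a
  replicate can miss its optimum, deflating support slightly — the
  multi-start design makes this rare at these sizes.
* No branch lengths, divergence times, likelihood/Bayesian methods,
  or tree-distance metrics.
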