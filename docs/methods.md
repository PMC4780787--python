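# Methods

## Model

`quartetnet` works under the multispecies coalescent on a species network.
The estimand is a **semi-directed level-1 network**: an unrooted,
leaf-labeled graph in which tree edges are undirected while each hybrid
node keeps its two directed incoming hybrid edges (inheritance
probabilities γ and 1−γ, γ being the minor share) and one outgoing tree
edge.  Level-1 means reticulation cycles never share edges.  Branch
lengths are in coalescent units (generations / effective population
size); with one sampled individual per taxon, external branch lengths
cannot affect quartet frequencies and are therefore never estimated.

Within a branch of length *t* carrying *j* gene lineages, each pair
coalesces at rate 1; at a hybrid node each remaining lineage follows the
minor parent with probability γ, independently of the others.  Lineages
reaching the root finish coalescing at the same rates.  The data are
summarized as quartet concordance factors: for each sampled 4-taxon set,
the proportions of genes displaying each of the three quartet topologies.

## Exact expected CFs

The central computational object is an exact solver for expected quartet
CFs on any level-1 network (`quartetnet.quartetcf.QuartetProgram`).  For
the four sampled lineages it enumerates every combination of leaf-to-root
paths (one binary choice per hybrid node ancestral to a taxon), weights
each combination by its product of γ factors, and then runs a small
dynamic program over the edges in leaf-to-root order: an edge of length
*t* occupied by *j* still-uncoalesced lineages produces a first
coalescence with probability 1 − exp(−j(j−1)t/2), the first pair uniform
among the j(j−1)/2; because the first coalescence among the four sampled
lineages fixes the unrooted quartet topology, the program can stop
tracking a history at that point.  This is exact (no Monte Carlo), fast
(programs are compiled once per topology and re-evaluated as the
continuous parameters move), and makes no case distinctions.

Three independent cross-checks guard it: the closed forms for the
species-tree case and for the single- and two-descendant hybrid cases; the
local reductions that replace an undetectable 2-cycle or single-descendant
3-cycle by a tree edge of transformed length (for instance
t′ = −log((1−γ)e^(−t₁) + γe^(−t₁−t₂)), which evaluates to 1.3002938 at
γ = 0.3, t₁ = 1, t₂ = 2); and Monte-Carlo simulation with the package's
own gene-tree simulator.  The test suite requires agreement to 1e−9
(analytic routes) and to 3 binomial standard errors at 10⁵ genes
(simulation), over grids of 50+ parameter combinations, and checks that
expected CFs are invariant to the rooting used internally (1e−12 over 200
random networks, n ≤ 8, h ≤ 2).

## Identifiability and its consequences

Quartet CFs cannot see everything.  The package encodes the known
conclusions as hard rules rather than re-deriving them symbolically:

* 2-cycles and 3-cycles with fewer than two 2-taxon subtrees are
  undetectable or unidentifiable; candidate networks containing them are
  excluded from the search space.
* Good triangles (all three subtrees ≥ 2 taxa) are kept with the cycle's
  tree edge pinned to 0.
* For 4-cycles, with subtree counts (n₀, n₁, n₂, n₃) = (parent, opposite,
  parent, hybrid): identifiable ("good diamond") iff n₀ ≥ 2 or n₂ ≥ 2 or
  both n₁, n₃ ≥ 2.  A **bad diamond I** (n₁ ≥ 2 only) identifies only
  γ(1−e^(−t₀)) and (1−γ)(1−e^(−t₁)), t₀/t₁ the two cycle tree edges; the
  implementation spans exactly that two-parameter family by forcing
  t₀ = t₁.  A **bad diamond II** (n₃ ≥ 2 only) has the tree edge below the
  hybrid node pinned to 0.
* Hybrid edges traversed by a single sampled lineage (hybrid node with one
  descendant taxon) cannot move any CF — one lineage cannot coalesce — so
  their lengths are set to 0 and never optimized, exactly like external
  edges.  This keeps the optimizer off flat ridges and makes "recover all
  free parameters" a well-posed statement.

The diamond index convention deserves a note: it is the unique assignment
under which the three identifiability statements (the good-diamond condition, the
bad-diamond-I reparameterization through the cycle tree edges, and the
bad-diamond-II constraint on the edge below the hybrid) are mutually
consistent; the package's tests verify the resulting behavior
computationally (the good/bad-I pair is CF-indistinguishable from 4 taxa
and distinguishable from 5).

On the same grounds, the brute-force enumeration of 4-taxon
one-hybridization networks canonicalizes 2-cycles by placing the hybrid
node at the end with the smaller subtree before deduplication: the two
orientations of a single-cut 2-cycle are CF-equal to the same tree family
for every parameter value, so they are counted as one network, giving
five classes in all.

## Estimation

**Pseudolikelihood.**  log L = Σ_s Σ_i X_qᵢ log CF_qᵢ with expected CFs
clamped below at 1e−12; the multinomial coefficient is constant in the
network and omitted.  When a table carries CFs rather than counts, X is
CF·n_genes rounded to integers by default (`fractional=True` keeps exact
weights).

**Branch-length initialization.**  Each internal branch starts from the
average CF of the quartets spanning it exactly, transformed by
t = −log(1 − 3/2·CF̄) and clamped to [1e−10, 10] (averages ≥ 2/3 clamp to
the upper bound).  This transform is not the inverse of the tree-CF
formula for the major CF — the consistent inversion −log(3/2(1−CF̄)) is
available via `consistent_inversion=True` — but it is initialization
only; the optimizer refines every free length.  Because the default
transform saturates for strongly supported branches, the optimizer always
includes an interior default point (t = 1, γ = 0.1) among its starts, and
the topology search initializes lengths from data once, at the starting
tree, carrying optimized values through subsequent proposals.

**Optimization.**  Bound-constrained adaptive Nelder-Mead (derivative
free) over the free parameters left by the identifiability constraints;
t ∈ [0, 10] (10 standing in for ∞; closed forms honor ∞ exactly),
γ ∈ [0, 1]; relative score tolerance 1e−6, parameter tolerance 1e−4;
three jittered/interior restarts for standalone fits, one inside the
search loop.  Estimates with γ̂ within 1e−4 of {0, 1} or t̂ within 1e−4
of 0 are flagged as boundary cases.

**Search.**  Strict hill climbing from a user-supplied tree or the
built-in quartet-based starter (neighbor joining on the dissimilarity
1 − CF of the pairing split, averaged over 4-taxon sets).  Moves are
drawn uniformly among the currently legal ones; every proposal is checked
for level-1 validity, h ≤ h_max, an existing root placement, and
admissible cycle classes.  A proposal is accepted when its optimized
score improves on the current one by > 1e−6.  γ̂ ≈ 0 removes the hybrid
edge and retries attachment among edges within graph distance one of the
old endpoints (random order, first improvement wins), else the
reticulation is deleted; t̂ ≈ 0 queues an immediate NNI on that branch.
A run ends after 30 consecutive failed proposals (an exposed constant,
chosen from the size of a 6-taxon move neighborhood); 10 independent runs
are the default and the best run is reported.  Everything is
deterministic given (table, start tree, seed).

**Bootstrap and model selection.**  Bootstrap tables draw each CF
uniformly from its 95% credibility interval and renormalize the triple;
each replicate is re-analyzed in full.  Support for a major-tree edge is
the percentage of bootstrap major trees with the same bipartition;
support for a reticulation is the percentage of bootstrap networks
containing a minor hybrid edge with the same (donor, recipient) hardwired
cluster pair under a common outgroup rooting.  The number of
hybridizations is the breakpoint of the best two-segment piecewise-linear
least-squares fit of the score profile over h (ties and linear profiles
resolve to the smallest h).

## The synthetic-data generator

`quartetnet.simulate` is both the Monte-Carlo oracle and the source of all
test data.  It emulates multi-locus sequencing studies at the gene-tree
level: unlinked loci, free recombination between them, none within; one
individual per taxon unless asked otherwise; equal population sizes
(absorbed by coalescent units).  It does **not** emulate sequence-level
noise — gene trees are observed without estimation error — nor gene-flow
models with intra-locus recombination, so passing tests speak to the
coalescent/hybridization model, not to robustness against gene-tree
estimation error (support-threshold filtering in `count_quartets` is the
hook for that).

Random networks follow the study recipe: a Kingman coalescent species
tree, plus hybridizations whose origin and target edges are chosen
uniformly at random, rejecting candidates that break the level-1 or
searchability constraints.  Draws whose internal branches fall below a
minimum length are also rejected — a near-zero internal branch is a hard
polytomy, which the model's own regularity assumption (all tree branch
lengths strictly positive) excludes, and which no finite number of genes
could resolve.  Four frozen designs are provided, (n, h) = (6, 1), (6, 2),
(10, 1), (15, 3), with minor-edge γ of 0.3 (0.2 on second reticulations),
4-cycles in every 6-taxon design, a bad diamond I in (6, 2), a bad
diamond II in (10, 1), and cycle sizes 4/5/6 in (15, 3) (larger
cycle-size combinations are essentially unreachable under this recipe).
Minimum internal lengths are 0.1 for n = 6, 0.03 for n = 10 and 0.01 for
n = 15, reflecting how short the shortest coalescent branches become as
n grows.

The end-to-end study in the acceptance tests is desk-scale: 10 replicates
of 10⁴ genes from the (6, 1) design, analyzed with h_max = 1 and 10 runs
from the data-derived starter tree, requiring the true unrooted topology
in ≥ 8 of 10 replicates.

## Numerical choices and degenerate inputs

* Expected CFs are clamped at 1e−12 before logs so a bad candidate scores
  very poorly instead of −∞.
* t = ∞ is represented by 10 during optimization; closed forms accept ∞.
* γ exactly 0.5: the edge flagged major at parse time wins; unflagged
  ties go to the first-encountered edge (determinism).
* Missing internal lengths default to 1.0 when optimization begins;
  missing external lengths stay missing and are irrelevant to CFs.
* Gene trees may be multifurcating and may miss taxa; a 4-taxon set
  counts a gene only if all four taxa are present and resolved.
* Polytomies in input *networks* are rejected (the searched space is
  binary).
* Support filtering uses the best annotated support among the gene-tree
  edges inducing the displayed quartet; genes without support annotations
  pass.

## Known limitations

* Level-1 only; overlapping reticulation cycles are rejected rather than
  approximated.
* The pseudolikelihood is not a likelihood: information criteria do not
  apply, which is why model selection uses the slope heuristic.
* Semi-directed networks currently have no accepted distance; comparisons
  here use Robinson-Foulds on major trees, hardwired cluster distance
  under an outgroup rooting, and labeled-graph isomorphism for equality.
* With a single individual per taxon, external branch lengths and
  single-lineage hybrid-edge lengths are not estimable — they are
  reported as 0/missing, not as estimates.
* The simulator's gene-tree branch lengths are accumulated coalescent
  exposures, suitable for topology-based analyses only.
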