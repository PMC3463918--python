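# Methods

This note records the models implemented in `vasctree`, the choices made
where the design was genuinely open, and what the synthetic test conditions
do and do not demonstrate.

## Data model and graph correction

A vascular tree is a strictly bifurcative rooted tree: nodes carry 3-D
positions (mm), edges carry radii (mm) and point in flow direction; exactly
one edge is incident to the root node and every edge has zero or two
daughters.  Lengths are always derived from node positions, never stored.
Zero-length *trivial* edges are bookkeeping devices that make
multifurcations representable in a binary tree without touching the
geometry; all derived features of trivial edges are undefined.

Skeletonized graphs from segmented images violate these invariants, and the
correction applies repairs in a fixed order: (1) drop self-loop edges;
(2) merge parallel parent edges sharing an initial node with the
area-conserving radius `sqrt(Σ r_i²)`; (3) among parent edges from distinct
initial nodes keep the one of maximal radius (ties: lexicographically
smallest edge id); (4) merge monofurcation chains, averaging the two radii
(the radii are image-derived estimates, so this is within measurement
error); (5) split k-furcations into k−1 bifurcations joined by trivial
edges; (6) drop isolated nodes; (7) give every root exactly one incident
daughter edge, inserting a trivial root edge where needed.  Within each
step nodes are visited in ascending id order, making the repair
deterministic and replayable from the correction log.  Proper loops
(directed cycles) abort with an error — they indicate segmentation failures
that cannot be repaired automatically.  Trivial edges inserted by step (5)
carry the radius of the bifurcation's incoming edge; the trivial root edge
of step (7) carries the area-conserving combination of its daughters.  When
several roots remain, the tree returned is the declared root's component,
or the component with the most edges.

## Orders and features

Strahler orders are computed iteratively (post-order traversal); Strahler\*
is the root order minus the edge order.  Trivial edges participate like any
other edge — multifurcations are split before ordering, and exempting them
would make the order depend on the splitting.

The bifurcation-angle frame places the two daughter directions in the
xy-plane with their bisector along +x.  `phi_a` is the angle between the
daughters, `phi_b` the unsigned inclination of the parent direction against
that plane (in [0°, 90°]; the side is not a feature), `phi_c` the angle of
the parent's in-plane projection to the bisector.  With the flow-direction
convention a straight pass-through gives `phi_c = 0`.  Angles attach to the
parent edge of the bifurcation, as do `gamma`, `sigma_r`, `sigma_l`; the
bifurcation at the root edge's terminal node is included like any other.
The exponent `gamma` is the bracketed root of `r_1^γ + r_2^γ = r_p^γ` in
[1e−3, 50], solved to 1e−10; configurations without a root in the bracket
(in particular `r_p ≤ max(r_1, r_2)`) are undefined.  Undefined values are
recorded as NaN and excluded from every downstream statistic, so the number
of bifurcations contributing to each feature varies.

## Similarity quantification

Per feature `f` and order `s`, the samples of two trees are compared with
the two-sample KS test at significance P = 0.05 (configurable; the value is
conventional).  The limiting Kolmogorov distribution is evaluated with the
alternating series for `x ≥ 1` and the theta-series form for `x < 1`
(numerically stable near 0), truncating terms below 1e−16.  For small
samples (`n0 + n1 ≤ 25` by default) the p-value is exact: all
`C(n0+n1, n0)` label splits are enumerated when that count is ≤ 2·10⁵,
otherwise 10⁵ seeded Monte-Carlo permutations are used.  The asymptotic
form overestimates p for small samples (it is conservative); the exact path
removes that bias.  Note that even the exact test is conservative as a
decision rule because `D` is discrete: at `n0 = n1 = 20` the attained size
at nominal 0.05 is `P(D ≥ 0.45) ≈ 0.034`.

The similarity ratio of a population (or of two populations) at `(f, s)` is
the fraction of tree pairs not rejected; pairs where either tree has no
defined values are excluded from numerator and denominator.  Averaging over
orders uses weights `w_s = n_s` (number of trees with edges at order `s`) —
the source defines `n_s` and uses `w_s` without defining it; we take them
equal — restricted to orders below the first `s` with `n_s < #trees/2`
(real division; exactly half still qualifies).  In the two-population case
the cutoff is the minimum of the two populations' cutoffs and
`w_s = sqrt(n_s·n_s')`.  Feature-group averages are arithmetic
(single-population) or weighted by the reference population's own
single-population values (two-population); group weights are the summed
reference values over the group size, and the total is the weighted group
mean.  The one-population total uses the same weighted form.  Because the
decisions are 5%-level tests, i.i.d. populations score near 1 − P ≈ 0.95,
never 1.

## Organ domains

Domains provide an inside test and the unsigned distance to the organ
(0 inside); the penalty is node-based and ignores edge radii, since the
straight cylinders already approximate curved vessels.  Sphere and box
distances are closed form; the ellipsoid's exterior distance solves the
closest-point equation by vectorized bisection (~1e−9); its interior
magnitude is the conservative bound `a_min(1 − ‖p/a‖)` — only the sign is
consumed (signed interior distances are out of scope).  CSG composition
uses min/max of signed distances: exact for the inside test, a continuous
1-Lipschitz lower bound near seams of a difference.  Voxel domains use a
Euclidean distance transform of the mask complement, interpolated
trilinearly, plus the exact excess outside the array bounds.  Leaf targets
are rejection-sampled with a seeded Mersenne Twister under a minimal
pairwise distance (a config parameter; no canonical value exists), with an
explicit infeasibility error after `10⁴·n` draws.

## CCO

The cost is `Σ l r^λ + C Σ dist²(node, organ)` with λ = 2 (volume-like)
and C = 42 mm^(λ−1).  Radius rebalancing runs as a fixed-point iteration:
each sweep freezes viscosities at the current radii, accumulates reduced
resistances leaf-to-root while choosing daughter fractions `β_i = r_i/r_p`
so that `β_1^γ + β_2^γ = 1` (γ = 3) and both daughter subtrees produce
equal pressure drops (quarter-power rule on `Q_i K_i`), then propagates
absolute radii root-to-leaf from the root condition.  With constant
viscosity the first sweep is exact; with radius-dependent viscosity a few
sweeps reach the 1e−10 relative stopping tolerance (cap 200).  The root
condition is a fixed root radius by default (taken from the seed tree,
whose root is observed); a fixed pressure-drop mode serves from-scratch
generation.  Internally geometry is mm, the viscosity formula is evaluated
in µm, and resistances are SI.

Viscosity: `μ(r) = 4.0 (1 + 4.29/r)²` cP for `r ≤ 140 µm` (clamped below
4 µm), a linear blend to `μ∞ = 4.0` cP across 140–160 µm, constant above —
continuous everywhere and monotone nonincreasing.

Each insertion tries the 40 edges with midpoints closest to the new leaf
(ties by edge id), optimizes each candidate bifurcation with the rough
tolerance `sqrt(final_tolerance)`, re-optimizes the 20 best fully, and
commits the cheapest.  The optimizer is gradient descent with Armijo
backtracking (factor 0.5, slope 1e−4, step cap 4 local lengths) on central
finite differences (`h = max(1e−4·local length, 1e−6 mm)`); gradients must
be numerical because moving a bifurcation changes radii globally through
the rebalancing, which runs at *every* cost evaluation — skipping it
changes results considerably.  The final tolerance defaults to 1e−3 mm (no
canonical value exists; it is config).  The starting point is the target
edge's midpoint, perturbed by 1e−6 mm if degenerate.  Only the new
bifurcation node moves during a descent, so the penalty of all other nodes
is cached per candidate.

## Postprocessing

Bisector shift: every bifurcation point moves by `fraction × mean daughter
length` (default 9%) along the daughters' unit bisector, away from the
parent side — the sign that widens `phi_a`.  All displacements are computed
from the input geometry and applied simultaneously; daughter endpoints and
radii are untouched and radii are *not* rebalanced afterwards (rebalancing
after the geometric edits reduces similarity).  The intravascular volume
decreases on average over CCO trees (thick parent, flat bifurcations),
though individual trees can move slightly the other way.

Nonflatness adjustment: targets are drawn once per nondegenerate
bifurcation (sorted parent-edge order) from the empirical distribution,
with a random normal-direction sign.  Placing a bifurcation at its closest
triangle point offset by `target × longest side` along the triangle normal
realizes its ratio exactly, but every bifurcation point is itself a vertex
of its neighbours' triangles, so the placements are iterated to a fixed
point (tolerance 1e−10, cap 500 passes; converges in a handful of passes in
practice).  The adjustment is applied uniformly, not per Strahler\* order.
The packaged default distribution is *synthetic* (half-normal, scale 0.05)
and labeled as such; the calibration pipeline measures the distribution
from the reference population instead, and users can supply one-column CSV
samples.

Coarse-anatomy pruning keeps the root edge and, recursively, daughters
whose initial node lies outside the organ or whose radius strictly exceeds
0.25 × the tree's maximum radius; leaf-level pruning removes leaf edges
(optionally restricted to a node set, cascading) — both re-correct the
resulting monofurcations through the standard graph correction.  Short-edge
contraction makes every nontrivial edge below a threshold (default 0.1 mm;
no canonical value exists) trivial by collapsing it onto its parent-side
node, repeating until stable.

## Synthetic data

No public cohort of skeletonized hepatic trees exists, so populations are
synthetic.  A tree is grown by recursively splitting the leaf budget
(uniform in a configured range; `Beta(2,2)` splits), with edge lengths and
radii scaling as `k^(1/3)` in the subtree leaf count times lognormal noise
(σ = 0.15), daughter opening angles normal around 80° (σ = 12°) split
between daughters inversely to flow share, and independent azimuthal jitter
(σ = 8°) producing nonflat bifurcations.  The defaults are chosen once as
plausible for hepatic trees at the scale of interest (terminal radii
~0.1 mm, terminal lengths ~4 mm, opening angles below a right angle).
Because lengths and radii depend on subtree size, their distributions
depend on the Strahler\* order, as in real trees; because all trees follow
one law, same-spec populations are the i.i.d. null of the similarity
analysis.

What this does *not* emulate: measurement noise and resolution limits of
CT, curved vessels, organ-shape-constrained growth, inter-patient anatomy
variation, or the specific invariances of clinical populations.  Passing
tests therefore demonstrate the correctness and internal consistency of
the machinery — ordering, statistics, physics invariants, calibration
direction — not clinical realism of any particular score.

`corrupt_graph` injects the skeletonization defects the correction must
repair (monofurcations, multifurcations, parallel parents, improper loops,
self-loops, isolated nodes, extra root components) while guaranteeing
referential integrity and acyclicity, so the repaired output is always
well defined.

## Calibration pipeline and problem sizes

The pipeline corrects each seed tree, prunes it to coarse anatomy, samples
`ceil(n/0.27)` leaf targets with `n` uniform in the configured range, grows
the tree by CCO, prunes the generated leaves together with the coarse
tree's leaves, contracts short edges, and optionally applies the two angle
steps with the nonflatness distribution measured on the reference
population.  Standard and improved outputs are scored against the reference
with the two-population report; every stage logs input/output checksums so
a run can be replayed bit for bit.

The 1/0.27 oversampling factor compensates the leaf pruning; it was tuned
for clinical CT resolution effects, and on synthetic sphere domains the
post-pruning ratio comes out near 0.4 (the cherry fraction of CCO
topologies) — the factor is config, with the printed default.

Default problem sizes are desk scale: leaf counts 30–80 with 3 repetitions
per seed tree (`CalibrationConfig.full_scale()` switches to 150–350 × 12);
the test suite and the acceptance script use 6-tree reference populations
of 25–45 leaves, generations of 10–50 leaves, and reduced candidate counts
(8/4 instead of 40/20) — sizes chosen so the whole suite exercises every
path at full numerical tolerances.  The physics invariants (Murray law,
equal pressure drops, flow conservation) are scale-free and hold to near
machine precision at any size.

## Known limitations

* Edges are straight cylinders with constant cross-section.
* The flow model ignores branching-angle-dependent losses.
* The similarity score compares purely geometric features; functional
  quantities (pressures, transit times, supplied territories) are out of
  scope.
* Single-tree generation only: no joint PV/HV growth with non-penetration.
* CSG difference distances are conservative near seams; voxel distances are
  accurate to one voxel diagonal.
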