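# Methods

## Model

The hidden-variable random graph on `n` vertices attaches to each vertex an
i.i.d. weight `h` with density `rho(h) = C h^{-tau}` on `[h_min, inf)`,
`tau in (2, 3)` (finite mean `mu = h_min (tau-1)/(tau-2)`, infinite
variance), and joins each pair independently with probability
`p(h, h') = min(h h' / (mu n), 1)`.  Degrees are asymptotically Poisson with
the weight as mean, so weights read as target degrees: the model produces
scale-free graphs with tail exponent `tau`, hubs of typical size
`n^{1/(tau-1)}`, and occasional much larger weights that dominate
*expectations* without appearing in typical samples.

## The variational principle

Write `h_i ~ n^{alpha_i}` for the vertices of a connected motif `H` on `k`
vertices.  The exponent of the contribution of that weight profile to the
expected number of copies of `H` is

    f(alpha) = (1 - tau) sum_i alpha_i
               + sum_{(i,j) in E_H : alpha_i + alpha_j < 1} (alpha_i + alpha_j - 1),

and `E[N(H)] = Theta~(n^{k + max f})` (up to log factors in degenerate
cases).  `f` is concave and piecewise linear, so the maximum over the free
box `alpha in [0,1]^k` is attained at assignments with
`alpha_i in {0, 1/2, 1}`; under the typical-sample cutoff
`alpha_i <= 1/(tau-1)` it is attained in
`{0, (tau-2)/(tau-1), 1/2, 1/(tau-1)}`.  The free optimum is equivalent to a
three-block partition problem: with `S1 = {alpha=0}`, `S2 = {alpha=1}`,
`S3 = {alpha=1/2}`,

    B_f(H) = max_P [ |S1| - |S2| - (2 E_{S1} + E_{S1,S3}) / (tau-1) ],
    k + max f = (3-tau) k / 2 + (tau-1) B_f(H) / 2,

an identity the test suite asserts exactly (rational arithmetic) for all 29
connected motifs on 3-5 vertices at five values of `tau`.

The graphlet (induced) variant adds the feasibility constraint
`alpha_i + alpha_j <= 1` on every non-edge: a non-edge between two vertices
whose weight product exceeds `n` could not actually be absent.  Within the
candidate sets only cutoff-cutoff non-edge pairs are ever infeasible; the
all-zero assignment is always feasible for the free box, so a connected
motif never has an empty feasible set, but the solver still reports an
explicit infeasible result rather than raising, as a guard.

### Degeneracy and logarithmic corrections

When two or more candidate assignments attain the maximum, concavity implies
a whole optimal face (for the diamond and the 4-cycle: the one-parameter
family `beta, 1-beta` with `beta in [1/2, 1]`, i.e. weight pairs with
`h_i h_j = Theta(n)`), and integrating over the face contributes a factor
`log n`.  We flag `log_flag = degenerate` and report the face dimension (the
affine dimension of the hull of the maximizing candidates); the exact log
power is only established for one-dimensional faces, so the package asserts
the polynomial exponent and flags, never a specific log power, for faces of
dimension >= 2.  Vertices whose `alpha` varies across the optimal face are
reported as "pair-constrained".

### Exponents as exact functions of tau

Every free candidate yields an exponent linear in `tau` (the edge-saturation
pattern of a fixed candidate does not depend on `tau`), so the count
exponent is the upper envelope of finitely many lines: piecewise linear,
convex, with rational breakpoints (e.g. the bow-tie's `7/3`).  In typical
mode each candidate yields a quadratic over `(tau - 1)`; here too every
edge-saturation regime is tau-independent on the whole of `(2, 3)` (checked
case by case for all pairs of the four candidate values), so the envelope is
computed globally by exact pairwise comparison.  Crossing points that are
quadratic surds are kept exact (a dedicated `p + s sqrt(d)` number type with
exact rational comparison); all winner decisions happen at rational probe
points, so no floating-point decision enters any exponent.

### The independent grid oracle

`grid_oracle` maximizes `f` over the dense grid of all multiples of `1/m`
inside the mode's box.  In typical mode the grid always contains the box
bound `1/(tau-1)` and its conjugate `(tau-2)/(tau-1)` — the kink locations
of the saturation terms toward a cutoff-level hub.  Without these two points
no uniform grid can express the typical optimizer (e.g. K_{2,3} at
`tau = 21/10` has the unique optimizer with centers `10/11` and leaves
`1/11`), so they are part of the oracle's definition, not a concession: the
oracle's purpose is to verify that nothing *between* the candidate values
does better, and it does so with thousands of grid points per motif.

## Variance and self-averaging

For a motif `H`, the variance of its count decomposes over the isomorphism
classes `H_i` of edge-unions of two labeled copies of `H` overlapped on
`r >= 1` vertices:

    Var(N(H)) = sum_i C_i E[N(H_i)] + E[N(H)]^2 O(1/n),

where `C_i` counts ordered configurations (pair of r-subsets plus a
bijection); the `C_i` sum to `sum_{s=0}^{k-1} binom(k,s)^2 (k-s)!` (6, 33,
208, 1545 for k = 2..5), asserted at construction.  Each merged class (up to
`2k-1 = 9` vertices) gets its free count exponent from the same envelope
machinery; the subtracted diagonal terms are tracked by their bound
`2 x count exponent - 1` and included in the envelope (they can never
strictly win it: the r=1 aligned merge always dominates them by
`(tau-1) alpha_v >= 0`).

`N(H)` is *self-averaging* when `Var/E^2 -> 0`; the exact ratio exponent
(variance envelope minus twice the count envelope) decides this sign on open
rational intervals.  Intervals where the ratio exponent is exactly zero are
classified non-self-averaging (a bounded, non-vanishing relative variance
fails the definition), and envelope pieces decided by a log-degenerate
merged class carry a tie warning, since polynomial orders alone cannot
separate them.  Types: III when `B_f > 0` (hub-dominated, never
self-averaging), else I on the self-averaging region and II off it.

For every catalog motif the self-averaging region comes out as `(2, tau*)`
or empty — computed, not assumed.  Notable exact thresholds: triangle
`(2, 5/2)` with ratio pieces `(tau-3)/2` then `2 tau - 5`; K4 `(2, 3)`;
wedge never (`tau - 2 > 0`); 4-cycle never (the two-copy merge over a
diagonal pair forms K_{2,4}, whose two-hub exponent `8 - 2 tau` always beats
`2 (6 - 2 tau)`).  The same two-hub merge mechanism gives the 5-vertex
catalog a richer structure than a superficial reading suggests — e.g. the
bow-tie's region is `(2, 9/4)`, set by the four-triangle star class
(`max(9(3-tau)/2, 6-tau)` against `5(3-tau)`) — and the package reports
whatever the full enumeration yields.

## Simulator and counting

Weights are drawn by inverse CDF (`h = h_min u^{-1/(tau-1)}`); edges by a
row-wise vectorized pair scan with per-row seed-sequence streams, making
each graph a pure function of `(n, tau, h_min, seed)`.  The naive scan is
`O(n^2)` and guarded at `n <= 5 x 10^4`; `mu` is analytic by default (the
model's definition; an empirical-mean switch exists).  The weight law is the
pure power law, without slowly-varying corrections.

Counting is exact and per unordered vertex subset (embeddings divided by
`|Aut(H)|`).  Connected k-subsets are enumerated once each (ESU expansion),
classified through a precomputed edge-mask table, and converted between
induced (graphlet) and non-induced (motif) counts by the exact unimodular
conversion matrix (squares = induced squares + diamonds + 3 K4, etc.).
Closed-form fast paths (edges; wedges `sum d(d-1)/2`; triangles via the
sparse adjacency product) are cross-checked against the general enumeration.
Orbit-resolved degree statistics attribute every vertex of every induced
4-vertex graphlet occurrence to its automorphism orbit ("vertex type") and
report mean degree and mean `log(degree)/log(n)` per orbit.

Canonical forms are computed in-package: lexicographically minimal adjacency
bit-string over relabelings, restricted to Weisfeiler-Leman color order and
pruned branch-and-bound — exact for the <= 9-vertex merged graphs that occur
and independent of any graph library (networkx VF2 serves as the test-side
oracle).

## Simulation experiments: what they do and do not show

`scaling_experiment` fits the log-log slope of the *median* count; medians
estimate the typical exponent because means are driven by vanishingly rare
hub configurations whenever `B_f > 0`.  Finite-size bias is substantial even
for hub-free motifs: exact quadrature of `E[triangles]` at `tau = 5/2` gives
an effective slope of about 0.85 on `n in [10^3, 10^4]` (and 0.77 still at
`n = 10^7`) against the asymptotic `3(3-tau)/2 = 0.75`, with the median
slope higher still near the self-averaging boundary; slopes measured at desk
scale must be read with that bias in mind.  The package therefore reports
both the fitted slopes and the exact exponents side by side.

`fluctuation_experiment` normalizes counts by the per-configuration sample
mean (so densities center at 1 regardless of unknown prefactors) and reports
the empirical relative variance.  Observing hub-driven (Type II/III)
variance requires samples that actually contain a near-hub vertex, which
happens with probability ~ `n^{2-tau}` per sample: the sample count must
exceed `n^{tau-2}` by a safe factor.  The shipped demonstration uses
`n in {200, 600, 2000}` with 4000 samples at `tau = 14/5` (threshold ~ 440
at n = 2000) and 1000 samples at `tau = 11/5`, asserting a monotone decrease
of `Var/mean^2` for the Type I case and no net decrease for Type II; the
Type III illustration (wedge at `tau = 5/2`) checks right-skew and
median < mean.  These are demonstrations of regime behavior at desk scale,
not estimates of the variance exponents themselves.

The generator emulates the model's own assumptions (i.i.d. pure power-law
weights, independent edges); it does not emulate degree correlations,
clustering beyond the model, or any feature of real networks, so passing
simulation tests validates the implementation against the theory, not the
theory against data.  Real-network analyses run through the same counting
stack on user-supplied edge lists.

## Numerical and design choices

- `tau` is rational everywhere in the exact layer; floats appear only in
  simulation and reporting.
- Candidate enumeration is exhaustive (`3^k`/`4^k`, vectorized in
  half-integer units for the 9-vertex merged graphs) — exact by
  construction, no LP solver or tolerance anywhere.
- Tie-breaking for "the" reported dominant structure: lexicographically
  smallest optimizer; all optimizers are retained.
- Boundary `tau` exactly at a self-averaging endpoint classifies
  non-self-averaging with an explicit warning.
- Experiment sub-seeds derive deterministically from (seed, n, sample
  index); identical inputs give bitwise-identical outputs.

## Known limitations

- Exponents only: no prefactors or finite-n corrections inside Theta.
- Merge calculus limited to motifs on <= 5 vertices (merged graphs on <= 9).
- The naive `O(n^2)` sampler caps graphs at `n = 5 x 10^4`.
- Log powers beyond one-dimensional optimal faces are reported as flags, not
  values, and envelope ties involving log-degenerate classes are warned
  about rather than resolved.
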