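# Methods

## The model

A *system* is a set of homologous parts (segments, castes, vertebrae).
All parts of all systems are embedded in one shared morphospace; each
system is then summarized by three independent indices.

**Part number** is a plain count of the system's rows in the
morphospace. Coincident points are counted separately: two segments
with identical measurements are still two segments.

**Differentiation** is the sum of univariate variances (SoV) of the
system's part coordinates across all morphospace axes. SoV was chosen
over the sum of ranges because it is invariant to the orientation of
the reference axes (a rotation of the point cloud redistributes
per-axis variances but preserves their sum) and less sensitive to
sample size. The profile also reports a bootstrapped median: each of
`reps` (default 100) pseudoreplicates resamples the system's own `n`
parts with replacement and recomputes SoV; the median of the replicate
values is reported. The median rather than the mean makes the summary
robust to the occasional collapsed resample.

**Regularity** is the coefficient of variation (sample SD / mean) of a
distance multiset, so it is dimensionless and invariant to translation,
rotation and uniform scaling — deliberately decoupled from the
*magnitude* of differentiation that SoV measures. Which multiset is
used depends on geometry:

- `n_axes ≥ n_parts − 1`: all n(n−1)/2 pairwise distances. In this
  regime all parts *can* be mutually equidistant (the vertices of a
  regular simplex), so CV = 0 is attainable and means perfect
  regularity.
- otherwise: the pooled 1st- and 2nd-order nearest-neighbour distances
  (NNDs), one pair per part. On a regular square lattice these are all
  identical (CV = 0) while the full pairwise multiset is not — with
  more parts than dimensions, local spacing is the meaningful notion
  of regularity. The dispatch chosen is recorded in each profile
  (`all_pairwise` / `nnd_1_2`).

A known blind spot: low-order NND CV measures local spacing only and
is insensitive to clustering at larger spatial scales; no multi-scale
statistic (Ripley's K and relatives) is implemented.

### Conventions and degenerate inputs

- Sample variance and SD (n−1 denominator) everywhere.
- A single part: SoV = 0, regularity undefined.
- Exactly two parts: one pairwise distance exhibits no variation, so
  CV is defined as 0 and flagged degenerate in spirit (the profile
  records the method normally).
- All parts coincident: every distance is 0, CV is 0/0 and reported as
  NaN / an empty CSV cell — never as 0, which would falsely claim
  perfect regularity.
- Coincident points inside a larger system contribute legitimate zero
  distances to the NND pool.
- NND ties share ranks by sorted order.

### Pooled-space design

Normalization, PCA and the indices all operate on the pooled set of
parts from every system. This is what makes profiles comparable: a
per-system ordination would give each system its own axes and destroy
the common scale. Per-system quantities are computed by masking rows
of the shared space. The bootstrap RNG stream for each system is
derived by hashing its system id together with the master seed
(SHA-256 into a `SeedSequence`), so adding, removing or reordering
systems never changes another system's bootstrap result.

Whether indices should use the full PC space or a leading subset is a
genuinely open choice; the default is the full space, with an
`axes=` subset option (e.g. `[0, 1]` for PC1–PC2) on
`complexity_profile` / `build_complexity_space` and `--axes` on the
CLI.

## Measurement pipeline

`normalize_by_system_mean` divides each variable by its per-system
mean, removing absolute size so that systems measured at different
scales (or in different units) become comparable; afterwards every
(system, variable) group has mean exactly 1, and the operation is
idempotent. A zero or non-finite group mean is an error naming the
system and variable. `build_morphospace` then maps each part to a
point, one axis per variable, in the requested order; `pca_ordinate`
(scikit-learn PCA on the pooled cloud) optionally rotates the space.
Centering is on by default; unit-scaling of input axes is off, because
normalized measurements and Fourier coefficients are already
commensurate (a flag enables it). The rotation is an isometry:
pairwise distances and total variance are preserved, which is exactly
why SoV does not care whether it is computed before or after PCA.

## Outline pipeline

Binary masks are binarized at > 0, the largest connected component is
selected (a tie between equally large components is an error rather
than a silent guess), interior holes are filled, and the outer
boundary is traced with a subpixel marching-squares contour. Pixel
(row r, col c) maps to Cartesian (x = c + 0.5, y = −(r + 0.5)) and
outlines are stored counterclockwise; fixing one convention end-to-end
avoids accidental mirror-image coefficients.

Outlines are resampled to `n_points` (default 200) vertices equally
spaced by arc length. Generalized Procrustes alignment then removes
position (centroid to origin), size (unit centroid size) and
orientation (least-squares rotation, reflections forbidden), iterating
the mean-shape estimate to a 1e-8 fixed point (cap 100 iterations,
with a warning on non-convergence). Vertex correspondence has no
landmarks: each outline initially starts at its maximal-x vertex after
centering (ties to maximal y), and because that heuristic is not
rotation-proof, correspondence is repaired by an exact search over
integer cyclic shifts against the reference and the evolving mean.
The final configuration is put in a canonical pose — the mean shape's
farthest-from-centroid vertex on the positive x-axis and re-indexed to
vertex 0 — so results are independent of input order. The canonical
pose assumes that vertex is unique; for shapes with exact rotational
symmetry the pose (though not the fit) is arbitrary.

Elliptic Fourier analysis expands each closed outline's x(t) and y(t)
in a truncated Fourier series; harmonic h contributes four
coefficients (a_h, b_h, c_h, d_h). The curve parameter is arc length
(the standard choice for digitized outlines). A `uniform`
parameterization — equal parameter step per vertex — is also
available; the two coincide for equal-arc-length-resampled outlines,
and uniform is the right choice when vertices were sampled in a
curve's natural parameter (an ellipse sampled at equal angles is
exactly one harmonic there, whereas under arc length an eccentric
ellipse genuinely has higher harmonics). No first-harmonic size or
orientation normalization is applied on top of Procrustes by default —
double normalization would silently re-rotate aligned shapes.

The harmonic count defaults to the smallest H whose cumulative
harmonic power (Σ(a²+b²+c²+d²)/2) reaches 99% for every outline in the
set, overridable. The coefficient table (4H variables per part, DC
terms dropped) feeds the measurement pipeline unchanged: PCA, then
indices.

## Synthetic data

The generators are first-class, seeded, pure functions:

- `simplex_points(n, edge)` — n mutually equidistant points in n−1
  dimensions (basis vectors projected to their affine span); the
  analytic CV = 0 case for the pairwise rule.
- `square_lattice(rows, cols, spacing)` — the analytic CV = 0 case
  for the NND rule (and a positive-CV case for the pairwise multiset).
- `gaussian_system(n, k, sigma)` — i.i.d. isotropic cloud with
  E[SoV] = k·σ², since the sample variance is unbiased.
- `synthetic_body(n_segments, differentiation, irregularity, seed)` —
  a two-variable (axial, pleural lobe width) segmented body. Segments
  sit on a smooth anteroposterior taper whose span scales with
  `differentiation`; their positions are a convex mixture (weight
  `irregularity`) of equal spacing and sorted uniform-random
  placement. Defaults emulate a ~12-segment body with measurements
  normalized to mean 1. Because both variables are linear in the
  gradient coordinate, the parts are collinear in morphospace — a
  deliberate simplification; real segment measurements scatter off the
  gradient. Equal spacing therefore does not make the *pairwise* CV
  zero (equally spaced collinear points have unequal pairwise
  distances); recovery tests use rank correlation against the dials,
  not absolute zeros.
- `synthetic_colony(caste_structure, shape_sep, seed)` — egg-tapered
  superellipse "heads", one per polyphenism: 3 parts for monomorphic
  (male, queen, worker), 4 for dimorphic, 5 for trimorphic. Caste
  offsets in aspect ratio and squareness scale with `shape_sep`
  (`shape_sep = 0` gives identical outlines and downstream SoV = 0).
  The superellipse family is an arbitrary but convenient closed,
  smooth, few-parameter family; the taper breaks its up-down symmetry
  the way a clypeus/vertex axis does and keeps alignment well-posed.

What passing tests on these fixtures shows: the indices recover known
geometry and respond monotonically to the generating dials. What they
do not show: robustness to digitization noise, partial occlusion,
landmark ambiguity or caste-assignment error in real images and
measurements.

## Run-length description length

The encoder's cost model: each symbol, parenthesis and count digit
costs one character; a run of block B repeated k ≥ 2 times may be
written `(B)k`; ties between a compressed and a literal form resolve
to the literal. Minimality over all block decompositions is found by
dynamic programming over prefix lengths, and every encoding is checked
to decode losslessly. Nested runs (runs of runs) are not considered —
one DP level keeps decoding single-pass, at the cost of missing
savings on deeply self-similar strings. Description length under any
fixed scheme is scheme-relative; this module illustrates the
information-theoretic reading of the indices and is not itself a
profile axis.

## Problem sizes

The test suite and benchmark script run on desk-scale inputs chosen to
keep every analytic statement exact and every stochastic check
well-resolved: simplices to n = 8, a 4×4 lattice, 100-random-cloud
oracle sweeps, exhaustive sequence enumeration to length 8 over a
3-symbol alphabet, 50-system parameter-recovery sweeps, and outlines
at 120–400 vertices with up to 20 harmonics.
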