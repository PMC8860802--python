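# Methods

## The multipoint procedure

The unit of analysis is a *sample point* on the aneurysm surface, not the
aneurysm. Points are distributed at an even target spacing *d* (default
0.5 mm) over the dome of a triangulated lumen surface, each point carries
four hemodynamic parameters interpolated from per-vertex CFD fields, and
the point populations of two labelled regions — the area where a bleb
later formed versus the rest of the dome — are compared with nonparametric
tests. The region labels are an input (clinically they come from expert
delineation on follow-up imaging; in tests they are synthetic ground
truth); the package never infers them.

Units are fixed throughout: mm for geometry, Pa for pressure and WSS,
seconds for time. No unit inference is attempted.

## Even sampling

The point distribution is seeded dart throwing over a dense
surface-area-weighted candidate pool: candidates are drawn uniformly by
area (square-root barycentric trick), visited in random order, and
accepted when no accepted point lies within `spacing_d * (1 -
spacing_tolerance)` (tolerance 0.05, i.e. acceptance radius 0.475 mm at
the default spacing). With the default pool density of 80 candidates per
d² of area the process saturates: the minimum-distance guarantee is exact
and, up to the candidate discretization, no further point at distance ≥ d
from all others can be inserted. On a 100 mm² flat patch this yields
≈ 305–312 points, between the random-saturation and hexagonal-packing
bounds for 0.5 mm discs. The candidate density is an algorithm-fidelity
parameter, fixed once to reach ≥ 95 % of saturation; it is not a study
condition.

Distances are 3D Euclidean chords, not geodesics. At 0.5 mm spacing on
mm-scale, gently curved aneurysm surfaces the difference is far below the
spacing tolerance. Measurement at a point is barycentric interpolation
over its anchor face — exact for fields linear in position, and never
overshooting vertex extrema. A point's region is the majority label of its
anchor face's vertices, with ties broken toward *bleb* (conservative when
characterizing the bleb region).

## Hemodynamic indices

Pressure and WSS magnitude are normalized by area-weighted averages over
an inlet cross-section 1 mm proximal to the aneurysm (vertex-count
weighting is available via `weighted=False`). Normalization removes the
dependence on inflow boundary conditions; references must be positive —
fields whose inlet average is non-positive are rejected rather than
re-gauged. Instantaneous quantities are evaluated at the peak systole of
the second simulated cardiac cycle (the time of maximum inlet flow within
that cycle, ties to the earliest); TAWSS and OSI integrate the full
supplied cycle with the trapezoidal rule on an arbitrary (possibly
non-uniform) grid:

- TAWSS = (1/T) ∫ |τ(t)| dt ≥ 0,
- OSI = ½ (1 − |∫ τ dt| / ∫ |τ| dt) ∈ [0, ½], exactly 0 for unidirectional
  shear and undefined (reported as missing and excluded from statistics)
  when WSS vanishes identically over the cycle.

These are the standard He–Ku definitions. Trapezoidal integration
converges at O(Δt²) on non-periodic integrands and is effectively exact
for the smooth periodic waveforms used here.

## Divergence-center detection

A *center of divergent WSS vectors* is a source of the tangential WSS
field — a point whose neighborhood field points radially outward. Fields
are first projected into the vertex tangent planes (WSS is tangential by
definition; projection removes numerical normal components). The discrete
surface divergence is computed per face from linear shape functions
(hat-function gradients (N × eᵢ)/(2A)) and averaged to vertices with area
weights; it is exact for affine fields on planar patches and satisfies the
discrete divergence theorem on closed surfaces to mesh resolution.

Detection flags vertices that

1. exceed the 95th percentile of divergence over the candidate region,
2. are one-ring local maxima up to a 10 % plateau slack (the slack makes
   localization robust to vertex noise on resolution-limited peaks; the
   outflow test then disambiguates within the plateau),
3. have outward-pointing field on ≥ 80 % of one-ring edges, and
4. are mutually separated by ≥ 1.0 mm (greedy, strongest first).

Boundary vertices (the open inlet ring) and, in the pipeline, all
non-dome vertices are excluded. The thresholds are explicit, reproducible
surrogates for what is clinically a visual judgement; they were calibrated
on the synthetic generator's ground truth, not on patient data. Each
detected center is assigned to its nearest sample point (`is_center`);
two centers colliding on one point is an error prompting denser sampling.

## Statistics

Group summaries are mean ± sample SD (ddof = 1, undefined below two
points). The four parameters use the Mann–Whitney U test: exact mode
enumerates all C(n, n_a) group assignments (midrank ties, two-sided
p = P(|U − n_a n_b/2| ≥ |U_obs − n_a n_b/2|)) and is selected automatically
up to 10⁵ assignments; otherwise the normal approximation with continuity
and tie correction is used. The two modes agree within 0.01 on tie-free
inputs near the feasibility boundary.

Divergence-center counts use Fisher's exact test, two-sided by the
sum-of-no-more-likely-tables criterion. Two 2×2 constructions are
provided: `as_printed` (columns = center count, total point count), which
is the construction consistent with the published p-values and is the
default, and `conventional` (center count, non-center count), the
statistically standard table. Significance is p < 0.05 with no
multiple-testing correction. Points on a surface are spatially correlated;
like the reference protocol, the tests treat them as independent —
p-values are descriptive of the point populations, not of independent
observations.

## Synthetic generator

The generator emulates the *structure* of the study's CFD output, not its
physics. Geometry: a spherical dome (default diameter 3.5 mm, the scale of
a small MCA aneurysm) sliced at a narrower neck (tube radius 1.2 mm) and
extruded into a straight parent-vessel tube, triangulated at ~0.15 mm
edges (icosphere subdivision, analytic normals); the inlet plane sits 1 mm
below the neck. The bleb patch is a geodesic disc (radius 1.2 mm) on the
dome flank.

Fields over one cycle (period 1.80 s, 25 steps), all modulated by a
two-harmonic positive pulse peaking 0.3 s into the cycle:

- **Pressure**: spatially constant base (2000 Pa) plus a Gaussian bump
  (σ = 1 mm) at the bleb-patch center, with the bump amplitude *solved* so
  that the maximum vertex pressure on the dome divided by the inlet
  average equals the target maximum normalized pressure (default 1.04,
  matching the published Case-1 maximum). Because interpolation cannot
  overshoot vertex values, the pipeline-measured maximum equals the target
  to within the sampling offset (≤ 0.003 at 0.5 mm spacing).
- **WSS**: the tangential projection of a fixed swirl-plus-axial analytic
  field (base 10 Pa scale), attenuated to 30 % inside the bleb patch with
  a smooth 0.6 mm rim — a flat-bottomed low-WSS patch whose bleb/non-bleb
  magnitude ratio (≈ 0.4–0.5) mirrors the published contrast; plus one
  radial source per region (at the bleb-patch center and diametrically
  opposite on the dome), modelled as F = s (r/σ) exp(−r²/2σ²) r̂ with
  s = 8 Pa, σ = 0.6 mm, so the field vanishes at the source (a stagnation
  point, enforced by locally suppressing the base flow) and the surface
  divergence peaks there at 2s/σ ≈ 27 Pa/mm; plus an orthogonal
  oscillatory component (2 Pa, cos(2πt/T)) inside the patch that raises
  OSI; plus iid Gaussian noise (1 Pa pressure, 0.1 Pa per WSS component).
- **Null fields** (type-I-error testing): constant-base pressure and
  constant-magnitude azimuthal WSS plus iid noise — no region-dependent
  structure. The azimuthal direction field is coherent everywhere except
  the single apex vertex, which keeps interpolated magnitudes
  region-exchangeable; with it, the pooled Mann–Whitney rejection rate at
  α = 0.05 is ≈ 0.05–0.06 over 200 simulations.

Everything is a deterministic function of (spec, seed). What the generator
does *not* emulate: Navier–Stokes physics, patient geometry, wall
compliance, spatially correlated CFD discretization error, and the
magnitude of real inter-point correlation. Passing recovery tests
therefore demonstrates that the pipeline measures what was planted at
realistic scales and noise levels — not that the clinical findings would
replicate on new patient data. The published per-point means (e.g. TAWSS
in Pa) are not reproducible without the original CFD fields and are not
targeted; only the printed contingency counts, re-analyzed exactly, and
the qualitative planted pattern are.

## Problem sizes and defaults

The default synthetic case yields ≈ 95–100 sample points at 0.5 mm spacing
(the same order as the published 146 and 152 per aneurysm; the published
counts include more neck area than the synthetic dome). Recovery checks
use 20 noise seeds; null calibration uses 200; both complete in seconds to
minutes on one CPU. The exact Mann–Whitney enumeration cap (10⁵
assignments) and the Fisher implementation (hypergeometric pmf summation)
are exercised against independent exhaustive-enumeration oracles in the
test suite.

## Known limitations

- Sampling maximality is stochastic (relative to the candidate pool), not
  certified; spacing is chordal, not geodesic.
- Divergence-center detection depends on four thresholds calibrated on
  synthetic data only; on real CFD fields they may need adjustment, which
  is why all four are exposed in the configuration.
- Inlet averages are area-weighted vertex means, which on coarse inlet
  rings differ slightly from true surface integrals.
- The statistics ignore spatial autocorrelation between points (by
  design, matching the reference protocol).
- Solver exports with per-face (cell-centered) fields must be converted to
  per-vertex values upstream; only node-centered fields are read.
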