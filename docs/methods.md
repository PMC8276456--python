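# Methods

This note documents the models, conventions and numerical choices behind
`tadstorm`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic experiments do and do not show.

## Point-cloud model and conventions

All coordinates are in nanometres; 2D analyses use (x, y), 3D adds z.
Every localization is treated as a point of unit mass, so the barycenter
of a cluster is the unweighted mean of its member coordinates and the
radius of gyration is the root-mean-square distance from that mean:
R_g² = (1/N) Σᵢ |rᵢ − r̄|².

Two normalizations of the focus-to-TAD barycenter distance coexist in
the field: dividing by the *radius of the TAD* (defined here as half the
major axis) or by the TAD's radius of gyration. Both are implemented;
the default is `half_major_axis`, because the analytic random-placement
null is naturally expressed in terms of the sampling radius R, and the
convention in force is recorded in every output row. The *major axis* of
a cluster is defined as 4σ along the first principal component of the
member coordinates (≈ the 95% extent of a Gaussian cluster); the
*diameter* is the maximum pairwise distance (computed on the convex-hull
vertices); *density* is detections per convex-hull area (µm⁻²) or
volume (µm⁻³). These definitions are pinned in the configuration and
echoed into outputs because the normalizer choice propagates into every
normalized statistic downstream.

A focus is associated with a TAD only if its barycenter lies strictly
within half the TAD's major axis of the TAD barycenter (nearest TAD
first; exact ties break to the lower cluster index). Foci failing the
rule are reported as unassigned rather than silently dropped.

## Random-placement null

For foci placed uniformly in a ball of radius R, the expected *in-plane*
(2D-projected) distance from the center is (3π/16)·R ≈ 0.589·R. The
polar-coordinate derivation uses the latitude convention (cos θ Jacobian
over [−π/2, π/2]); with a colatitude convention the same integral is
written with sin θ over [0, π]. The full table of closed forms:

| geometry            | mean    | median        |
|---------------------|---------|---------------|
| ball, 3D distance   | 3/4     | 2^(−1/3) ≈ 0.794 |
| ball, projected     | 3π/16 ≈ 0.589 | (Monte Carlo) |
| disk (2D)           | 2/3     | √½ ≈ 0.707    |

A frequently quoted reference value of 0.71 for "randomly distributed
foci" falls inside the span of these conventions (0.589–0.794) and is
numerically closest to the disk median, but equals none of the mean
values; `tadstorm` therefore exposes every convention explicitly and the
test suite asserts only the closed forms against Monte Carlo. Monte-Carlo
nulls draw seeded uniform samples and report a standard error estimated
from 50 batch statistics, which is valid for medians as well as means.

## Synthetic data generator

The generator emulates the statistical structure of dual-color STORM
data of TADs and replication foci; its defaults are the study
conditions of the analyses it feeds:

* TAD: uniform ball of radius 200 nm (3D R_g of the noisy cloud ≈ 165
  nm, i.e. the few-hundred-nanometre chromatin-domain regime), 2500
  localizations per cell, channel "561". Ellipsoidal and Gaussian shapes
  are available; for `gaussian` the `radius` field is the isotropic σ.
* foci: 7 per TAD, 30 nm diameter, 300 localizations each, channel
  "647". Focus centers sit at a controlled radial fraction d of the TAD
  radius with isotropic random direction, or uniformly in the volume
  (`"random"`). Presets: `g1s_peripheral` (d = 1), `g1_uniform`
  (random), `interior` (d = 0.2).
* localization precision: isotropic Gaussian noise per axis, σ = 20 nm
  lateral and 50 nm axial. The noise model is an explicit choice; real
  acquisitions specify a resolution, not a noise law.
* movies: per-frame pixel-integrated elliptical-Gaussian PSFs with
  astigmatic widths wx(z), wy(z), Poisson photon statistics, constant
  background, injected stage drift applied to both emitters and a set of
  fiducial beads. The default movie length is 2000 frames at a 64×64 px
  camera (160 nm/px) — a desk-scale stand-in for production acquisitions
  of tens of thousands of frames at 256×256 px; both are configurable.

Ground truth (per-localization labels, true focus centers and radial
fractions, injected drift) accompanies every simulated dataset. What the
generator does *not* model: polymer structure within the TAD, blinking
kinetics and repeated localizations of one fluorophore, false
localizations from overlapping emitters, and background localizations
outside the domain. Passing tests therefore demonstrate that the
*measurement chain* is unbiased and robust under controlled geometry,
not that real chromatin behaves like a uniform ball.

## Localization

Detection is local-maximum search above a user threshold with
non-maximum suppression. Fitting uses an axis-aligned elliptical
Gaussian integrated over each pixel (erf form) plus a constant offset;
the axis alignment reflects cylindrical-lens astigmatism being aligned
with the camera axes. Residuals are Pearson-weighted
((model − data)/√(model + 1)), which approximates the Poisson likelihood;
unweighted least squares would inflate the centroid variance by roughly
2× at zero background. Fits that do not converge, whose widths collapse
below 0.3 px, or whose amplitude vanishes are flagged and discarded.
Photons are computed as 2π·A·σx·σy/gain (gain defaults to 1; synthetic
data is already in photons). Patch size defaults to 7×7 px.

The astigmatism calibration fits quadratics to the *squared* widths
versus stage z — exact for the standard defocus model
w(z) = w₀√(1 + ((z − c)/d)²) — which guarantees monotonicity on either
side of each minimum; construction fails if the wx and wy curves do not
cross exactly once in the calibrated range. z lookup minimizes
D(z) = (√wx − √wx(z))² + (√wy − √wy(z))² on a 1 nm grid (configurable);
detections with minimal D above 0.1 (√nm units) are rejected. The
√width metric and the cutoff are declared defaults, not values inferred
from any particular instrument.

## Drift and channel registration

Drift is estimated from fiducial bead images only (no redundant
cross-correlation on the localizations): block-averaged frames (default
block 500; tests use shorter movies with proportionally shorter blocks)
are cross-correlated against the first block via FFT, the correlation
peak is refined by per-axis parabolic interpolation, and the per-block
displacement is interpolated linearly between block centers (clamped at
the ends) and subtracted per frame. Featureless blocks raise an error
naming the block. Axial drift is out of scope (hardware focus locks
handle z). Channel registration fits a translation by default (rigid
drift between interlaced bright-field images); an affine mode is
available for chromatic aberration and requires ≥3 non-collinear control
points. The RMS residual over control points is always reported.

## Segmentation

The two-radius DBSCAN differs from textbook DBSCAN (one ε): the
neighbor-counting radius `r` decides coreness (≥ `n_min` neighbors, self
excluded; the inclusive reading of the threshold is the default and
configurable), while `r_ref` (default `r`) governs both core-core
connectivity (strict <) and border attachment. Border points reachable
from several clusters go to the nearest core, ties to the lower cluster
index; cluster numbering is canonicalized by smallest member row so the
output is permutation-invariant. An O(n²) brute-force reference
implementation of the same contract lives in the test suite and the two
are compared exactly on hundreds of random instances.

`auto_thresholds` sets r = 3× the 5th percentile of nearest-neighbor
distances, n_min = max(4, expected neighbor count within r under the
global convex-hull density), r_ref = r, and logs all three.

Voronoi-density segmentation assigns each point the first-rank density
1/(cell area); unbounded hull cells are excluded rather than clipped to
avoid bounding-box bias. Points denser than δ× the global mean density
(total points / convex-hull area — the whole field, which is logged)
are selected and merged when their cells share an edge; clusters below
`min_detections` are discarded. Raising δ can only shrink the selected
set, which the suite asserts as a monotonicity property.

## Subsampling robustness

Reducing the localization count of a cluster to a half or a quarter (30
independent subsamples without replacement, seeded) perturbs R_g and the
barycenter only at the nanometre scale: on a synthetic 2500-localization
TAD with R_g ≈ 165 nm the mean R_g shifts by < 1% and std(R_g) stays
below 2% of R_g, with the quarter fraction noisier than the half. This
is the stability required for comparing clusters whose localization
counts differ by label or acquisition length.

## Parameter recovery and the dimensionality choice

Foci are planted at a 3D radial fraction d with isotropic direction, so
recovery experiments measure 3D distances against the 3D half-major-axis
normalizer: projecting to 2D would foreshorten the planted distance by
E[sin θ] = π/4 on average and the comparison to d would conflate the
statistic with the projection. Both dimensionalities are available; the
default configuration remains `2d_projected` (matching the common 2D
export convention of Voronoi-based tools), and the recovery and
end-to-end acceptance experiments set `3d` explicitly. Recovery
conditions on ground-truth focus memberships because foci planted near
the center physically overlap — no segmentation can separate them, and
the point of the experiment is the statistic, not the clusterer. The
end-to-end preset experiment, by contrast, runs the full DBSCAN
segmentation per channel; at the interior preset the overlapping foci
merge into fewer clusters, which is expected and does not affect the
group ordering.

Problem sizes used by the tests and the acceptance script — 1e6 draws
per Monte-Carlo null, ~1000 foci per planted level (143 cells × 7), 16
cells per end-to-end condition, 40-frame bead movies — were chosen as
the smallest sizes at which the statistical assertions are stable
across seeds.

## Statistical reporting

Group comparison is an unpaired two-sample t test, Student (pooled) by
default with Welch available, with tiers ****P < 0.0001, ***P < 0.0005,
**P < 0.01, *P < 0.05, N.S. otherwise (note the nonstandard *** cutoff).
No multiple-testing correction is applied; raw tiered P values are
reported. Scatter summaries are mean ± sd; box summaries are median,
quartiles, and whiskers at the most extreme observations within 1.5×
IQR of the box limits. The end-to-end runner uses per-cell mean
distances as the unit of comparison, writes tidy CSVs plus a JSON
manifest embedding the resolved configuration and seed, and is
bit-reproducible for a fixed seed.

## Known limitations

* The simulator's uniform-ball TAD is a deliberate idealization; real
  chromatin domains are anisotropic and internally structured.
* Single-emitter fitting only: overlapping emitters are either merged
  by detection or rejected by the fit, so very high activation densities
  are outside the validated regime.
* Drift correction assumes rigid lateral drift; axial drift and
  field-dependent distortions are not modeled.
* Voronoi segmentation is 2D (first-rank density); the DBSCAN engine is
  the 3D path.
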