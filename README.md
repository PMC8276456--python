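# tadstorm

Quantitative analysis of single-molecule localization microscopy (STORM)
data of chromatin domains: where do replication foci and origins sit
inside an individual topologically associating domain (TAD)?

A TAD imaged by STORM is a cloud of 10³–10⁴ single-molecule
localizations with a radius of gyration around 200 nm; replication
initiation sites appear as ~30 nm sub-foci within it. `tadstorm`
implements the full measurement chain that turns raw dual-color movies
(or synthetic stand-ins) into the spatial statistics that distinguish a
peripheral from an interior or homogeneous arrangement of foci:

* **localize** — spot detection and pixel-integrated elliptical-Gaussian
  fitting, with astigmatism-based z assignment from a wx(z)/wy(z)
  calibration curve;
* **register** — stage-drift correction by cross-correlating fiducial
  bead images (subpixel parabolic peak), and dual-channel alignment;
* **segment** — two cluster engines: a two-radius DBSCAN variant (core
  points by neighbor count within `r`, connectivity and border
  attachment within `r_ref`) and Voronoi-density segmentation
  (SR-Tesseler convention: density factor 3 for domains, 20 for origins,
  3.5 for protein clusters);
* **spatstats** — barycenters (each localization has unit mass), radius
  of gyration, the normalized barycenter distance with its analytic
  random-placement nulls, the radial density distribution (RDD), and
  subsampling robustness;
* **report** — unpaired two-sample t tests with tiered significance
  (\*\*\*\*P < 0.0001, \*\*\*P < 0.0005, \*\*P < 0.01, \*P < 0.05),
  scatter/box summaries, and an end-to-end pipeline runner;
* **simulate** — a first-class synthetic-data generator producing
  localization tables (and optionally raw movies with PSF widths, Poisson
  noise, drift and beads) with known ground truth.

## The statistics

For a cluster of N localizations at positions rᵢ (mass 1 each):

* barycenter r̄ = (1/N) Σ rᵢ
* radius of gyration R_g² = (1/N) Σ |rᵢ − r̄|²
* normalized barycenter distance of a focus F inside TAD T:
  d = |r̄_F − r̄_T| / R, where R is half the TAD's major axis (default)
  or, alternatively, the TAD's R_g — both conventions are implemented
  and recorded in every output row.
* random-placement null: for foci uniform in a ball of radius R, the
  mean in-plane (projected) distance is (3π/16)·R ≈ 0.589·R; the mean 3D
  distance is (3/4)·R, the median 2^(−1/3)·R ≈ 0.794·R; for a disk the
  mean is (2/3)·R and the median √½·R ≈ 0.707·R. Monte-Carlo estimates
  with standard errors are available for any geometry/statistic pair.
* RDD = central tendency (median by default) of the focus
  localizations' radial distances from the TAD barycenter, divided by
  the TAD size; larger RDD = more peripheral.

A focus is associated with a TAD only when its barycenter lies strictly
within half the TAD's major axis of the TAD barycenter.

## Worked example

Three synthetic conditions, 16 cells each, differing only in where the
7 foci are planted inside a 200 nm TAD: on the periphery (`g1s_peripheral`,
radial fraction d = 1), uniformly in the volume (`g1_uniform`), or near
the center (`interior`, d = 0.2):

```python
import tadstorm as ts

cfg = ts.AnalysisConfig.from_dict(
    {"dimensionality": "3d", "seed": 11, "output_dir": "runs/demo"})
res = ts.run_pipeline(cfg)
print(res["summary"][["preset", "n", "mean", "sd", "median"]].round(3))
print(res["tests"][["group_a", "group_b", "t", "df", "p", "tier"]].round(4))
print("null:", round(res["null"].value, 4))
```

prints

```
        preset  n  mean    sd  median
    g1_uniform 16 0.702 0.115   0.736
g1s_peripheral 16 0.953 0.024   0.958
      interior 16 0.073 0.041   0.074

       group_a    group_b       t   df   p tier
g1s_peripheral g1_uniform  8.5343 30.0 0.0 ****
g1s_peripheral   interior 74.0052 30.0 0.0 ****
    g1_uniform   interior 20.5084 30.0 0.0 ****

null: 0.75
```

Peripheral foci score a mean normalized barycenter distance near 1,
uniformly placed foci land on the 3D random null (3/4), and interior
foci fall far below both; the group differences are significant at the
**** tier. The same experiment is available from the shell:

```sh
tadstorm run --seed 11 --out runs/demo
```

Per-localization CSVs use columns `x, y, z, frame, channel, photons,
width_x, width_y` (nm, frames 0-based); ThunderSTORM-style exports
(`"x [nm]"` headers, 1-based frames) are read with
`read_localizations(path, dialect="thunderstorm")`.

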