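# psmorph

Single-particle morphometry and crosstalk quantification for nuclear-body
super-resolution imaging.

Paraspeckles (PS) are nuclear condensates scaffolded by the long noncoding
RNA NEAT1_2.  They have a core–shell architecture with a roughly fixed
sphere diameter of ~360 nm: the 5′ and 3′ ends of NEAT1_2 sit in the shell,
the middle region in the core.  Their crosstalk with nuclear speckles
(condensates of SR splicing factors such as SRSF5) reorganizes under stress
and under acute depletion of individual RNA-binding proteins.  `psmorph`
implements the quantitative post-processing such studies need, end to end,
for users of single-molecule localization microscopy (dSTORM/DNA-PAINT) and
STED data as well as for the surrounding RNA decay and nascent-RNA-seq
analyses:

* **render** — localization-table quality filtering (PSF ellipticity and
  width), merging of re-activations across transient dark frames, and
  rendering into super-resolution count histograms (10 nm pixels).
* **morphometry** — Gaussian smoothing, threshold segmentation, and
  particle analysis: area, fitted-ellipse axes, roundness
  `Round = 4·Area / (π·major_axis²)`, filters (area > 0.025 µm²,
  roundness > 0.8), small/large split at an equivalent radius of 140 nm,
  cluster quantification (area > 0.2 µm²), and radial signal distributions
  with FWHM.
* **ring_fit** — single-particle STED analysis: circular-Hough detection of
  ring-shaped shell signals (sensitivity 0.85), mutual-nearest-neighbor
  matching of 5′ and 3′ channels, least-squares fitting of the ring
  function

      f(x, y) = C1 + C2·exp(−(((x−a)/u1)² + ((y−b)/v1)²))
                   + C3·exp(−(((x−a)/u2)² + ((y−b)/u2)² + ((y−b)/(v1·u2/u1))²))

  radius extraction as the center-to-outer-FWHM distance of the fitted
  model, small/large classification at 280 nm, and the 5′/3′ radius ratio.
* **coloc** — Pearson correlation between channels over nucleus masks, a
  randomization null built by mirroring one channel along the vertical
  image axis, object-overlap counting with percentages, averaged radial
  profiles of one channel around the other's particle centers, and line
  scans.
* **decay** — RNA decay fitting with `N(t) = N0·e^(−kt)` (one-phase) and a
  plateau-then-one-phase variant, half-life `t½ = ln2 / k`, and AICc model
  selection.
* **splice** — MAJIQ-style local splicing variation (LSV) post-processing:
  regulated calling (|ΔPSI| > 5 % and P(change) > 0.5), non-regulated
  calling (|ΔPSI| < 2 % and P = 0), binary stratification to the two main
  junctions, event classification (cassette, alt 3′/5′ splice site, intron
  retention) with cassette sub-classification, and counting of reads with
  non-templated 3′ A-tails (soft-clipped, strand-aware) as polyA evidence.
* **synthetic** — generators for every input above with machine-readable
  ground truth: core–shell particle scenes (localization tables), decay
  time courses, SAM records with/without A-tails, and LSV tables.

## Worked example

Simulate a field of thirty 360 nm shell-labeled particles, render it at
10 nm pixels, and measure it; then fit a decay course:

```python
import numpy as np
from psmorph import synthetic as syn, render, morphometry as morph, decay

params = syn.SceneParams(
    n_particles=30, field_size_nm=(12000, 12000), seed=1,
    channels=(syn.ChannelModel("fiveprime", "shell_ring", 2500,
                               shell_mode="sphere"),))
tables, truth = syn.simulate_scene(params)
img = render.render_histogram(tables["fiveprime"], pixel_size=10.0,
                              field_size_nm=params.field_size_nm)
seg = morph.segment_image(img, blur_sigma=15.0, threshold="half_max")
particles = morph.filter_particles(morph.measure_particles(seg))
diameters = [2 * p.equivalent_radius_nm for p in particles]
print(f"particles: {len(particles)} (truth: {truth.n_particles})")
print(f"mean diameter: {np.mean(diameters):.1f} nm (truth: 360 nm)")

series = syn.simulate_decay_series(1.0, 44.0, 0.0,
                                   [0, 30, 60, 120, 240, 480],
                                   noise_cv=0.05, seed=1, n_replicates=3)
fit = decay.fit_auto(series)
print(f"decay model: {fit.model}, half-life {fit.half_life:.1f} min")
```

prints

```
particles: 30 (truth: 30)
mean diameter: 368.2 nm (truth: 360 nm)
decay model: one_phase, half-life 45.1 min
```

Every segmented particle is recovered, the mean measured diameter is within
3 % of the simulated truth, and the model-selection step identifies the
generating decay law with a half-life estimate within the noise of the
5 %-CV course.

A command-line interface mirrors the library (`psmorph render`, `psmorph
measure`, `psmorph ringfit`, `psmorph coloc`, `psmorph decay`, `psmorph
splice`, `psmorph pareads`); run `psmorph --help` for options.

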