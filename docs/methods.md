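# Methods

This note documents the models, parameter choices, and numerical decisions
behind `psmorph`, and states what the synthetic-data tests do and do not
show about real data.

## Synthetic scenes

`synthetic.simulate_scene` fabricates two-channel paraspeckle fields at the
localization-table level — the form real single-molecule pipelines reach
after spot fitting.  Camera frames, emitter photophysics, and drift are not
modeled; drift correction and localization-precision (NeNA) estimation are
therefore out of scope, and the linking radius is a plain nanometre
parameter.

**Particles.**  Centers are rejection-sampled with a minimum pairwise
separation (default 900 nm) inside a margin that keeps shells in the field.
The shell radius defaults to 180 nm — the canonical ~360 nm particle
diameter — with an optional normal spread.  The shell label is sampled in
one of two modes:

* `ring` (default): radius ~ Normal(R, t/2.3548), angle uniform — a thin
  optical section through the particle equator, as in scanning (STED-like)
  data.  The shell thickness `t` (default 60 nm) is interpreted as the FWHM
  of the radial label distribution.
* `sphere`: points uniform on the 3-D shell surface, projected to 2-D —
  the widefield (dSTORM/DNA-PAINT) view, a filled rim-bright disk.  This is
  the mode used for threshold-morphometry recovery, because a 2-D annulus
  is not what a projection of a spherical shell looks like: its binary mask
  would have a hole and fail the roundness filter that real projected data
  pass.

Isotropic localization noise (default sd 5 nm, within the precision range
of well-corrected dSTORM data) is added to every position.  Clusters place
k sphere centers either collinearly at one diameter spacing (`rod`, the
elongated cylinder-like morphology) or by hard-sphere random attachment
(`aggregate`, the irregular grape-like morphology).  The protein channel
(`speckle`) is uniform nucleoplasmic background plus Gaussian speckle blobs
plus, for a chosen fraction of particles, a shell-decoration annulus at
100–180 nm from the particle center.  Frame, photon, ellipticity, and PSF
width columns are drawn from fixed plausible distributions whose only role
is to exercise the quality filters.

All distributional choices are stand-ins: no generative model for real
paraspeckle images exists, so passing recovery tests demonstrates the
correctness of the *analysis* under the stated sampling laws, not
biological realism.  In particular real data add out-of-focus background,
chromatic offsets between channels, incomplete labeling, and spatially
varying density, none of which are emulated.

**Signal density.**  Recovery tests and the acceptance script use 2500
localizations per particle (morphometry) or 600 (colocalization scenes),
typical post-linking counts for bright FISH labels, and fields of 30 or
200 particles — sizes chosen so the whole suite runs in minutes on one
core while keeping Monte-Carlo standard errors well inside the stated
tolerances.

## Rendering

Localizations land in 10 nm pixels by the half-open convention
pixel i covers [i·px, (i+1)·px); the unblurred image sum equals the
localization count.  Linking merges a localization into an open track when
it lies within the link radius of the track's last position with at most
`max_dark_frames` empty frames between (defaults: NEAT1 channel 2, protein
channel 6); a track collapses to the photon-weighted mean position with
photons summed.  Whether upstream tools merge by mean or first position is
not standardized; the photon-weighted mean is the information-optimal
choice for Gaussian localization errors.

## Threshold morphometry

Images are smoothed (Gaussian, sigma in nm), thresholded, and labeled with
8-connectivity.  Three threshold modes:

* a fixed numeric value — the reproducible analogue of a manually chosen
  threshold;
* `auto` — Otsu on the blurred image.  Used for cluster quantification,
  where touching spheres must remain one connected object;
* `half_max` — two-stage: Otsu objects first, then each object is re-cut
  at half its own intensity maximum, closed, hole-filled (shell labels
  leave dim cores), and opened.  Used for single-particle size
  measurements: on sparse localization histograms Otsu places boundaries
  roughly 2 smoothing sigmas outside the particle and inflates diameters
  by ~12 %, while the per-object half-maximum contour is the binary
  analogue of an FWHM size and recovers 360 nm spheres to within ~3 %.

The threshold actually applied is recorded in the segmentation result.
Roundness uses the second-moment fitted ellipse (particle-analyzer
behavior), and equals the minor/major axis ratio analytically for an
ellipse; rasterization keeps it within 0.05 of that for objects a few
hundred nm across at 5–10 nm pixels.  The 140 nm small/large rule uses the
equivalent radius sqrt(Area/π), with the boundary value counting as small.
Radial distributions are per-annulus means, peak-normalized; FWHM is
interpolated linearly between half-maximum crossings, with a centered peak
completed symmetrically and a flat profile flagged undefined.

## Ring detection and fitting

**Detection.**  The circular Hough accumulator is built by correlating the
image with zero-mean, unit-norm annular templates (expected ring FWHM
60 nm) over the radius range — every pixel votes for centers at its
distance r, weighted by intensity.  Graded votes are essential: binary
votes from a 40–80 nm-wide annulus plateau across the whole band of radii
and return the outer edge rather than the ridge.  Candidates are local
maxima of the (r, y, x) accumulator above (1 − sensitivity)·max, the
conventional monotone mapping in which higher sensitivity admits weaker
circles.  Candidates are accepted greedily, strongest first, if (i) the
smoothed intensity along their perimeter is high for at least 70 % of
angles and roughly uniform (10th percentile ≥ 0.6 × 90th percentile) —
rejecting arcs that graze genuine rings — and (ii) at least 40 % of the
intensity in their annulus band is not already claimed by accepted rings —
removing shifted/harmonic duplicates while letting genuinely concentric
rings of distinct radius through.

**Fitting.**  The ring function (constant offset plus two concentric
elliptical Gaussians; a bright annulus arises for C2 > 0 broad and C3 < 0
narrow) is fitted by bounded trust-region least squares.  The printed form
of the second Gaussian carries the (y−b) term twice with mixed widths and
reuses u2 for both axes; it is implemented exactly as printed (default) —
the likely-intended symmetric form, with the y width scaled as v1·u2/u1,
is available as `variant="symmetric"`.  Initialization follows the Hough
candidate: center (a, b) at the detection, u1 = v1 = 1.1 r, u2 = 0.55 r,
C2 = image amplitude, C3 = −0.6 amplitude; bounds keep widths positive and
C2 ≥ 0; convergence uses a relative cost tolerance of 1e−8 within 500
function evaluations.  Fits on flat patches or fits whose model has no
positive ring profile are flagged and excluded downstream.

**Radius.**  The particle radius is the distance from the fitted center to
the outermost point where the background-subtracted, angle-averaged radial
profile of the *fitted model* (sampled at 1 nm, 90 angles) falls to half
its maximum.  Computing it on the model rather than the raw profile makes
the radius noise-robust but model-filtered: for label distributions far
outside the model family (e.g. a very thin ridge) the model's outer tail,
and hence the radius, can differ from the data's own half-maximum point.
Self-consistency tests therefore define truth through the same radius
functional.  The 280 nm small/large cutoff takes the boundary as large;
5′/3′ ratios are only formed from pairs of converged fits, matched by
mutual nearest neighbors within 300 nm.

## Colocalization

PCC is the standard Pearson statistic over masked pixels, undefined (and
flagged) for constant channels.  The randomization null mirrors one channel
along the vertical image axis — an involution that conserves every
single-channel statistic while destroying spatial correspondence, valid
because nuclei are not left-right symmetric.  Object overlap counts an
8-connected object of the reference channel as colocalized when at least
one pixel (configurable) intersects the other channel's mask.  Radial
profiles around particle centers normalize per annulus first (flat fields
give flat profiles) and per particle second (each profile divided by its
own maximum) before averaging; absolute profile heights are therefore not
comparable across normalization conventions, only shapes and peak
positions.

## Decay kinetics

One-phase decay N(t) = N0·e^(−kt) and plateau-then-one-phase decay (N0
until t0, exponential after) are fitted by unweighted least squares on the
natural scale, the convention of common curve-fitting software for such
qPCR time courses; a log-scale objective is available for strongly
multiplicative noise.  k is initialized from a log-linear regression.
Because the objective is only piecewise-smooth in t0, the plateau end is
scanned over a grid (observed timepoints plus 9 equispaced values over
80 % of the range) and refined jointly by bounded least squares.  Two
identifiability guards flag fits as unconverged: no measurable decline
over the observed window (k·span < 1e−3), and a fitted plateau ending
before the second observation, in which case only t = 0 lies on the
claimed plateau and the model degenerates to a reparametrized one-phase
curve.  Model choice minimizes AICc (Gaussian likelihood, noise variance
counted as a parameter), ties and unidentifiable plateau fits falling back
to the simpler model.  `half_life·k = ln 2` holds exactly for every
returned fit.  Simulated courses use the sampling grid 0/30/60/120/240/480
min with lognormal noise of unit mean.

## Splicing and polyA evidence

Regulated/non-regulated calling applies the unsigned thresholds to the
maximum-|ΔPSI| junction of each LSV; the 2–5 % gap and strong-ΔPSI/
weak-probability combinations yield an explicit `ambiguous` class rather
than silently dropping rows.  Binary stratification ranks junctions by
|ΔPSI| and retains the LSV when the second junction explains at least half
of the strongest junction's change *with opposite sign* — the
absolute-ratio reading of the retention rule; a same-sign second junction
is treated as non-binary.  Event geometry works on the two main junctions
of a source and a target LSV: an intron-kind junction means intron
retention; a shared skipping junction with nested inclusion junctions
bracketing a middle exon means cassette (multiple such patterns mark the
event complex); shared donors with differing acceptors mean alt 3′SS, and
the converse alt 5′SS.  Cassette events become alt-first/alt-last when the
variable exon coincides with the transcript model's terminal exon; without
a model the terminal calls are unavailable and non-complex events fall
back to simple.

A read counts as polyA evidence when its 3′-end soft clip is at least 6 nt
with ≥ 80 % adenosine — thresholds in line with common polyA-site-calling
practice, exposed as parameters — where the 3′ end is the right alignment
end on forward reads and the left end (with a T-run, the reverse
complement) on reverse reads.  Template-encoded A-runs never count, since
only soft-clipped bases are inspected.  Reads are assigned to a region by
their aligned 3′-end position (0-based half-open internally; 1-based
closed at the CLI/TSV boundary), and fold changes against a reference
count use a +1 pseudocount on both sides.

## Known limitations

* The synthetic scenes validate the analysis under stated sampling laws
  only; absolute numbers from real micrographs additionally depend on
  manual threshold choices that published workflows do not fully specify.
* The intensity-weighted Hough detector assumes rings are bright along
  most of their perimeter; strongly incomplete rings are rejected by the
  coverage test.
* The ring-function radius is model-filtered (see above); comparisons
  should stay within one radius definition.
* Event classification consumes already-quantified LSV tables; building
  splice graphs from reads, and the upstream quantification itself, are
  out of scope.
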