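"""Single-particle ring analysis of STED-style intensity images.

Ring-shaped shell signals (the 5' or 3' end label of the scaffold RNA
forming an annulus around the particle core) are detected with a circular
Hough transform, matched across channels, and fitted with a ring function —
the sum of a constant offset and two concentric elliptical Gaussians:

    f(x, y) = C1
            + C2 * exp(-(((x-a)/u1)^2 + ((y-b)/v1)^2))
            + C3 * exp(-(((x-a)/u2)^2 + ((y-b)/u2)^2 + ((y-b)/(v1*u2/u1))^2))

With C2 > 0 broad and C3 < 0 narrow the model describes a bright annulus
with a darker center.  The third exponential carries the (y-b) term twice
with mixed widths; the ``"printed"`` variant implements it exactly as
written above, while the ``"symmetric"`` variant drops the extra
``((y-b)/u2)^2`` term so that the second Gaussian scales both axes by the
same factor u2/u1 relative to the first.  The particle radius is the
distance from the fitted center to the outer half-maximum of the
background-subtracted, angularly averaged model profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, signal

from .image import SRImage

#: 5' radius (nm) separating "small" from "large" particles
RADIUS_CUTOFF_NM = 280.0
#: FWHM of a Gaussian = FWHM_SIGMA * sigma
FWHM_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class RingModelParams:
    """Parameters of the ring function (lengths in nm)."""

    c1: float
    c2: float
    c3: float
    a: float
    b: float
    u1: float
    v1: float
    u2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.c1, self.c2, self.c3, self.a, self.b,
                         self.u1, self.v1, self.u2])

    @classmethod
    def from_array(cls, p) -> "RingModelParams":
        return cls(*map(float, p))


def ring_model(x: np.ndarray, y: np.ndarray, p: RingModelParams,
               variant: str = "printed") -> np.ndarray:
    """Evaluate the ring function at positions (x, y) in nm."""
    dx = x - p.a
    dy = y - p.b
    g1 = np.exp(-((dx / p.u1) ** 2 + (dy / p.v1) ** 2))
    w2y = p.v1 * p.u2 / p.u1
    if variant == "printed":
        g2 = np.exp(-((dx / p.u2) ** 2 + (dy / p.u2) ** 2 + (dy / w2y) ** 2))
    elif variant == "symmetric":
        g2 = np.exp(-((dx / p.u2) ** 2 + (dy / w2y) ** 2))
    else:
        raise ValueError(f"unknown model variant {variant!r}")
    return p.c1 + p.c2 * g1 + p.c3 * g2


def ring_model_image(p: RingModelParams, shape: tuple[int, int],
                     pixel_size: float, variant: str = "printed") -> SRImage:
    """Render the ring function on a pixel grid (pixel centers at (i+0.5)px)."""
    yy, xx = np.indices(shape)
    x = (xx + 0.5) * pixel_size
    y = (yy + 0.5) * pixel_size
    return SRImage(ring_model(x, y, p, variant), pixel_size)


@dataclass
class RingDetection:
    """One Hough-circle candidate (center and radius in nm)."""

    x_nm: float
    y_nm: float
    radius_nm: float
    score: float


def _annulus_kernel(r_px: float, sigma_px: float) -> np.ndarray:
    """Zero-mean, unit-norm annular template of radius r (pixels)."""
    half = int(math.ceil(r_px + 3.0 * sigma_px))
    yy, xx = np.indices((2 * half + 1, 2 * half + 1))
    d = np.hypot(yy - half, xx - half)
    k = np.exp(-((d - r_px) ** 2) / (2.0 * sigma_px ** 2))
    k -= k.mean()
    norm = np.linalg.norm(k)
    return k / norm if norm > 0 else k


def detect_rings(img: SRImage, sensitivity: float = 0.85,
                 radius_range: tuple[float, float] = (80.0, 400.0),
                 radius_step_nm: float = 10.0,
                 ring_width_nm: float = 60.0,
                 min_coverage: float = 0.7) -> list[RingDetection]:
    """Detect ring-shaped signals with an intensity-weighted circular Hough.

    The accumulator is built by correlating the image with zero-mean
    annular templates over radii in ``radius_range`` (nm): every pixel
    votes, weighted by its intensity, for circle centers at its distance r
    — the Hough transform with graded instead of binary votes, which peaks
    in the radius dimension at the annulus ridge.  ``ring_width_nm`` is the
    expected FWHM of the ring cross-section (the template width).

    Candidates are local maxima of the (radius, y, x) accumulator above
    ``(1 - sensitivity) * max`` (higher sensitivity admits weaker circles,
    following the common convention).  They are accepted greedily, strongest
    first, with two checks: (i) angular coverage — the candidate must be
    bright along at least ``min_coverage`` of its perimeter, rejecting
    partial-arc ghosts; (ii) vote provenance — at least 40% of the
    intensity in the candidate's annulus band must be unexplained by
    already-accepted rings, so duplicates and harmonics of a detected ring
    vanish while concentric rings of genuinely distinct radius survive.
    """
    if not 0.0 < sensitivity < 1.0:
        raise ValueError("sensitivity must be in (0, 1)")
    rmin, rmax = radius_range
    if rmin <= 0 or rmax <= rmin:
        raise ValueError("radius_range must be positive and ordered")
    px = img.pixel_size
    data = img.data.astype(float)
    if data.max() <= 0 or np.ptp(data) == 0:
        return []
    data = data / data.max()
    sigma_px = (ring_width_nm / FWHM_SIGMA) / px
    radii_px = np.arange(max(rmin / px, 2.0), rmax / px + 1e-9,
                         max(radius_step_nm / px, 1.0))
    acc = np.stack([
        signal.fftconvolve(data, _annulus_kernel(r, sigma_px), mode="same")
        for r in radii_px
    ])
    peak_thr = (1.0 - sensitivity) * acc.max()
    local_max = ndimage.maximum_filter(acc, size=(3, 5, 5))
    peaks = np.argwhere((acc == local_max) & (acc >= peak_thr))
    candidates = sorted(
        ((float(acc[ir, yy, xx]), (xx + 0.5) * px, (yy + 0.5) * px,
          float(radii_px[ir]) * px) for ir, yy, xx in peaks),
        reverse=True)

    theta = np.linspace(0.0, 2.0 * np.pi, 72, endpoint=False)
    smooth = ndimage.gaussian_filter(data, max(sigma_px / 2.0, 1.0))

    def covered(x, y, r) -> bool:
        # a genuine ring is bright along (almost) its whole perimeter and
        # roughly uniformly so; arc ghosts grazing real rings are neither
        xs = (x + r * np.cos(theta)) / px - 0.5
        ys = (y + r * np.sin(theta)) / px - 0.5
        vals = ndimage.map_coordinates(smooth, [ys, xs], order=1,
                                       mode="constant")
        ref = np.percentile(vals, 90)
        if ref <= 0:
            return False
        if np.percentile(vals, 10) < 0.6 * ref:
            return False
        return float(np.mean(vals > 0.3 * ref)) >= min_coverage

    claimed = np.zeros(data.shape, dtype=bool)
    yy, xx = np.indices(data.shape)
    band_nm = ring_width_nm

    def annulus_mask(x, y, r):
        d = np.hypot((yy + 0.5) * px - y, (xx + 0.5) * px - x)
        return np.abs(d - r) <= band_nm

    kept: list[RingDetection] = []
    for score, x, y, r in candidates:
        band = annulus_mask(x, y, r)
        total = float(data[band].sum())
        if total <= 0 or not covered(x, y, r):
            continue
        new = float(data[band & ~claimed].sum())
        if new / total < 0.4:
            continue
        kept.append(RingDetection(x, y, r, score))
        claimed |= band
    return kept


@dataclass
class RingFitResult:
    """Least-squares fit of the ring function to one particle patch."""

    params: RingModelParams
    radius_nm: float
    residual_norm: float
    converged: bool
    variant: str = "printed"


def radial_profile_of_model(p: RingModelParams, variant: str = "printed",
                            r_max: float | None = None,
                            dr: float = 1.0, n_theta: int = 90,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Background-subtracted angular average of the fitted model.

    Returns distances (nm, step ``dr``) and the mean of ``f - C1`` over
    ``n_theta`` angles at each distance from the fitted center.
    """
    if r_max is None:
        r_max = 5.0 * max(p.u1, p.v1, p.u2)
    r = np.arange(0.0, r_max + dr, dr)
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    x = p.a + np.outer(r, np.cos(theta))
    y = p.b + np.outer(r, np.sin(theta))
    prof = ring_model(x, y, p, variant) - p.c1
    return r, prof.mean(axis=1)


def outer_half_max_radius(r: np.ndarray, profile: np.ndarray) -> float:
    """Outermost distance where a radial profile falls to half its maximum.

    Found by linear interpolation on the sampled profile; ``nan`` when the
    profile has no positive peak or never drops through half maximum.
    """
    r = np.asarray(r, dtype=float)
    profile = np.asarray(profile, dtype=float)
    peak = profile.max() if len(profile) else 0.0
    if peak <= 0:
        return float("nan")
    half = peak / 2.0
    ipk = int(np.argmax(profile))
    for i in range(len(profile) - 1, max(ipk, 0), -1):
        if profile[i] < half <= profile[i - 1]:
            lo, hi = profile[i], profile[i - 1]
            t = (half - hi) / (lo - hi)
            return float(r[i - 1] + t * (r[i] - r[i - 1]))
    return float("nan")


def ring_radius(fit: RingFitResult) -> float:
    """Center-to-outer-half-maximum distance of the fitted model (nm).

    The radius is where the background-subtracted radial profile of the
    fitted model last falls through half its maximum, found numerically
    with linear interpolation.  Returns ``nan`` when the profile never
    reaches a positive half maximum (no ring).
    """
    p = fit.params
    if p.c2 <= 0 and p.c3 <= 0:
        return float("nan")
    r, prof = radial_profile_of_model(p, fit.variant)
    return outer_half_max_radius(r, prof)


def fit_ring(patch: SRImage, init_center_nm: tuple[float, float],
             init_radius_nm: float, variant: str = "printed",
             max_nfev: int = 500) -> RingFitResult:
    """Fit the ring function to an image patch by bounded least squares.

    Initialization follows the Hough candidate: center (a, b) and widths
    scaled from the candidate radius (u1 = v1 = 1.1 r broad positive term,
    u2 = 0.55 r narrow negative term).  Convergence uses a relative cost
    tolerance of 1e-8; non-converged fits are flagged and should be
    excluded from downstream statistics.
    """
    px = patch.pixel_size
    x0, y0 = init_center_nm
    r0 = float(init_radius_nm)
    # restrict the fit to a local window around the candidate so large
    # multi-particle frames can be fitted particle by particle
    pad_px = int(math.ceil(2.5 * r0 / px))
    ci, cj = int(y0 / px), int(x0 / px)
    i0, i1 = max(ci - pad_px, 0), min(ci + pad_px + 1, patch.data.shape[0])
    j0, j1 = max(cj - pad_px, 0), min(cj + pad_px + 1, patch.data.shape[1])
    data = patch.data[i0:i1, j0:j1]
    if np.ptp(data) == 0:  # flat patch: no ring to fit
        flat = RingModelParams(float(data.max()) if data.size else 0.0,
                               0.0, 0.0, x0, y0, r0, r0, r0 / 2.0)
        return RingFitResult(flat, float("nan"), 0.0, False, variant)
    yy, xx = np.indices(data.shape)
    x = (xx + j0 + 0.5) * px
    y = (yy + i0 + 0.5) * px
    vmax, vmin = float(data.max()), float(data.min())
    amp = max(vmax - vmin, 1e-12)
    p0 = np.array([vmin, amp, -0.6 * amp, x0, y0, 1.1 * r0, 1.1 * r0, 0.55 * r0])
    wmax = 3.0 * max(*patch.extent_nm)
    lb = [-np.inf, 0.0, -np.inf, x0 - r0, y0 - r0, 2.0, 2.0, 2.0]
    ub = [np.inf, np.inf, np.inf, x0 + r0, y0 + r0, wmax, wmax, wmax]
    p0 = np.clip(p0, lb, ub)

    def resid(p):
        return (ring_model(x, y, RingModelParams.from_array(p), variant)
                - data).ravel()

    sol = optimize.least_squares(resid, p0, bounds=(lb, ub), xtol=1e-10,
                                 ftol=1e-8, gtol=1e-10, max_nfev=max_nfev)
    params = RingModelParams.from_array(sol.x)
    converged = bool(sol.status > 0)
    fit = RingFitResult(params, float("nan"), float(np.linalg.norm(sol.fun)),
                        converged, variant)
    if converged:
        fit.radius_nm = ring_radius(fit)
        if not np.isfinite(fit.radius_nm):
            fit.converged = False  # degenerate (flat / no ring) fit
    return fit


def classify_particle(fit: RingFitResult,
                      cutoff: float = RADIUS_CUTOFF_NM) -> str:
    """Classify a particle by its 5' ring radius (cutoff itself is large)."""
    if not fit.converged:
        raise ValueError("cannot classify a non-converged fit")
    return "small" if fit.radius_nm < cutoff else "large"


@dataclass
class ParticlePair:
    """Matched 5'/3' ring fits of one particle."""

    fit_5prime: RingFitResult
    fit_3prime: RingFitResult
    ratio_5_3: float = field(init=False)
    size_class: str = field(init=False)

    def __post_init__(self) -> None:
        r5, r3 = self.fit_5prime.radius_nm, self.fit_3prime.radius_nm
        self.ratio_5_3 = r5 / r3 if r3 > 0 else float("nan")
        self.size_class = classify_particle(self.fit_5prime)


def match_channels(detections_5: list[RingDetection],
                   detections_3: list[RingDetection],
                   max_dist: float = 300.0,
                   ) -> tuple[list[tuple[RingDetection, RingDetection]],
                              list[RingDetection], list[RingDetection]]:
    """Pair 5' and 3' detections by mutual nearest neighbors.

    Two detections pair when each is the other's nearest neighbor and
    their centers are within ``max_dist`` (nm).  Returns (pairs,
    unmatched_5, unmatched_3).
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    if not detections_5 or not detections_3:
        return [], list(detections_5), list(detections_3)
    a = np.array([[d.x_nm, d.y_nm] for d in detections_5])
    b = np.array([[d.x_nm, d.y_nm] for d in detections_3])
    dist = np.hypot(a[:, None, 0] - b[None, :, 0],
                    a[:, None, 1] - b[None, :, 1])
    nn_a = dist.argmin(axis=1)
    nn_b = dist.argmin(axis=0)
    pairs, used_a, used_b = [], set(), set()
    for i, j in enumerate(nn_a):
        if nn_b[j] == i and dist[i, j] <= max_dist:
            pairs.append((detections_5[i], detections_3[j]))
            used_a.add(i)
            used_b.add(int(j))
    return (pairs,
            [d for i, d in enumerate(detections_5) if i not in used_a],
            [d for j, d in enumerate(detections_3) if j not in used_b])


def five_three_ratio(pair: ParticlePair) -> float:
    """Radius ratio of the 5' to the 3' shell signal of one particle."""
    if not (pair.fit_5prime.converged and pair.fit_3prime.converged):
        raise ValueError("both fits must have converged")
    return pair.ratio_5_3
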