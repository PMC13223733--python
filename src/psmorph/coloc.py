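"""Two-channel colocalization with a mirrored-randomization null.

The null model flips one channel along the vertical image axis (column
order reversed); because nuclei are not left-right symmetric this destroys
true spatial correspondence while preserving every single-channel
statistic.  Colocalization is quantified two ways: the Pearson correlation
coefficient over masked pixels, and object-level overlap counting after
threshold segmentation of both channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from skimage import measure

from .image import SRImage
from .morphometry import segment_image


@dataclass
class ColocResult:
    pcc: float
    pcc_randomized: float
    n_overlap: int
    n_total: int
    percent_overlap: float
    n_overlap_randomized: int
    percent_overlap_randomized: float


@dataclass
class RadialProfile:
    """Averaged, normalized radial intensity around reference centers."""

    distances_nm: np.ndarray
    values: np.ndarray
    n_particles: int


def crop_to_nucleus(img: SRImage, nucleus_mask: np.ndarray) -> SRImage:
    """Zero out pixels outside the nucleus mask.

    Downstream statistics must be computed on the masked pixel set only;
    this helper returns the masked image for rendering while analyses
    should pass the mask explicitly where supported.
    """
    mask = np.asarray(nucleus_mask, dtype=bool)
    if mask.shape != img.shape:
        raise ValueError("mask extent differs from image extent")
    if not mask.any():
        raise ValueError("empty nucleus mask")
    out = img.copy()
    out.data[~mask] = 0.0
    return out


def pearson(img_a: SRImage, img_b: SRImage,
            mask: np.ndarray | None = None) -> float:
    """Pearson correlation of two channels over the masked pixels."""
    if img_a.shape != img_b.shape:
        raise ValueError("channel extents differ")
    a, b = img_a.data, img_b.data
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != a.shape:
            raise ValueError("mask extent differs from image extent")
        a, b = a[mask], b[mask]
    else:
        a, b = a.ravel(), b.ravel()
    if a.size < 2:
        raise ValueError("need at least 2 pixels")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")  # undefined for a constant channel
    return float(stats.pearsonr(a, b).statistic)


def mirror_randomize(img: SRImage) -> SRImage:
    """Flip the image along the vertical axis (reverse column order)."""
    return SRImage(img.data[:, ::-1].copy(), img.pixel_size)


def count_overlaps(mask_a: np.ndarray, mask_b: np.ndarray,
                   min_overlap_px: int = 1) -> tuple[int, int, float]:
    """Count objects of ``mask_a`` that touch ``mask_b``.

    Objects are 8-connected components of ``mask_a``; an object counts as
    overlapping when at least ``min_overlap_px`` of its pixels fall on
    ``mask_b``.  Returns (n_overlap, n_total, percent); the percentage is
    ``nan`` when ``mask_a`` holds no objects.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError("mask extents differ")
    labels, n_total = measure.label(mask_a, connectivity=2, return_num=True)
    if n_total == 0:
        return 0, 0, float("nan")
    overlap_px = ndimage.sum_labels(mask_b.astype(np.int64), labels,
                                    index=np.arange(1, n_total + 1))
    n_overlap = int(np.sum(overlap_px >= min_overlap_px))
    return n_overlap, n_total, 100.0 * n_overlap / n_total


def coloc_analysis(img_neat: SRImage, img_protein: SRImage,
                   nucleus_mask: np.ndarray | None = None,
                   threshold_a: float | str = "auto",
                   threshold_b: float | str = "auto") -> ColocResult:
    """Full colocalization readout with its mirrored null.

    Channel A (the RNA channel) is segmented into particles; channel B
    (the protein channel) into clusters; the PCC and the object-overlap
    percentage are reported for the true pairing and for the pairing with
    channel A mirrored.
    """
    if nucleus_mask is not None:
        img_neat = crop_to_nucleus(img_neat, nucleus_mask)
        img_protein = crop_to_nucleus(img_protein, nucleus_mask)
    pcc = pearson(img_neat, img_protein, nucleus_mask)
    mirrored = mirror_randomize(img_neat)
    mir_mask = nucleus_mask[:, ::-1] if nucleus_mask is not None else None
    both = (mir_mask & nucleus_mask) if nucleus_mask is not None else None
    pcc_rand = pearson(mirrored, img_protein, both)

    seg_a = segment_image(img_neat, threshold=threshold_a)
    seg_b = segment_image(img_protein, threshold=threshold_b)
    n_ov, n_tot, pct = count_overlaps(seg_a.labels > 0, seg_b.labels > 0)
    seg_a_mir = segment_image(mirrored, threshold=threshold_a)
    n_ov_r, _, pct_r = count_overlaps(seg_a_mir.labels > 0, seg_b.labels > 0)
    return ColocResult(pcc, pcc_rand, n_ov, n_tot, pct, n_ov_r, pct_r)


def radial_profile_around(img_signal: SRImage,
                          centers_nm: np.ndarray,
                          max_radius: float = 1000.0,
                          step: float = 20.0) -> RadialProfile:
    """Average radial profile of one channel around reference centers.

    For each center (x, y in nm) the mean signal intensity per annulus is
    computed (per-annulus area normalization, so a flat field gives a flat
    profile), each particle's profile is divided by its own maximum, and
    the normalized profiles are averaged per distance bin.
    """
    centers_nm = np.atleast_2d(np.asarray(centers_nm, dtype=float))
    if centers_nm.size == 0:
        raise ValueError("need at least one center")
    px = img_signal.pixel_size
    ny, nx = img_signal.shape
    yy, xx = np.indices(img_signal.shape)
    edges = np.arange(0.0, max_radius + step, step)
    nbins = len(edges) - 1
    profiles = []
    for cx, cy in centers_nm:
        dist = np.hypot(yy - cy / px, xx - cx / px) * px
        idx = np.digitize(dist.ravel(), edges) - 1
        ok = (idx >= 0) & (idx < nbins)
        sums = np.bincount(idx[ok], weights=img_signal.data.ravel()[ok],
                           minlength=nbins)
        counts = np.bincount(idx[ok], minlength=nbins)
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        peak = np.nanmax(mean)
        profiles.append(mean / peak if peak > 0 else mean)
    avg = np.nanmean(np.vstack(profiles), axis=0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RadialProfile(centers, avg, len(profiles))


def line_scan(img: SRImage, p0_nm: tuple[float, float],
              p1_nm: tuple[float, float], n_samples: int = 100) -> np.ndarray:
    """Bilinear intensity profile along the segment p0 -> p1 (nm coords)."""
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    px = img.pixel_size
    ny, nx = img.shape
    for (x, y) in (p0_nm, p1_nm):
        if not (0 <= x <= nx * px and 0 <= y <= ny * px):
            raise ValueError("line endpoints must lie inside the image")
    t = np.linspace(0.0, 1.0, n_samples)
    xs = (p0_nm[0] + t * (p1_nm[0] - p0_nm[0])) / px - 0.5
    ys = (p0_nm[1] + t * (p1_nm[1] - p0_nm[1])) / px - 0.5
    return ndimage.map_coordinates(img.data, [ys, xs], order=1,
                                   mode="nearest")
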