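"""Localization-table post-processing and histogram rendering.

Mirrors the standard single-molecule pipeline between spot fitting and
image analysis: quality filtering on PSF shape, merging of re-activations
of the same emitter across transient dark frames, and rendering of the
surviving localizations into a super-resolution count histogram.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import SRImage


def filter_localizations(table: pd.DataFrame,
                         ellipticity_range: tuple[float, float] = (0.0, 0.15),
                         psf_width_range: tuple[float, float] = (0.8, 1.15),
                         ) -> pd.DataFrame:
    """Keep localizations inside both closed quality ranges.

    Defaults are the scaffold-RNA channel settings (ellipticity 0–0.15, PSF
    width 0.8–1.15 px); the protein channel typically uses wider ranges.
    Row order is preserved.
    """
    for lo, hi in (ellipticity_range, psf_width_range):
        if lo > hi:
            raise ValueError("range bounds must be ordered low <= high")
    e_lo, e_hi = ellipticity_range
    w_lo, w_hi = psf_width_range
    keep = (table["ellipticity"].between(e_lo, e_hi)
            & table["psf_width_px"].between(w_lo, w_hi))
    return table[keep].reset_index(drop=True)


def link_localizations(table: pd.DataFrame, link_radius: float,
                       max_dark_frames: int = 2) -> pd.DataFrame:
    """Merge repeated localizations of one binding/blinking event.

    A localization joins an open track when it lies within ``link_radius``
    (nm) of the track's current position and at most ``max_dark_frames``
    empty frames separate it from the track's last appearance.  Each track
    collapses to one record at the photon-weighted mean position with
    photons summed, the first frame, and photon-weighted means of the
    quality columns.
    """
    if link_radius <= 0:
        raise ValueError("link_radius must be positive")
    if max_dark_frames < 0:
        raise ValueError("max_dark_frames must be >= 0")
    if len(table) == 0:
        return table.copy()

    df = table.sort_values("frame", kind="stable").reset_index()
    # open tracks: [x, y, last_frame, member row indices]
    tracks: list[list] = []
    r2 = link_radius ** 2
    for row in df.itertuples():
        best, best_d2 = None, r2
        for tr in tracks:
            if row.frame - tr[2] - 1 > max_dark_frames or row.frame == tr[2]:
                continue
            d2 = (row.x_nm - tr[0]) ** 2 + (row.y_nm - tr[1]) ** 2
            if d2 <= best_d2:
                best, best_d2 = tr, d2
        if best is None:
            tracks.append([row.x_nm, row.y_nm, row.frame, [row.Index]])
        else:
            best[0], best[1], best[2] = row.x_nm, row.y_nm, row.frame
            best[3].append(row.Index)

    out = []
    for tr in tracks:
        sub = df.loc[tr[3]]
        w = sub["photons"].to_numpy()
        w = w / w.sum() if w.sum() > 0 else np.full(len(sub), 1.0 / len(sub))
        out.append({
            "x_nm": float(sub["x_nm"] @ w),
            "y_nm": float(sub["y_nm"] @ w),
            "frame": int(sub["frame"].iloc[0]),
            "photons": float(sub["photons"].sum()),
            "ellipticity": float(sub["ellipticity"] @ w),
            "psf_width_px": float(sub["psf_width_px"] @ w),
        })
    return (pd.DataFrame(out)
            .sort_values(["frame", "x_nm"], kind="stable")
            .reset_index(drop=True))


def render_histogram(table: pd.DataFrame, pixel_size: float = 10.0,
                     blur_sigma: float | None = None,
                     field_size_nm: tuple[float, float] | None = None,
                     ) -> SRImage:
    """Render localizations into a 2-D count histogram.

    A localization at (x, y) lands in pixel ``(floor(y/px), floor(x/px))``.
    Without blurring the image sum equals the number of in-field
    localizations.  ``blur_sigma`` (nm) applies a normalized Gaussian.
    ``field_size_nm`` fixes the physical extent (height, width); by default
    it is taken from the data.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if field_size_nm is not None:
        ny = int(math.ceil(field_size_nm[0] / pixel_size))
        nx = int(math.ceil(field_size_nm[1] / pixel_size))
    elif len(table):
        ny = int(table["y_nm"].max() // pixel_size) + 1
        nx = int(table["x_nm"].max() // pixel_size) + 1
    else:
        ny = nx = 1
    img = np.zeros((ny, nx))
    if len(table):
        cols = (table["x_nm"].to_numpy() / pixel_size).astype(int)
        rows = (table["y_nm"].to_numpy() / pixel_size).astype(int)
        ok = (rows >= 0) & (rows < ny) & (cols >= 0) & (cols < nx)
        np.add.at(img, (rows[ok], cols[ok]), 1.0)
    if blur_sigma:
        img = ndimage.gaussian_filter(img, blur_sigma / pixel_size,
                                      mode="constant", truncate=6.0)
    return SRImage(img, pixel_size)
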