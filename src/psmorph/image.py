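"""Super-resolution image container and TIFF I/O.

All morphometry in this package operates on :class:`SRImage`: a plain 2-D
intensity grid plus a physical pixel size in nanometres.  The array follows
the usual image convention — ``data[row, col]`` with the origin at the
top-left corner, *y* increasing downward and *x* increasing to the right.
Pixel ``(i, j)`` covers the half-open physical square
``[j*px, (j+1)*px) x [i*px, (i+1)*px)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class SRImage:
    """A 2-D intensity grid with physical pixel size.

    Parameters
    ----------
    data
        Non-negative 2-D array of intensities (counts or photons).
    pixel_size
        Physical edge length of one pixel in nanometres.
    """

    data: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("SRImage data must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def extent_nm(self) -> tuple[float, float]:
        """Physical (height, width) of the field in nm."""
        return (self.data.shape[0] * self.pixel_size,
                self.data.shape[1] * self.pixel_size)

    def copy(self) -> "SRImage":
        return SRImage(self.data.copy(), self.pixel_size)


def write_srimage(img: SRImage, path: str | Path) -> None:
    """Write a single-channel TIFF plus a JSON sidecar with the pixel size.

    The sidecar lives next to the TIFF as ``<name>.json`` and records
    ``{"pixel_size_nm": ...}`` so round trips preserve physical units.
    """
    path = Path(path)
    tifffile.imwrite(path, img.data.astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"pixel_size_nm": img.pixel_size}))


def read_srimage(path: str | Path, pixel_size: float | None = None) -> SRImage:
    """Read a TIFF written by :func:`write_srimage`.

    If no sidecar is found the pixel size must be supplied explicitly.
    """
    path = Path(path)
    data = tifffile.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        pixel_size = float(meta["pixel_size_nm"])
    if pixel_size is None:
        raise ValueError(f"no pixel-size sidecar for {path}; pass pixel_size")
    return SRImage(np.asarray(data, dtype=float), pixel_size)
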