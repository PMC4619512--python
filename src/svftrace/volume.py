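"""Volume container and image-stack I/O.

Coordinate convention used throughout the package: voxel centers sit at
integer ``(x, y, z)``, 0-based, with ``x`` the fastest-varying axis within a
slice and ``z`` the slice (page) index.  ``Volume.data`` is indexed
``data[x, y, z]``.  Intensities are stored as floating point in ``[0, 255]``;
16-bit inputs are linearly rescaled on load.  Physical voxel spacing is
carried but all filter parameters are expressed in voxel units.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import tifffile


class VolumeFormatError(ValueError):
    """Raised for unreadable stacks, mixed slice shapes or odd bit depths."""


@dataclass
class Volume:
    """A 3-D scalar intensity grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Intensities in ``[0, 255]``, float.
    spacing : tuple of float
        Physical size of a voxel along each axis (default isotropic 1.0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise VolumeFormatError(
                f"expected a 3-D array with positive shape, got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise VolumeFormatError("volume intensities must be finite")
        if self.data.size and (self.data.min() < 0 or self.data.max() > 255):
            raise VolumeFormatError("volume intensities must lie in [0, 255]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def in_bounds(self, p) -> bool:
        """True when point ``p`` lies inside the voxel-center bounding box."""
        p = np.asarray(p, dtype=float)
        return bool(np.all(p >= 0) and np.all(p <= np.array(self.shape) - 1))

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.spacing)


def _pages_to_data(pages: np.ndarray) -> np.ndarray:
    """Convert a (z, y, x) page array to the (x, y, z) convention, rescaled."""
    if pages.ndim == 2:
        pages = pages[None, ...]
    if pages.ndim != 3:
        raise VolumeFormatError(f"expected 2-D pages, got array of ndim {pages.ndim}")
    if pages.dtype == np.uint8:
        data = pages.astype(np.float64)
    elif pages.dtype == np.uint16:
        data = pages.astype(np.float64) * (255.0 / 65535.0)
    elif np.issubdtype(pages.dtype, np.floating):
        data = pages.astype(np.float64)
        if data.size and (data.min() < 0 or data.max() > 255):
            raise VolumeFormatError("float stack values must lie in [0, 255]")
    else:
        raise VolumeFormatError(f"unsupported bit depth / dtype: {pages.dtype}")
    # pages are (z, y, x); transpose to (x, y, z)
    return np.ascontiguousarray(data.transpose(2, 1, 0))


def load_stack(path) -> Volume:
    """Load a multi-page TIFF or a directory of equally sized 2-D slices.

    The page index becomes ``z``.  8-bit values are used as-is; 16-bit values
    are rescaled so 65535 maps to 255.
    """
    path = os.fspath(path)
    if os.path.isdir(path):
        names = sorted(
            f for f in os.listdir(path)
            if f.lower().endswith((".tif", ".tiff", ".png"))
        )
        if not names:
            raise VolumeFormatError(f"no image slices found in directory {path!r}")
        slices = []
        for name in names:
            full = os.path.join(path, name)
            if name.lower().endswith(".png"):
                from PIL import Image

                arr = np.asarray(Image.open(full))
                if arr.ndim == 3:  # drop color, keep luminance-ish first channel
                    arr = arr[..., 0]
            else:
                arr = tifffile.imread(full)
            slices.append(arr)
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise VolumeFormatError(f"inconsistent slice shapes: {sorted(shapes)}")
        pages = np.stack(slices, axis=0)
    else:
        try:
            pages = tifffile.imread(path)
        except (OSError, ValueError, tifffile.TiffFileError) as exc:
            raise VolumeFormatError(f"cannot read {path!r}: {exc}") from exc
    return Volume(_pages_to_data(pages))


def save_stack(volume: Volume, path, dtype=np.uint8) -> None:
    """Write a Volume as a multi-page TIFF (8-bit by default).

    A load after save reproduces intensities within 0.5 (8-bit rounding).
    Pass ``dtype=np.float32`` for lossless intermediate results.
    """
    path = os.fspath(path)
    pages = volume.data.transpose(2, 1, 0)  # back to (z, y, x)
    if dtype == np.uint8:
        pages = np.clip(np.rint(pages), 0, 255).astype(np.uint8)
    else:
        pages = pages.astype(dtype)
    try:
        tifffile.imwrite(path, pages)
    except OSError as exc:
        raise OSError(f"cannot write {path!r}: {exc}") from exc
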