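"""Core data model and I/O for volumetric OCT data.

A volume is stored as a float array indexed ``[z, x, y]`` (axial index first,
increasing with depth), together with its physical calibration: pixel sizes in
micrometres and the tissue refractive index used to convert optical to
geometric path length.  On disk a volume is a multi-page TIFF (one page per
B-scan, y-major, each page ``(nz, nx)`` float32) with a JSON metadata sidecar
``<name>.meta.json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "DermoctError",
    "ValidationError",
    "GeometryError",
    "OCTVolume",
    "write_volume",
    "read_volume",
    "box_smooth_lateral",
    "circular_roi_mask",
]

# Nominal acquisition geometry of the swept-source system the package targets:
# 10 mm x 10 mm x 2.59 mm sampled at 1000 x 1000 x 1024 px, n = 1.38.
DEFAULT_DX_UM = 10.0
DEFAULT_DY_UM = 10.0
DEFAULT_DZ_UM = 2590.0 / 1024.0
DEFAULT_N_TISSUE = 1.38


class DermoctError(Exception):
    """Base class for all package errors."""


class ValidationError(DermoctError):
    """An input object violates one of its documented invariants."""


class GeometryError(DermoctError):
    """A requested geometry does not fit inside the sampled axial range."""


@dataclass
class OCTVolume:
    """3-D OCT intensity volume with physical calibration.

    Attributes
    ----------
    intensity : ndarray, shape (nz, nx, ny)
        Non-negative linear intensity (arbitrary units).
    dz, dx, dy : float
        Pixel size in micrometres; ``dz`` is the axial size *in tissue*.
    n_tissue : float
        Refractive index used to compute ``dz``.
    """

    intensity: np.ndarray
    dz: float = DEFAULT_DZ_UM
    dx: float = DEFAULT_DX_UM
    dy: float = DEFAULT_DY_UM
    n_tissue: float = DEFAULT_N_TISSUE
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.intensity.ndim != 3:
            raise ValidationError("intensity must be 3-D (z, x, y)")
        if min(self.intensity.shape) < 2:
            raise ValidationError("all volume dimensions must be >= 2")
        for name in ("dz", "dx", "dy"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"pixel size {name} must be > 0")
        if not np.all(np.isfinite(self.intensity)):
            raise ValidationError("intensities must be finite")
        if self.intensity.min() < 0:
            raise ValidationError("intensities must be >= 0")

    @property
    def nz(self) -> int:
        return self.intensity.shape[0]

    @property
    def nx(self) -> int:
        return self.intensity.shape[1]

    @property
    def ny(self) -> int:
        return self.intensity.shape[2]

    def b_scan(self, y: int) -> np.ndarray:
        """Cross-sectional (z, x) image at lateral position ``y``."""
        return self.intensity[:, :, y]


def write_volume(volume: OCTVolume, path: str | Path) -> Path:
    """Write ``volume`` as a y-major multi-page float32 TIFF plus sidecar.

    ``path`` may omit the ``.tif`` suffix.  The sidecar ``<stem>.meta.json``
    records pixel sizes, refractive index and page layout.
    """
    path = Path(path)
    if path.suffix != ".tif":
        path = path.with_suffix(".tif")
    pages = np.ascontiguousarray(
        volume.intensity.transpose(2, 0, 1).astype(np.float32)
    )
    tifffile.imwrite(path, pages)
    meta = {
        "format": "dermoct-volume",
        "axes": "ZXY",
        "pages": "y",
        "page_shape": ["nz", "nx"],
        "dz_um": volume.dz,
        "dx_um": volume.dx,
        "dy_um": volume.dy,
        "n_tissue": volume.n_tissue,
        **volume.meta,
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))
    return path


def read_volume(path: str | Path) -> OCTVolume:
    """Read a volume written by :func:`write_volume`."""
    path = Path(path)
    if path.suffix != ".tif":
        path = path.with_suffix(".tif")
    meta_path = path.with_suffix(".meta.json")
    if not meta_path.exists():
        raise ValidationError(f"missing metadata sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    pages = tifffile.imread(path)
    if pages.ndim == 2:  # single B-scan
        pages = pages[None]
    intensity = pages.transpose(1, 2, 0).astype(np.float64)
    return OCTVolume(
        intensity=intensity,
        dz=float(meta.get("dz_um", DEFAULT_DZ_UM)),
        dx=float(meta.get("dx_um", DEFAULT_DX_UM)),
        dy=float(meta.get("dy_um", DEFAULT_DY_UM)),
        n_tissue=float(meta.get("n_tissue", DEFAULT_N_TISSUE)),
        meta=meta,
    )


def _box1d_truncated(arr: np.ndarray, window: int, axis: int) -> np.ndarray:
    """Moving average with windows truncated (renormalized) at the edges."""
    if window == 1:
        return arr.astype(np.float64, copy=True)
    kernel = np.ones(window)
    num = np.apply_along_axis(
        lambda v: np.convolve(v, kernel, mode="same"), axis, arr
    )
    counts = np.convolve(np.ones(arr.shape[axis]), kernel, mode="same")
    shape = [1] * arr.ndim
    shape[axis] = -1
    return num / counts.reshape(shape)


def box_smooth_lateral(intensity: np.ndarray, window: int = 5) -> np.ndarray:
    """Separable lateral (x then y) moving average of a ``(z, x, y)`` volume
    or a ``(z, x)`` B-scan; edge windows are truncated, not padded."""
    if window % 2 != 1 or window < 1:
        raise ValidationError("smoothing window must be odd and >= 1")
    if window > intensity.shape[1] or (
        intensity.ndim == 3 and window > intensity.shape[2]
    ):
        raise ValidationError("smoothing window larger than lateral extent")
    out = _box1d_truncated(np.asarray(intensity, dtype=np.float64), window, axis=1)
    if intensity.ndim == 3:
        out = _box1d_truncated(out, window, axis=2)
    return out


def circular_roi_mask(
    shape: tuple[int, int],
    center: tuple[float, float] | None = None,
    radius: float | None = None,
) -> np.ndarray:
    """Boolean mask of the circular region ``(x-x0)^2 + (y-y0)^2 <= r^2``.

    Defaults: centre at the image centroid, radius ``0.4 * min(nx, ny)``.
    """
    nx, ny = shape
    if center is None:
        center = ((nx - 1) / 2.0, (ny - 1) / 2.0)
    if radius is None:
        radius = 0.4 * min(nx, ny)
    if radius <= 0:
        raise ValidationError("ROI radius must be > 0")
    x0, y0 = center
    if not (0 <= x0 <= nx - 1 and 0 <= y0 <= ny - 1):
        raise ValidationError("ROI centre outside image")
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    return (xx - x0) ** 2 + (yy - y0) ** 2 <= radius**2
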