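"""GLCM texture features (ASM, COR) on intra-epidermal ROIs.

B-scan intensities are quantized to G = 8 gray levels using the *global*
volume min/max (so contrast is never renormalized per ROI or per group), a
gray-level co-occurrence matrix is accumulated for ordered pixel pairs at an
integer-lattice offset — distance d = 3 at 45 degrees means "3 right, 3 up in
depth" — and two features are computed:

* ASM (angular second moment), sum of squared pair probabilities: texture
  uniformity, 1 for a single repeated pair value;
* COR, the raw autocorrelation moment ``sum i*j*P(i,j)`` of the 1-based
  levels.  Note this is not the mean-subtracted, SD-normalized GLCM
  correlation; a standardized variant is available via
  ``texture_features(..., standard_correlation=True)``.

ROIs are 20 px (z) x 100 px (x) sections of the living-cell layer, placed
deterministically in 3 B-scans (25/50/75% of the y extent) at 3 lateral
positions each, vertically centred between the segmented cuticle bottom and
membrane top and clipped to exclude both reflector bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import DermoctError, OCTVolume, ValidationError
from .segmentation import LayerBoundaries

__all__ = [
    "GrayImage",
    "GLCM",
    "TextureFeatures",
    "RoiSpec",
    "to_gray",
    "glcm",
    "texture_features",
    "select_rois",
    "roi_features",
]

_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass
class GrayImage:
    """Integer gray levels in 1..G with the mapping that produced them."""

    levels: np.ndarray  # (nz, nx) int, values 1..G
    G: int
    source_min: float
    source_max: float


@dataclass
class GLCM:
    """Normalized ordered-pair co-occurrence matrix P[i][j], 1-based levels."""

    P: np.ndarray  # (G, G), sums to 1 when pair_count > 0
    d: int
    theta: int
    pair_count: int
    symmetric: bool = False


@dataclass
class TextureFeatures:
    asm: float
    cor: float


@dataclass(frozen=True)
class RoiSpec:
    """Coordinates of one texture ROI: ``levels[z0:z0+h, x0:x0+wx]`` of
    B-scan ``y``."""

    y: int
    z0: int
    x0: int
    height: int
    width: int


def to_gray(
    roi: np.ndarray, G: int = 8, global_min: float = None, global_max: float = None
) -> GrayImage:
    """Quantize intensities to levels 1..G against the volume-global range.

    ``g = clamp(floor((g0 - gmin) / (gmax - gmin) * G), 0, G-1) + 1`` —
    monotone non-decreasing, with the extremes mapping to levels 1 and G.
    """
    roi = np.asarray(roi, dtype=np.float64)
    if global_min is None:
        global_min = float(roi.min())
    if global_max is None:
        global_max = float(roi.max())
    if not global_max > global_min:
        raise ValidationError("global_max must exceed global_min")
    scaled = (roi - global_min) / (global_max - global_min) * G
    levels = np.clip(np.floor(scaled), 0, G - 1).astype(np.int64) + 1
    return GrayImage(levels=levels, G=G, source_min=global_min, source_max=global_max)


def glcm(gray: GrayImage, d: int = 3, theta: int = 45, symmetric: bool = False) -> GLCM:
    """Ordered-pair co-occurrence matrix at integer-lattice offset.

    For theta = 45 degrees the pair partner sits ``d`` pixels right and ``d``
    pixels up in depth — the offset is taken on the integer lattice, with no
    Euclidean rounding.  ``symmetric=True`` also accumulates the reversed
    pairs.
    """
    if theta not in _OFFSETS:
        raise ValidationError(f"theta must be one of {sorted(_OFFSETS)} degrees")
    if d < 1:
        raise ValidationError("d must be >= 1")
    dz_unit, dx_unit = _OFFSETS[theta]
    dz_off, dx_off = dz_unit * d, dx_unit * d
    lv = gray.levels
    nz, nx = lv.shape
    if nz <= abs(dz_off) or nx <= abs(dx_off):
        raise ValidationError("ROI smaller than the pair offset")
    z0, z1 = max(0, -dz_off), min(nz, nz - dz_off)
    x0, x1 = max(0, -dx_off), min(nx, nx - dx_off)
    src = lv[z0:z1, x0:x1]
    dst = lv[z0 + dz_off : z1 + dz_off, x0 + dx_off : x1 + dx_off]
    G = gray.G
    counts = np.zeros((G, G), dtype=np.int64)
    np.add.at(counts, (src.ravel() - 1, dst.ravel() - 1), 1)
    if symmetric:
        counts = counts + counts.T
    pair_count = int(counts.sum())
    P = counts / pair_count if pair_count else counts.astype(np.float64)
    return GLCM(P=P, d=d, theta=theta, pair_count=pair_count, symmetric=symmetric)


def texture_features(P: GLCM, standard_correlation: bool = False) -> TextureFeatures:
    """ASM and COR from a normalized GLCM.

    ``asm = sum P^2``; ``cor = sum i*j*P`` over 1-based levels (range
    ``[1, G^2]``).  With ``standard_correlation=True`` COR is replaced by the
    mean-subtracted, SD-normalized GLCM correlation in [-1, 1].
    """
    mat = P.P
    if abs(mat.sum() - 1.0) > 1e-9:
        raise ValidationError("GLCM is not normalized (sum != 1)")
    asm = float((mat**2).sum())
    g = mat.shape[0]
    i = np.arange(1, g + 1)[:, None]
    j = np.arange(1, g + 1)[None, :]
    if standard_correlation:
        pi, pj = mat.sum(axis=1), mat.sum(axis=0)
        mi, mj = (np.arange(1, g + 1) * pi).sum(), (np.arange(1, g + 1) * pj).sum()
        si = np.sqrt(((np.arange(1, g + 1) - mi) ** 2 * pi).sum())
        sj = np.sqrt(((np.arange(1, g + 1) - mj) ** 2 * pj).sum())
        if si == 0 or sj == 0:
            raise DermoctError("degenerate GLCM: zero marginal variance")
        cor = float(((i - mi) * (j - mj) * mat).sum() / (si * sj))
    else:
        cor = float((i * j * mat).sum())
    return TextureFeatures(asm=asm, cor=cor)


def select_rois(
    volume: OCTVolume,
    boundaries: LayerBoundaries,
    n_bscans: int = 3,
    rois_per_bscan: int = 3,
    roi_shape: tuple[int, int] = (20, 100),
) -> list[RoiSpec]:
    """Deterministic placement of intra-epidermal ROIs.

    B-scans at 25/50/75% of the y extent (generalized to ``n_bscans``
    quantiles), ROIs centred at 25/50/75% of x, vertically centred in the
    cell layer and clipped so no cuticle or membrane pixel is included.
    B-scans whose cell layer is locally thinner than the ROI are skipped with
    a warning; zero placeable ROIs raises.
    """
    h, wx = roi_shape
    nx, ny = volume.nx, volume.ny
    if wx > nx:
        raise ValidationError("ROI wider than the volume")
    ys = [int(round((k + 1) / (n_bscans + 1) * (ny - 1))) for k in range(n_bscans)]
    xcs = [
        int(round((k + 1) / (rois_per_bscan + 1) * (nx - 1)))
        for k in range(rois_per_bscan)
    ]
    rois: list[RoiSpec] = []
    skipped = 0
    for y in ys:
        for xc in xcs:
            x0 = int(np.clip(xc - wx // 2, 0, nx - wx))
            cols = slice(x0, x0 + wx)
            if not boundaries.valid_mask[cols, y].all():
                skipped += 1
                continue
            zmin = int(boundaries.cuticle_bottom[cols, y].max())
            zmax = int(boundaries.membrane_top[cols, y].min())  # exclusive
            if zmax - zmin < h:
                skipped += 1
                continue
            z0 = zmin + (zmax - zmin - h) // 2
            rois.append(RoiSpec(y=y, z0=z0, x0=x0, height=h, width=wx))
    if skipped:
        warnings.warn(
            f"{skipped} ROI position(s) skipped: cell layer thinner than ROI",
            stacklevel=2,
        )
    if not rois:
        raise DermoctError("cell layer too thin everywhere: no ROI placeable")
    return rois


def roi_features(
    volume: OCTVolume,
    rois: list[RoiSpec],
    G: int = 8,
    d: int = 3,
    theta: int = 45,
    scale: str = "log",
) -> list[TextureFeatures]:
    """ASM/COR per ROI using the volume-global intensity range for
    quantization.

    ``scale="log"`` (default) quantizes the log-compressed image — the
    domain in which OCT B-scans are displayed and in which speckle contrast
    is range-independent; on the raw linear scale the bright reflector bands
    dominate the global range and collapse intra-tissue texture onto the
    lowest level.  ``scale="linear"`` quantizes raw intensity.
    """
    if scale not in ("log", "linear"):
        raise ValidationError("scale must be 'log' or 'linear'")
    data = volume.intensity
    if scale == "log":
        eps = 1e-6 * float(data.max())
        data = np.log10(np.maximum(data, eps))
    gmin = float(data.min())
    gmax = float(data.max())
    out = []
    for r in rois:
        patch = data[r.z0 : r.z0 + r.height, r.x0 : r.x0 + r.width, r.y]
        gray = to_gray(patch, G=G, global_min=gmin, global_max=gmax)
        out.append(texture_features(glcm(gray, d=d, theta=theta)))
    return out
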