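"""Synthetic OCT phantoms of stratified artificial-skin (AS) models.

The phantom emulates the A-scan signal structure of an air-liquid cultured
epidermal model imaged with OCT: two bright reflector bands (the cuticle top
and the basement membrane of the culture insert), a living keratinocyte layer
in between whose backscatter decays as a single-scattering Beer-Lambert
exponential, a constant additive background floor, and optionally fully
developed multiplicative speckle.  Every geometric and optical parameter is
carried as ground truth so each downstream stage (thickness, roughness,
segmentation, texture, scattering) can be validated without external data.

Conventions
-----------
* axial index 0-based, increasing with depth; voxel ``i`` samples ``z = i*dz``;
* all physical positions/thicknesses in micrometres, scattering in mm^-1;
* the membrane (culture insert) plane is flat apart from an optional tilt,
  and surface fluctuation lives entirely in the *thickness* field, so the
  thickness-derived roughness is tilt-invariant by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
import json

import numpy as np
from scipy import ndimage

from .core import (
    DEFAULT_DX_UM,
    DEFAULT_DY_UM,
    DEFAULT_DZ_UM,
    DEFAULT_N_TISSUE,
    GeometryError,
    OCTVolume,
    ValidationError,
    write_volume,
)

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "generate_surface_field",
    "generate_ascan",
    "generate_volume",
    "write_phantom",
    "load_phantom_spec",
]


@dataclass
class PhantomSpec:
    """Parameters of a synthetic AS volume.

    Defaults mirror the nominal acquisition geometry (2.59 mm / 1024 px axial
    range in tissue of index 1.38) and the pre-irradiation state of the AS
    models: ~90 um total thickness, ~22 um cuticle, scattering 2.16 mm^-1.

    ``mu_s`` may be a scalar or an ``(nx, ny)`` lateral field (mm^-1).
    ``tilt`` is the planar surface gradient in um per lateral mm, ``(x, y)``
    components.  ``band_width`` is the Gaussian sigma of the reflector bands
    in um; the default equals one axial pixel, the in-tissue axial resolution
    of the modelled system.
    """

    nx: int = 64
    ny: int = 64
    nz: int = 256
    dx: float = DEFAULT_DX_UM
    dy: float = DEFAULT_DY_UM
    dz: float = DEFAULT_DZ_UM
    n_tissue: float = DEFAULT_N_TISSUE
    surface_depth: float = 100.0
    mean_thickness: float = 90.0
    mean_cuticle: float = 22.0
    roughness_amplitude: float = 0.5
    roughness_smooth_px: float = 3.0
    tilt: tuple[float, float] = (0.0, 0.0)
    mu_s: float | np.ndarray = 2.16
    band_intensity_cuticle: float = 40.0
    band_intensity_membrane: float = 30.0
    band_width: float = DEFAULT_DZ_UM
    backscatter_amplitude: float = 10.0
    noise_floor: float = 0.5
    speckle_on: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("dx", "dy", "dz"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"invariant violated: pixel size {name} > 0")
        if not np.all(np.asarray(self.mu_s) > 0):
            raise ValidationError("invariant violated: mu_s > 0")
        if not self.mean_cuticle < self.mean_thickness:
            raise ValidationError(
                "invariant violated: mean_cuticle < mean_thickness"
            )
        margin = 6.0 * self.band_width + 4.0 * self.dz
        if self.nz * self.dz < self.surface_depth + self.mean_thickness + margin:
            raise ValidationError(
                "invariant violated: nz*dz >= surface_depth + mean_thickness"
                " + margin (volume must contain the whole model)"
            )
        if self.roughness_amplitude < 0:
            raise ValidationError("invariant violated: roughness_amplitude >= 0")
        mu = np.asarray(self.mu_s)
        if mu.ndim not in (0, 2) or (mu.ndim == 2 and mu.shape != (self.nx, self.ny)):
            raise ValidationError("mu_s must be scalar or an (nx, ny) field")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mu_s"] = np.asarray(self.mu_s).tolist()
        d["tilt"] = list(self.tilt)
        return d


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated volume.

    Indices are 0-based axial pixel indices; ``cell_top_index`` is the first
    voxel of the living-cell layer and ``cell_bottom_index`` the first voxel
    past it (the membrane band centre), so the layer is
    ``[cell_top_index, cell_bottom_index)``.
    """

    upper_surface: np.ndarray       # (nx, ny) um
    thickness: np.ndarray           # (nx, ny) um
    cuticle_thickness: np.ndarray   # (nx, ny) um
    surface_index: np.ndarray       # (nx, ny) int
    cell_top_index: np.ndarray      # (nx, ny) int
    cell_bottom_index: np.ndarray   # (nx, ny) int
    true_sa: float                  # um, mean |thickness - mean| (w=1 Sa)
    true_mu_s: np.ndarray           # (nx, ny) mm^-1


def _tilt_plane(spec: PhantomSpec) -> np.ndarray:
    x_mm = (np.arange(spec.nx) - (spec.nx - 1) / 2.0) * spec.dx / 1000.0
    y_mm = (np.arange(spec.ny) - (spec.ny - 1) / 2.0) * spec.dy / 1000.0
    return spec.tilt[0] * x_mm[:, None] + spec.tilt[1] * y_mm[None, :]


def _roughness_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean band-limited field whose mean absolute deviation equals
    ``roughness_amplitude`` exactly (unless the amplitude is zero)."""
    if spec.roughness_amplitude == 0:
        return np.zeros((spec.nx, spec.ny))
    white = rng.standard_normal((spec.nx, spec.ny))
    rough = ndimage.gaussian_filter(white, spec.roughness_smooth_px, mode="wrap")
    rough -= rough.mean()
    mad = np.abs(rough).mean()
    if mad == 0:  # pathological but possible on tiny fields
        return np.zeros((spec.nx, spec.ny))
    return rough * (spec.roughness_amplitude / mad)


def generate_surface_field(spec: PhantomSpec) -> np.ndarray:
    """Upper-surface height field (um): mean depth + tilt plane + roughness.

    Deterministic under a fixed ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng([int(spec.seed), 0])
    return spec.surface_depth + _tilt_plane(spec) + _roughness_field(spec, rng)


def _ascan_profile(
    z_um: np.ndarray,
    surface_z,
    cell_top_z,
    cell_bottom_z,
    mu_s,
    spec: PhantomSpec,
) -> np.ndarray:
    """Noiseless A-scan intensity; broadcasts over lateral fields.

    The cell-layer backscatter follows a single-scattering Beer-Lambert
    decay ``A * exp(-2 mu_s (z - z_top))`` with z in mm; the first and last
    cell voxels are scaled by their fractional coverage of the layer so the
    continuous layer geometry survives discretization.
    """
    sigma = spec.band_width
    dz = spec.dz
    out = np.full(np.broadcast_shapes(z_um.shape, np.shape(surface_z)),
                  float(spec.noise_floor))
    out = out + spec.band_intensity_cuticle * np.exp(
        -((z_um - surface_z) ** 2) / (2 * sigma**2)
    )
    out = out + spec.band_intensity_membrane * np.exp(
        -((z_um - cell_bottom_z) ** 2) / (2 * sigma**2)
    )
    # fractional overlap of voxel [z-dz/2, z+dz/2] with [cell_top, cell_bottom]
    cover = (
        np.minimum(z_um + dz / 2.0, cell_bottom_z)
        - np.maximum(z_um - dz / 2.0, cell_top_z)
    ) / dz
    cover = np.clip(cover, 0.0, 1.0)
    decay = np.exp(-2.0 * mu_s * np.maximum(z_um - cell_top_z, 0.0) / 1000.0)
    out = out + cover * spec.backscatter_amplitude * decay
    return out


def generate_ascan(
    z_um: np.ndarray,
    surface_z: float,
    cuticle_thickness: float,
    cell_bottom_z: float,
    mu_s: float,
    spec: PhantomSpec,
) -> np.ndarray:
    """Single noiseless A-scan ``I(z)`` for the given layer geometry.

    Raises :class:`GeometryError` if the layers do not fit inside ``z_um``.
    """
    z_um = np.asarray(z_um, dtype=np.float64)
    cell_top_z = surface_z + cuticle_thickness
    if not (cell_top_z < cell_bottom_z):
        raise GeometryError("cell layer top must lie above its bottom")
    if surface_z - 3 * spec.band_width < z_um[0] or (
        cell_bottom_z + 3 * spec.band_width > z_um[-1]
    ):
        raise GeometryError("layer geometry outside the sampled depth axis")
    return _ascan_profile(z_um, surface_z, cell_top_z, cell_bottom_z, mu_s, spec)


def generate_volume(spec: PhantomSpec) -> tuple[OCTVolume, PhantomTruth]:
    """Generate a full phantom volume and its ground truth.

    The thickness field carries the surface roughness (the membrane plane is
    flat up to tilt), so ``thickness = membrane_z - upper_surface`` and
    ``cuticle + cell = thickness`` hold exactly.
    """
    spec.validate()
    rng_surface = np.random.default_rng([int(spec.seed), 0])
    rough = _roughness_field(spec, rng_surface)
    tilt = _tilt_plane(spec)

    membrane_z = spec.surface_depth + spec.mean_thickness + tilt
    thickness = spec.mean_thickness - rough
    upper_surface = membrane_z - thickness
    cuticle = np.full((spec.nx, spec.ny), float(spec.mean_cuticle))
    cell_top_z = upper_surface + cuticle
    mu_field = np.broadcast_to(
        np.asarray(spec.mu_s, dtype=np.float64), (spec.nx, spec.ny)
    ).copy()

    z_um = np.arange(spec.nz, dtype=np.float64) * spec.dz
    lo = upper_surface - 3 * spec.band_width
    hi = membrane_z + 3 * spec.band_width
    bad = (lo < z_um[0]) | (hi > z_um[-1])
    if np.any(bad):
        x, y = np.argwhere(bad)[0]
        raise GeometryError(
            f"layer geometry outside the depth axis at (x={x}, y={y})"
        )

    intensity = _ascan_profile(
        z_um[:, None, None],
        upper_surface[None, :, :],
        cell_top_z[None, :, :],
        membrane_z[None, :, :],
        mu_field[None, :, :],
        spec,
    )
    if spec.speckle_on:
        rng_speckle = np.random.default_rng([int(spec.seed), 1])
        speckle = rng_speckle.exponential(
            1.0, size=(spec.nz, spec.nx, spec.ny)
        )
        tissue = intensity - spec.noise_floor
        intensity = spec.noise_floor + tissue * speckle

    truth = PhantomTruth(
        upper_surface=upper_surface,
        thickness=thickness,
        cuticle_thickness=cuticle,
        surface_index=np.rint(upper_surface / spec.dz).astype(int),
        cell_top_index=np.rint(cell_top_z / spec.dz).astype(int),
        cell_bottom_index=np.rint(membrane_z / spec.dz).astype(int),
        true_sa=float(np.abs(thickness - thickness.mean()).mean()),
        true_mu_s=mu_field,
    )
    volume = OCTVolume(
        intensity=intensity,
        dz=spec.dz,
        dx=spec.dx,
        dy=spec.dy,
        n_tissue=spec.n_tissue,
    )
    return volume, truth


def write_phantom(
    spec: PhantomSpec, out_dir: str | Path, name: str = "phantom"
) -> Path:
    """Generate and write ``<name>.tif`` + metadata + truth files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    volume, truth = generate_volume(spec)
    volume.meta["phantom_spec"] = spec.to_dict()
    tif_path = write_volume(volume, out_dir / name)
    truth_scalar = {
        "true_sa_um": truth.true_sa,
        "spec": spec.to_dict(),
        "fields": {},
    }
    import tifffile

    for key in (
        "upper_surface",
        "thickness",
        "cuticle_thickness",
        "true_mu_s",
    ):
        fpath = out_dir / f"{name}.truth_{key}.tif"
        tifffile.imwrite(fpath, getattr(truth, key).astype(np.float32))
        truth_scalar["fields"][key] = fpath.name
    (out_dir / f"{name}.truth.json").write_text(
        json.dumps(truth_scalar, indent=2)
    )
    return tif_path


def load_phantom_spec(path: str | Path) -> PhantomSpec:
    """Load a :class:`PhantomSpec` from a JSON config file."""
    d = json.loads(Path(path).read_text())
    if "tilt" in d:
        d["tilt"] = tuple(d["tilt"])
    if "mu_s" in d and isinstance(d["mu_s"], list):
        d["mu_s"] = np.asarray(d["mu_s"], dtype=np.float64)
    return PhantomSpec(**d)
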