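"""Synthetic voxel phantoms with uniform or heterogeneous acoustic properties.

The generators here reproduce the study media used in protoacoustic
range-verification work:

* thermal water phantoms: per-voxel temperature drawn i.i.d. from
  Normal(25 degC, sd^2) and converted voxel-wise to sound speed and density
  (uniform 25 degC mean preserved by construction);
* single-tissue phantoms (soft tissue / bone / lung), either uniform at the
  tissue means or non-uniform with i.i.d. per-voxel CT-number fluctuation
  mapped to properties;
* two-material phantoms split half/half across a plane perpendicular to the
  source-detector axis;
* CT-like labeled volumes (synthetic anatomy with optional air pockets) for
  detector-placement studies, plus a loader for external CT volumes.

Heterogeneity is i.i.d. per voxel with no spatial correlation: the study
conditions prescribe only per-tissue means and standard deviations, so the
voxel size sets the correlation length of the disorder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import media
from .media import TISSUES, TissueSpec, resolve_tissue

__all__ = [
    "MediumGrid",
    "PhantomConfig",
    "make_thermal_water_phantom",
    "make_tissue_phantom",
    "make_bimaterial_phantom",
    "make_ct_like_volume",
    "load_ct_volume",
    "save_grid",
    "load_grid",
]

# Positivity floor applied to generated properties: 1% of the lung means,
# guarding against Gaussian tail voxels that would be non-physical or
# numerically unstable.
_SPEED_FLOOR = 0.01 * TISSUES["lung"].speed_mean
_DENSITY_FLOOR = 0.01 * TISSUES["lung"].density_mean


@dataclass
class MediumGrid:
    """Voxel volume of acoustic properties.

    ``shape`` is (nx, ny, nz); nz == 1 means 2-D mode.  ``spacing`` is the
    isotropic voxel size in mm.  ``alpha0`` is the power-law absorption
    prefactor per voxel (Np/((rad/s)^d m)); ``labels`` optionally tags each
    voxel with a small integer material id.
    """

    spacing: float
    speed: np.ndarray
    density: np.ndarray
    alpha0: np.ndarray | None = None
    labels: np.ndarray | None = None
    hu: np.ndarray | None = None
    temperature: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.speed = np.atleast_3d(np.asarray(self.speed, dtype=float))
        self.density = np.atleast_3d(np.asarray(self.density, dtype=float))
        if self.alpha0 is None:
            self.alpha0 = np.zeros_like(self.speed)
        else:
            self.alpha0 = np.atleast_3d(np.asarray(self.alpha0, dtype=float))
        if self.labels is not None:
            self.labels = np.atleast_3d(np.asarray(self.labels))
        if self.hu is not None:
            self.hu = np.atleast_3d(np.asarray(self.hu, dtype=float))
        if self.temperature is not None:
            self.temperature = np.atleast_3d(np.asarray(self.temperature, dtype=float))
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        for name in ("density", "alpha0", "labels", "hu", "temperature"):
            arr = getattr(self, name)
            if arr is not None and arr.shape != self.speed.shape:
                raise ValueError(f"{name} shape {arr.shape} != {self.speed.shape}")
        if np.any(self.speed <= 0) or np.any(self.density <= 0):
            raise ValueError("speed and density must be positive everywhere")
        if np.any(self.alpha0 < 0):
            raise ValueError("alpha0 must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.speed.shape

    @property
    def is_2d(self) -> bool:
        return self.shape[2] == 1

    @property
    def ndim_effective(self) -> int:
        return 2 if self.is_2d else 3


@dataclass
class PhantomConfig:
    """Recipe for a synthetic phantom.

    ``kind`` selects the generator; ``tissues`` names one or two built-in
    tissue specs; ``heterogeneity`` is "uniform" (all SDs treated as zero)
    or "nonuniform".  Shapes follow MediumGrid conventions (nz = 1 for 2-D);
    the default is the full-size 2-D study section: 200 mm x 200 mm at 1 mm.
    """

    kind: str = "thermal_water"
    tissues: tuple[str, ...] = ()
    heterogeneity: str = "uniform"
    temperature_sd: float = 0.0
    temperature_mean: float = 25.0
    seed: int | None = 0
    shape: tuple[int, int, int] = (200, 200, 1)
    spacing: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in {"thermal_water", "homogeneous", "bimaterial", "ct_volume"}:
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.heterogeneity not in {"uniform", "nonuniform"}:
            raise ValueError("heterogeneity must be 'uniform' or 'nonuniform'")
        if self.temperature_sd < 0:
            raise ValueError("temperature_sd must be >= 0")
        if len(self.shape) != 3 or min(self.shape) < 1:
            raise ValueError("shape must be (nx, ny, nz) with all >= 1")

    def to_yaml(self, path) -> None:
        """Write the phantom recipe to a YAML file."""
        import yaml
        from dataclasses import asdict

        payload = asdict(self)
        payload["tissues"] = list(payload["tissues"])
        payload["shape"] = list(payload["shape"])
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PhantomConfig":
        """Read a phantom recipe written by :meth:`to_yaml`."""
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["tissues"] = tuple(payload.get("tissues", ()))
        payload["shape"] = tuple(payload["shape"])
        return cls(**payload)


def _floor_properties(speed: np.ndarray, density: np.ndarray, warn: bool = True) -> None:
    n = int(np.count_nonzero(speed < _SPEED_FLOOR) + np.count_nonzero(density < _DENSITY_FLOOR))
    if n and warn:
        warnings.warn(f"floored {n} non-physical voxels from Gaussian tails", stacklevel=3)
    np.maximum(speed, _SPEED_FLOOR, out=speed)
    np.maximum(density, _DENSITY_FLOOR, out=density)


def make_thermal_water_phantom(
    config: PhantomConfig, *, conversion: str = "linear"
) -> MediumGrid:
    """Water phantom with i.i.d. Gaussian spatial temperature fluctuation.

    Voxel temperatures are Normal(mean, sd^2) around the 25 degC baseline;
    sd = 0 yields exactly 1498 m/s and 997 kg/m3 everywhere.

    ``conversion`` selects how temperatures map to properties:

    * ``"linear"`` (default): tangent-line conversion at the reference
      temperature, c = 1498 + (dc/dT)|_25 * (T - 25) and likewise for the
      density.  This keeps the perturbation exactly zero-mean, i.e. the
      bulk medium properties are unchanged and only intra-medium
      heterogeneity remains — the condition the thermal study isolates.
      (The anchored polynomials are concave at 25 degC, so converting a
      wide symmetric temperature distribution through them would lower the
      bulk mean speed and mix a bulk effect into the heterogeneity effect.)
    * ``"polynomial"``: full anchored Marczak/Kell curves evaluated
      voxel-wise (tails extrapolated smoothly outside (0, 100) degC).
    """
    if config.kind != "thermal_water":
        raise ValueError("config.kind must be 'thermal_water'")
    if conversion not in {"linear", "polynomial"}:
        raise ValueError("conversion must be 'linear' or 'polynomial'")
    sd = 0.0 if config.heterogeneity == "uniform" else config.temperature_sd
    if sd == 0.0:
        speed = np.full(config.shape, media.WATER_SPEED_25C)
        density = np.full(config.shape, media.WATER_DENSITY_25C)
        temp = np.full(config.shape, config.temperature_mean)
        return MediumGrid(
            spacing=config.spacing, speed=speed, density=density, temperature=temp
        )
    rng = np.random.default_rng(config.seed)
    temp = rng.normal(config.temperature_mean, sd, size=config.shape)
    if conversion == "linear":
        eps = 1e-5
        t0 = config.temperature_mean
        c0 = media.water_speed_of_sound(t0)
        r0 = media.water_density(t0)
        dc = (media.water_speed_of_sound(t0 + eps) - media.water_speed_of_sound(t0 - eps)) / (2 * eps)
        dr = (media.water_density(t0 + eps) - media.water_density(t0 - eps)) / (2 * eps)
        speed = c0 + dc * (temp - t0)
        density = r0 + dr * (temp - t0)
    else:
        speed = np.asarray(media.water_speed_of_sound(temp, extrapolate=True))
        density = np.asarray(media.water_density(temp, extrapolate=True))
    _floor_properties(speed, density)
    return MediumGrid(
        spacing=config.spacing, speed=speed, density=density, temperature=temp
    )


def _tissue_fields(
    spec: TissueSpec, shape, rng: np.random.Generator | None, nonuniform: bool
):
    """Per-voxel (hu, speed, density) fields for one tissue.

    Non-uniform fields share a single standard-normal draw per voxel: the CT
    number and both properties are perturbed coherently, with the per-tissue
    property SDs taken from the measured tissue statistics (a local
    linearization of the CT-number-to-property conversion calibrated to
    those statistics).  This keeps the uniform and non-uniform phantoms
    matched in expectation.
    """
    if not nonuniform:
        hu = np.full(shape, spec.hu_mean)
        speed = np.full(shape, spec.speed_mean)
        density = np.full(shape, spec.density_mean)
        return hu, speed, density
    z = rng.standard_normal(size=shape)
    hu = spec.hu_mean + spec.hu_sd * z
    speed = spec.speed_mean + spec.speed_sd * z
    density = spec.density_mean + spec.density_sd * z
    return hu, speed, density


def make_tissue_phantom(config: PhantomConfig) -> MediumGrid:
    """Homogeneous single-tissue phantom, uniform or non-uniform."""
    if config.kind != "homogeneous":
        raise ValueError("config.kind must be 'homogeneous'")
    if len(config.tissues) != 1:
        raise ValueError("homogeneous phantom needs exactly one tissue name")
    spec = resolve_tissue(config.tissues[0])
    rng = np.random.default_rng(config.seed)
    hu, speed, density = _tissue_fields(
        spec, config.shape, rng, config.heterogeneity == "nonuniform"
    )
    _floor_properties(speed, density)
    labels = np.zeros(config.shape, dtype=np.int8)
    return MediumGrid(
        spacing=config.spacing, speed=speed, density=density, labels=labels, hu=hu
    )


def make_bimaterial_phantom(config: PhantomConfig) -> MediumGrid:
    """Two-material phantom split at the domain midplane.

    The split plane is perpendicular to the first grid axis (the
    source-detector axis by convention): the first tissue fills the low-x
    half where the Bragg peak sits, the second the detector half.  With a
    100 mm source-detector separation centred on the midplane the straight
    path crosses 50 mm of each material.
    """
    if config.kind != "bimaterial":
        raise ValueError("config.kind must be 'bimaterial'")
    if len(config.tissues) != 2:
        raise ValueError("bimaterial phantom needs exactly two tissue names")
    spec_a, spec_b = (resolve_tissue(t) for t in config.tissues)
    if spec_a.name == spec_b.name:
        raise ValueError("bimaterial phantom requires two distinct tissues")
    rng = np.random.default_rng(config.seed)
    nonuniform = config.heterogeneity == "nonuniform"
    nx = config.shape[0]
    half = nx // 2
    hu = np.empty(config.shape)
    speed = np.empty(config.shape)
    density = np.empty(config.shape)
    labels = np.empty(config.shape, dtype=np.int8)
    for sl, spec, lab in (
        (slice(0, half), spec_a, 0),
        (slice(half, nx), spec_b, 1),
    ):
        sub_shape = (sl.stop - sl.start,) + tuple(config.shape[1:])
        h, s, d = _tissue_fields(spec, sub_shape, rng, nonuniform)
        hu[sl], speed[sl], density[sl], labels[sl] = h, s, d, lab
    _floor_properties(speed, density)
    return MediumGrid(
        spacing=config.spacing, speed=speed, density=density, labels=labels, hu=hu
    )


def make_ct_like_volume(
    shape: tuple[int, int, int] = (200, 200, 1),
    spacing: float = 1.0,
    *,
    body_tissue: str = "soft_tissue",
    bone_shell_mm: float = 8.0,
    air_pocket: tuple[tuple[float, float, float], float] | None = None,
    air_slab: tuple[tuple[float, float, float], float, float] | None = None,
    lung_region: tuple[tuple[float, float, float], float] | None = None,
    seed: int | None = None,
    hu_sd_scale: float = 0.0,
) -> MediumGrid:
    """Synthetic CT-like labeled volume for detector-placement studies.

    An elliptical soft-tissue body surrounded by air, with an optional bone
    shell at the body surface, an optional spherical lung region and an
    optional air pocket (centre in mm, radius in mm) and an optional thin
    air slab ``((centre_mm), width_mm, half_extent_mm)`` perpendicular to
    the first axis — a thin wide barrier forces waves to detour around its
    edge while barely changing the straight-path average speed, the
    configuration that drives large clinical range overestimates.
    ``hu_sd_scale`` scales the per-tissue CT-number SDs (0 = uniform
    tissue interiors).
    Properties are produced by the anchor CT-number mapping, so the volume
    exercises exactly the pipeline a real CT volume would.
    """
    rng = np.random.default_rng(seed)
    spec = resolve_tissue(body_tissue)
    nx, ny, nz = shape
    idx = np.indices(shape, dtype=float)
    centre = (np.array(shape, dtype=float)[:, None, None, None] - 1) / 2.0
    pos_mm = idx * spacing  # voxel-centre coordinates, mm
    r_ell = np.sqrt(
        ((idx[0] - centre[0]) / (0.45 * nx)) ** 2
        + ((idx[1] - centre[1]) / (0.45 * ny)) ** 2
        + (((idx[2] - centre[2]) / (0.45 * nz)) ** 2 if nz > 1 else 0.0)
    )
    hu = np.zeros(shape)  # air background
    labels = np.full(shape, -1, dtype=np.int8)
    body = r_ell <= 1.0
    hu[body] = spec.hu_mean
    labels[body] = 0
    if bone_shell_mm > 0:
        shell = body & (r_ell >= 1.0 - bone_shell_mm / (0.45 * nx * spacing))
        hu[shell] = TISSUES["bone"].hu_mean
        labels[shell] = 1

    def _ball(centre_mm, radius_mm):
        d2 = sum((pos_mm[i] - centre_mm[i]) ** 2 for i in range(3 if nz > 1 else 2))
        return d2 <= radius_mm**2

    if lung_region is not None:
        m = _ball(*lung_region) & body
        hu[m] = TISSUES["lung"].hu_mean
        labels[m] = 2
    if hu_sd_scale > 0:
        for lab, name in ((0, body_tissue), (1, "bone"), (2, "lung")):
            m = labels == lab
            if m.any():
                sd = hu_sd_scale * resolve_tissue(name).hu_sd
                hu[m] += rng.normal(0.0, sd, size=int(m.sum()))
    if air_pocket is not None:
        m = _ball(*air_pocket)
        hu[m] = 0.0
        labels[m] = -1
    if air_slab is not None:
        (cx, cy, cz), width_mm, half_mm = air_slab
        m = (np.abs(pos_mm[0] - cx) <= width_mm / 2.0) & (
            np.abs(pos_mm[1] - cy) <= half_mm
        )
        if nz > 1:
            m &= np.abs(pos_mm[2] - cz) <= half_mm
        hu[m] = 0.0
        labels[m] = -1
    hu = np.clip(hu, 0.0, 1850.0)
    speed = np.asarray(media.hu_to_speed(hu))
    density = np.asarray(media.hu_to_density(hu))
    _floor_properties(speed, density, warn=False)  # air voxels are expected here
    return MediumGrid(
        spacing=spacing, speed=speed, density=density, labels=labels, hu=hu
    )


def load_ct_volume(path, spacing: float | None = None, *, hu_scale: str) -> MediumGrid:
    """Load a CT volume (NIfTI or .npz raw voxels) and map it to properties.

    ``hu_scale`` must be declared explicitly: "offset" (water ~ 1000) or
    "conventional" (water = 0).  For NIfTI input the voxel size is read from
    the header unless ``spacing`` overrides it; .npz input must contain an
    ``hu`` array and, if ``spacing`` is not given, a scalar ``spacing``.
    """
    if hu_scale not in {"offset", "conventional"}:
        raise ValueError("hu_scale must be declared as 'offset' or 'conventional'")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    if p.suffix == ".npz":
        with np.load(p) as data:
            if "hu" not in data:
                raise ValueError("raw voxel archive must contain an 'hu' array")
            hu = np.asarray(data["hu"], dtype=float)
            if spacing is None:
                if "spacing" not in data:
                    raise ValueError("spacing not declared in file or argument")
                spacing = float(data["spacing"])
    else:
        import nibabel as nib

        img = nib.load(str(p))
        hu = np.asarray(img.get_fdata(), dtype=float)
        if spacing is None:
            zooms = img.header.get_zooms()[:3]
            if not np.allclose(zooms, zooms[0]):
                raise ValueError("anisotropic NIfTI voxels; pass spacing explicitly")
            spacing = float(zooms[0])
    if hu_scale == "conventional":
        hu = np.asarray(media.hu_from_conventional(hu))
    hu = np.atleast_3d(hu)
    speed = np.asarray(media.hu_to_speed(np.clip(hu, 0.0, 1850.0)))
    density = np.asarray(media.hu_to_density(np.clip(hu, 0.0, 1850.0)))
    _floor_properties(speed, density, warn=False)
    return MediumGrid(spacing=float(spacing), speed=speed, density=density, hu=hu)


def save_grid(grid: MediumGrid, path) -> None:
    """Write a MediumGrid to a compressed .npz archive."""
    payload = {
        "spacing": np.float64(grid.spacing),
        "speed": grid.speed,
        "density": grid.density,
        "alpha0": grid.alpha0,
    }
    if grid.labels is not None:
        payload["labels"] = grid.labels
    if grid.hu is not None:
        payload["hu"] = grid.hu
    np.savez_compressed(path, **payload)


def load_grid(path) -> MediumGrid:
    """Read a MediumGrid written by :func:`save_grid`."""
    with np.load(path) as data:
        return MediumGrid(
            spacing=float(data["spacing"]),
            speed=data["speed"],
            density=data["density"],
            alpha0=data["alpha0"],
            labels=data["labels"] if "labels" in data else None,
            hu=data["hu"] if "hu" in data else None,
        )
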