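"""Acoustic material models for thermoacoustic simulation.

This module converts the two kinds of raw material descriptions used in
protoacoustic range-verification studies into acoustic properties:

* water temperature fields  -> speed of sound and density via published
  temperature polynomials (Marczak sound-speed polynomial, Kell density
  formula), affinely anchored so that 25 degC maps exactly to the study
  baseline of 1498 m/s and 997 kg/m3;
* CT numbers (offset Hounsfield scale, water ~ 1000) -> speed of sound and
  density via piecewise-linear interpolation through per-tissue anchor
  points (lung, water, soft tissue, cortical bone).

It also provides the thermoacoustic efficiency (Grüneisen) coefficient
``Gamma = c^2 * beta / Cp`` and the frequency power-law attenuation
``alpha(omega) = alpha0 * omega^d``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "TissueSpec",
    "ThermoacousticParams",
    "AttenuationLaw",
    "TISSUES",
    "WATER_SPEED_25C",
    "WATER_DENSITY_25C",
    "WATER_HU",
    "water_speed_of_sound",
    "water_density",
    "hu_to_speed",
    "hu_to_density",
    "hu_from_conventional",
    "gruneisen",
    "attenuation_at",
    "thermo_defaults",
    "load_tissue_table",
    "dump_tissue_table",
]

# Study baseline: water at the 25 degC reference temperature.
WATER_SPEED_25C = 1498.0  # m/s
WATER_DENSITY_25C = 997.0  # kg/m3
WATER_HU = 1000.0  # offset CT-number scale (air ~ 0, water ~ 1000)


@dataclass(frozen=True)
class TissueSpec:
    """Per-tissue CT-number and acoustic-property statistics.

    CT numbers are on the offset scale (water ~ 1000, air ~ 0).  The three
    built-in specs (soft tissue, bone, lung) carry the voxel statistics
    measured on an ATOM anthropomorphic phantom CT.
    """

    name: str
    hu_mean: float
    hu_sd: float
    density_mean: float  # kg/m3
    density_sd: float
    speed_mean: float  # m/s
    speed_sd: float

    def __post_init__(self) -> None:
        if min(self.hu_sd, self.density_sd, self.speed_sd) < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.density_mean <= 0 or self.speed_mean <= 0:
            raise ValueError("mean density and speed must be positive")


#: Built-in tissue statistics (offset-HU scale).
TISSUES: dict[str, TissueSpec] = {
    "soft_tissue": TissueSpec("soft_tissue", 1042.5, 62.5, 1050.4, 32.8, 1567.1, 36.8),
    "bone": TissueSpec("bone", 1850.0, 50.0, 1574.4, 19.3, 2153.9, 21.6),
    "lung": TissueSpec("lung", 234.5, 71.5, 234.0, 42.7, 652.8, 47.8),
}

_TISSUE_ALIASES = {
    "soft tissue": "soft_tissue",
    "tissue": "soft_tissue",
    "soft-tissue": "soft_tissue",
}


def resolve_tissue(name: str) -> TissueSpec:
    """Look up a built-in tissue spec by name (a few aliases accepted)."""
    key = _TISSUE_ALIASES.get(name.lower().strip(), name.lower().strip())
    try:
        return TISSUES[key]
    except KeyError:
        raise KeyError(
            f"unknown tissue {name!r}; available: {sorted(TISSUES)}"
        ) from None


@dataclass(frozen=True)
class ThermoacousticParams:
    """Thermoacoustic material constants entering the Grüneisen coefficient.

    c : sound speed [m/s]; beta : volumetric thermal expansion [1/K];
    cp : specific heat [J/(K kg)]; rho : mass density [kg/m3].
    """

    c: float
    beta: float
    cp: float
    rho: float

    def __post_init__(self) -> None:
        if self.c <= 0 or self.cp <= 0 or self.rho <= 0:
            raise ValueError("c, cp and rho must be positive")


@dataclass(frozen=True)
class AttenuationLaw:
    """Frequency power-law acoustic absorption alpha(omega) = alpha0 * omega^d.

    ``alpha0`` is in Np/((rad/s)^d m); the exponent defaults to 1.05, a
    typical soft-tissue value.
    """

    alpha0: float
    d: float = 1.05

    def __post_init__(self) -> None:
        if self.alpha0 < 0:
            raise ValueError("alpha0 must be >= 0")


# Marczak five-degree polynomial for the speed of sound in pure water
# (0-95 degC, m/s); evaluated with an affine offset so the 25 degC value is
# exactly the study baseline.
_MARCZAK = (
    1402.385,
    5.038813,
    -5.799136e-2,
    3.287156e-4,
    -1.398845e-6,
    2.787860e-9,
)


def _marczak_raw(t: np.ndarray) -> np.ndarray:
    out = np.zeros_like(t, dtype=float)
    for k, a in enumerate(_MARCZAK):
        out += a * t**k
    return out


_MARCZAK_OFFSET = WATER_SPEED_25C - float(_marczak_raw(np.float64(25.0)))


# Kell (1975) density of air-free water at atmospheric pressure (kg/m3),
# again anchored affinely to the 25 degC study baseline.
_KELL_NUM = (
    999.83952,
    16.945176,
    -7.9870401e-3,
    -46.170461e-6,
    105.56302e-9,
    -280.54253e-12,
)
_KELL_DEN = 16.897850e-3


def _kell_raw(t: np.ndarray) -> np.ndarray:
    num = np.zeros_like(t, dtype=float)
    for k, a in enumerate(_KELL_NUM):
        num += a * t**k
    return num / (1.0 + _KELL_DEN * t)


_KELL_OFFSET = WATER_DENSITY_25C - float(_kell_raw(np.float64(25.0)))


def _check_temperature(t: np.ndarray, extrapolate: bool) -> None:
    if not np.all(np.isfinite(t)):
        raise ValueError("temperature must be finite")
    if not extrapolate and (np.any(t <= 0.0) or np.any(t >= 100.0)):
        raise ValueError("temperature outside the (0, 100) degC liquid range")


def water_speed_of_sound(temperature_celsius, *, extrapolate: bool = False):
    """Speed of sound in water [m/s] at the given temperature(s) [degC].

    Monotone increasing on [0, 74] degC and exactly 1498 m/s at 25 degC.
    With ``extrapolate=True`` the anchored polynomial is evaluated outside
    the liquid range as well (used when sampling wide Gaussian temperature
    fields whose tails leave (0, 100) degC).
    """
    t = np.asarray(temperature_celsius, dtype=float)
    _check_temperature(t, extrapolate)
    out = _marczak_raw(t) + _MARCZAK_OFFSET
    return out if out.ndim else float(out)


def water_density(temperature_celsius, *, extrapolate: bool = False):
    """Density of water [kg/m3]; exactly 997 at 25 degC, decreasing above 4 degC."""
    t = np.asarray(temperature_celsius, dtype=float)
    _check_temperature(t, extrapolate)
    out = _kell_raw(t) + _KELL_OFFSET
    return out if out.ndim else float(out)


# Piecewise-linear CT-number -> property anchors on the offset HU scale:
# air, lung, water (25 degC), soft tissue, cortical bone.
_HU_ANCHORS = np.array([0.0, 234.5, WATER_HU, 1042.5, 1850.0])
_SPEED_ANCHORS = np.array([343.0, 652.8, WATER_SPEED_25C, 1567.1, 2153.9])
_DENSITY_ANCHORS = np.array([1.2, 234.0, WATER_DENSITY_25C, 1050.4, 1574.4])


def _hu_interp(hu, anchors: np.ndarray, what: str):
    h = np.asarray(hu, dtype=float)
    if not np.all(np.isfinite(h)):
        raise ValueError("CT number must be finite")
    if np.any(h < _HU_ANCHORS[0]) or np.any(h > _HU_ANCHORS[-1]):
        warnings.warn(
            f"CT number outside [{_HU_ANCHORS[0]:g}, {_HU_ANCHORS[-1]:g}] "
            f"clamped in {what} mapping",
            stacklevel=3,
        )
    out = np.interp(h, _HU_ANCHORS, anchors)
    return out if out.ndim else float(out)


def hu_to_speed(hu):
    """Map offset-scale CT numbers to sound speed [m/s] (anchor interpolation)."""
    return _hu_interp(hu, _SPEED_ANCHORS, "speed")


def hu_to_density(hu):
    """Map offset-scale CT numbers to density [kg/m3] (anchor interpolation)."""
    return _hu_interp(hu, _DENSITY_ANCHORS, "density")


def hu_from_conventional(hu):
    """Convert conventional Hounsfield units (water = 0) to the offset scale."""
    out = np.asarray(hu, dtype=float) + 1000.0
    return out if out.ndim else float(out)


def gruneisen(params: ThermoacousticParams) -> float:
    """Grüneisen coefficient Gamma = c^2 beta / Cp (dimensionless)."""
    g = params.c**2 * params.beta / params.cp
    if not np.isfinite(g):
        raise ValueError("non-finite Grüneisen coefficient")
    return float(g)


def attenuation_at(law: AttenuationLaw, omega) -> float:
    """Power-law absorption alpha(omega) = alpha0 * omega^d [Np/m]."""
    w = np.asarray(omega, dtype=float)
    if np.any(w < 0):
        raise ValueError("angular frequency must be >= 0")
    out = law.alpha0 * w**law.d
    return out if out.ndim else float(out)


# Configurable thermoacoustic constants per tissue.  The study geometry only
# prescribes the acoustic properties; beta and Cp default to water-like
# soft-tissue values and may be overridden from a YAML/JSON table.
_DEFAULT_THERMO_TABLE: dict[str, dict[str, float]] = {
    "water": {"beta": 2.3e-4, "cp": 4178.0, "alpha0": 0.0},
    "soft_tissue": {"beta": 2.3e-4, "cp": 4178.0, "alpha0": 0.0},
    "bone": {"beta": 2.3e-4, "cp": 4178.0, "alpha0": 0.0},
    "lung": {"beta": 2.3e-4, "cp": 4178.0, "alpha0": 0.0},
}


def thermo_defaults(tissue: str = "water") -> ThermoacousticParams:
    """Default thermoacoustic constants for a named material.

    Sound speed/density come from the tissue table (or the water baseline);
    beta and Cp from the configurable constants table.
    """
    key = _TISSUE_ALIASES.get(tissue.lower(), tissue.lower())
    row = _DEFAULT_THERMO_TABLE.get(key)
    if row is None:
        raise KeyError(f"no thermoacoustic defaults for {tissue!r}")
    if key == "water":
        c, rho = WATER_SPEED_25C, WATER_DENSITY_25C
    else:
        spec = resolve_tissue(key)
        c, rho = spec.speed_mean, spec.density_mean
    return ThermoacousticParams(c=c, beta=row["beta"], cp=row["cp"], rho=rho)


def dump_tissue_table(path) -> None:
    """Write the built-in tissue statistics and thermo constants to YAML."""
    payload = {
        "tissues": {
            k: {
                "hu_mean": v.hu_mean,
                "hu_sd": v.hu_sd,
                "density_mean": v.density_mean,
                "density_sd": v.density_sd,
                "speed_mean": v.speed_mean,
                "speed_sd": v.speed_sd,
            }
            for k, v in TISSUES.items()
        },
        "thermoacoustic": _DEFAULT_THERMO_TABLE,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_tissue_table(path) -> dict[str, TissueSpec]:
    """Load a tissue-statistics table from YAML (same layout as the dump)."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return {
        name: TissueSpec(name=name, **row) for name, row in payload["tissues"].items()
    }
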