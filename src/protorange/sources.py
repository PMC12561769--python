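"""Spatio-temporal thermoacoustic pressure sources.

The initial pressure deposited by a pulsed proton beam is
``P0(r) = Gamma(r) * rho(r) * Dose(r)`` and the time-dependent source is the
spatial map convolved with the (Gaussian) temporal beam profile,
``P0(r, t) = P0(r) x G(t)``.  Because the source map and the pulse are
separable, the solver injects ``amplitude * pulse[n]`` at each source voxel
and time step.

Study sources follow the standard protoacoustic configuration: one
Bragg-peak source (12 mPa by default) plus weaker sources (2 mPa) at every
voxel along the proton entrance path, all sharing the same pulse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .media import ThermoacousticParams, gruneisen
from .phantoms import MediumGrid

__all__ = [
    "SourceTerm",
    "DoseMap",
    "gaussian_pulse",
    "initial_pressure",
    "build_study_sources",
    "BRAGG_PEAK_PRESSURE",
    "ENTRANCE_PRESSURE",
    "DEFAULT_PULSE_WIDTH",
]

#: Default source amplitudes [Pa] and pulse width [s] for study runs.
BRAGG_PEAK_PRESSURE = 12e-3
ENTRANCE_PRESSURE = 2e-3
DEFAULT_PULSE_WIDTH = 10e-6


@dataclass
class SourceTerm:
    """Separable space-time pressure source.

    ``positions`` are integer voxel coordinates, ``amplitudes`` the per-voxel
    peak pressures [Pa]; ``pulse`` is the shared unit-peak temporal waveform
    sampled at ``dt`` (must match the solver step).
    """

    positions: np.ndarray  # (n, 3) int voxel coordinates
    amplitudes: np.ndarray  # (n,) Pa
    pulse: np.ndarray
    dt: float
    pulse_width: float = DEFAULT_PULSE_WIDTH

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=int))
        if self.positions.shape[1] == 2:  # 2-D convenience: pad z = 0
            self.positions = np.hstack(
                [self.positions, np.zeros((len(self.positions), 1), dtype=int)]
            )
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        self.pulse = np.asarray(self.pulse, dtype=float)
        if len(self.amplitudes) != len(self.positions):
            raise ValueError("positions and amplitudes must have equal length")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be >= 0")
        if np.any(self.pulse < 0) or self.pulse.size < 2:
            raise ValueError("pulse must be a non-negative sampled waveform")
        if not np.isclose(self.pulse.max(), 1.0):
            raise ValueError("pulse must be normalized to unit peak")


@dataclass
class DoseMap:
    """Per-voxel dose [Gy or relative units] on a MediumGrid-shaped lattice."""

    dose: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        self.dose = np.atleast_3d(np.asarray(self.dose, dtype=float))
        if np.any(self.dose < 0):
            raise ValueError("dose must be >= 0 everywhere")


def gaussian_pulse(width: float = DEFAULT_PULSE_WIDTH, dt: float = 1e-8) -> np.ndarray:
    """Unit-peak Gaussian pulse of total width ``width`` sampled at ``dt``.

    The total width is read as the 6-sigma support (sigma = width / 6), the
    peak sits at t = width / 2 and the waveform is truncated to [0, width].
    """
    if width <= 0 or dt <= 0:
        raise ValueError("width and dt must be positive")
    if dt > width / 20:
        raise ValueError("dt too coarse: need dt <= width / 20")
    n = int(round(width / dt)) + 1
    t = np.arange(n) * dt
    sigma = width / 6.0
    g = np.exp(-((t - width / 2.0) ** 2) / (2.0 * sigma**2))
    return g / g.max()


def initial_pressure(
    dose: DoseMap, medium: MediumGrid, thermo: ThermoacousticParams
) -> np.ndarray:
    """Initial pressure map P0 = Gamma * rho * Dose [Pa].

    The Grüneisen coefficient uses the supplied thermoacoustic constants
    with the per-voxel sound speed of the medium; density comes from the
    medium grid.
    """
    if dose.dose.shape != medium.shape:
        raise ValueError(f"dose shape {dose.dose.shape} != medium {medium.shape}")
    gamma = medium.speed**2 * thermo.beta / thermo.cp
    return gamma * medium.density * dose.dose


def _line_voxels(start: np.ndarray, stop: np.ndarray) -> np.ndarray:
    """Integer voxels along a straight segment (inclusive, unit steps)."""
    delta = stop - start
    n = int(np.abs(delta).max())
    if n == 0:
        return start[None, :]
    steps = np.linspace(0.0, 1.0, n + 1)[:, None]
    return np.rint(start + steps * delta).astype(int)


def build_study_sources(
    bragg_position,
    beam_axis,
    entrance_length: float,
    medium: MediumGrid,
    *,
    bragg_pressure: float = BRAGG_PEAK_PRESSURE,
    entrance_pressure: float = ENTRANCE_PRESSURE,
    pulse_width: float = DEFAULT_PULSE_WIDTH,
    dt: float = 1e-8,
) -> SourceTerm:
    """Bragg-peak plus entrance-path sources on a medium grid.

    The beam travels along ``beam_axis`` (grid-frame vector) and stops at
    ``bragg_position`` (voxel coordinates); sources of ``entrance_pressure``
    are placed at every voxel of the ``entrance_length`` mm of path
    preceding the Bragg peak, which itself receives ``bragg_pressure``.
    All sources share one Gaussian pulse.
    """
    bragg = np.asarray(bragg_position, dtype=float)
    if bragg.size == 2:
        bragg = np.append(bragg, 0.0)
    axis = np.asarray(beam_axis, dtype=float)
    if axis.size == 2:
        axis = np.append(axis, 0.0)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("beam_axis must be non-zero")
    axis = axis / norm
    if entrance_length < 0:
        raise ValueError("entrance_length must be >= 0")

    shape = np.array(medium.shape)
    if np.any(bragg < 0) or np.any(bragg > shape - 1):
        raise ValueError("bragg_position outside the grid")

    positions = [np.rint(bragg).astype(int)]
    amplitudes = [bragg_pressure]
    if entrance_length > 0:
        n_back = entrance_length / medium.spacing
        entry = bragg - axis * n_back
        if np.any(entry < 0) or np.any(entry > shape - 1):
            raise ValueError("entrance path exits the grid")
        line = _line_voxels(np.rint(entry).astype(int), np.rint(bragg).astype(int))
        for vox in line[:-1]:  # exclude the Bragg voxel itself
            positions.append(vox)
            amplitudes.append(entrance_pressure)
    pulse = gaussian_pulse(pulse_width, dt)
    return SourceTerm(
        positions=np.array(positions),
        amplitudes=np.array(amplitudes),
        pulse=pulse,
        dt=dt,
        pulse_width=pulse_width,
    )
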