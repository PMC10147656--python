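"""Core containers shared by every pipeline stage.

All quantities are SI throughout (metres, seconds, kelvin, pascal);
display-layer code may convert to µm/nm but files and APIs never do.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

#: Boltzmann constant, J/K (exact, 2019 SI redefinition).
BOLTZMANN_KB = 1.380649e-23


class MicrorheoError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(MicrorheoError, ValueError):
    """A precondition on an argument was violated."""


@dataclass(frozen=True)
class ProbeContext:
    """Probe and medium metadata entering every Stokes–Einstein-type formula.

    Parameters
    ----------
    radius_a : float
        Bead radius ``a`` in metres.
    temperature_T : float
        Absolute temperature in kelvin.
    solvent_viscosity_eta_s : float
        Newtonian viscosity of the pure solvent, Pa·s. Used both as the
        simulation medium viscosity (unless overridden) and as the reference
        for relative viscosity.
    """

    radius_a: float
    temperature_T: float
    solvent_viscosity_eta_s: float
    boltzmann_kB: float = BOLTZMANN_KB

    def __post_init__(self) -> None:
        for name in ("radius_a", "temperature_T", "solvent_viscosity_eta_s"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be strictly positive, "
                                           f"got {getattr(self, name)!r}")

    @property
    def kBT(self) -> float:
        """Thermal energy k_B·T in joules."""
        return self.boltzmann_kB * self.temperature_T

    @property
    def drag(self) -> float:
        """Stokes drag γ = 6π·η_s·a for the bead in the pure solvent, kg/s."""
        return 6.0 * np.pi * self.solvent_viscosity_eta_s * self.radius_a

    @property
    def diffusion_coefficient(self) -> float:
        """Stokes–Einstein free diffusion coefficient D = k_B·T / (6π·η_s·a)."""
        return self.kBT / self.drag


def water_context(radius_a: float = 3e-6, temperature_T: float = 298.15) -> ProbeContext:
    """A bead in water at 25 °C (η = 0.89 mPa·s); the default validation medium."""
    return ProbeContext(radius_a=radius_a, temperature_T=temperature_T,
                        solvent_viscosity_eta_s=0.89e-3)


@dataclass
class Trajectory:
    """Time-stamped probe positions on a uniform time base.

    ``positions`` has shape ``(n_samples, n_axes)`` in metres. Axes are named
    (subset of ``x, y, z``). Rows listed in ``dropped_frames`` may be NaN
    (localization failures that are flagged, never interpolated); all other
    values must be finite.
    """

    t: np.ndarray
    positions: np.ndarray
    frame_rate: float
    context: ProbeContext
    axes: tuple[str, ...] = ("x",)
    provenance: dict[str, Any] = field(default_factory=dict)
    dropped_frames: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape[0] == 1 and self.t.size > 1:
            self.positions = self.positions.T
        if self.t.ndim != 1 or self.t.size < 2:
            raise InvalidArgumentError("trajectory needs at least 2 samples")
        if len(self.t) != len(self.positions):
            raise InvalidArgumentError(
                f"t has {len(self.t)} samples but positions has {len(self.positions)}")
        if len(self.axes) != self.positions.shape[1]:
            raise InvalidArgumentError("axes names do not match position columns")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise InvalidArgumentError("time must be strictly increasing")
        if np.abs(dt * self.frame_rate - 1.0).max() > 1e-6:
            raise InvalidArgumentError("time base is not uniform at 1/frame_rate")
        mask = np.zeros(len(self.t), dtype=bool)
        if self.dropped_frames is not None:
            self.dropped_frames = np.asarray(self.dropped_frames, dtype=int)
            mask[self.dropped_frames] = True
        if not np.all(np.isfinite(self.positions[~mask])):
            raise InvalidArgumentError("non-finite positions outside dropped frames")

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def n_axes(self) -> int:
        return self.positions.shape[1]

    def axis(self, name: str) -> np.ndarray:
        """Return the position series (m) for one named axis."""
        try:
            i = self.axes.index(name)
        except ValueError:
            raise InvalidArgumentError(
                f"axis {name!r} not in trajectory (has {self.axes})") from None
        return self.positions[:, i]

    def with_positions(self, positions: np.ndarray, **extra_provenance: Any) -> "Trajectory":
        prov = dict(self.provenance)
        prov.update(extra_provenance)
        return replace(self, positions=np.asarray(positions, dtype=float),
                       provenance=prov)

    def select_axes(self, names: tuple[str, ...] | list[str]) -> "Trajectory":
        idx = [self.axes.index(n) for n in names]
        return replace(self, positions=self.positions[:, idx], axes=tuple(names))
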