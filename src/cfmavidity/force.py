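"""Centrifugal force model for cell detachment assays.

A cell spinning at angular speed ``omega`` at distance ``r`` from the rotor
axis experiences a net pulling force ``F = m_eff * r * omega**2``, where the
effective mass is the buoyancy-corrected mass of the cell,
``m_eff = V_cell * (rho_cell - rho_medium)``.  Public quantities use the
field's customary units (pN, um, g/mL, rpm); SI is used internally.

The module also designs stair-step rpm schedules that realise a target
linear force ramp (pN/s), mirroring how a programmable benchtop centrifuge
approximates a continuous ramp with small speed increments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "STANDARD_GRAVITY",
    "DEFAULT_ROTOR_RADIUS_M",
    "DEFAULT_RPM_CEILING",
    "CellParams",
    "RampProtocol",
    "ForceTrace",
    "effective_mass",
    "force_at_rpm",
    "gravity_force",
    "design_ramp",
    "force_trace",
]

#: Standard gravitational acceleration, m/s^2.
STANDARD_GRAVITY = 9.81

#: Default effective rotor radius (m).  Derived from the instrument's printed
#: rpm <-> relative-centrifugal-force pairs (300 rpm = 13 g, 3000 rpm = 1340 g):
#: r = 1340 * 9.81 / (2*pi*3000/60)**2.  A larger radius (~0.16 m, consistent
#: with ~1600 g at 3000 rpm) is sometimes quoted for the same rotor class;
#: pass ``rotor_radius`` explicitly to override.
DEFAULT_ROTOR_RADIUS_M = 1340.0 * STANDARD_GRAVITY / (2.0 * np.pi * 3000.0 / 60.0) ** 2

#: Default maximum rotor speed (rpm) accepted by :func:`design_ramp`.
DEFAULT_RPM_CEILING = 3000.0

_UM_TO_M = 1e-6
_G_PER_ML_TO_KG_PER_M3 = 1e3
_N_TO_PN = 1e12


@dataclass(frozen=True)
class CellParams:
    """Physical cell properties that set the effective (buoyant) mass.

    Parameters
    ----------
    diameter_um
        Cell diameter in micrometers; the cell is modeled as a sphere.
    cell_density_g_ml
        Cell mass density in g/mL.
    medium_density_g_ml
        Density of the surrounding medium in g/mL.  Must be strictly below
        the cell density, otherwise the centrifugal force would not pull the
        cell off the surface and the assay geometry breaks down.
    """

    diameter_um: float = 10.0
    cell_density_g_ml: float = 1.07
    medium_density_g_ml: float = 1.00

    def __post_init__(self) -> None:
        if not self.diameter_um > 0:
            raise ValueError(f"diameter_um must be > 0, got {self.diameter_um}")
        if not self.cell_density_g_ml > self.medium_density_g_ml:
            raise ValueError(
                "cell density must exceed medium density for a positive "
                f"effective mass (got cell {self.cell_density_g_ml} g/mL "
                f"<= medium {self.medium_density_g_ml} g/mL)"
            )


@dataclass(frozen=True)
class RampProtocol:
    """A stair-step rotor-speed schedule.

    ``steps`` is an ordered sequence of ``(start_time_s, rpm)`` pairs; each
    speed holds until the next step's start time.  ``end_time_s`` closes the
    final step (defaults to open-ended).
    """

    rotor_radius_m: float
    steps: tuple[tuple[float, float], ...]
    end_time_s: float | None = None
    nominal_loading_rate_pn_s: float | None = None

    def __post_init__(self) -> None:
        if not self.rotor_radius_m > 0:
            raise ValueError("rotor_radius_m must be > 0")
        if len(self.steps) == 0:
            raise ValueError("protocol needs at least one step")
        steps = tuple((float(t), float(r)) for t, r in self.steps)
        object.__setattr__(self, "steps", steps)
        times = np.array([t for t, _ in steps])
        rpms = np.array([r for _, r in steps])
        if np.any(np.diff(times) <= 0):
            raise ValueError("step start times must be strictly increasing")
        if np.any(rpms < 0):
            raise ValueError("rpm values must be >= 0")
        if self.end_time_s is not None and self.end_time_s <= times[-1]:
            raise ValueError("end_time_s must lie beyond the last step start")

    @property
    def start_time_s(self) -> float:
        return self.steps[0][0]

    @property
    def span_s(self) -> tuple[float, float]:
        end = np.inf if self.end_time_s is None else self.end_time_s
        return (self.steps[0][0], end)

    def rpm_at(self, times_s: np.ndarray) -> np.ndarray:
        """Piecewise-constant rpm lookup (vectorized)."""
        t = np.asarray(times_s, dtype=float)
        starts = np.array([s for s, _ in self.steps])
        rpms = np.array([r for _, r in self.steps])
        idx = np.searchsorted(starts, t, side="right") - 1
        if np.any(idx < 0):
            raise ValueError("sample time precedes first protocol step")
        lo, hi = self.span_s
        if np.any(t > hi):
            raise ValueError("sample time exceeds protocol end")
        return rpms[idx]


@dataclass(frozen=True)
class ForceTrace:
    """Aligned times (s) and per-cell forces (pN), piecewise constant."""

    times_s: np.ndarray
    forces_pn: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        f = np.asarray(self.forces_pn, dtype=float)
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError("times and forces must be aligned 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(f < 0):
            raise ValueError("forces must be >= 0")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "forces_pn", f)

    def force_at(self, times_s: np.ndarray) -> np.ndarray:
        """Piecewise-constant (previous-sample) force lookup."""
        t = np.asarray(times_s, dtype=float)
        idx = np.searchsorted(self.times_s, t, side="right") - 1
        if np.any(idx < 0):
            raise ValueError("query time precedes trace start")
        return self.forces_pn[np.clip(idx, 0, len(self.forces_pn) - 1)]


def effective_mass(cell: CellParams) -> float:
    """Buoyancy-corrected cell mass ``(pi/6) d^3 (rho_cell - rho_medium)`` in kg."""
    d = cell.diameter_um * _UM_TO_M
    drho = (cell.cell_density_g_ml - cell.medium_density_g_ml) * _G_PER_ML_TO_KG_PER_M3
    return (np.pi / 6.0) * d**3 * drho


def force_at_rpm(rpm: float, radius_m: float, cell: CellParams) -> float:
    """Centrifugal force (pN) on one cell at rotor speed ``rpm`` and radius ``radius_m``."""
    if rpm < 0:
        raise ValueError("rpm must be >= 0")
    if not radius_m > 0:
        raise ValueError("radius_m must be > 0")
    omega = 2.0 * np.pi * rpm / 60.0
    return effective_mass(cell) * radius_m * omega**2 * _N_TO_PN


def gravity_force(cell: CellParams) -> float:
    """Net pull (pN) on a cell hanging under 1 g in an inverted chamber."""
    return effective_mass(cell) * STANDARD_GRAVITY * _N_TO_PN


def _rpm_for_force(force_pn: float, radius_m: float, cell: CellParams) -> float:
    m = effective_mass(cell)
    omega = np.sqrt(force_pn / _N_TO_PN / (m * radius_m))
    return omega * 60.0 / (2.0 * np.pi)


def design_ramp(
    loading_rate_pn_s: float,
    f_start_pn: float = 0.0,
    f_max_pn: float = 480.0,
    step_duration_s: float = 1.0,
    radius_m: float = DEFAULT_ROTOR_RADIUS_M,
    cell: CellParams = CellParams(),
    rpm_ceiling: float = DEFAULT_RPM_CEILING,
    t_start_s: float = 0.0,
    hold_duration_s: float = 0.0,
) -> RampProtocol:
    """Design a stair-step rpm schedule realising a linear force ramp.

    Each step holds for ``step_duration_s``; its rpm is chosen so that the
    force at the step midpoint lies on the line
    ``f_start_pn + loading_rate_pn_s * (t - t_start_s)``.  The schedule ends
    when the line reaches ``f_max_pn``; a positive ``hold_duration_s`` keeps
    the rotor at the final speed for that long afterwards (recording
    typically continues at maximum speed until detachment has run its
    course).

    Raises
    ------
    ValueError
        If the target forces would require a rotor speed above
        ``rpm_ceiling``.
    """
    if not loading_rate_pn_s > 0:
        raise ValueError("loading_rate_pn_s must be > 0")
    if not (0 <= f_start_pn < f_max_pn):
        raise ValueError("need 0 <= f_start_pn < f_max_pn")
    if not step_duration_s > 0:
        raise ValueError("step_duration_s must be > 0")

    f_ceiling = force_at_rpm(rpm_ceiling, radius_m, cell)
    if f_max_pn > f_ceiling:
        raise ValueError(
            f"f_max_pn={f_max_pn:.1f} pN is unreachable: the {rpm_ceiling:.0f} rpm "
            f"ceiling at radius {radius_m:.4f} m caps the force at {f_ceiling:.1f} pN"
        )

    duration = (f_max_pn - f_start_pn) / loading_rate_pn_s
    n_steps = int(np.ceil(duration / step_duration_s))
    starts = t_start_s + step_duration_s * np.arange(n_steps)
    midpoints = starts - t_start_s + step_duration_s / 2.0
    targets = np.minimum(f_start_pn + loading_rate_pn_s * midpoints, f_max_pn)
    rpms = np.array([_rpm_for_force(f, radius_m, cell) for f in targets])
    steps = tuple(zip(starts.tolist(), rpms.tolist()))
    return RampProtocol(
        rotor_radius_m=radius_m,
        steps=steps,
        end_time_s=t_start_s + n_steps * step_duration_s + max(hold_duration_s, 0.0),
        nominal_loading_rate_pn_s=loading_rate_pn_s,
    )


def force_trace(
    protocol: RampProtocol,
    cell: CellParams,
    sample_times_s: Sequence[float] | np.ndarray,
) -> ForceTrace:
    """Evaluate the per-cell force at ``sample_times_s`` under ``protocol``."""
    t = np.asarray(sample_times_s, dtype=float)
    rpms = protocol.rpm_at(t)  # validates span
    m = effective_mass(cell)
    omega = 2.0 * np.pi * rpms / 60.0
    forces = m * protocol.rotor_radius_m * omega**2 * _N_TO_PN
    return ForceTrace(times_s=t, forces_pn=forces)
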