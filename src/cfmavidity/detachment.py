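"""Detachment curves and adhesion frequency from per-frame cell counts.

The assay produces one cell count per video frame.  Two derived quantities
drive the downstream kinetics:

* the *adhesion frequency* (AF) — the fraction of cells still attached at
  the end of the low-force gravity interval, relative to the count when the
  chamber was flipped; and
* the *detachment curve* — the fraction of cells remaining bound over time
  during the force ramp, normalized at the start of centrifugation.

Frame-to-frame counts jitter by a few cells because detection is imperfect,
so endpoint counts are taken as medians over a short window and curves are
median-filtered before normalization.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

__all__ = [
    "CurveOrigin",
    "CountTrace",
    "DetachmentCurve",
    "AdhesionResult",
    "adhesion_frequency",
    "build_detachment_curve",
    "average_curves",
    "flag_monolayer_qc",
]

#: Tolerated upward excursion of fraction_bound above 1 due to count jitter.
JITTER_EPSILON = 0.05

#: Default half-width (s) of the robust-count median window.
ROBUST_WINDOW_S = 2.0

#: Default gravity-interval duration (s): two minutes between chamber flip
#: and centrifuge activation.
GRAVITY_INTERVAL_S = 120.0

#: Default relative drop in monolayer counts that flags a trial for QC.
MONOLAYER_DROP_FRACTION = 0.20


class CurveOrigin(str, enum.Enum):
    """Time origin of a detachment curve."""

    FLIP = "flip"
    CENTRIFUGE_START = "centrifuge_start"


@dataclass(frozen=True)
class CountTrace:
    """Per-frame timestamped cell counts.

    ``target_counts`` is the channel being detached; ``monolayer_counts`` is
    an optional second channel used only for coverage QC.  ``rpm`` optionally
    records the rotor speed at each frame.
    """

    times_s: np.ndarray
    target_counts: np.ndarray
    monolayer_counts: np.ndarray | None = None
    rpm: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        c = np.asarray(self.target_counts)
        if t.ndim != 1 or t.shape != c.shape:
            raise ValueError("times and target_counts must be aligned 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("counts must be >= 0")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "target_counts", np.asarray(c, dtype=float))
        for name in ("monolayer_counts", "rpm"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != t.shape:
                    raise ValueError(f"{name} must align with times")
                object.__setattr__(self, name, v)

    @property
    def span_s(self) -> tuple[float, float]:
        return (float(self.times_s[0]), float(self.times_s[-1]))

    def to_frame(self) -> pd.DataFrame:
        data = {"time_s": self.times_s, "target_count": self.target_counts}
        if self.rpm is not None:
            data["rpm"] = self.rpm
        if self.monolayer_counts is not None:
            data["monolayer_count"] = self.monolayer_counts
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountTrace":
        return cls(
            times_s=df["time_s"].to_numpy(),
            target_counts=df["target_count"].to_numpy(),
            monolayer_counts=df["monolayer_count"].to_numpy()
            if "monolayer_count" in df
            else None,
            rpm=df["rpm"].to_numpy() if "rpm" in df else None,
        )


@dataclass(frozen=True)
class DetachmentCurve:
    """Fraction of cells remaining bound vs time, re-zeroed at ``origin``."""

    times_s: np.ndarray
    fraction_bound: np.ndarray
    normalization_count: float
    origin: CurveOrigin

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        f = np.asarray(self.fraction_bound, dtype=float)
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError("times and fraction_bound must be aligned 1-D arrays")
        if np.any(f < 0) or np.any(f > 1 + JITTER_EPSILON):
            raise ValueError(
                f"fraction_bound must lie in [0, 1+{JITTER_EPSILON}] (count jitter bound)"
            )
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "fraction_bound", f)

    def value_at(self, time_s: float) -> float:
        """Linearly interpolated fraction bound at ``time_s``."""
        return float(np.interp(time_s, self.times_s, self.fraction_bound))


@dataclass(frozen=True)
class AdhesionResult:
    adhesion_frequency: float
    n_initial: float
    n_after_gravity: float
    gravity_interval_s: float


def _robust_count(trace: CountTrace, t_center: float, window_s: float) -> float:
    """Median target count over frames within ``t_center ± window_s``."""
    mask = np.abs(trace.times_s - t_center) <= window_s
    if not np.any(mask):
        # fall back to the nearest frame
        mask = np.zeros_like(trace.times_s, dtype=bool)
        mask[np.argmin(np.abs(trace.times_s - t_center))] = True
    return float(np.median(trace.target_counts[mask]))


def adhesion_frequency(
    trace: CountTrace,
    t_flip_s: float = 0.0,
    t_centrifuge_s: float = GRAVITY_INTERVAL_S,
    window_s: float = ROBUST_WINDOW_S,
) -> AdhesionResult:
    """Fraction of cells surviving the gravity interval.

    ``n_initial`` is the robust (median-window) count around the chamber
    flip; ``n_after_gravity`` the robust count just before the centrifuge
    starts.  Their ratio, clipped to [0, 1], is the adhesion frequency.
    """
    if not t_flip_s < t_centrifuge_s:
        raise ValueError("t_flip_s must precede t_centrifuge_s")
    lo, hi = trace.span_s
    if t_flip_s < lo - window_s or t_centrifuge_s > hi + window_s:
        raise ValueError("flip/centrifuge times fall outside the count trace")
    if t_flip_s + window_s >= t_centrifuge_s - window_s:
        raise ValueError("endpoint windows overlap; shrink window_s")

    n_initial = _robust_count(trace, t_flip_s, window_s)
    # window ending at centrifuge start, not straddling it
    n_after = _robust_count(trace, t_centrifuge_s - window_s, window_s)
    if n_initial <= 0:
        raise ValueError("no cells detected at the start of the trace")
    af = float(np.clip(n_after / n_initial, 0.0, 1.0))
    return AdhesionResult(
        adhesion_frequency=af,
        n_initial=n_initial,
        n_after_gravity=n_after,
        gravity_interval_s=t_centrifuge_s - t_flip_s,
    )


def build_detachment_curve(
    trace: CountTrace,
    origin: CurveOrigin = CurveOrigin.CENTRIFUGE_START,
    t_origin_s: float = GRAVITY_INTERVAL_S,
    smoothing_window: int = 5,
) -> DetachmentCurve:
    """Normalize counts into a fraction-bound curve starting at ``t_origin_s``.

    Counts are median-filtered with an odd ``smoothing_window`` (frames) to
    suppress detection jitter, then divided by the filtered count at the
    origin frame, so the curve starts at exactly 1.
    """
    lo, hi = trace.span_s
    if not (lo <= t_origin_s <= hi):
        raise ValueError("t_origin_s outside trace span")
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be a positive odd number of frames")

    filtered = median_filter(trace.target_counts, size=smoothing_window, mode="nearest")
    i0 = int(np.searchsorted(trace.times_s, t_origin_s, side="left"))
    i0 = min(i0, len(filtered) - 1)
    norm = float(filtered[i0])
    if norm <= 0:
        raise ValueError("zero cells at the normalization origin")
    frac = np.clip(filtered[i0:] / norm, 0.0, 1.0 + JITTER_EPSILON)
    return DetachmentCurve(
        times_s=trace.times_s[i0:] - trace.times_s[i0],
        fraction_bound=frac,
        normalization_count=norm,
        origin=origin,
    )


def average_curves(
    curves: list[DetachmentCurve], grid_s: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and sample SD of curves interpolated onto ``grid_s``."""
    if len(curves) < 2:
        raise ValueError("need at least two curves to average")
    grid = np.asarray(grid_s, dtype=float)
    lo = max(c.times_s[0] for c in curves)
    hi = min(c.times_s[-1] for c in curves)
    if lo >= hi:
        raise ValueError("curves have no overlapping time span")
    if grid[0] < lo or grid[-1] > hi:
        raise ValueError(f"grid must lie inside the common span [{lo:.2f}, {hi:.2f}] s")
    stack = np.vstack([np.interp(grid, c.times_s, c.fraction_bound) for c in curves])
    return stack.mean(axis=0), stack.std(axis=0, ddof=1)


def flag_monolayer_qc(
    trace: CountTrace, drop_fraction: float = MONOLAYER_DROP_FRACTION
) -> bool:
    """True when monolayer coverage dropped by more than ``drop_fraction``.

    Flags (never drops) a trial whose QC channel lost coverage, e.g. from a
    bubble crossing the field of view.  Returns False when no monolayer
    channel was recorded.
    """
    if trace.monolayer_counts is None:
        return False
    start = float(np.median(trace.monolayer_counts[: max(3, len(trace.times_s) // 20)]))
    if start <= 0:
        return False
    low = float(np.min(trace.monolayer_counts))
    return (start - low) / start > drop_fraction
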