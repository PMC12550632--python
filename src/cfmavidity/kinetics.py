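"""Kinetic models linking adhesion frequency, lifetime, and off-rate.

Three pieces of model fitting live here.

**Stretched-exponential survival.**  Under a linear force ramp the fraction
of cells remaining bound is well described by

    f(t) = 1 - g + g * exp(-(t / tau)**beta)

where ``g`` is the detachable fraction, ``tau`` the population lifetime and
``beta`` a stretching exponent that absorbs the force-driven acceleration
of the off-rate over time.

**Poisson bond-number universal curve.**  If each cell forms a Poisson(lam)
number of bonds, the adhesion frequency is the probability of at least one
bond, AF(lam) = 1 - exp(-lam), and — for independent bonds loaded in
parallel — the population lifetime grows roughly linearly with the bond
number, tau(lam) = k*lam + x0.  Sweeping lam traces a single parametric
curve in the (AF, tau) plane; fitting (k, x0) across trials collapses data
taken at many surface densities onto it.  ``k`` (seconds per unit lam)
measures per-bond strength under the given ramp.

**Off-rate vs force.**  A binned hazard estimate: cells detached in a force
bin, divided by cells available at the bin start and by the bin's duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lmfit import Model
from scipy.optimize import minimize_scalar

from .detachment import DetachmentCurve
from .force import ForceTrace

__all__ = [
    "StretchedExpFit",
    "TrialPoint",
    "UniversalCurveFit",
    "OffRateSeries",
    "stretched_exponential",
    "af_from_lambda",
    "lambda_from_af",
    "fit_stretched_exponential",
    "fit_universal_curve",
    "off_rate_vs_force",
]

#: Adhesion frequencies are capped just below 1 before inverting the Poisson
#: relation; AF = 1 would map to lam = infinity.
AF_CAP = 0.999

#: Default force-bin width (pN) for the off-rate estimator.
OFF_RATE_BIN_PN = 20.0

#: Bins with fewer available cells than this are masked (hazard estimates
#: from a handful of cells are dominated by shot noise).
OFF_RATE_FLOOR_CELLS = 5.0


@dataclass(frozen=True)
class StretchedExpFit:
    g: float
    tau_s: float
    beta: float
    rmse: float
    n_points: int
    converged: bool
    flags: tuple[str, ...] = ()

    def evaluate(self, t_s: np.ndarray) -> np.ndarray:
        return stretched_exponential(np.asarray(t_s, dtype=float), self.g, self.tau_s, self.beta)


@dataclass(frozen=True)
class TrialPoint:
    adhesion_frequency: float
    tau_s: float
    condition_label: str = ""
    n_cells: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.adhesion_frequency <= 1.0):
            raise ValueError("adhesion_frequency must lie in [0, 1]")
        if not self.tau_s > 0:
            raise ValueError("tau_s must be > 0")


@dataclass(frozen=True)
class UniversalCurveFit:
    k: float
    x0: float
    rmse: float
    n_trials: int
    flags: tuple[str, ...] = ()

    def tau_of_lambda(self, lam: np.ndarray) -> np.ndarray:
        return self.k * np.asarray(lam, dtype=float) + self.x0


@dataclass(frozen=True)
class OffRateSeries:
    force_bins_pn: np.ndarray
    off_rate_per_s: np.ndarray
    n_detached: np.ndarray
    n_available: np.ndarray
    dt_s: np.ndarray

    def valid(self) -> np.ndarray:
        """Mask of bins with enough cells for a meaningful hazard estimate."""
        return np.isfinite(self.off_rate_per_s)


def stretched_exponential(t_s: np.ndarray, g: float, tau_s: float, beta: float) -> np.ndarray:
    """Survival fraction ``1 - g + g*exp(-(t/tau)**beta)``; equals 1 at t=0."""
    t = np.asarray(t_s, dtype=float)
    return 1.0 - g + g * np.exp(-((t / tau_s) ** beta))


def af_from_lambda(lam) -> np.ndarray | float:
    """Adhesion frequency ``1 - exp(-lam)``: P(at least one bond) under Poisson(lam)."""
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr < 0):
        raise ValueError("lam must be >= 0")
    out = -np.expm1(-lam_arr)
    return float(out) if np.isscalar(lam) else out


def lambda_from_af(af, af_cap: float = AF_CAP) -> np.ndarray | float:
    """Invert AF = 1 - exp(-lam); AF is capped at ``af_cap`` to avoid divergence."""
    af_arr = np.asarray(af, dtype=float)
    if np.any((af_arr < 0) | (af_arr > 1)):
        raise ValueError("adhesion frequency must lie in [0, 1]")
    out = -np.log1p(-np.minimum(af_arr, af_cap))
    return float(out) if np.isscalar(af) else out


def fit_stretched_exponential(
    curve: DetachmentCurve,
    g_bounds: tuple[float, float] = (0.0, 1.0),
    beta_bounds: tuple[float, float] = (0.2, 5.0),
    tau_max_factor: float = 10.0,
) -> StretchedExpFit:
    """Least-squares fit of the stretched-exponential survival model.

    Initialization is deterministic and scale-aware: ``g`` starts at one
    minus the final fraction bound, ``tau`` at the time of half decay (of
    the detachable part), and ``beta`` at 1 (plain exponential).  ``tau`` is
    bounded by ``tau_max_factor`` times the curve span so a flat curve
    cannot drive it to infinity.
    """
    t = curve.times_s
    f = curve.fraction_bound
    if len(t) < 10:
        raise ValueError("need at least 10 points spanning the decay")
    span = float(t[-1] - t[0])
    if span <= 0:
        raise ValueError("degenerate time span")

    flags: list[str] = []
    f_end = float(np.mean(f[-max(3, len(f) // 20):]))
    # start strictly inside the bounds: trust-region bound handling loses
    # its gradient for a parameter initialized exactly on a bound
    g0 = float(np.clip(1.0 - f_end, 1e-3, 0.999))
    half_level = 1.0 - g0 / 2.0
    below = np.nonzero(f <= half_level)[0]
    tau0 = float(t[below[0]]) if len(below) else span / 2.0
    tau0 = float(np.clip(tau0, span * 1e-3, span * tau_max_factor))

    model = Model(stretched_exponential, independent_vars=["t_s"])
    params = model.make_params(g=g0, tau_s=tau0, beta=1.0)
    params["g"].set(min=g_bounds[0], max=g_bounds[1])
    params["tau_s"].set(min=span * 1e-4, max=span * tau_max_factor)
    params["beta"].set(min=beta_bounds[0], max=beta_bounds[1])

    result = model.fit(f, params, t_s=t, method="least_squares")
    g = float(result.params["g"].value)
    tau = float(result.params["tau_s"].value)
    beta = float(result.params["beta"].value)
    rmse = float(np.sqrt(np.mean(result.residual**2)))
    if not result.success:
        flags.append("non_convergence")
    if g <= g_bounds[0] + 1e-2:
        # effectively flat curve: the detachable fraction collapsed onto
        # its lower bound, so tau and beta are not interpretable
        flags.append("g_at_lower_bound")
    return StretchedExpFit(
        g=g, tau_s=tau, beta=beta, rmse=rmse, n_points=len(t),
        converged=bool(result.success), flags=tuple(flags),
    )


def _ols_universal(lam: np.ndarray, tau: np.ndarray) -> tuple[float, float]:
    k, x0 = np.polyfit(lam, tau, 1)
    return float(k), float(x0)


def _orthogonal_universal(
    af: np.ndarray, tau: np.ndarray, tau_scale: float, k0: float, x00: float
) -> tuple[float, float]:
    """Orthogonal-distance variant: minimize summed squared distance from each
    (AF, tau/sd) point to the parametric curve (AF(lam), (k*lam+x0)/sd)."""
    from scipy.optimize import minimize

    def point_dist2(k: float, x0: float, a: float, tval: float) -> float:
        def d2(lam: float) -> float:
            lam = max(lam, 0.0)
            da = a - (1.0 - np.exp(-lam))
            dt = (tval - (k * lam + x0)) / tau_scale
            return da * da + dt * dt

        res = minimize_scalar(d2, bounds=(0.0, 20.0), method="bounded")
        return float(res.fun)

    def objective(theta: np.ndarray) -> float:
        k, x0 = theta
        return sum(point_dist2(k, x0, a, tv) for a, tv in zip(af, tau))

    res = minimize(objective, x0=np.array([k0, x00]), method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-10})
    return float(res.x[0]), float(res.x[1])


def fit_universal_curve(
    points: list[TrialPoint],
    method: str = "ols",
    af_cap: float = AF_CAP,
    weight_by_cells: bool = False,
) -> UniversalCurveFit:
    """Fit ``tau = k*lam + x0`` across trials, with ``lam`` from each trial's AF.

    The default ("ols") maps each adhesion frequency to its bond-number mean
    through the exact inverse of AF(lam) and then fits tau on lam by
    (optionally cell-weighted) least squares, which is linear and has a
    closed-form solution.  ``method="orthogonal"`` instead minimizes
    orthogonal distances in the (AF, tau) plane (tau scaled by its sample
    SD) as a sensitivity check.

    The reported ``rmse`` is the root-mean-square residual of tau around the
    fitted line, scaled by the sample SD of tau — a dimensionless misfit in
    the same plane the curve is plotted in.
    """
    if len(points) < 5:
        raise ValueError("need at least 5 trials for an identifiable universal curve")
    af = np.array([p.adhesion_frequency for p in points])
    tau = np.array([p.tau_s for p in points])
    if np.ptp(af) == 0:
        raise ValueError("all adhesion frequencies identical: lam is not identifiable")

    flags: list[str] = []
    if np.any(af > af_cap):
        flags.append("af_capped")
    lam = np.asarray(lambda_from_af(af, af_cap=af_cap))
    tau_scale = float(np.std(tau, ddof=1))
    if tau_scale == 0:
        tau_scale = 1.0

    if method == "ols":
        if weight_by_cells:
            w = np.sqrt(np.array([max(p.n_cells, 1) for p in points], dtype=float))
            k, x0 = np.polyfit(lam, tau, 1, w=w)
            k, x0 = float(k), float(x0)
        else:
            k, x0 = _ols_universal(lam, tau)
    elif method == "orthogonal":
        k0, x00 = _ols_universal(lam, tau)
        k, x0 = _orthogonal_universal(af, tau, tau_scale, k0, x00)
    else:
        raise ValueError(f"unknown method {method!r}")

    resid = (tau - (k * lam + x0)) / tau_scale
    rmse = float(np.sqrt(np.mean(resid**2)))
    return UniversalCurveFit(k=k, x0=x0, rmse=rmse, n_trials=len(points), flags=tuple(flags))


def off_rate_vs_force(
    curve: DetachmentCurve,
    force: ForceTrace,
    bin_width_pn: float = OFF_RATE_BIN_PN,
    floor_cells: float = OFF_RATE_FLOOR_CELLS,
) -> OffRateSeries:
    """Binned off-rate estimate: detachments per available cell per second.

    ``curve`` and ``force`` must share a time base (force sampled at least
    over the curve's span).  For each force bin the estimator computes
    ``delta_N / (N_available_at_bin_start * delta_t)``; bins entered with
    fewer than ``floor_cells`` available cells get NaN.
    """
    if not bin_width_pn > 0:
        raise ValueError("bin_width_pn must be > 0")
    if force.times_s[0] > curve.times_s[0] or force.times_s[-1] < curve.times_s[-1] * (1 - 1e-9):
        raise ValueError("force trace does not cover the curve's time base")

    f_at = force.force_at(curve.times_s)
    n = curve.fraction_bound * curve.normalization_count
    edges = np.arange(0.0, f_at.max() + bin_width_pn, bin_width_pn)
    centers, rates, detached, avail, dts = [], [], [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = np.nonzero((f_at >= lo) & (f_at < hi))[0]
        if len(in_bin) < 2:
            continue
        i0, i1 = in_bin[0], in_bin[-1]
        dt = float(curve.times_s[i1] - curve.times_s[i0])
        if dt <= 0:
            continue
        n_avail = float(n[i0])
        dn = float(max(n[i0] - n[i1], 0.0))
        centers.append((lo + hi) / 2.0)
        detached.append(dn)
        avail.append(n_avail)
        dts.append(dt)
        rates.append(dn / (n_avail * dt) if n_avail >= floor_cells else np.nan)
    return OffRateSeries(
        force_bins_pn=np.array(centers),
        off_rate_per_s=np.array(rates),
        n_detached=np.array(detached),
        n_available=np.array(avail),
        dt_s=np.array(dts),
    )
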