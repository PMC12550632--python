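"""End-to-end orchestration: simulate or load trials, fit, and report.

A run takes a validated :class:`RunConfig`, executes the stages in assay
order (counts -> adhesion frequency -> detachment curve -> stretched
exponential fit -> cross-trial universal curve), and produces a
:class:`RunReport` whose every number is traceable to the configuration and
seeds that generated it.  Per-trial failures are recorded and skipped; the
run fails only if no trial succeeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .detachment import (
    CountTrace,
    CurveOrigin,
    adhesion_frequency,
    build_detachment_curve,
    flag_monolayer_qc,
)
from .force import CellParams, RampProtocol, design_ramp
from .kinetics import (
    StretchedExpFit,
    TrialPoint,
    UniversalCurveFit,
    fit_stretched_exponential,
    fit_universal_curve,
)
from .simulate import BondModel, simulate_trial

log = logging.getLogger("cfmavidity")

__all__ = [
    "RunConfig",
    "TrialResult",
    "RunReport",
    "run_pipeline",
    "summarize_conditions",
    "recover_universal_slope",
]

_CONFIG_KEYS = {
    "cell",
    "ramp",
    "trials",
    "analysis",
    "seed",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for one pipeline run.

    ``trials`` entries are either simulation requests
    (``{"lam": 1.0, "n_cells": 1000, "condition": "..."}``) or input files
    (``{"counts_csv": "path", "condition": "..."}``).
    """

    cell: CellParams = CellParams()
    loading_rate_pn_s: float = 4.0
    f_max_pn: float = 480.0
    hold_s: float = 240.0
    gravity_interval_s: float = 120.0
    trials: tuple[dict, ...] = ()
    bond_model: BondModel = BondModel()
    seed: int = 0
    smoothing_window: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cell = CellParams(**raw.get("cell", {}))
        ramp = raw.get("ramp", {})
        analysis = raw.get("analysis", {})
        bond = BondModel(**analysis.pop("bond_model", {})) if "bond_model" in analysis else BondModel()
        return cls(
            cell=cell,
            loading_rate_pn_s=ramp.get("loading_rate_pn_s", 4.0),
            f_max_pn=ramp.get("f_max_pn", 480.0),
            hold_s=ramp.get("hold_s", 240.0),
            gravity_interval_s=ramp.get("gravity_interval_s", 120.0),
            trials=tuple(raw.get("trials", [])),
            bond_model=bond,
            seed=int(raw.get("seed", 0)),
            smoothing_window=int(analysis.get("smoothing_window", 5)),
        )

    def config_hash(self) -> str:
        payload = json.dumps(_to_jsonable(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class TrialResult:
    condition: str
    seed: int
    adhesion_frequency: float
    n_initial: float
    fit: StretchedExpFit | None
    flags: tuple[str, ...] = ()
    error: str | None = None


@dataclass(frozen=True)
class RunReport:
    trials: tuple[TrialResult, ...]
    universal: UniversalCurveFit | None
    flags: tuple[str, ...]
    config_hash: str
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(_to_jsonable(self), indent=2, default=str)

    def trial_table(self) -> pd.DataFrame:
        rows = [
            {
                "condition": t.condition,
                "seed": t.seed,
                "adhesion_frequency": t.adhesion_frequency,
                "n_initial": t.n_initial,
                "g": t.fit.g if t.fit else np.nan,
                "tau_s": t.fit.tau_s if t.fit else np.nan,
                "beta": t.fit.beta if t.fit else np.nan,
                "rmse": t.fit.rmse if t.fit else np.nan,
                "flags": ";".join(t.flags),
                "error": t.error or "",
            }
            for t in self.trials
        ]
        return pd.DataFrame(rows)


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def _analyze_trace(
    trace: CountTrace, t_spin_s: float, smoothing_window: int
) -> tuple[float, float, StretchedExpFit, tuple[str, ...]]:
    flags: list[str] = []
    if flag_monolayer_qc(trace):
        flags.append("monolayer_qc")
    af = adhesion_frequency(trace, t_centrifuge_s=t_spin_s)
    curve = build_detachment_curve(
        trace,
        origin=CurveOrigin.CENTRIFUGE_START,
        t_origin_s=t_spin_s,
        smoothing_window=smoothing_window,
    )
    fit = fit_stretched_exponential(curve)
    flags.extend(fit.flags)
    return af.adhesion_frequency, af.n_initial, fit, tuple(flags)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every configured trial and fit the cross-trial universal curve."""
    if not config.trials:
        raise ValueError("config lists no trials")
    protocol = design_ramp(
        loading_rate_pn_s=config.loading_rate_pn_s,
        f_max_pn=config.f_max_pn,
        cell=config.cell,
        t_start_s=config.gravity_interval_s,
        hold_duration_s=config.hold_s,
    )
    results: list[TrialResult] = []
    run_flags: list[str] = []
    for i, spec in enumerate(config.trials):
        condition = str(spec.get("condition", f"trial{i}"))
        trial_seed = int(spec.get("seed", config.seed + i))
        try:
            if "counts_csv" in spec:
                trace = CountTrace.from_frame(pd.read_csv(spec["counts_csv"]))
            else:
                model = replace(config.bond_model, lam=float(spec["lam"]))
                trial = simulate_trial(
                    model,
                    protocol,
                    cell=config.cell,
                    n_cells=int(spec.get("n_cells", 1000)),
                    seed=trial_seed,
                )
                trace = trial.count_trace
            af, n0, fit, flags = _analyze_trace(
                trace, config.gravity_interval_s, config.smoothing_window
            )
            log.info("trial %s: AF=%.3f tau=%.1fs n0=%.0f flags=%s",
                     condition, af, fit.tau_s, n0, flags)
            results.append(
                TrialResult(condition, trial_seed, af, n0, fit, flags)
            )
        except Exception as exc:  # recorded, run continues
            log.warning("trial %s failed: %s", condition, exc)
            results.append(
                TrialResult(condition, trial_seed, np.nan, np.nan, None,
                            ("failed",), error=str(exc))
            )
    ok = [t for t in results if t.error is None]
    if not ok:
        raise RuntimeError("no trial succeeded; see per-trial errors in the report")

    universal = None
    if len(ok) >= 5:
        points = [
            TrialPoint(t.adhesion_frequency, t.fit.tau_s, t.condition, int(t.n_initial))
            for t in ok
        ]
        try:
            universal = fit_universal_curve(points)
        except ValueError as exc:
            run_flags.append(f"universal_fit_failed: {exc}")
    else:
        run_flags.append("universal_underdetermined_lt_5_trials")

    return RunReport(
        trials=tuple(results),
        universal=universal,
        flags=tuple(run_flags),
        config_hash=config.config_hash(),
    )


def summarize_conditions(reports: list[RunReport], by: str = "condition") -> pd.DataFrame:
    """Per-condition mean and SD of adhesion frequency and lifetime."""
    frames = [r.trial_table() for r in reports]
    if not frames:
        raise ValueError("no reports to summarize")
    df = pd.concat(frames, ignore_index=True)
    df = df[df["error"] == ""]
    if df.empty:
        raise ValueError("no successful trials to summarize")
    if by not in df.columns:
        raise ValueError(f"unknown grouping column {by!r}")
    out = (
        df.groupby(by)
        .agg(
            n_trials=("adhesion_frequency", "size"),
            af_mean=("adhesion_frequency", "mean"),
            af_sd=("adhesion_frequency", "std"),
            tau_mean=("tau_s", "mean"),
            tau_sd=("tau_s", "std"),
        )
        .reset_index()
    )
    return out


def recover_universal_slope(
    model: BondModel,
    protocol: RampProtocol,
    cell: CellParams = CellParams(),
    n_trials: int = 30,
    lam_range: tuple[float, float] = (0.2, 5.0),
    n_cells: int = 1000,
    seed: int = 0,
) -> UniversalCurveFit:
    """Simulate ``n_trials`` across a bond-number sweep and fit the universal curve.

    This is the parameter-recovery harness: trials draw ``lam`` evenly across
    ``lam_range``, each is pushed through the full measurement pipeline
    (per-frame counts, adhesion frequency, detachment curve, stretched
    exponential), and the cross-trial ``tau = k*lam + x0`` fit is returned.
    """
    lams = np.linspace(lam_range[0], lam_range[1], n_trials)
    trials = tuple(
        {"lam": float(l), "n_cells": n_cells, "condition": f"lam={l:.2f}", "seed": seed + i}
        for i, l in enumerate(lams)
    )
    cfg = RunConfig(cell=cell, trials=trials, bond_model=model, seed=seed)
    report = run_pipeline(cfg)
    if report.universal is None:
        raise RuntimeError(f"universal fit unavailable: {report.flags}")
    return report.universal
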