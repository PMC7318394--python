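"""End-to-end pipeline: ingest or simulate, compute curves and fits, report.

``run_pipeline`` executes ingestion → Time-Gain → pharmaco-economic indices
in order and collects everything into a :class:`PisaReport`, a flat record of
one trial mirroring a per-trial results column: observed values at the
report horizons and at the end of study, the f50% quadratic fit with its R²
inside and outside the fit window, power fits of both indices with
fixed-horizon estimates, and threshold-crossing times.  Every derived value
carries a ``source`` flag (observed / fitted / extrapolated) and rejected
fits (R² below the acceptance cut) suppress extrapolation.

``render_report`` serializes a report deterministically: ``text`` (rounded,
human-readable), ``delimited`` (CSV, full precision) or ``structured``
(JSON, full precision).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import km as _km
from . import pharmaco as ph
from . import timegain as tg
from .errors import ConfigError, PisaError
from .km import FollowUpProfile, TrialDataset, compute_t50
from .synthetic import SyntheticTrialSpec, generate_trial

__all__ = ["RunConfig", "PisaReport", "run_pipeline", "render_report", "write_outputs"]

log = logging.getLogger(__name__)

DEFAULT_HORIZONS = (24.0, 72.0)
DEFAULT_MOT_LEVELS = (1000.0,)
DEFAULT_NNT_LEVELS = (200.0, 50.0)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed for one pipeline run.

    Exactly one of (control_path & active_path) or ``synthetic`` must be set.
    """

    control_path: str | None = None
    active_path: str | None = None
    at_risk_path: str | None = None
    synthetic: SyntheticTrialSpec | None = None
    duration_T: float | None = None
    t50_override: float | None = None
    grid_step: float = _km.GRID_STEP
    horizons: tuple[float, ...] = DEFAULT_HORIZONS
    mot_levels: tuple[float, ...] = DEFAULT_MOT_LEVELS
    nnt_levels: tuple[float, ...] = DEFAULT_NNT_LEVELS
    trial_label: str = ""
    outcome_label: str = ""

    def __post_init__(self) -> None:
        have_files = self.control_path is not None and self.active_path is not None
        if have_files == (self.synthetic is not None):
            raise ConfigError(
                "exactly one input source required: control/active files OR a synthetic spec"
            )
        if any(h <= 0 for h in self.horizons):
            raise ConfigError("report horizons must be positive")


def _flagged(value: float | None, source: str, **extra: Any) -> dict[str, Any] | None:
    if value is None or not np.isfinite(value):
        return None
    return {"value": float(value), "source": source, **extra}


@dataclass
class PisaReport:
    """Structured per-trial results record."""

    trial_label: str
    outcome_label: str
    duration_T: float
    t50: float
    n_total: int | None
    timegain: dict[str, Any] = field(default_factory=dict)
    mot: dict[str, Any] = field(default_factory=dict)
    nnt: dict[str, Any] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "trial_label": self.trial_label,
            "outcome_label": self.outcome_label,
            "duration_T": self.duration_T,
            "t50": self.t50,
            "n_total": self.n_total,
            "timegain": self.timegain,
            "mot": self.mot,
            "nnt": self.nnt,
            "warnings": self.warnings,
        }


def _ingest(config: RunConfig) -> TrialDataset:
    if config.synthetic is not None:
        return generate_trial(config.synthetic)
    arms = {}
    for role, path in (("control", config.control_path), ("active", config.active_path)):
        curves = _km.read_km_table(path, arm_label=role)
        if len(curves) != 1:
            raise ConfigError(f"{role} file must hold exactly one arm, found {len(curves)}")
        arms[role] = _km.clean_raw_curve(next(iter(curves.values())))
    duration = config.duration_T
    if duration is None:
        last = min(arms["control"].times[-1], arms["active"].times[-1])
        duration = np.floor(last / config.grid_step) * config.grid_step
    grids = {
        role: _km.regularize_grid(raw, config.grid_step, duration)
        for role, raw in arms.items()
    }
    profile = None
    if config.at_risk_path is not None:
        frame = pd.read_csv(config.at_risk_path)
        if not {"time", "at_risk"}.issubset(frame.columns):
            raise ConfigError("at-risk file needs columns: time, at_risk")
        vals = frame["at_risk"].to_numpy(dtype=float)
        if vals.max() > 1.5:  # counts, not fractions
            profile = FollowUpProfile.from_counts(frame["time"].to_numpy(float), vals)
        else:
            profile = FollowUpProfile(frame["time"].to_numpy(float), vals)
    t50 = (
        config.t50_override
        if config.t50_override is not None
        else compute_t50(profile, duration, mode="step" if profile is not None else "linear")
    )
    return TrialDataset(
        control=grids["control"],
        active=grids["active"],
        duration_T=float(duration),
        t50=float(t50),
        trial_label=config.trial_label,
        outcome_label=config.outcome_label,
        follow_up=profile,
    )


def _index_at(curve: ph.IndexCurve, t: float) -> float | None:
    """Observed index value at t (interpolated over the defined region)."""
    ok = np.isfinite(curve.values)
    if t > curve.times[-1] + 1e-9 or not ok.any():
        return None
    val = float(np.interp(t, curve.times[ok], curve.values[ok]))
    # refuse extrapolation outside the defined region
    if t < curve.times[ok][0] - 1e-9:
        return None
    return val


def _power_section(
    index_fitted: ph.IndexCurve,
    index_observed: ph.IndexCurve,
    config: RunConfig,
    duration_T: float,
    levels: tuple[float, ...],
    quad_accepted: bool,
) -> dict[str, Any]:
    sec: dict[str, Any] = {
        "observed": {
            f"@{h:g}m": _flagged(_index_at(index_observed, h), "observed")
            for h in config.horizons
            if h <= duration_T + 1e-9
        }
    }
    sec["observed"]["@T"] = _flagged(_index_at(index_observed, duration_T), "observed")
    if not quad_accepted:
        sec["fit"] = None
        sec["estimated"] = None
        sec["crossings"] = None
        return sec
    try:
        fit = ph.fit_power(index_fitted)
    except PisaError as exc:
        sec["fit"] = None
        sec["estimated"] = None
        sec["crossings"] = None
        sec["fit_error"] = str(exc)
        return sec
    sec["fit"] = {
        "coef": fit.coef,
        "expo": fit.expo,
        "window": list(fit.window),
        "r_squared": fit.r_squared,
    }
    horizon = max(config.horizons)
    sec["estimated"] = {
        f"@{h:g}m": _flagged(
            ph.eval_power(fit, h),
            "fitted" if fit.window[0] <= h <= fit.window[1] else "extrapolated",
        )
        for h in config.horizons
    }
    crossings: dict[str, Any] = {}
    for level in levels:
        t_cross = ph.threshold_crossing_time(fit, level)
        crossings[f"level_{level:g}"] = {
            "time": t_cross,
            "time_reported": ph.round_up_to(t_cross, 0.1),
            "beyond_horizon": bool(t_cross > horizon),
        }
    sec["crossings"] = crossings
    return sec


def run_pipeline(config: RunConfig) -> PisaReport:
    """Execute the full pipeline and return the per-trial report."""
    try:
        dataset = _ingest(config)
    except PisaError as exc:
        raise type(exc)(f"[ingest] {exc}") from exc

    report = PisaReport(
        trial_label=dataset.trial_label or config.trial_label,
        outcome_label=dataset.outcome_label or config.outcome_label,
        duration_T=dataset.duration_T,
        t50=dataset.t50,
        n_total=dataset.n_total,
    )

    lost_c = tg.time_lost(dataset.control)
    lost_a = tg.time_lost(dataset.active)
    gain = tg.time_gain(lost_c, lost_a)
    if gain.values[-1] <= 0:
        report.warnings.append(
            "active arm shows no net benefit at end of study (Time-Gain@T <= 0); "
            "pharmaco-economic indices are masked where gain <= 0"
        )

    quad = tg.fit_timegain_quadratic(gain, dataset.t50)
    r2_full = tg.r_squared_vs_observed(quad, gain, dataset.duration_T)
    if not quad.accepted:
        report.warnings.append(
            f"quadratic f50% fit rejected (R^2={quad.r_squared:.4f} <= {tg.R2_ACCEPT}); "
            "no extrapolation or power fits reported"
        )
    log.info(
        "quadratic fit window [0, %g] months: a2=%g a1=%g R2=%.4f accepted=%s",
        dataset.t50, quad.a2, quad.a1, quad.r_squared, quad.accepted,
    )

    observed = {
        f"@{h:g}m": _flagged(tg.timegain_at(gain, h), "observed")
        for h in config.horizons
        if h <= dataset.duration_T + 1e-9
    }
    observed["@T"] = _flagged(tg.timegain_at(gain, dataset.duration_T), "observed")
    report.timegain = {
        "observed": observed,
        "fit": {
            "a2": quad.a2,
            "a1": quad.a1,
            "window": list(quad.window),
            "r_squared_window": quad.r_squared,
            "r_squared_full": r2_full,
            "accepted": quad.accepted,
        },
        "fitted": {
            f"@{h:g}m": _flagged(
                tg.eval_quadratic(quad, h),
                "fitted" if h <= dataset.t50 + 1e-9 else "extrapolated",
            )
            for h in config.horizons
        }
        if quad.accepted
        else None,
    }

    exposure = ph.months_of_treatment(dataset.active)
    fitted_gain = tg.fitted_gain_curve(quad, gain.times)
    mot_obs = ph.mot_per_year_gained(exposure, gain, "observed")
    nnt_obs = ph.nnt_per_year_gained(exposure, gain, "observed")
    mot_fit = ph.mot_per_year_gained(exposure, fitted_gain, "fitted")
    nnt_fit = ph.nnt_per_year_gained(exposure, fitted_gain, "fitted")
    report.mot = _power_section(
        mot_fit, mot_obs, config, dataset.duration_T, config.mot_levels, quad.accepted
    )
    report.nnt = _power_section(
        nnt_fit, nnt_obs, config, dataset.duration_T, config.nnt_levels, quad.accepted
    )
    # stash curves for optional persistence by callers
    report._curves = {  # type: ignore[attr-defined]
        "dataset": dataset,
        "time_lost_control": lost_c,
        "time_lost_active": lost_a,
        "time_gain": gain,
        "quad": quad,
        "exposure": exposure,
        "mot_observed": mot_obs,
        "nnt_observed": nnt_obs,
        "mot_fitted": mot_fit,
        "nnt_fitted": nnt_fit,
    }
    return report


# ---------------------------------------------------------------------------
# rendering


def _fmt_value(entry: dict[str, Any] | None, kind: str) -> str:
    if entry is None:
        return "n/a"
    v = entry["value"]
    if kind == "timegain":
        s = f"{v:.1f}"
    elif kind == "mot":
        s = f"{v:.0f}" if v >= 100 else f"{v:.1f}"
    else:  # nnt
        s = f"{v:.1f}"
    mark = {"observed": "", "fitted": "*", "extrapolated": "**"}[entry["source"]]
    return s + mark


def _flatten(prefix: str, obj: Any, rows: list[tuple[str, str, str]]) -> None:
    if isinstance(obj, dict):
        for k in sorted(obj):
            _flatten(f"{prefix}.{k}" if prefix else str(k), obj[k], rows)
    elif isinstance(obj, list):
        for i, item in enumerate(obj):
            _flatten(f"{prefix}[{i}]", item, rows)
    elif isinstance(obj, bool) or obj is None:
        rows.append((prefix, "flag", json.dumps(obj)))
    elif isinstance(obj, (int, float)):
        rows.append((prefix, "number", repr(float(obj)) if isinstance(obj, float) else str(obj)))
    else:
        rows.append((prefix, "text", str(obj)))


def render_report(report: PisaReport, fmt: str = "text") -> str:
    """Render a report deterministically as text, delimited CSV, or JSON."""
    d = report.to_dict()
    if fmt == "structured":
        return json.dumps(d, indent=2, sort_keys=True) + "\n"
    if fmt == "delimited":
        rows: list[tuple[str, str, str]] = []
        _flatten("", d, rows)
        lines = ["key,type,value"] + [f"{k},{t},{v}" for k, t, v in rows]
        return "\n".join(lines) + "\n"
    if fmt != "text":
        raise ConfigError(f"unknown report format {fmt!r}")

    L: list[str] = []
    L.append(f"Trial: {report.trial_label or '(unnamed)'}  Outcome: {report.outcome_label or '-'}")
    L.append(f"Duration/t50 (months): {report.duration_T:g}/{report.t50:g}")
    fit = d["timegain"]["fit"]
    L.append("Time-Gain (months per 100):")
    for key, entry in d["timegain"]["observed"].items():
        L.append(f"  observed {key:>6}: {_fmt_value(entry, 'timegain')}")
    L.append(
        f"  f50% fit: a2={fit['a2']:.4g} a1={fit['a1']:.4g} "
        f"R2[0-t50]={fit['r_squared_window']:.4f} R2[0-T]={fit['r_squared_full']:.4f} "
        f"accepted={fit['accepted']}"
    )
    if d["timegain"]["fitted"]:
        for key, entry in d["timegain"]["fitted"].items():
            L.append(f"  f50% {key:>9}: {_fmt_value(entry, 'timegain')}")
    for name, kind in (("mot", "mot"), ("nnt", "nnt")):
        label = "MoT/y+" if name == "mot" else "NNT/y+"
        sec = d[name]
        L.append(f"{label}:")
        for key, entry in sec["observed"].items():
            L.append(f"  observed {key:>6}: {_fmt_value(entry, kind)}")
        if sec.get("fit"):
            f = sec["fit"]
            L.append(
                f"  power fit: coef={f['coef']:.6g} expo={f['expo']:.4g} "
                f"R2={f['r_squared']:.4f} window=[{f['window'][0]:g}, {f['window'][1]:g}]"
            )
            for key, entry in sec["estimated"].items():
                L.append(f"  e{label} {key:>6}: {_fmt_value(entry, kind)}")
            for lev, cr in sec["crossings"].items():
                shown = (
                    f"> {max(DEFAULT_HORIZONS):g}"
                    if cr["beyond_horizon"]
                    else f"{cr['time_reported']:.1f}"
                )
                L.append(f"  {label} = {lev.split('_')[1]} reached after {shown} months")
        else:
            L.append("  power fit: n/a (quadratic fit rejected or window insufficient)")
    for w in report.warnings:
        L.append(f"WARNING: {w}")
    L.append("(* fitted within window, ** extrapolated)")
    return "\n".join(L) + "\n"


def write_outputs(report: PisaReport, outdir: str | Path) -> list[Path]:
    """Persist report (all three formats) and intermediate curves as CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for fmt, name in (("text", "report.txt"), ("delimited", "report.csv"), ("structured", "report.json")):
        p = outdir / name
        p.write_text(render_report(report, fmt))
        written.append(p)
    curves = getattr(report, "_curves", None)
    if curves:
        ds: TrialDataset = curves["dataset"]
        _km.write_grid_csv([ds.control, ds.active], outdir / "km_curves.csv")
        written.append(outdir / "km_curves.csv")
        gain = curves["time_gain"]
        quad = curves["quad"]
        frame = pd.DataFrame(
            {
                "time_months": gain.times,
                "time_gain_observed": gain.values,
                "time_gain_fitted": quad.predict(gain.times),
                "source": np.where(gain.times <= ds.t50 + 1e-9, "fitted", "extrapolated"),
                "mot": curves["exposure"].mot,
                "mot_per_year_observed": curves["mot_observed"].values,
                "nnt_per_year_observed": curves["nnt_observed"].values,
                "mot_per_year_fitted_gain": curves["mot_fitted"].values,
                "nnt_per_year_fitted_gain": curves["nnt_fitted"].values,
            }
        )
        p = outdir / "curves.csv"
        frame.to_csv(p, index=False)
        written.append(p)
    return written
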