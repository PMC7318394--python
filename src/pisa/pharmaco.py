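"""Treatment exposure (MoT) and the pharmaco-economic indices MoT/y+ and NNT/y+.

MoT (months of treatment) is the running integral of the active arm's
event-free percentage: total months on treatment accumulated by a 100-person
cohort.  Dividing MoT by the event-free *years* gained at the same time gives
MoT/y+ — months of cohort treatment per event-free year gained.  Replacing
MoT with the average number of patients on treatment (MoT divided by elapsed
time) gives NNT/y+ — patients who need to be treated to gain one event-free
year.  With both MoT and Time-Gain expressed per 100 baseline individuals the
per-100 normalization cancels in NNT/y+, so it counts actual patients.

Both indices are noisy while the gain denominator is small; once the gain
reaches 6 months per 100 they follow a power law ``a*t**b`` closely, which is
fitted by straight-line least squares on log-log values from that threshold
to the end of follow-up and used for fixed-horizon estimates and
threshold-crossing ("cost-efficacy level reached") times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import DomainError, GridError, InsufficientDataError, MonotonicityError
from .km import KMCurveGrid
from .timegain import TimeGainCurve, _check_shared, _check_uniform

__all__ = [
    "ExposureCurve",
    "IndexCurve",
    "PowerFit",
    "months_of_treatment",
    "mot_per_year_gained",
    "nnt_per_year_gained",
    "fit_power",
    "eval_power",
    "threshold_crossing_time",
    "round_up_to",
    "GAIN_THRESHOLD",
]

#: months of gain per 100 at which the index curves settle onto power
#: kinetics; start of the power-fit window
GAIN_THRESHOLD = 6.0

MIN_FIT_POINTS = 8


@dataclass(frozen=True)
class ExposureCurve:
    """Cumulative months of active treatment per 100 baseline individuals."""

    times: np.ndarray
    mot: np.ndarray


@dataclass(frozen=True)
class IndexCurve:
    """MoT/y+ or NNT/y+ sampled on the grid; NaN where the gain is <= 0.

    ``valid_from`` is the first time the gain reaches :data:`GAIN_THRESHOLD`
    (None if never) and marks the start of the power-fit window.
    """

    times: np.ndarray
    values: np.ndarray
    kind: str  # "MoT_per_year" | "NNT_per_year"
    valid_from: float | None
    gain_source: str = "observed"  # "observed" | "fitted"


@dataclass(frozen=True)
class PowerFit:
    """Power model ``coef * t**expo`` fitted on log-log scale over ``window``."""

    coef: float
    expo: float
    window: tuple[float, float]
    r_squared: float


def months_of_treatment(active: KMCurveGrid) -> ExposureCurve:
    """Running trapezoid integral of the event-free percentage (100 - incidence)."""
    _check_uniform(active.times)
    mot = cumulative_trapezoid(100.0 - active.incidence, active.times, initial=0.0)
    return ExposureCurve(active.times, mot)


def _valid_from(gain: TimeGainCurve) -> float | None:
    hit = np.flatnonzero(gain.values >= GAIN_THRESHOLD)
    return float(gain.times[hit[0]]) if hit.size else None


def mot_per_year_gained(
    exposure: ExposureCurve, gain: TimeGainCurve, gain_source: str = "observed"
) -> IndexCurve:
    """MoT/y+: months of cohort treatment per event-free year gained.

    Defined only where the gain is positive (a harmful or neutral treatment
    has no event-free year to buy); elsewhere NaN.
    """
    _check_shared(exposure.times, gain.times)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(gain.values > 0, exposure.mot / (gain.values / 12.0), np.nan)
    return IndexCurve(exposure.times, vals, "MoT_per_year", _valid_from(gain), gain_source)


def nnt_per_year_gained(
    exposure: ExposureCurve, gain: TimeGainCurve, gain_source: str = "observed"
) -> IndexCurve:
    """NNT/y+: patients on treatment per event-free year gained.

    The average number treated up to time t is MoT/t, so pointwise
    ``NNT/y+(t) * t == MoT/y+(t)`` wherever both are defined.  Undefined at
    t = 0.
    """
    _check_shared(exposure.times, gain.times)
    t = exposure.times
    with np.errstate(divide="ignore", invalid="ignore"):
        avg_treated = np.where(t > 0, exposure.mot / t, np.nan)
        vals = np.where(gain.values > 0, avg_treated / (gain.values / 12.0), np.nan)
    return IndexCurve(t, vals, "NNT_per_year", _valid_from(gain), gain_source)


def fit_power(index: IndexCurve) -> PowerFit:
    """Fit ``a*t**b`` on ``[valid_from, end]`` by log-log linear least squares.

    ``coef = exp(intercept)`` and ``expo = slope``; R² is reported on the
    log-log scale.
    """
    if index.valid_from is None:
        raise DomainError(
            "gain never reached the 6-month threshold; power fit is undefined"
        )
    mask = index.times >= index.valid_from - 1e-9
    t = index.times[mask]
    v = index.values[mask]
    if np.any(~np.isfinite(v)) or np.any(v <= 0):
        raise DomainError("non-positive or undefined index values inside the fit window")
    if t.size < MIN_FIT_POINTS:
        raise InsufficientDataError(
            f"power-fit window holds {t.size} points; need >= {MIN_FIT_POINTS}"
        )
    logt, logv = np.log(t), np.log(v)
    design = np.column_stack([logt, np.ones_like(logt)])
    (slope, intercept), *_ = np.linalg.lstsq(design, logv, rcond=None)
    resid = logv - design @ np.array([slope, intercept])
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((logv - logv.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PowerFit(float(np.exp(intercept)), float(slope), (float(t[0]), float(t[-1])), r2)


def eval_power(fit: PowerFit, t) -> float | np.ndarray:
    """Evaluate ``coef * t**expo``; t outside ``fit.window`` is extrapolation."""
    arr = np.asarray(t, dtype=float)
    if np.any(arr <= 0):
        raise DomainError("power model requires t > 0")
    out = fit.coef * arr**fit.expo
    return float(out) if np.isscalar(t) or arr.ndim == 0 else out


def threshold_crossing_time(fit: PowerFit, level: float) -> float:
    """Time at which a decreasing power index first attains ``level``.

    Unique solution of ``coef * t**expo == level``; requires ``expo < 0``.
    For reporting, round *up* to the displayed resolution (see
    :func:`round_up_to`): the level is only attained after the exact
    crossing.
    """
    if fit.expo >= 0:
        raise MonotonicityError("index is not decreasing (expo >= 0): no crossing")
    if level <= 0:
        raise DomainError("threshold level must be positive")
    return float((level / fit.coef) ** (1.0 / fit.expo))


def round_up_to(t: float, resolution: float = 0.1) -> float:
    """Smallest multiple of ``resolution`` at or above ``t``.

    Reporting convention for "reached after" times: with a decreasing index,
    the first displayed time at which the level has been attained is the
    crossing rounded up.  A tiny relative guard keeps exact multiples fixed.
    """
    scaled = t / resolution
    return round(math.ceil(scaled - 1e-9 * max(1.0, abs(scaled))) * resolution, 10)
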