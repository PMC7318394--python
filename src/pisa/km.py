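"""Ingestion and regularization of digitized Kaplan-Meier incidence curves.

A digitizer produces irregular ``(time, cumulative incidence)`` pairs per trial
arm.  This module cleans them (duplicate collapse, monotonicity repair),
resamples them onto the canonical regular grid (0.25-month step by default)
with linear interpolation, and determines the fit horizon ``t50`` — the time
at which half of the randomized cohort is still in follow-up, or half the
study duration when no numbers-at-risk information is available.

Incidence is kept on the percent scale (0–100), i.e. events per 100
individuals at baseline; input on the proportion scale is auto-detected
(maximum ≤ 1.5) and rescaled with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CoverageError,
    DegenerateCurveError,
    EmptyInputError,
    FormatError,
    GridError,
    ParseError,
)

__all__ = [
    "KMCurveRaw",
    "KMCurveGrid",
    "FollowUpProfile",
    "TrialDataset",
    "read_km_table",
    "clean_raw_curve",
    "regularize_grid",
    "compute_t50",
    "write_grid_csv",
    "GRID_STEP",
]

log = logging.getLogger(__name__)

#: canonical resampling step, in months
GRID_STEP = 0.25

#: default tolerance (percentage points) below the running maximum within
#: which a decreasing point is clipped up rather than removed
MAX_VIOLATION = 0.2

_TOL = 1e-9


@dataclass(frozen=True)
class KMCurveRaw:
    """Raw digitizer output for one arm: ordered (time, incidence %) pairs."""

    times: np.ndarray
    incidence: np.ndarray
    arm_label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.incidence, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise FormatError("times and incidence must be 1-D arrays of equal length")
        if t.size and t[0] < -_TOL:
            raise FormatError("negative time in raw curve")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "incidence", y)

    @property
    def n_points(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class KMCurveGrid:
    """Cumulative-incidence curve on a regular time grid.

    Invariants enforced: ``times[k] == k * grid_step``, incidence
    non-decreasing and within [0, 100].
    """

    grid_step: float
    times: np.ndarray
    incidence: np.ndarray
    arm_label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.incidence, dtype=float)
        if t.shape != y.shape or t.ndim != 1 or t.size < 2:
            raise GridError("grid curve needs two 1-D arrays with >= 2 points")
        expected = np.arange(t.size) * self.grid_step
        if not np.allclose(t, expected, atol=1e-6, rtol=0.0):
            raise GridError("times are not a regular grid starting at 0")
        if np.any(np.diff(y) < -1e-6):
            raise GridError("incidence must be non-decreasing (cumulative)")
        if y.min() < -1e-6 or y.max() > 100.0 + 1e-6:
            raise GridError("incidence outside [0, 100] percent")
        object.__setattr__(self, "times", expected)
        object.__setattr__(self, "incidence", np.clip(y, 0.0, 100.0))

    @property
    def duration(self) -> float:
        return float(self.times[-1])


@dataclass(frozen=True)
class FollowUpProfile:
    """Fraction of the baseline cohort still in follow-up over time."""

    times: np.ndarray
    fractions: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fractions, dtype=float)
        if t.shape != f.shape or t.ndim != 1 or t.size < 1:
            raise FormatError("profile needs matching 1-D time/fraction arrays")
        if np.any(np.diff(t) < 0):
            raise FormatError("profile times must be non-decreasing")
        if np.any(np.diff(f) > 1e-9):
            raise FormatError("at-risk fraction must be non-increasing")
        if f.max() > 1.0 + 1e-9 or f.min() < -1e-9:
            raise FormatError("at-risk fraction must lie in [0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fractions", f)

    @classmethod
    def from_counts(cls, times: Sequence[float], counts: Sequence[float]) -> "FollowUpProfile":
        counts = np.asarray(counts, dtype=float)
        if counts.size == 0 or counts[0] <= 0:
            raise FormatError("at-risk counts must start with a positive baseline count")
        return cls(np.asarray(times, dtype=float), counts / counts[0])


@dataclass(frozen=True)
class TrialDataset:
    """Paired control/active grid curves plus trial metadata."""

    control: KMCurveGrid
    active: KMCurveGrid
    duration_T: float
    t50: float
    n_total: int | None = None
    trial_label: str = ""
    outcome_label: str = ""
    follow_up: FollowUpProfile | None = None

    def __post_init__(self) -> None:
        if self.control.times.shape != self.active.times.shape or not np.allclose(
            self.control.times, self.active.times
        ):
            raise GridError("control and active arms must share one time grid")
        if not (0.0 < self.t50 <= self.duration_T + _TOL):
            raise FormatError("t50 must satisfy 0 < t50 <= duration_T")


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def _numeric_column(frame: pd.DataFrame, name: str) -> np.ndarray:
    raw = frame[name].astype(str).str.strip()
    vals = pd.to_numeric(raw, errors="coerce")
    bad = vals.isna() & (raw != "")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"non-numeric value {raw.iloc[row]!r} in column {name!r} at data row {row}"
        )
    if vals.isna().any():
        row = int(np.flatnonzero(vals.isna().to_numpy())[0])
        raise ParseError(f"empty cell in column {name!r} at data row {row}")
    return vals.to_numpy(dtype=float)


def read_km_table(
    path: str | Path,
    column_spec: Mapping[str, str] | None = None,
    arm_label: str | None = None,
) -> dict[str, KMCurveRaw]:
    """Read a delimited text file of digitized KM coordinates.

    Parameters
    ----------
    path
        CSV or TSV file (delimiter chosen from the extension) with a header.
    column_spec
        Maps the roles ``time``, ``incidence`` and optionally ``arm`` to
        column names.  Defaults to columns named ``time``, ``incidence`` and
        (if present) ``arm``.
    arm_label
        Label used when the file holds a single unlabeled arm; defaults to
        the file stem.

    Returns
    -------
    dict mapping arm label to :class:`KMCurveRaw`, rows sorted by time.
    """
    path = Path(path)
    spec = dict(column_spec or {})
    time_col = spec.get("time", "time")
    inc_col = spec.get("incidence", "incidence")
    frame = pd.read_csv(path, sep=_delimiter_for(path), dtype=str, keep_default_na=False)
    frame.columns = [c.strip() for c in frame.columns]
    for col in (time_col, inc_col):
        if col not in frame.columns:
            raise FormatError(f"required column {col!r} missing from {path.name}")
    arm_col = spec.get("arm", "arm" if "arm" in frame.columns else None)
    if arm_col is not None and arm_col not in frame.columns:
        raise FormatError(f"arm column {arm_col!r} missing from {path.name}")

    groups: list[tuple[str, pd.DataFrame]]
    if arm_col is None:
        groups = [(arm_label or path.stem, frame)]
    else:
        labels = frame[arm_col].astype(str).str.strip()
        groups = [(str(lab), sub) for lab, sub in frame.groupby(labels, sort=True)]
        if not groups:
            raise EmptyInputError(f"no arms found in {path.name}")

    out: dict[str, KMCurveRaw] = {}
    for label, sub in groups:
        if len(sub) == 0:
            raise EmptyInputError(f"arm {label!r} in {path.name} has no rows")
        times = _numeric_column(sub, time_col)
        inc = _numeric_column(sub, inc_col)
        order = np.argsort(times, kind="stable")
        times, inc = times[order], inc[order]
        if inc.size and 0.0 < inc.max() <= 1.5:
            log.warning(
                "arm %r: incidence looks like a proportion (max %.3g); rescaling to percent",
                label,
                inc.max(),
            )
            inc = inc * 100.0
        out[label] = KMCurveRaw(times, inc, arm_label=label)
    return out


def clean_raw_curve(raw: KMCurveRaw, max_violation: float = MAX_VIOLATION) -> KMCurveRaw:
    """Repair digitization artifacts so the curve is a valid cumulative incidence.

    Duplicate times are collapsed to their mean incidence.  Points that fall
    below the running maximum by more than ``max_violation`` percentage points
    are removed (gross digitizer misplacements); smaller dips are clipped up
    to the running maximum.  A ``(0, 0)`` origin is prepended when the first
    point is at a positive time.
    """
    if raw.n_points < 2:
        raise DegenerateCurveError("raw curve has fewer than 2 points")
    order = np.argsort(raw.times, kind="stable")
    t, y = raw.times[order], raw.incidence[order]
    # collapse exact duplicate times by averaging
    ut, inv = np.unique(t, return_inverse=True)
    if ut.size != t.size:
        sums = np.bincount(inv, weights=y)
        counts = np.bincount(inv)
        t, y = ut, sums / counts
    keep_t: list[float] = []
    keep_y: list[float] = []
    running = -np.inf
    n_removed = n_clipped = 0
    for ti, yi in zip(t, y):
        if yi < running - max_violation:
            n_removed += 1
            continue
        if yi < running:
            yi = running
            n_clipped += 1
        running = yi
        keep_t.append(float(ti))
        keep_y.append(float(yi))
    if len(keep_t) < 2:
        raise DegenerateCurveError("fewer than 2 points survive monotonicity repair")
    if keep_t[0] > _TOL:
        keep_t.insert(0, 0.0)
        keep_y.insert(0, 0.0)
    if n_removed or n_clipped:
        log.info(
            "arm %r: monotonicity repair removed %d and clipped %d points",
            raw.arm_label,
            n_removed,
            n_clipped,
        )
    cleaned = np.clip(np.asarray(keep_y), 0.0, 100.0)
    return KMCurveRaw(np.asarray(keep_t), cleaned, arm_label=raw.arm_label)


def regularize_grid(
    raw: KMCurveRaw,
    grid_step: float = GRID_STEP,
    duration_T: float | None = None,
) -> KMCurveGrid:
    """Resample a cleaned raw curve onto the regular grid by linear interpolation.

    The curve must cover ``[0, duration_T]``; extrapolation beyond the last
    digitized point is refused.  Monotonicity is re-enforced after
    interpolation (floating-point safety; interpolation of a monotone curve
    is already monotone).
    """
    if duration_T is None:
        duration_T = float(raw.times[-1])
    n = int(round(duration_T / grid_step))
    if abs(n * grid_step - duration_T) > 1e-6:
        raise GridError(
            f"duration_T={duration_T} is not a multiple of grid_step={grid_step}"
        )
    if raw.times[-1] < duration_T - 1e-6:
        raise CoverageError(
            f"raw curve for arm {raw.arm_label!r} ends at {raw.times[-1]:g} months, "
            f"before duration_T={duration_T:g}"
        )
    times = np.arange(n + 1) * grid_step
    inc = np.interp(times, raw.times, raw.incidence)
    inc = np.maximum.accumulate(np.clip(inc, 0.0, 100.0))
    return KMCurveGrid(grid_step, times, inc, arm_label=raw.arm_label)


def compute_t50(
    profile: FollowUpProfile | None,
    duration_T: float,
    mode: str = "linear",
) -> float:
    """Fit horizon: earliest time the in-follow-up fraction drops below one half.

    With no numbers-at-risk information the documented fallback is half the
    follow-up length.  ``mode='linear'`` interpolates between profile entries;
    ``mode='step'`` (numbers-at-risk tables, which are step functions) takes
    the first entry strictly below 50%.
    """
    if profile is None:
        return duration_T / 2.0
    f = profile.fractions
    t = profile.times
    below = np.flatnonzero(f < 0.5)
    if below.size == 0:
        return float(duration_T)
    i = int(below[0])
    if mode == "step" or i == 0:
        return float(t[i])
    t0, t1 = t[i - 1], t[i]
    f0, f1 = f[i - 1], f[i]
    if f0 == f1:
        return float(t1)
    return float(t0 + (f0 - 0.5) * (t1 - t0) / (f0 - f1))


def write_grid_csv(curves: Sequence[KMCurveGrid], path: str | Path) -> None:
    """Write regularized curves as CSV with columns time_months, incidence_pct, arm."""
    frames = [
        pd.DataFrame(
            {
                "time_months": c.times,
                "incidence_pct": c.incidence,
                "arm": c.arm_label,
            }
        )
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(Path(path), index=False)
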