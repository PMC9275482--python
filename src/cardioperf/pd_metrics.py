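"""Per-recording pharmacodynamic metrics and dose-response fitting.

Implements the percent-change normalisation against the first-minute
baseline, the per-interval slope coefficient ``a = (y2 - y1)/(x2 - x1)``,
the effect summary (maximal effect, effect at reporting minutes, time to
half-maximal effect ``t50``, recovery half-time ``RT50``), and
Hill/four-parameter-logistic dose-response fitting with closed-form
inversion (IC50, EC75).

Conventions
-----------
* Effects are kept signed throughout: negative = inhibition.
* The ``t50`` clock starts at exposure onset; the ``RT50`` clock starts at
  exposure end.  Both origins are carried in :class:`PDSummary`.
* ``RT50`` measures the time to regain half of the drug-induced change
  (pct_change back to ``E_max/2``), the only reading defined for effects
  smaller than a 50% decrease.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .core_io import ProtocolSpec, Recording, ValidationError

__all__ = [
    "PercentChangeSeries",
    "SlopeSeries",
    "PDSummary",
    "DoseResponseFit",
    "FitError",
    "percent_change",
    "slope_coefficient",
    "effect_summary",
    "t50",
    "rt50",
    "fit_dose_response",
    "inverse_dose",
    "ec",
]


class FitError(ValidationError):
    """Nonlinear fit failed to converge; carries the best candidate."""

    def __init__(self, message: str, best: "DoseResponseFit | None" = None):
        super().__init__(message)
        self.best = best


# ---------------------------------------------------------------------------
# percent change and slope
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PercentChangeSeries:
    """Baseline-referenced percent-change trajectory of one recording."""

    times: np.ndarray  # minutes
    pct_change: np.ndarray  # %
    baseline_value: float  # contractions/min
    baseline_window: tuple[float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, float))
        object.__setattr__(self, "pct_change", np.asarray(self.pct_change, float))
        if self.baseline_value <= 0:
            raise ValidationError("baseline_value must be > 0")


@dataclass(frozen=True)
class SlopeSeries:
    """Per-interval difference quotients; times are right endpoints."""

    times: np.ndarray  # minutes, x2 of each interval
    a_values: np.ndarray  # %/min


def percent_change(rec: Recording, baseline_window: tuple[float, float] = (0.0, 1.0)) -> PercentChangeSeries:
    """Normalise a recording to percent change from its baseline mean.

    ``y(t) = 100 * (f(t) - f_base) / f_base`` with ``f_base`` the mean
    frequency over ``baseline_window`` (half-open, default the first
    minute of the registration).
    """
    t0, t1 = baseline_window
    mask = (rec.times >= t0 - 1e-12) & (rec.times < t1 - 1e-12)
    if not np.any(mask):
        raise ValidationError(f"no samples in baseline window [{t0:g}, {t1:g})")
    f_base = float(np.mean(rec.frequencies[mask]))
    if f_base <= 0:
        raise ValidationError("baseline mean frequency is zero; cannot normalise")
    y = 100.0 * (rec.frequencies - f_base) / f_base
    return PercentChangeSeries(rec.times, y, f_base, (t0, t1))


def slope_coefficient(pcs: PercentChangeSeries) -> SlopeSeries:
    """Difference quotient of consecutive points; exact for any spacing."""
    t, y = pcs.times, pcs.pct_change
    if t.size < 2:
        raise ValidationError("need at least two points for a slope")
    dx = np.diff(t)
    if np.any(dx == 0):
        raise ValidationError("duplicate times in percent-change series")
    return SlopeSeries(times=t[1:].copy(), a_values=np.diff(y) / dx)


# ---------------------------------------------------------------------------
# effect summary, t50, RT50
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PDSummary:
    e_max: float  # signed extreme % change in the effect window
    t_max: float  # minute of the extreme
    e_at: Mapping[float, float] = field(default_factory=dict)  # minute -> %
    t50: float = math.nan  # minutes from exposure onset
    rt50: float = math.nan  # minutes from exposure end; nan when censored
    rt50_censored: bool = False
    arrested: bool = False
    non_monotone_onset: bool = False
    exposure_onset: float = math.nan
    exposure_end: float = math.nan


def _effect_window(pcs: PercentChangeSeries, protocol: ProtocolSpec, tail: float) -> tuple[float, float]:
    onset, end = protocol.exposure_window()
    t_last = float(pcs.times[-1])
    return onset, min(end + tail, t_last)


def _signed_extreme(pcs: PercentChangeSeries, lo: float, hi: float) -> tuple[float, float]:
    mask = (pcs.times >= lo - 1e-12) & (pcs.times <= hi + 1e-12)
    if not np.any(mask):
        raise ValidationError("no samples inside the effect window")
    seg = pcs.pct_change[mask]
    ts = pcs.times[mask]
    i = int(np.argmax(np.abs(seg)))
    return float(seg[i]), float(ts[i])


def _sample_at(pcs: PercentChangeSeries, minute: float) -> float:
    """Value at the sample nearest ``minute`` (within half a bin)."""
    if minute < pcs.times[0] - 1e-9 or minute > pcs.times[-1] + 1e-9:
        raise ValidationError(f"report minute {minute:g} outside recording span")
    spacing = float(np.median(np.diff(pcs.times))) if pcs.times.size > 1 else math.inf
    i = int(np.argmin(np.abs(pcs.times - minute)))
    if abs(pcs.times[i] - minute) > spacing / 2 + 1e-9:
        raise ValidationError(f"no sample within half a bin of minute {minute:g}")
    return float(pcs.pct_change[i])


def _interp_crossing(times: np.ndarray, values: np.ndarray, target: float, direction: str) -> float | None:
    """First time the trajectory crosses ``target``.

    ``direction='toward'`` looks for |values| rising through |target|
    (onset); ``'back'`` for |values| falling through |target| (recovery).
    Piecewise-linear interpolation between samples.
    """
    hit = np.abs(values) >= abs(target) if direction == "toward" else np.abs(values) <= abs(target)
    for i in range(times.size):
        if hit[i]:
            if i == 0:
                return float(times[0])
            y0, y1 = values[i - 1], values[i]
            if y1 == y0:
                return float(times[i])
            frac = (target - y0) / (y1 - y0)
            frac = min(max(frac, 0.0), 1.0)
            return float(times[i - 1] + frac * (times[i] - times[i - 1]))
    return None


def _fit_rate(ts: np.ndarray, ys: np.ndarray, e_max: float, kind: str, k0: float) -> float:
    """Least-squares rate of ``E_max*(1-exp(-k t))`` or ``E_max*exp(-k t)``."""

    def resid(p: np.ndarray) -> np.ndarray:
        k = p[0]
        model = e_max * (1.0 - np.exp(-k * ts)) if kind == "onset" else e_max * np.exp(-k * ts)
        return model - ys

    sol = least_squares(resid, x0=[max(k0, 1e-3)], bounds=([1e-6], [1e3]))
    if not sol.success:
        raise FitError("mono-exponential rate fit did not converge")
    return float(sol.x[0])


def t50(pcs: PercentChangeSeries, protocol: ProtocolSpec, method: str = "interp", tail: float = 0.5) -> float:
    """Minutes from exposure onset until half the maximal change is reached.

    ``method='interp'``: monotone piecewise-linear crossing on raw points
    (assumption-free default).  ``method='fit'``: least-squares
    mono-exponential onset, ``t50 = ln 2 / k``.
    """
    onset, win_hi = _effect_window(pcs, protocol, tail)
    e_max, t_peak = _signed_extreme(pcs, onset, win_hi)
    if e_max == 0:
        raise ValidationError("maximal change is zero; t50 undefined")
    mask = (pcs.times >= onset - 1e-12) & (pcs.times <= t_peak + 1e-12)
    ts, ys = pcs.times[mask], pcs.pct_change[mask]
    # anchor at the last pre-onset sample so an immediate jump interpolates
    before = np.where(pcs.times < onset - 1e-12)[0]
    if before.size:
        ts = np.concatenate([[onset], ts])
        ys = np.concatenate([[pcs.pct_change[before[-1]]], ys])
    if method == "interp":
        cross = _interp_crossing(ts, ys, e_max / 2.0, "toward")
        if cross is None:  # unreachable on sampled data by construction of e_max
            raise ValidationError("onset never reaches half of the maximal change")
        return cross - onset
    if method == "fit":
        guess = _interp_crossing(ts, ys, e_max / 2.0, "toward")
        k0 = math.log(2.0) / max(guess - onset, 1e-3) if guess is not None else 1.0
        k = _fit_rate(ts - onset, ys, e_max, "onset", k0)
        return math.log(2.0) / k
    raise ValidationError(f"unknown t50 method {method!r}")


def rt50(pcs: PercentChangeSeries, protocol: ProtocolSpec, method: str = "interp", tail: float = 0.5) -> tuple[float, bool]:
    """(minutes from exposure end to half recovery, censored flag).

    The recovery target is halfway back toward the 0% baseline, i.e.
    ``E_max / 2``.  When the trajectory never recovers that far before the
    recording ends the value is ``nan`` and the flag is True
    (right-censored).
    """
    onset, end = protocol.exposure_window()
    if end >= pcs.times[-1] + 1e-9:
        raise ValidationError("exposure does not end within the recording; RT50 undefined")
    e_max, _ = _signed_extreme(pcs, onset, min(end + tail, float(pcs.times[-1])))
    if e_max == 0:
        raise ValidationError("maximal change is zero; RT50 undefined")
    mask = pcs.times >= end - 1e-12
    ts, ys = pcs.times[mask], pcs.pct_change[mask]
    before = np.where(pcs.times < end - 1e-12)[0]
    if before.size:
        ts = np.concatenate([[end], ts])
        ys = np.concatenate([[pcs.pct_change[before[-1]]], ys])
    if method == "interp":
        cross = _interp_crossing(ts, ys, e_max / 2.0, "back")
        if cross is None:
            return math.nan, True
        return cross - end, False
    if method == "fit":
        guess = _interp_crossing(ts, ys, e_max / 2.0, "back")
        if guess is None:
            return math.nan, True
        k0 = math.log(2.0) / max(guess - end, 1e-3)
        k = _fit_rate(ts - end, ys, float(ys[0]), "recovery", k0)
        return math.log(2.0) / k, False
    raise ValidationError(f"unknown rt50 method {method!r}")


def effect_summary(
    pcs: PercentChangeSeries,
    protocol: ProtocolSpec,
    report_minutes: Sequence[float] = (9.0, 13.0),
    method: str = "interp",
    tail: float = 0.5,
) -> PDSummary:
    """Summarise one percent-change trajectory against its protocol."""
    onset, end = protocol.exposure_window()
    lo, hi = _effect_window(pcs, protocol, tail)
    e_max, t_peak = _signed_extreme(pcs, lo, hi)
    e_at = {float(m): _sample_at(pcs, float(m)) for m in report_minutes}

    arrested = bool(np.any(pcs.pct_change[(pcs.times >= lo - 1e-12) & (pcs.times <= hi + 1e-12)] <= -100.0 + 1e-9))

    onset_mask = (pcs.times >= lo - 1e-12) & (pcs.times <= t_peak + 1e-12)
    onset_y = pcs.pct_change[onset_mask]
    non_monotone = False
    if onset_y.size >= 2 and e_max != 0:
        steps = np.diff(onset_y) * np.sign(e_max)
        non_monotone = bool(np.any(steps < -1e-9))

    if e_max == 0:
        t50_val: float = math.nan
        rt50_val, censored = math.nan, False
        t_peak = lo
    else:
        t50_val = t50(pcs, protocol, method=method, tail=tail)
        if end < pcs.times[-1] - 1e-9:
            rt50_val, censored = rt50(pcs, protocol, method=method, tail=tail)
        else:
            rt50_val, censored = math.nan, True
    return PDSummary(
        e_max=e_max,
        t_max=t_peak,
        e_at=e_at,
        t50=t50_val,
        rt50=rt50_val,
        rt50_censored=censored,
        arrested=arrested,
        non_monotone_onset=non_monotone,
        exposure_onset=onset,
        exposure_end=end,
    )


# ---------------------------------------------------------------------------
# dose-response
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted Hill curve ``E(C) = E_bot + (E_top - E_bot)/(1 + (IC50/C)^h)``."""

    ic50: float
    hill_slope: float
    e_top: float
    e_bottom: float
    residual_sse: float
    doses: np.ndarray
    effects: np.ndarray
    fitted: np.ndarray
    converged: bool = True
    extrapolated: bool = False
    degenerate: bool = False


def _hill_curve(c: np.ndarray, log_ic50: float, h: float, e_top: float, e_bot: float) -> np.ndarray:
    # E(0) = e_top, E(inf) = e_bot, E(ic50) = midpoint
    ic50 = 10.0**log_ic50
    out = np.full_like(c, e_top, dtype=float)
    pos = c > 0
    out[pos] = e_top + (e_bot - e_top) / (1.0 + (ic50 / c[pos]) ** h)
    return out


def fit_dose_response(
    doses: Sequence[float],
    effects: Sequence[float],
    e_top: float = 0.0,
    e_bottom: float | None = None,
    hill_starts: Sequence[float] = (0.5, 1.0, 2.0, 4.0),
) -> DoseResponseFit:
    """Least-squares Hill fit on log-dose with deterministic multi-start.

    ``e_top`` is fixed (default 0: no effect at zero dose); ``e_bottom`` is
    free in [-100, 0] unless a fixed value is supplied.  Start points scan
    ``hill_starts`` crossed with every positive dose as an IC50 seed; the
    lowest-SSE convergent solution wins (ties resolved by the scan order).
    """
    c = np.asarray(doses, dtype=float)
    y = np.asarray(effects, dtype=float)
    if c.shape != y.shape or c.ndim != 1:
        raise ValidationError("doses and effects must be equally long 1-D sequences")
    if np.unique(c).size < 3:
        raise ValidationError("need at least 3 distinct doses")
    if np.any(c < 0):
        raise ValidationError("negative dose")

    if np.all(np.abs(y) < 1e-9):
        return DoseResponseFit(math.nan, math.nan, e_top, e_top, 0.0, c, y, np.zeros_like(y), converged=False, degenerate=True)

    free_bottom = e_bottom is None

    def resid(p: np.ndarray) -> np.ndarray:
        e_bot = p[2] if free_bottom else e_bottom
        return _hill_curve(c, p[0], p[1], e_top, e_bot) - y

    pos = c[c > 0]
    lo_ic, hi_ic = math.log10(pos.min()) - 4.0, math.log10(pos.max()) + 4.0
    bounds_lo = [lo_ic, 1e-3] + ([-100.0] if free_bottom else [])
    bounds_hi = [hi_ic, 100.0] + ([0.0] if free_bottom else [])
    bot0 = float(np.clip(y.min(), -100.0, 0.0)) if free_bottom else None

    best: tuple[float, np.ndarray] | None = None
    for h0 in hill_starts:
        for ic0 in pos:
            x0 = [math.log10(ic0), h0] + ([bot0] if free_bottom else [])
            try:
                sol = least_squares(resid, x0=np.asarray(x0, float), bounds=(bounds_lo, bounds_hi))
            except Exception:
                continue
            if not sol.success:
                continue
            sse = float(np.sum(sol.fun**2))
            if best is None or sse < best[0] - 1e-12:
                best = (sse, sol.x)
    if best is None:
        raise FitError("dose-response fit did not converge from any start point")
    sse, p = best
    ic50 = 10.0 ** float(p[0])
    e_bot = float(p[2]) if free_bottom else float(e_bottom)
    fitted = _hill_curve(c, float(p[0]), float(p[1]), e_top, e_bot)
    extrapolated = not (pos.min() * 1e-2 <= ic50 <= pos.max() * 1e2)
    return DoseResponseFit(ic50, float(p[1]), e_top, e_bot, sse, c, y, fitted, converged=True, extrapolated=extrapolated)


def inverse_dose(fit: DoseResponseFit, effect_level: float) -> float:
    """Dose at which the fitted curve passes ``effect_level`` (closed form)."""
    if fit.degenerate or not fit.converged:
        raise ValidationError("cannot invert a degenerate or unconverged fit")
    span = fit.e_bottom - fit.e_top
    if span == 0:
        raise ValidationError("flat fitted curve")
    f = (effect_level - fit.e_top) / span
    if not (0.0 < f < 1.0):
        raise ValidationError(f"effect level {effect_level:g} outside the fitted range ({fit.e_top:g}, {fit.e_bottom:g})")
    return float(fit.ic50 * (f / (1.0 - f)) ** (1.0 / fit.hill_slope))


def ec(fit: DoseResponseFit, fraction: float) -> float:
    """Dose producing ``fraction`` of the fitted span, e.g. 0.75 for EC75."""
    if not (0.0 < fraction < 1.0):
        raise ValidationError("fraction must be in (0, 1)")
    return inverse_dose(fit, fit.e_top + fraction * (fit.e_bottom - fit.e_top))
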