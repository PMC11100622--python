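"""Temperature-aligned analyses of the pyloric rhythm.

This module takes the per-cycle table produced by :mod:`pyloric.bursts`
(each row one pyloric cycle, annotated with its local temperature) and
computes the temperature-facing summaries of the study design:

* mean burst frequency at each holding temperature of the step protocol,
* the temperature coefficient Q10 of cycle frequency,
  f(T) = f_ref * Q10**((T - T_ref)/10),
* the frequency change between the temperature extremes,
* the "jag" classifier: a moving-average based labelling of cycles into
  temperature states (increasing / stable) and frequency states
  (increasing / decreasing / stable), and the two headline proportions
  (frequency falling while temperature rises; frequency rising while
  temperature is stable) that quantify non-monotonic transitions, and
* least-squares phase-vs-temperature slopes used to assess phase constancy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, FitError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "TemperatureTrace",
    "ThermalSummary",
    "JagClassification",
    "PhaseSlopeFit",
    "holding_means",
    "fit_q10",
    "delta_f",
    "smooth_series",
    "classify_jags",
    "fit_phase_slope",
]


@dataclass(frozen=True)
class TemperatureTrace:
    """A sampled bath-temperature trace.

    Parameters
    ----------
    times : array of float
        Sample times in seconds, strictly increasing.
    temps : array of float
        Temperature in degrees Celsius, same length as ``times``.
    """

    times: np.ndarray
    temps: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        temps = np.asarray(self.temps, dtype=float)
        if times.ndim != 1 or times.shape != temps.shape:
            raise DataError("times and temps must be 1-D arrays of equal length")
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise DataError("temperature trace times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "temps", temps)

    def at(self, t) -> np.ndarray:
        """Linearly interpolated temperature at time(s) ``t``."""
        return np.interp(t, self.times, self.temps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "temp_c": self.temps})


@dataclass
class ThermalSummary:
    """Per-holding-temperature frequency means and the fitted Q10."""

    targets: list[float]
    mean_f: dict[float, float]
    sd_f: dict[float, float]
    n_cycles: dict[float, int]
    q10: float | None = None
    f_ref: float | None = None
    t_ref: float = 11.0
    delta_f_21_11: float | None = None

    def to_dict(self) -> dict:
        return {
            "targets": list(self.targets),
            "mean_f": {str(k): v for k, v in self.mean_f.items()},
            "sd_f": {str(k): v for k, v in self.sd_f.items()},
            "n_cycles": {str(k): v for k, v in self.n_cycles.items()},
            "q10": self.q10,
            "f_ref": self.f_ref,
            "t_ref": self.t_ref,
            "delta_f_21_11": self.delta_f_21_11,
        }


@dataclass
class JagClassification:
    """Per-cycle temperature/frequency state labels and headline proportions.

    ``labels`` has one row per cycle with the smoothed series, their first
    differences, and the categorical states.  The first cycle has no
    difference and carries state ``"undefined"``; proportions are computed
    over cycles 1..n-1.
    """

    labels: pd.DataFrame
    p_dec_during_inc: float | None
    p_inc_during_stable: float | None
    n_increasing: int
    n_stable: int
    w_f: int
    w_t: int
    theta_t: float
    theta_f: float

    def to_dict(self) -> dict:
        return {
            "p_dec_during_inc": self.p_dec_during_inc,
            "p_inc_during_stable": self.p_inc_during_stable,
            "n_increasing": self.n_increasing,
            "n_stable": self.n_stable,
            "w_f": self.w_f,
            "w_t": self.w_t,
            "theta_t": self.theta_t,
            "theta_f": self.theta_f,
        }


@dataclass
class PhaseSlopeFit:
    """OLS fit of mean phase against temperature for one phase reference point.

    A negative slope means the event moves earlier in the cycle as the
    preparation warms (a phase advance).
    """

    phase_name: str
    slope: float  # phase units per degree C
    intercept: float
    r_squared: float
    n_points: int

    @property
    def slope_per_10c(self) -> float:
        return 10.0 * self.slope

    @property
    def advance_per_10c(self) -> float:
        """Magnitude of the advance per 10 degrees C (positive when advancing)."""
        return -self.slope_per_10c

    def to_dict(self) -> dict:
        return {
            "phase_name": self.phase_name,
            "slope": self.slope,
            "slope_per_10C": self.slope_per_10c,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
        }


def holding_means(
    cycles: pd.DataFrame,
    targets: list[float],
    tol: float = 0.3,
) -> ThermalSummary:
    """Mean and SD of cycle frequency at each holding temperature.

    A cycle belongs to a target's holding window when the temperature stayed
    within ``tol`` degrees C of the target for the whole cycle (judged on the
    cycle's min/max temperature when available, else its mean).  A cycle that
    satisfies this for two targets is assigned to the nearer one.

    Parameters
    ----------
    cycles : DataFrame
        Per-cycle table with at least ``freq_hz`` and ``temp_c`` columns;
        ``temp_min_c``/``temp_max_c`` are used when present.
    targets : list of float
        Protocol holding temperatures in degrees C.
    tol : float
        Half-width of the holding window in degrees C.
    """
    if "temp_c" not in cycles.columns:
        raise DataError("cycles must carry a temp_c column; run annotate_temperature")
    targets = [float(t) for t in targets]
    tarr = np.asarray(targets)
    temp_mean = cycles["temp_c"].to_numpy(dtype=float)
    if {"temp_min_c", "temp_max_c"}.issubset(cycles.columns):
        lo = cycles["temp_min_c"].to_numpy(dtype=float)
        hi = cycles["temp_max_c"].to_numpy(dtype=float)
    else:
        lo = hi = temp_mean

    # nearest-target assignment, then the whole-cycle tolerance test
    nearest = np.abs(temp_mean[:, None] - tarr[None, :]).argmin(axis=1)
    assigned = tarr[nearest]
    within = (lo >= assigned - tol) & (hi <= assigned + tol)

    freq = cycles["freq_hz"].to_numpy(dtype=float)
    mean_f: dict[float, float] = {}
    sd_f: dict[float, float] = {}
    n_cycles: dict[float, int] = {}
    for i, target in enumerate(targets):
        sel = within & (nearest == i)
        n = int(sel.sum())
        n_cycles[target] = n
        if n == 0:
            logger.warning("no cycles within %.2f degC of target %.1f degC", tol, target)
            mean_f[target] = float("nan")
            sd_f[target] = float("nan")
        else:
            mean_f[target] = float(freq[sel].mean())
            sd_f[target] = float(freq[sel].std(ddof=1)) if n > 1 else 0.0
    return ThermalSummary(targets=targets, mean_f=mean_f, sd_f=sd_f, n_cycles=n_cycles)


def fit_q10(
    means: ThermalSummary | dict[float, float],
    t_ref: float = 11.0,
) -> tuple[float, float]:
    """Least-squares Q10 of frequency over the holding-temperature means.

    Fits ``log f = log f_ref + ((T - t_ref)/10) * log Q10`` by unweighted
    ordinary least squares over all non-missing holding means.  With exactly
    two points this reduces to the endpoint formula
    ``Q10 = (f2/f1)**(10/(T2 - T1))``.

    Returns ``(q10, f_ref)`` and, when given a :class:`ThermalSummary`,
    stores them on it.
    """
    summary = means if isinstance(means, ThermalSummary) else None
    mean_f = means.mean_f if summary is not None else dict(means)
    pts = [(t, f) for t, f in mean_f.items() if np.isfinite(f)]
    if len(pts) < 2:
        raise FitError(f"Q10 fit needs >= 2 holding means, got {len(pts)}")
    temps = np.array([t for t, _ in pts], dtype=float)
    freqs = np.array([f for _, f in pts], dtype=float)
    if np.any(freqs <= 0):
        raise DataError("Q10 fit requires strictly positive frequencies")
    x = (temps - t_ref) / 10.0
    slope, intercept = np.polyfit(x, np.log(freqs), 1)
    q10 = float(np.exp(slope))
    f_ref = float(np.exp(intercept))
    if summary is not None:
        summary.q10 = q10
        summary.f_ref = f_ref
        summary.t_ref = t_ref
    return q10, f_ref


def delta_f(
    means: ThermalSummary | dict[float, float],
    t_hi: float = 21.0,
    t_lo: float = 11.0,
) -> float:
    """Difference of holding-mean frequency between two targets, in Hz."""
    summary = means if isinstance(means, ThermalSummary) else None
    mean_f = means.mean_f if summary is not None else dict(means)
    for t in (t_hi, t_lo):
        if t not in mean_f or not np.isfinite(mean_f[t]):
            raise FitError(f"missing holding mean at {t} degC")
    df = float(mean_f[t_hi] - mean_f[t_lo])
    if summary is not None and (t_hi, t_lo) == (21.0, 11.0):
        summary.delta_f_21_11 = df
    return df


def smooth_series(values, window: int) -> np.ndarray:
    """Centered moving average with symmetric truncation at the edges.

    At index ``i`` the average runs over ``[i - r, i + r]`` with
    ``r = min(window // 2, i, n - 1 - i)``, so the output has the same
    length as the input and carries no systematic lag.  ``window=1`` is the
    identity; a window longer than the series collapses to the global mean
    (with a warning).
    """
    if window < 1:
        raise ParameterError("window must be >= 1")
    x = np.asarray(values, dtype=float)
    n = x.size
    if n == 0:
        return x.copy()
    if window > n:
        warnings.warn(
            f"smoothing window {window} exceeds series length {n}; returning global mean",
            stacklevel=2,
        )
        return np.full(n, x.mean())
    half = window // 2
    idx = np.arange(n)
    r = np.minimum(half, np.minimum(idx, n - 1 - idx))
    csum = np.concatenate(([0.0], np.cumsum(x)))
    return (csum[idx + r + 1] - csum[idx - r]) / (2 * r + 1)


def classify_jags(
    cycles: pd.DataFrame,
    w_f: int = 30,
    w_t: int = 10,
    theta_t: float = 0.01,
    theta_f: float = 0.002,
) -> JagClassification:
    """Label cycles by smoothed temperature/frequency change and count jags.

    Frequency and temperature are smoothed with centered moving averages over
    ``w_f`` and ``w_t`` cycles respectively, then differenced between
    consecutive cycles.  A cycle's temperature state is *increasing* when the
    smoothed temperature rose by more than ``theta_t`` degC per cycle, else
    *stable*; its frequency state is *decreasing* / *increasing* when the
    smoothed frequency changed by more than ``theta_f`` Hz per cycle in that
    direction, else *stable*.

    The two returned proportions measure the non-monotonic "jag" signature:
    the fraction of temperature-increasing cycles in which frequency fell,
    and the fraction of temperature-stable cycles in which frequency rose.
    An empty denominator class yields ``None``, never zero.
    """
    n = len(cycles)
    if n < w_f + 1:
        raise DataError(f"classify_jags needs >= {w_f + 1} cycles, got {n}")
    freq = cycles["freq_hz"].to_numpy(dtype=float)
    temp = cycles["temp_c"].to_numpy(dtype=float)
    sm_f = smooth_series(freq, w_f)
    sm_t = smooth_series(temp, w_t)
    d_f = np.diff(sm_f)
    d_t = np.diff(sm_t)

    temp_state = np.where(d_t > theta_t, "increasing", "stable")
    freq_state = np.where(
        d_f < -theta_f, "decreasing", np.where(d_f > theta_f, "increasing", "stable")
    )

    inc = temp_state == "increasing"
    stable = ~inc
    n_inc = int(inc.sum())
    n_stable = int(stable.sum())
    p_dec = float((inc & (freq_state == "decreasing")).sum() / n_inc) if n_inc else None
    p_inc = (
        float((stable & (freq_state == "increasing")).sum() / n_stable) if n_stable else None
    )
    if n_inc == 0:
        logger.warning("no temperature-increasing cycles; p_dec_during_inc is missing")
    if n_stable == 0:
        logger.warning("no temperature-stable cycles; p_inc_during_stable is missing")

    labels = pd.DataFrame(
        {
            "smoothed_temp_c": sm_t,
            "smoothed_freq_hz": sm_f,
            "d_temp": np.concatenate(([np.nan], d_t)),
            "d_freq": np.concatenate(([np.nan], d_f)),
            "temp_state": np.concatenate((["undefined"], temp_state)),
            "freq_state": np.concatenate((["undefined"], freq_state)),
        },
        index=cycles.index,
    )
    return JagClassification(
        labels=labels,
        p_dec_during_inc=p_dec,
        p_inc_during_stable=p_inc,
        n_increasing=n_inc,
        n_stable=n_stable,
        w_f=w_f,
        w_t=w_t,
        theta_t=theta_t,
        theta_f=theta_f,
    )


def fit_phase_slope(temps, mean_phases, phase_name: str = "") -> PhaseSlopeFit:
    """OLS line of mean phase versus temperature.

    A negative slope is a phase advance with warming.  Requires at least two
    temperatures with finite mean phase.
    """
    t = np.asarray(temps, dtype=float)
    p = np.asarray(mean_phases, dtype=float)
    ok = np.isfinite(t) & np.isfinite(p)
    t, p = t[ok], p[ok]
    if t.size < 2:
        raise FitError("phase-slope fit needs >= 2 temperatures with mean phase")
    if np.ptp(t) == 0:
        raise FitError("phase-slope fit needs >= 2 distinct temperatures")
    res = sps.linregress(t, p)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
    return PhaseSlopeFit(
        phase_name=phase_name,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        n_points=int(t.size),
    )
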