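"""Burst detection, cycle extraction, and phase assignment for the pyloric rhythm.

The triphasic pyloric pattern is described here by three labeled units:
PD (pyloric dilator, part of the pacemaker kernel), LP (lateral pyloric)
and PY (pyloric).  A *burst* is a run of two or more consecutive spikes in
one unit separated from its neighbours by an inter-burst interval of at
least 200 ms.  A *cycle* runs from the first spike of one PD burst to the
first spike of the next; every other event is expressed as a *phase*: its
latency from the cycle start divided by the cycle period.

The per-cycle table built here (a pandas DataFrame, one row per cycle) is
the interchange object for the rest of the package: `pyloric.thermal`
consumes it for Q10 and jag analyses, `pyloric.stats` for inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .errors import DataError
from .thermal import TemperatureTrace

logger = logging.getLogger(__name__)

UNITS = ("PD", "LP", "PY")

#: phase columns of the per-cycle table, in firing order
PHASE_COLUMNS = ("pd_off", "lp_on", "lp_off", "py_on", "py_off")

__all__ = [
    "UNITS",
    "PHASE_COLUMNS",
    "SpikeTrain",
    "Burst",
    "PhaseSummary",
    "detect_bursts",
    "extract_cycles",
    "annotate_temperature",
    "assign_phases",
    "phase_summary",
    "match_periods",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Strictly increasing spike times (seconds) for one labeled unit."""

    unit: str
    times: np.ndarray

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise DataError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        times = np.asarray(self.times, dtype=float)
        if times.ndim != 1:
            raise DataError("spike times must be a 1-D array")
        if times.size and times[0] < 0:
            raise DataError("spike times must be non-negative")
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise DataError(f"{self.unit} spike times must be strictly increasing")
        object.__setattr__(self, "times", times)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class Burst:
    """One burst: first/last spike time and spike count for one unit."""

    unit: str
    t_first: float
    t_last: float
    n_spikes: int

    @property
    def duration(self) -> float:
        return self.t_last - self.t_first


@dataclass
class PhaseSummary:
    """Across-cycle phase statistics for one condition.

    ``delay_pd_off_lp_on`` is the mean over cycles of (LP onset phase minus
    PD offset phase), the latency of the LP burst behind the end of the PD
    burst in phase units.
    """

    mean: dict[str, float]
    sd: dict[str, float]
    n: dict[str, int]
    delay_pd_off_lp_on: float
    delay_sd: float
    pd_duration_ms: float
    duty_cycle: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mean": dict(self.mean),
            "sd": dict(self.sd),
            "n": dict(self.n),
            "delay_pd_off_lp_on": self.delay_pd_off_lp_on,
            "delay_sd": self.delay_sd,
            "pd_duration_ms": self.pd_duration_ms,
            "duty_cycle": dict(self.duty_cycle),
        }


def detect_bursts(
    train: SpikeTrain,
    min_spikes: int = 2,
    split_gap: float = 0.2,
) -> list[Burst]:
    """Group spikes into bursts by the inter-burst-interval rule.

    Consecutive spikes closer than ``split_gap`` seconds belong to the same
    burst; an inter-spike interval of ``split_gap`` or more closes the burst.
    Groups with fewer than ``min_spikes`` spikes are discarded.  The default
    rule (two or more spikes, 200 ms interval) is the standard pyloric burst
    definition.
    """
    times = train.times
    if times.size >= 2 and not np.all(np.diff(times) > 0):
        raise DataError("spike train must be strictly increasing")
    if times.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(times) >= split_gap) + 1
    groups = np.split(times, breaks)
    return [
        Burst(unit=train.unit, t_first=float(g[0]), t_last=float(g[-1]), n_spikes=g.size)
        for g in groups
        if g.size >= min_spikes
    ]


def extract_cycles(pd_bursts: list[Burst]) -> pd.DataFrame:
    """Build the per-cycle table from PD bursts.

    Cycle k spans from the first spike of PD burst k to the first spike of
    burst k+1; its period is that interval and its frequency the reciprocal.
    The final burst starts no cycle.  Returns an empty table (with a
    warning) when fewer than two bursts are available.
    """
    cols = ["t_start", "period_s", "freq_hz", "pd_t_last"]
    if len(pd_bursts) < 2:
        logger.warning("extract_cycles: need >= 2 PD bursts, got %d", len(pd_bursts))
        return pd.DataFrame(columns=cols)
    firsts = np.array([b.t_first for b in pd_bursts])
    lasts = np.array([b.t_last for b in pd_bursts])
    periods = np.diff(firsts)
    if np.any(periods <= 0):
        raise DataError("PD bursts must be ordered with positive periods")
    return pd.DataFrame(
        {
            "t_start": firsts[:-1],
            "period_s": periods,
            "freq_hz": 1.0 / periods,
            "pd_t_last": lasts[:-1],
        }
    )


def annotate_temperature(cycles: pd.DataFrame, temp: TemperatureTrace) -> pd.DataFrame:
    """Attach cycle-local temperature statistics to the per-cycle table.

    ``temp_c`` is the time-average of the (linearly interpolated) trace over
    the cycle; ``temp_min_c``/``temp_max_c`` bound the excursion within the
    cycle.  Vectorised via the cumulative integral of the trace.
    """
    if cycles.empty:
        out = cycles.copy()
        out["temp_c"] = out["temp_min_c"] = out["temp_max_c"] = np.nan
        return out
    t0 = cycles["t_start"].to_numpy(dtype=float)
    t1 = t0 + cycles["period_s"].to_numpy(dtype=float)

    # cumulative integral of the trace, linearly interpolated at cycle edges
    cum = np.concatenate(([0.0], cumulative_trapezoid(temp.temps, temp.times)))
    integral = np.interp(t1, temp.times, cum) - np.interp(t0, temp.times, cum)
    mean_t = integral / (t1 - t0)

    # min/max over interior samples plus interpolated endpoint values
    i0 = np.searchsorted(temp.times, t0, side="left")
    i1 = np.searchsorted(temp.times, t1, side="right")
    ends = np.column_stack([temp.at(t0), temp.at(t1)])
    lo = ends.min(axis=1)
    hi = ends.max(axis=1)
    for k in np.flatnonzero(i1 > i0):
        seg = temp.temps[i0[k] : i1[k]]
        lo[k] = min(lo[k], seg.min())
        hi[k] = max(hi[k], seg.max())

    out = cycles.copy()
    out["temp_c"] = mean_t
    out["temp_min_c"] = lo
    out["temp_max_c"] = hi
    return out


def _locate_bursts(
    cycles: pd.DataFrame, bursts: list[Burst], unit: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Match each cycle to the burst whose first spike falls within it.

    Returns (onset time, offset time, found mask); cycles without a burst get
    NaN.  Two bursts starting inside one cycle trigger a warning and the
    earlier is used.
    """
    n = len(cycles)
    on = np.full(n, np.nan)
    off = np.full(n, np.nan)
    if not bursts:
        return on, off, np.zeros(n, dtype=bool)
    firsts = np.array([b.t_first for b in bursts])
    lasts = np.array([b.t_last for b in bursts])
    t0 = cycles["t_start"].to_numpy(dtype=float)
    t1 = t0 + cycles["period_s"].to_numpy(dtype=float)
    lo = np.searchsorted(firsts, t0, side="left")
    hi = np.searchsorted(firsts, t1, side="left")
    count = hi - lo
    found = count >= 1
    multi = count > 1
    if np.any(multi):
        for k in np.flatnonzero(multi):
            logger.warning(
                "%d %s bursts start within cycle %d; using the earliest", count[k], unit, k
            )
    on[found] = firsts[lo[found]]
    off[found] = lasts[lo[found]]
    return on, off, found


def assign_phases(
    cycles: pd.DataFrame,
    pd_bursts: list[Burst],
    lp_bursts: list[Burst],
    py_bursts: list[Burst],
) -> pd.DataFrame:
    """Fill per-neuron onset/offset phases into the per-cycle table.

    Phase is the latency from the cycle start (first PD spike) to the first
    (onset) or last (offset) spike of the unit's burst in that cycle,
    normalised by the period.  PD onset is identically 0 and not stored.
    Offsets extending past the cycle end are kept as raw phases > 1 and
    flagged in ``<unit>_wrapped``; reducing them mod 1 would corrupt means
    of offsets near 1.  Cycles lacking an LP or PY burst carry NaN for those
    phases.
    """
    out = cycles.copy()
    if out.empty:
        for c in PHASE_COLUMNS:
            out[c] = np.nan
        out["lp_wrapped"] = out["py_wrapped"] = False
        return out
    t0 = out["t_start"].to_numpy(dtype=float)
    period = out["period_s"].to_numpy(dtype=float)

    if "pd_t_last" in out.columns:
        pd_last = out["pd_t_last"].to_numpy(dtype=float)
    else:
        _, pd_last, found = _locate_bursts(out, pd_bursts, "PD")
        if not np.all(found):
            raise DataError("every cycle must contain its defining PD burst")
    out["pd_off"] = (pd_last - t0) / period

    for unit, bursts in (("lp", lp_bursts), ("py", py_bursts)):
        on, off, found = _locate_bursts(out, bursts, unit.upper())
        out[f"{unit}_on"] = (on - t0) / period
        out[f"{unit}_off"] = (off - t0) / period
        out[f"{unit}_wrapped"] = np.where(found, out[f"{unit}_off"] > 1.0, False)
    return out


def phase_summary(cycles: pd.DataFrame) -> PhaseSummary:
    """Across-cycle means and SDs of phases, the PD-off-to-LP-on delay, PD
    burst duration (ms), and per-unit duty cycles.

    Missing phases are excluded per statistic; the delay is computed per
    cycle (LP onset minus PD offset) and then averaged.
    """
    if cycles.empty:
        raise DataError("phase_summary needs at least one cycle")
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    n: dict[str, int] = {}
    for col in PHASE_COLUMNS:
        vals = cycles[col].to_numpy(dtype=float) if col in cycles else np.array([])
        vals = vals[np.isfinite(vals)]
        n[col] = int(vals.size)
        if vals.size == 0:
            logger.warning("phase %s missing in all cycles; omitted from summary", col)
            mean[col] = float("nan")
            sd[col] = float("nan")
        else:
            mean[col] = float(vals.mean())
            sd[col] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0

    delay = (cycles["lp_on"] - cycles["pd_off"]).to_numpy(dtype=float)
    delay = delay[np.isfinite(delay)]
    delay_mean = float(delay.mean()) if delay.size else float("nan")
    delay_sd = float(delay.std(ddof=1)) if delay.size > 1 else 0.0

    pd_dur = (cycles["pd_off"] * cycles["period_s"]).to_numpy(dtype=float)
    pd_dur = pd_dur[np.isfinite(pd_dur)]
    pd_duration_ms = float(pd_dur.mean() * 1000.0) if pd_dur.size else float("nan")

    duty: dict[str, float] = {"PD": mean["pd_off"]}
    for unit in ("lp", "py"):
        d = (cycles[f"{unit}_off"] - cycles[f"{unit}_on"]).to_numpy(dtype=float)
        d = d[np.isfinite(d)]
        duty[unit.upper()] = float(d.mean()) if d.size else float("nan")

    return PhaseSummary(
        mean=mean,
        sd=sd,
        n=n,
        delay_pd_off_lp_on=delay_mean,
        delay_sd=delay_sd,
        pd_duration_ms=pd_duration_ms,
        duty_cycle=duty,
    )


def match_periods(
    reference_cycles: pd.DataFrame,
    other_cycles: pd.DataFrame,
    rel_tol: float = 0.02,
) -> pd.DataFrame:
    """Greedy one-to-one period matching across conditions.

    Each reference cycle, in order, is paired with the not-yet-matched
    other-condition cycle of closest period; the pair is kept only when
    |P_other - P_ref| / P_ref <= ``rel_tol``.  For every accepted pair the
    latency differences (other minus reference, in ms) of PD offset, LP
    onset and PY onset are reported — the quantities used to ask whether a
    phase advance survives at matched period.
    """
    if reference_cycles.empty or other_cycles.empty:
        raise DataError("match_periods needs non-empty cycle sets")
    p_ref = reference_cycles["period_s"].to_numpy(dtype=float)
    p_oth = other_cycles["period_s"].to_numpy(dtype=float)
    available = np.ones(p_oth.size, dtype=bool)
    rows = []
    for i, p in enumerate(p_ref):
        free = np.flatnonzero(available)
        if free.size == 0:
            break
        j = free[np.argmin(np.abs(p_oth[free] - p))]
        if abs(p_oth[j] - p) / p <= rel_tol:
            available[j] = False
            row = {
                "ref_index": reference_cycles.index[i],
                "other_index": other_cycles.index[j],
                "period_ref_s": p,
                "period_other_s": p_oth[j],
            }
            for col in ("pd_off", "lp_on", "py_on"):
                if col in reference_cycles and col in other_cycles:
                    lat_ref = reference_cycles[col].iloc[i] * p
                    lat_oth = other_cycles[col].iloc[j] * p_oth[j]
                    row[f"{col}_latency_diff_ms"] = (lat_oth - lat_ref) * 1000.0
            rows.append(row)
    if not rows:
        logger.warning("match_periods: no pairs within rel_tol=%g", rel_tol)
        return pd.DataFrame(
            columns=["ref_index", "other_index", "period_ref_s", "period_other_s"]
        )
    return pd.DataFrame(rows)
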