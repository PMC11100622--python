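"""Quantification of the hyperpolarisation-activated current (Ih).

Ih activates slowly, so during a sustained hyperpolarising voltage step the
clamp current grows from an instantaneous (leak-dominated) level toward a
steady state.  Ih amplitude is quantified as the difference between the
current needed to hold the hyperpolarisation initially and at steady
state: ``delta_i = |mean(steady window) - mean(initial window)|``.

The default windows are [20, 80] ms after step onset (late enough to skip
the capacitive transient, short enough that Ih with an activation time
constant around 2 s has barely begun to develop) and the final 1 s of the
nominal 12 s step.  Both are caller-configurable; the estimator's bias is
the fraction of Ih already active in the initial window plus the fraction
still missing in the steady window, so it underestimates for fast
activation (small tau_h).

``percent_block`` compares paired measurements across conditions (e.g.
saline vs Cs+) cell by cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DataError, ParameterError, StatsError
from .synth import ClampStep

logger = logging.getLogger(__name__)

__all__ = ["IhMeasurement", "measure_ih", "percent_block", "ClampStep"]

#: default analysis windows, seconds from step onset
INITIAL_WINDOW = (0.02, 0.08)
STEADY_LAST = 1.0


@dataclass(frozen=True)
class IhMeasurement:
    """Ih amplitude for one voltage step.

    ``delta_i`` is the magnitude of the slow current change; signed window
    means are retained so the raw current convention is never lost.
    """

    step_voltage: float
    i_initial: float  # nA, mean over the initial window (signed)
    i_steady: float  # nA, mean over the steady window (signed)
    delta_i: float  # nA, |i_steady - i_initial|
    initial_window: tuple[float, float]
    steady_window: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "step_voltage": self.step_voltage,
            "i_initial": self.i_initial,
            "i_steady": self.i_steady,
            "delta_i": self.delta_i,
            "initial_window": list(self.initial_window),
            "steady_window": list(self.steady_window),
        }


def measure_ih(
    step: ClampStep,
    initial_window: tuple[float, float] = INITIAL_WINDOW,
    steady_window: tuple[float, float] | None = None,
) -> IhMeasurement:
    """Window-mean Ih estimate for one hyperpolarising step.

    ``steady_window`` defaults to the final second of the trace.  Windows
    must lie within the trace and must not overlap.
    """
    t = np.asarray(step.times, dtype=float)
    i = np.asarray(step.current, dtype=float)
    if t.size < 2:
        raise DataError("clamp step trace is too short")
    t_end = t[-1]
    if steady_window is None:
        steady_window = (t_end - STEADY_LAST, t_end)
    a0, a1 = (float(x) for x in initial_window)
    b0, b1 = (float(x) for x in steady_window)
    if not (0.0 <= a0 < a1 and b0 < b1 <= t_end + 1e-12):
        raise ParameterError("analysis windows must be ordered and within the trace")
    if a1 > b0:
        raise ParameterError("initial and steady windows must not overlap")

    init_mask = (t >= a0) & (t <= a1)
    steady_mask = (t >= b0) & (t <= b1)
    if not init_mask.any() or not steady_mask.any():
        raise ParameterError("analysis windows contain no samples")
    i_initial = float(i[init_mask].mean())
    i_steady = float(i[steady_mask].mean())
    return IhMeasurement(
        step_voltage=step.step_voltage,
        i_initial=i_initial,
        i_steady=i_steady,
        delta_i=abs(i_steady - i_initial),
        initial_window=(a0, a1),
        steady_window=(b0, b1),
    )


def percent_block(
    pairs: list[tuple[float, float]],
    noise_floor: float = 0.0,
) -> tuple[float, float]:
    """Mean +/- SD percent reduction of Ih across paired cells.

    Each pair is ``(delta_i_control, delta_i_blocked)`` for one cell; the
    per-cell reduction is ``100 * (1 - blocked/control)``.  Cells whose
    control amplitude does not exceed ``noise_floor`` are excluded with a
    warning.  Negative reductions (potentiation) are allowed and flagged.
    """
    if not pairs:
        raise StatsError("percent_block needs at least one pair")
    reductions = []
    for k, (a, b) in enumerate(pairs):
        if a <= noise_floor:
            logger.warning(
                "cell %d excluded from percent_block: control delta_i %.3g <= noise floor",
                k,
                a,
            )
            continue
        r = 100.0 * (1.0 - b / a)
        if r < 0:
            logger.warning("cell %d shows potentiation (%.1f%% reduction)", k, r)
        reductions.append(r)
    if not reductions:
        raise StatsError("no pairs above the noise floor")
    arr = np.asarray(reductions)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd
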