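import numpy as np
import pytest

from pyloric import (
    SpikeTrain,
    TemperatureProtocolSpec,
    TemperatureTrace,
    annotate_temperature,
    assign_phases,
    detect_bursts,
    extract_cycles,
    gen_temperature,
)


def constant_trace(temp_c: float, duration: float = 60.0, dt: float = 0.1) -> TemperatureTrace:
    times = np.arange(0.0, duration, dt)
    return TemperatureTrace(times=times, temps=np.full(times.size, temp_c))


def triphasic_trains(
    n_cycles: int,
    period: float,
    pd_span: tuple[float, float] = (0.0, 0.19),
    lp_span: tuple[float, float] = (0.40, 0.66),
    py_span: tuple[float, float] | None = (0.58, 0.87),
    n_spikes: dict[str, int] | None = None,
) -> dict[str, SpikeTrain]:
    """Noiseless, perfectly periodic triphasic spike trains.

    Spans are phase fractions of the period; spikes are evenly spaced over
    each burst.  One extra PD burst is appended so the last full cycle has
    a closing boundary.
    """
    n_spikes = n_spikes or {"PD": 5, "LP": 6, "PY": 6}
    spans = {"PD": pd_span, "LP": lp_span}
    if py_span is not None:
        spans["PY"] = py_span
    starts = np.arange(n_cycles + 1) * period
    trains = {}
    for unit, (on, off) in spans.items():
        cycle_starts = starts if unit == "PD" else starts[:-1]
        ramp = np.linspace(on * period, off * period, n_spikes[unit])
        trains[unit] = SpikeTrain(
            unit=unit, times=(cycle_starts[:, None] + ramp[None, :]).ravel()
        )
    return trains


def run_phase_pipeline(trains, trace=None):
    """detect_bursts → extract_cycles → (annotate) → assign_phases."""
    bursts = {
        u: detect_bursts(trains[u]) if u in trains else [] for u in ("PD", "LP", "PY")
    }
    cycles = extract_cycles(bursts["PD"])
    if trace is not None:
        cycles = annotate_temperature(cycles, trace)
    return assign_phases(cycles, bursts["PD"], bursts["LP"], bursts["PY"])


@pytest.fixture(scope="session")
def staircase_trace():
    """Default step protocol in the zero-lag (exact staircase) limit."""
    return gen_temperature(TemperatureProtocolSpec(relax_tau=1e-9))


@pytest.fixture(scope="session")
def default_trace():
    """Default step protocol with first-order bath relaxation (tau = 10 s)."""
    return gen_temperature(TemperatureProtocolSpec())
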