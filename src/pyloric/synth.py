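"""Synthetic pyloric-rhythm experiments.

Generates the three ingredients of a temperature-step experiment so the
whole analysis chain can be exercised and validated without recordings:

1. **Temperature protocols** — a staircase of holding temperatures
   (default 11→21 °C in 2 °C steps, 4 min holds) with first-order bath
   relaxation toward each new target.

2. **Triphasic spike trains** — PD/LP/PY bursts laid out cycle by cycle.
   Instantaneous cycle frequency follows the temperature-coefficient law

       f(t) = f11 * q10**((T(t) - 11)/10) + u(t),

   where the optional *jag* term ``u`` obeys the linear relaxation
   ``du/dt = -u/tau_u + gamma * dT/dt``.  With ``gamma < 0`` frequency
   transiently dips while temperature rises and recovers (time constant
   ``tau_u``) once it stabilises — the phenomenological signature seen
   when Ih is blocked.  Burst onset/offset phases come from a per-neuron
   phase table, optionally drifting linearly with temperature, with
   Gaussian jitter applied to burst edges before spikes are placed.

3. **Voltage-clamp traces** — hyperpolarising steps whose current relaxes
   as ``i_instant + delta_i * (1 - exp(-t/tau_h))`` plus white noise, the
   textbook slow-activation profile of Ih.

Every generator takes an explicit seed and is bit-for-bit reproducible.
Ground truth (cycle starts, periods, unjittered phases, true delta_i) is
returned alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bursts import SpikeTrain
from .errors import GenerationError, ParameterError
from .thermal import TemperatureTrace

__all__ = [
    "TemperatureProtocolSpec",
    "GeneratorParams",
    "ClampGenParams",
    "SyntheticExperiment",
    "ClampStep",
    "gen_temperature",
    "gen_spiketrains",
    "gen_clamp_trace",
]

T_REF = 11.0  # reference temperature (degC) for frequency and phase laws

#: Table-1-style phase table under control (saline) conditions at 11 degC.
SALINE_PHASE_TABLE = {
    "PD": (0.0, 0.19),
    "LP": (0.40, 0.66),
    "PY": (0.58, 0.87),
}

#: Phase table with PD off, LP on and LP off advanced, as under Cs+ block.
CS_PHASE_TABLE = {
    "PD": (0.0, 0.12),
    "LP": (0.29, 0.56),
    "PY": (0.60, 0.90),
}


@dataclass(frozen=True)
class TemperatureProtocolSpec:
    """A step protocol of holding temperatures.

    The bath starts at the first target and relaxes exponentially (time
    constant ``relax_tau``) toward each subsequent target, holding each for
    ``hold_duration`` seconds.  ``return_to_start`` appends a final hold
    back at the first target (the descending leg, excluded from the
    steady-state analyses).
    """

    target_temps: tuple[float, ...] = (11.0, 13.0, 15.0, 17.0, 19.0, 21.0)
    hold_duration: float = 240.0
    relax_tau: float = 10.0
    sample_dt: float = 0.1
    return_to_start: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_temps", tuple(float(t) for t in self.target_temps))
        if not self.target_temps:
            raise ParameterError("target_temps must be non-empty")
        if len(self.target_temps) >= 2 and np.any(np.diff(self.target_temps) <= 0):
            raise ParameterError("target_temps must be strictly increasing on the upward leg")
        for name in ("hold_duration", "relax_tau", "sample_dt"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the spike-train generator.

    Defaults describe a control-like preparation (1.2 Hz at 11 degC, Q10
    1.75, saline phase table) with the jag mechanism switched on.  The jag
    gain default is calibrated against the closed-form step response: for a
    2 degC step through a first-order bath (tau 10 s) feeding the jag ODE
    (tau_u 30 s), the transient peaks at about 0.58 * gamma * dT, so
    gamma = -0.12 Hz/degC yields the ~0.1 Hz frequency dips with ~30 s
    recovery that characterise transitions when Ih is blocked (gamma = -0.05
    would peak at under 0.02 Hz once the steady-state Q10 rise is netted
    out, invisible to the 0.002 Hz/cycle criterion).  Set ``jag_gain=0``
    for smooth, monotone responses.  Use :meth:`saline`, :meth:`cesium` and
    :meth:`cesium_ptx` for condition presets.
    """

    f11: float = 1.2  # steady-state cycle frequency at 11 degC, Hz
    q10: float = 1.75  # temperature coefficient of frequency
    jag_gain: float = -0.12  # gamma, Hz per degC; 0 disables jags
    jag_tau: float = 30.0  # recovery time constant of the jag term, s
    phase_table: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(SALINE_PHASE_TABLE)
    )
    phase_slopes: dict[str, tuple[float, float]] = field(default_factory=dict)
    spikes_per_burst: dict[str, int] = field(
        default_factory=lambda: {"PD": 5, "LP": 6, "PY": 6}
    )
    phase_jitter_sd: float = 0.01  # SD of burst-edge jitter, fraction of period
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f11 <= 0:
            raise ParameterError("f11 must be positive")
        if self.q10 <= 0:
            raise ParameterError("q10 must be positive")
        if self.jag_tau <= 0:
            raise ParameterError("jag_tau must be positive")
        if self.phase_jitter_sd < 0:
            raise ParameterError("phase_jitter_sd must be non-negative")
        table = dict(self.phase_table)
        if set(table) != {"PD", "LP", "PY"}:
            raise ParameterError("phase_table must have entries for PD, LP and PY")
        if table["PD"][0] != 0.0:
            raise ParameterError("PD onset phase is fixed at 0")
        for unit, (on, off) in table.items():
            if not (0.0 <= on < off <= 1.0):
                raise ParameterError(
                    f"{unit} phase table must satisfy 0 <= onset < offset <= 1"
                )
        for unit, n in self.spikes_per_burst.items():
            if n < 2:
                raise ParameterError(f"{unit} spikes_per_burst must be >= 2")

    @classmethod
    def saline(cls, **overrides) -> "GeneratorParams":
        """Control preparation: 1.2 Hz at 11 degC, Q10 1.75, no jags."""
        defaults = dict(f11=1.2, q10=1.75, jag_gain=0.0,
                        phase_table=dict(SALINE_PHASE_TABLE))
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def cesium(cls, **overrides) -> "GeneratorParams":
        """Ih-blocked preparation: slower (0.9 Hz), Q10 1.35, jags on,
        advanced PD off / LP on / LP off phases."""
        defaults = dict(f11=0.9, q10=1.35, jag_gain=-0.12,
                        phase_table=dict(CS_PHASE_TABLE))
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def cesium_ptx(cls, **overrides) -> "GeneratorParams":
        """Ih blocked with the pacemaker isolated by picrotoxin: the
        steady-state temperature sensitivity recovers toward control while
        the transition jags persist."""
        defaults = dict(f11=0.9, q10=1.75, jag_gain=-0.12,
                        phase_table=dict(CS_PHASE_TABLE))
        defaults.update(overrides)
        return cls(**defaults)


@dataclass(frozen=True)
class ClampGenParams:
    """Parameters of the voltage-clamp trace generator (one cell)."""

    hold_voltage: float = -50.0  # mV
    step_voltages: tuple[float, ...] = (-100.0, -110.0, -120.0)
    step_duration: float = 12.0  # s
    i_instant: float = -2.0  # instantaneous (leak) current per step, nA
    delta_i: float = 1.5  # Ih amplitude (ground truth), nA
    tau_h: float = 2.0  # Ih activation time constant, s
    noise_sd: float = 0.0  # nA
    sample_dt: float = 0.001  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step_duration <= 0:
            raise ParameterError("step_duration must be positive")
        if self.tau_h <= 0:
            raise ParameterError("tau_h must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        if self.sample_dt <= 0:
            raise ParameterError("sample_dt must be positive")


@dataclass(frozen=True)
class ClampStep:
    """One hyperpolarising step: its current trace and metadata."""

    step_voltage: float  # mV
    times: np.ndarray  # s from step onset
    current: np.ndarray  # nA
    temperature: float = 11.0
    condition: str = "saline"
    true_delta_i: float | None = None  # ground truth when synthetic


@dataclass
class SyntheticExperiment:
    """Generated spike trains plus the ground truth used to make them."""

    trains: dict[str, SpikeTrain]
    cycles: pd.DataFrame  # ground truth: t_start, period_s, freq_hz, temp_c, phases
    temperature: TemperatureTrace
    params: GeneratorParams


def gen_temperature(spec: TemperatureProtocolSpec) -> TemperatureTrace:
    """Realise a step protocol as a sampled temperature trace.

    Within each hold the trace relaxes exponentially from its current value
    toward the hold's target with time constant ``relax_tau``.  The trace
    starts exactly at the first target.
    """
    targets = list(spec.target_temps)
    if spec.return_to_start and len(targets) > 1:
        targets = targets + [targets[0]]
    dt = spec.sample_dt
    n_per_hold = int(round(spec.hold_duration / dt))
    if n_per_hold < 1:
        raise ParameterError("hold_duration must cover at least one sample")
    # sample k of a hold has relaxed for (k+1)*dt since the step change,
    # so the zero-lag limit is an exact staircase
    t_local = np.arange(1, n_per_hold + 1) * dt
    decay = np.exp(-t_local / spec.relax_tau)

    temps = np.empty(n_per_hold * len(targets))
    current = targets[0]
    for k, target in enumerate(targets):
        seg = target + (current - target) * decay
        temps[k * n_per_hold : (k + 1) * n_per_hold] = seg
        current = seg[-1]
    times = np.arange(temps.size) * dt
    return TemperatureTrace(times=times, temps=temps)


def _phases_at(params: GeneratorParams, temp: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-unit onset/offset phase arrays after linear temperature drift."""
    out = {}
    dT = temp - T_REF
    for unit, (on0, off0) in params.phase_table.items():
        s_on, s_off = params.phase_slopes.get(unit, (0.0, 0.0))
        out[unit] = (on0 + s_on * dT, off0 + s_off * dT)
    return out


def gen_spiketrains(
    params: GeneratorParams, temp: TemperatureTrace
) -> SyntheticExperiment:
    """Generate triphasic PD/LP/PY spike trains over a temperature trace.

    The instantaneous frequency law and jag ODE are integrated by explicit
    Euler on the temperature sample grid; cycle starts are the (linearly
    interpolated) times where the accumulated phase crosses successive
    integers.  Within a cycle of period P starting at t0, each unit bursts
    between its onset and offset phases (evaluated at the cycle-start
    temperature), with independent Gaussian jitter of SD
    ``phase_jitter_sd * P`` on each burst edge and ``spikes_per_burst``
    evenly spaced spikes per burst.

    The returned ground-truth table records every cycle's start, period,
    frequency, temperature and *unjittered* phases.
    """
    rng = np.random.default_rng(params.seed)
    times = temp.times
    temps = temp.temps
    if times.size < 2:
        raise ParameterError("temperature trace must cover the simulation interval")
    dt = np.diff(times)

    # jag ODE, explicit Euler on the sample grid: u += -u*dt/tau + gamma*dT
    u = np.zeros_like(temps)
    if params.jag_gain != 0.0:
        dT = np.diff(temps)
        decay = 1.0 - dt / params.jag_tau
        for i in range(temps.size - 1):
            u[i + 1] = u[i] * decay[i] + params.jag_gain * dT[i]

    f = params.f11 * params.q10 ** ((temps - T_REF) / 10.0) + u
    if np.any(f <= 0):
        raise GenerationError(
            "jag transient drove instantaneous frequency <= 0; "
            "use a smaller |jag_gain| or slower temperature steps"
        )

    # accumulated phase; integer crossings mark cycle starts
    phase = np.concatenate(([0.0], np.cumsum(f[:-1] * dt)))
    n_cycles_total = int(np.floor(phase[-1]))
    ks = np.arange(n_cycles_total + 1, dtype=float)  # crossings 0..N
    idx = np.searchsorted(phase, ks, side="right") - 1
    idx = np.clip(idx, 0, phase.size - 2)
    frac = (ks - phase[idx]) / (phase[idx + 1] - phase[idx])
    starts = times[idx] + frac * dt[idx]
    starts[0] = times[0]
    if starts.size < 2:
        raise GenerationError("temperature trace too short to produce a full cycle")

    t_start = starts[:-1]
    period = np.diff(starts)
    temp_at_start = np.interp(t_start, times, temps)
    tables = _phases_at(params, temp_at_start)
    for unit, (on, off) in tables.items():
        bad = np.flatnonzero((on < 0) | (on >= off))
        if bad.size:
            raise GenerationError(
                f"phase drift made {unit} onset/offset inconsistent at cycle {bad[0]}"
            )

    gt = pd.DataFrame(
        {
            "t_start": t_start,
            "period_s": period,
            "freq_hz": 1.0 / period,
            "temp_c": temp_at_start,
            "pd_off": tables["PD"][1],
            "lp_on": tables["LP"][0],
            "lp_off": tables["LP"][1],
            "py_on": tables["PY"][0],
            "py_off": tables["PY"][1],
        }
    )

    trains: dict[str, SpikeTrain] = {}
    for unit in ("PD", "LP", "PY"):
        on_phase, off_phase = tables[unit]
        on_t = t_start + on_phase * period
        off_t = t_start + off_phase * period
        if params.phase_jitter_sd > 0:
            sd = params.phase_jitter_sd * period
            # clip at 0 so jitter cannot push the opening burst before t=0
            on_t = np.maximum(on_t + rng.normal(0.0, 1.0, on_t.size) * sd, 0.0)
            off_t = off_t + rng.normal(0.0, 1.0, off_t.size) * sd
        if np.any(off_t <= on_t):
            raise GenerationError(
                f"burst-edge jitter collapsed a {unit} burst; reduce phase_jitter_sd"
            )
        n = params.spikes_per_burst[unit]
        ramp = np.linspace(0.0, 1.0, n)
        spikes = (on_t[:, None] + ramp[None, :] * (off_t - on_t)[:, None]).ravel()
        if np.any(np.diff(spikes) <= 0):
            raise GenerationError(
                f"{unit} bursts overlap after jitter; reduce phase_jitter_sd"
            )
        trains[unit] = SpikeTrain(unit=unit, times=spikes)

    return SyntheticExperiment(trains=trains, cycles=gt, temperature=temp, params=params)


def gen_clamp_trace(params: ClampGenParams) -> list[ClampStep]:
    """Generate one cell's hyperpolarising-step current traces.

    Per step the clamp current is
    ``i_instant + delta_i * (1 - exp(-t / tau_h))`` plus Gaussian noise —
    an instantaneous (leak) jump followed by the slow development of Ih.
    The ground-truth ``delta_i`` is recorded on every step.
    """
    rng = np.random.default_rng(params.seed)
    t = np.arange(0.0, params.step_duration + 0.5 * params.sample_dt, params.sample_dt)
    steps = []
    for v in params.step_voltages:
        current = params.i_instant + params.delta_i * (1.0 - np.exp(-t / params.tau_h))
        if params.noise_sd > 0:
            current = current + rng.normal(0.0, params.noise_sd, t.size)
        steps.append(
            ClampStep(
                step_voltage=float(v),
                times=t.copy(),
                current=current,
                true_delta_i=params.delta_i,
            )
        )
    return steps
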