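# pyloric

Analysis toolkit for the temperature response of the crustacean pyloric
rhythm, with a focus on the role of the hyperpolarisation-activated inward
current (Ih).

The pyloric central pattern generator of the stomatogastric ganglion
produces a triphasic motor pattern — pacemaker-driven PD bursts followed by
LP, then PY. As the bath warms from 11 to 21 °C the rhythm speeds up while
the relative timing (phase) of each neuron stays nearly constant; blocking
Ih with Cs⁺ slows the rhythm, flattens its temperature sensitivity,
advances PD/LP phases, and produces "jags" — transient episodes in which
frequency *falls* while temperature is still rising, then recovers once it
stabilises.

`pyloric` implements the full analysis chain for such experiments, plus a
synthetic experiment generator so every stage is testable without
recordings:

| module | what it does |
|---|---|
| `pyloric.synth` | temperature step protocols, triphasic PD/LP/PY spike trains (Q10 frequency law + jag dynamics + phase drift), voltage-clamp Ih traces; all seeded, with ground truth |
| `pyloric.bursts` | burst detection (≥ 2 spikes, 200 ms inter-burst interval), PD-to-PD cycle extraction, phase assignment, phase summaries, period-matched sampling across conditions |
| `pyloric.thermal` | holding-temperature frequency means, Q10 fits, moving-average jag classification (0.01 °C and 0.002 Hz per-cycle criteria), phase-vs-temperature slope fits |
| `pyloric.clamp` | Ih amplitude ΔI from hyperpolarising steps (initial vs steady-state window means), percent block across paired cells |
| `pyloric.stats` | Shapiro-Wilk-gated paired t / Wilcoxon tests, repeated-measures ANOVA + Tukey HSD, Bonferroni, Pearson, deterministic report bundles |

The core quantities, in standard notation: cycle period `P` (first PD spike
to first PD spike), frequency `f = 1/P`, phase `φ_X = (t_X − t_start)/P`,
temperature coefficient `Q10` from `f(T) = f_ref · Q10^((T−11)/10)`, and
Ih amplitude `ΔI = |I_steady − I_initial|` during a 12 s hyperpolarising
step.

## Worked example

Simulate an Ih-blocked-like preparation over the default step protocol
(11→21 °C, 2 °C steps, 4 min holds) and run the whole pipeline:

```python
from pyloric import (
    GeneratorParams, TemperatureProtocolSpec, annotate_temperature, classify_jags,
    detect_bursts, extract_cycles, assign_phases, fit_q10, gen_spiketrains,
    gen_temperature, holding_means, phase_summary,
)

trace = gen_temperature(TemperatureProtocolSpec())          # 11 -> 21 degC staircase
exp = gen_spiketrains(GeneratorParams.cesium(seed=1), trace)

bursts = {u: detect_bursts(t) for u, t in exp.trains.items()}
cycles = annotate_temperature(extract_cycles(bursts["PD"]), trace)
cycles = assign_phases(cycles, bursts["PD"], bursts["LP"], bursts["PY"])

summary = holding_means(cycles, [11, 13, 15, 17, 19, 21])
q10, f_ref = fit_q10(summary)
jags = classify_jags(cycles)
phases = phase_summary(cycles)
```

Output:

```text
cycles analysed:        1473
f at 11 degC:           0.900 Hz
f at 21 degC:           1.193 Hz
fitted Q10:             1.335
PD off / LP on phases:  0.121 / 0.290
PD off -> LP on delay:  0.170
P(freq falls | T rising):  0.433
P(freq rises | T stable):  0.089
```

The recovered Q10 (1.335) matches the generator's blocked-condition value
of 1.35 up to the residual jag transients inside the holding windows; the
extracted phases reproduce the blocked-condition phase table (PD off 0.12,
LP on 0.29, delay 0.17); and the jag proportions show the signature
non-monotonicity — 43% of temperature-rising cycles had falling frequency,
versus 0% for the same seed with jags disabled (`GeneratorParams.saline()`).

The same workflow is available from the shell:

```sh
pyloric simulate --config config.toml --seed 1 --outdir sim/
pyloric analyze --spikes sim/spikes.csv --temperature sim/temperature.csv --out results/
pyloric analyze-clamp --clamp sim/clamp.csv --out results/
pyloric report --in results/ --out report/
```

See `docs/methods.md` for the models, estimator definitions, window and
threshold choices, and the generator's calibration.

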