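# Methods

This note documents the models, estimators and design choices behind the
`pyloric` package: what each stage computes, the assumptions it makes, and
what the synthetic data generator does and does not emulate.

## The system being analysed

The pyloric rhythm of the crustacean stomatogastric ganglion is a triphasic
motor pattern: the pacemaker kernel (AB plus two PD neurons) bursts first,
followed by LP, then PY. Two properties of this rhythm under temperature
change are the package's focus:

* **frequency scaling** — cycle frequency rises roughly exponentially with
  temperature, summarised by the temperature coefficient
  `f(T) = f_ref · Q10^((T − T_ref)/10)` with `T_ref = 11 °C`;
* **phase constancy** — the onset/offset times of each neuron, expressed as
  fractions of the cycle period, stay approximately fixed as the period
  shrinks.

Blocking the hyperpolarisation-activated inward current Ih (e.g. with
extracellular Cs⁺) slows the rhythm, lowers its Q10, advances PD offset and
LP onset/offset, and introduces *jags*: transient non-monotonic episodes in
which frequency falls while temperature is still rising and recovers over
tens of seconds once it stabilises.

## Burst, cycle and phase extraction (`pyloric.bursts`)

A burst is two or more consecutive spikes of one unit in which every
inter-spike interval is strictly less than 200 ms; an interval of 200 ms or
more closes the burst. The same rule is applied to PD, LP and PY (the
boundary convention — a gap of exactly 200 ms splits — is a deliberate
strict-inequality choice, and both the gap and the minimum spike count are
parameters).

A cycle runs from the first spike of one PD burst to the first spike of the
next; period `P` is that interval and frequency `f = 1/P`. Phases are
latencies from the cycle start to a unit's burst onset (first spike) or
offset (last spike), divided by `P`. PD onset is identically zero. An LP or
PY burst belongs to the cycle in which its first spike falls; offsets that
extend past the cycle end are **kept as raw phases > 1** and flagged, never
reduced mod 1 — wrapping would corrupt means of offsets near 1 (PY offsets
sit around 0.87 with substantial spread, so wrapped cycles are normal).
Cycles lacking an LP or PY burst carry missing values, never zeros. If two
bursts of a unit start inside one cycle the earlier is used and a warning
logged.

Cycle-local temperature is the time-average of the linearly interpolated
temperature trace over the cycle; the cycle's min/max temperature is stored
alongside. Period matching across conditions (used to ask whether a phase
advance survives at matched period) is greedy nearest-period one-to-one
matching with a 2% relative tolerance — both unspecified in the original
protocol and therefore explicit parameters here.

## Temperature-aligned analyses (`pyloric.thermal`)

**Holding means.** For each protocol target temperature, the mean and SD of
cycle frequency are taken over cycles whose *entire* temperature excursion
(min and max over the cycle) lies within 0.3 °C of the target. This
implements "times when the preparation was within 0.3 °C of target" at
cycle resolution: a cycle that straddles a step change belongs to no
holding window. (Assigning by cycle-mean temperature instead would admit
straddling cycles whose frequency mixes two temperatures and bias the means
of staircase-like protocols.)

**Q10.** Ordinary least squares of `log f` on `(T − 11)/10` over all
non-missing holding means; `Q10 = exp(slope)`. With exactly two points this
reduces to the endpoint formula `(f2/f1)^(10/(T2−T1))`.

**Jag classification.** Per-cycle frequency and temperature series are
smoothed with centered moving averages over 30 and 10 cycles respectively
(edge-truncated symmetrically; an even window `w` acts as the centered odd
window `w+1` in the interior — the truncation radius is
`min(w//2, i, n−1−i)`). First differences of the smoothed series between
consecutive cycles are thresholded: temperature is *increasing* when its
smoothed change exceeds 0.01 °C/cycle, else *stable*; frequency is
*decreasing*/*increasing* when its smoothed change exceeds 0.002 Hz/cycle in
that direction, else stable. Two proportions summarise non-monotonicity:
the fraction of temperature-increasing cycles with decreasing frequency,
and the fraction of temperature-stable cycles with increasing frequency.
Empty denominator classes yield missing values, not zeros. Centered (rather
than trailing) smoothing was chosen so the temperature and frequency labels
carry no relative lag; the definition of "change per cycle" as the first
difference of the smoothed series is the main replication risk for any
quantitative comparison of these proportions.

**Phase constancy.** For each phase reference point (PD off, LP on, LP off,
PY on, PY off), the per-holding-temperature mean phase is regressed on
temperature by OLS; the slope times 10 is the change per 10 °C, negative
values being advances. Slopes across preparations are tested against zero
with the normality-gated one-sample machinery and Bonferroni-adjusted over
the family of 10 tests (5 phases × 2 conditions).

## Ih quantification (`pyloric.clamp`)

During a sustained hyperpolarising step from −50 mV (nominally 12 s, −100
to −120 mV in −10 mV increments), Ih develops slowly, so the holding
current drifts from an instantaneous level toward a steady state. The
estimator is the difference of two window means:
`ΔI = |mean(last 1 s) − mean([20, 80] ms)|`.

The window choice trades off two biases: the initial window must start late
enough to skip the capacitive/settling transient (a few ms to ~10 ms for
typical electrode RC) but end early enough that Ih (activation time
constant τ_h ≈ 2 s) has barely begun. For an exponential with amplitude Δ
the window-mean estimate is `Δ·[m(steady) − m(initial)]` where `m(a,b) =
1 − τ(e^(−a/τ) − e^(−b/τ))/(b−a)`; with the default windows this gives
0.97Δ at τ_h = 2 s (2.8% low) and stays within [0.90, 1.0]·Δ over
τ_h ∈ [0.5, 3] s. The bias grows as activation gets faster — no fixed-window
difference estimator can avoid that — and the underestimate shrinks
monotonically as τ_h increases over the physiological range. No leak
subtraction or P/N protocol is applied; a linear baseline drift of rate `d`
biases ΔI by `d` times the ~11.4 s separation of the window centres, which
is why the drift sensitivity is documented by a dedicated test rather than
corrected for.

Percent block is computed per cell as `100·(1 − ΔI_blocked/ΔI_control)`
and then averaged across cells (so the mean of ratios, not the ratio of
means); cells whose control amplitude does not exceed a caller-set noise
floor are excluded, and negative reductions (potentiation) are allowed and
flagged.

## Gated statistics (`pyloric.stats`)

Paired comparisons test the differences for normality (Shapiro-Wilk,
α = 0.05 — the α is a package choice) and route to a two-sided paired
Student's t-test when normal, otherwise a two-sided Wilcoxon signed-rank
test with zero differences split between signs (so identical pairs yield
statistic 0, p = 1 rather than an error). Zero-variance differences are
degenerate and routed to the non-parametric branch with a warning. All
tests are two-sided. Calibration: under a normal paired null (n = 21) the
gated procedure's type-I error stays at the nominal 5% level (bounded by
7% in the acceptance suite at 2000 replicates).

Three-condition within-subject designs use one-way repeated-measures ANOVA
(statsmodels `AnovaRM`; with two conditions this is algebraically the
paired t-test, F = t²). Post-hoc Tukey HSD runs only after a significant
omnibus F and operates on subject-centered values so its error term
reflects within-subject variability, consistent with the omnibus; the
pooled error df (N·k − k) slightly exceeds the strict RM df, a mild
liberality accepted for simplicity. Bonferroni adjustment is
`min(1, m·p)`. `build_report` assembles summaries into deterministic JSON
and Markdown (identical inputs give byte-identical output).

## The synthetic experiment generator (`pyloric.synth`)

The generator emulates the structure the analysis assumes, not membrane
biophysics.

**Temperature protocol.** Targets 11→21 °C in 2 °C steps, 240 s holds,
sampled at 0.1 s. The bath relaxes toward each new target first-order with
τ = 10 s (chosen to make each 2 °C transition take a few tens of seconds,
the order of magnitude of the recorded ramps; the true bath dynamics are
not published, so τ is a parameter; τ → 0 gives an exact staircase).

**Spike trains.** Instantaneous frequency is
`f(t) = f11·q10^((T(t)−11)/10) + u(t)` with the jag term
`du/dt = −u/τ_u + γ·dT/dt`, integrated by explicit Euler on the 0.1 s
temperature grid (adequate since τ_u = 30 s ≫ dt). Cycle starts are the
linearly interpolated integer crossings of the accumulated phase `∫f dt`.
Within each cycle, burst onset/offset phases come from a per-neuron phase
table (control defaults: PD [0, 0.19], LP [0.40, 0.66], PY [0.58, 0.87];
an Ih-blocked preset advances PD off/LP on/LP off), optionally drifting
linearly with temperature; Gaussian jitter of SD 0.01·P is applied to burst
edges (not to individual spikes, so phase-extraction error remains
interpretable), and spikes are placed evenly within each burst (intra-burst
spike statistics are not modelled). Identical seeds give bit-identical
output.

**Jag calibration.** The jag term is a phenomenological stand-in, not a
mechanistic model of the IA/Ih interaction. For a 2 °C step through the
τ = 10 s bath, the transient peaks at ≈ 0.58·γ·ΔT (two-exponential closed
form) and the steady-state Q10 rise nets against it, so the default gain
γ = −0.12 Hz/°C is what actually produces the target behaviour of ~0.1 Hz
dips with ~30 s recovery under Ih-blocked-like parameters (f11 = 0.9 Hz,
q10 = 1.35). Under control-like parameters (q10 = 1.75) the steady-state
rise of ~0.084 Hz/°C dominates and no plausible γ yields a visible dip —
which is the point: jags are a property of the blocked condition, and the
`saline()` preset sets γ = 0. Note the moving-average criterion can only
flag dips exceeding ~0.06 Hz per 30 cycles, so under-calibrated jag gains
are silently invisible to the classifier.

**Clamp traces.** Per step, `I(t) = i_instant + Δ·(1 − e^(−t/τ_h))` plus
white noise, sampled at 1 kHz; no capacitive transient is synthesised, so
the initial-window bias measured on synthetic data reflects Ih activation
only.

**What passing tests do not show.** The generator has no spike-detection or
sorting errors, no missing or extra bursts, no electrode drift, no
solution-exchange transients, and its jag dynamics are linear; agreement of
the pipeline with the generator's ground truth validates the estimators'
algebra and calibration, not their robustness to real recording artefacts.

## Problem sizes and numerical choices

Simulation-based checks use the full six-hold protocol (1440 s, ~1500–2500
cycles per run): 100 seeded runs for jitter recovery of Q10 (|error| < 0.05
in ≥ 95% of runs; jitter-free recovery is exact to 10⁻⁶ in the zero-lag
staircase limit, where every holding cycle sits exactly at its target),
20 matched seed pairs for jag directionality, 1000 random trains against
the brute-force burst oracle, 100 seeds for the ΔI noise spread, and 2000
replicates for the type-I calibration. Ties and degenerate inputs: gaps of
exactly 200 ms split bursts; jag label thresholds are strict inequalities
and the in-between band is "stable"; empty denominator classes and
all-missing phases propagate as missing values with warnings, never as
zeros.
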