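"""Burst detection, cycle extraction, phase assignment and period matching."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pyloric import (
    Burst,
    DataError,
    SpikeTrain,
    assign_phases,
    detect_bursts,
    extract_cycles,
    match_periods,
    phase_summary,
)
from conftest import run_phase_pipeline, triphasic_trains


def brute_force_bursts(times, min_spikes=2, split_gap=0.2):
    """Independent oracle: linear scan over all maximal runs."""
    groups, current = [], []
    for t in times:
        if current and t - current[-1] >= split_gap:
            groups.append(current)
            current = []
        current.append(t)
    if current:
        groups.append(current)
    return [(g[0], g[-1], len(g)) for g in groups if len(g) >= min_spikes]


class TestDetectBursts:
    def test_two_bursts_from_gap_rule(self):
        train = SpikeTrain("PD", np.array([0.0, 0.05, 0.10, 0.50, 0.55]))
        bursts = detect_bursts(train)
        assert [(b.t_first, b.t_last, b.n_spikes) for b in bursts] == [
            (0.0, 0.10, 3),
            (0.50, 0.55, 2),
        ]

    def test_singletons_discarded(self):
        train = SpikeTrain("PD", np.array([0.0, 0.30, 0.60]))
        assert detect_bursts(train) == []

    def test_gaps_just_under_threshold_merge(self):
        train = SpikeTrain("PD", np.array([0.0, 0.19999, 0.39998]))
        bursts = detect_bursts(train)
        assert len(bursts) == 1 and bursts[0].n_spikes == 3

    def test_gap_exactly_at_threshold_splits(self):
        train = SpikeTrain("PD", np.array([0.0, 0.05, 0.25, 0.30]))
        assert len(detect_bursts(train)) == 2

    def test_empty_train_is_empty_list(self):
        assert detect_bursts(SpikeTrain("LP", np.array([]))) == []

    def test_unsorted_rejected(self):
        with pytest.raises(DataError):
            SpikeTrain("PD", np.array([0.3, 0.1]))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        gaps=st.lists(
            st.floats(min_value=1e-4, max_value=0.6, allow_nan=False), max_size=199
        )
    )
    def test_matches_brute_force_oracle(self, gaps):
        times = np.cumsum(np.asarray([0.0] + gaps))
        got = detect_bursts(SpikeTrain("PY", times))
        expected = brute_force_bursts(times)
        assert [(b.t_first, b.t_last, b.n_spikes) for b in got] == expected


class TestExtractCycles:
    def test_period_and_frequency_from_burst_starts(self):
        bursts = [Burst("PD", 0.0, 0.1, 3), Burst("PD", 1 / 1.2, 1 / 1.2 + 0.1, 3)]
        cycles = extract_cycles(bursts)
        assert len(cycles) == 1
        assert cycles["freq_hz"].iloc[0] == pytest.approx(1.2)

    def test_uniform_train(self):
        bursts = [Burst("PD", float(k), k + 0.2, 4) for k in range(3)]
        cycles = extract_cycles(bursts)
        assert list(cycles["period_s"]) == [1.0, 1.0]
        assert list(cycles["freq_hz"]) == [1.0, 1.0]

    def test_reciprocal_of_differences(self):
        bursts = [Burst("PD", t, t + 0.1, 2) for t in (0.0, 0.5, 1.5)]
        cycles = extract_cycles(bursts)
        np.testing.assert_allclose(cycles["freq_hz"], [2.0, 1.0])

    def test_frequency_period_identity(self):
        rng = np.random.default_rng(0)
        starts = np.cumsum(rng.uniform(0.5, 1.5, 50))
        bursts = [Burst("PD", float(t), float(t) + 0.1, 2) for t in starts]
        cycles = extract_cycles(bursts)
        np.testing.assert_array_equal(
            cycles["freq_hz"], 1.0 / cycles["period_s"]
        )  # frequency is exactly the reciprocal period
        np.testing.assert_allclose(cycles["freq_hz"] * cycles["period_s"], 1.0, rtol=1e-15)

    def test_too_few_bursts_empty_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            cycles = extract_cycles([Burst("PD", 0.0, 0.1, 2)])
        assert cycles.empty
        assert "PD bursts" in caplog.text


class TestAssignPhases:
    def test_textbook_cycle(self):
        pd_b = [Burst("PD", 10.0, 10.19, 5), Burst("PD", 11.0, 11.19, 5)]
        lp_b = [Burst("LP", 10.40, 10.66, 6)]
        cycles = assign_phases(extract_cycles(pd_b), pd_b, lp_b, [])
        row = cycles.iloc[0]
        assert row["pd_off"] == pytest.approx(0.19)
        assert row["lp_on"] == pytest.approx(0.40)
        assert row["lp_off"] == pytest.approx(0.66)
        assert np.isnan(row["py_on"]) and np.isnan(row["py_off"])

    def test_coincident_lp_onset_is_zero(self):
        pd_b = [Burst("PD", 10.0, 10.19, 5), Burst("PD", 11.0, 11.19, 5)]
        lp_b = [Burst("LP", 10.0, 10.3, 4)]
        cycles = assign_phases(extract_cycles(pd_b), pd_b, lp_b, [])
        assert cycles["lp_on"].iloc[0] == 0.0

    def test_offset_past_cycle_end_kept_raw_and_flagged(self):
        pd_b = [Burst("PD", 10.0, 10.19, 5), Burst("PD", 11.0, 11.19, 5)]
        py_b = [Burst("PY", 10.58, 11.05, 6)]
        cycles = assign_phases(extract_cycles(pd_b), pd_b, [], py_b)
        row = cycles.iloc[0]
        assert row["py_on"] == pytest.approx(0.58)
        assert row["py_off"] == pytest.approx(1.05)
        assert bool(row["py_wrapped"])

    def test_two_lp_bursts_warns_and_uses_earlier(self, caplog):
        pd_b = [Burst("PD", 0.0, 0.19, 5), Burst("PD", 1.0, 1.19, 5)]
        lp_b = [Burst("LP", 0.40, 0.55, 4), Burst("LP", 0.70, 0.85, 4)]
        with caplog.at_level(logging.WARNING):
            cycles = assign_phases(extract_cycles(pd_b), pd_b, lp_b, [])
        assert cycles["lp_on"].iloc[0] == pytest.approx(0.40)
        assert "LP bursts" in caplog.text


class TestPhaseSummary:
    def test_delay_between_pd_off_and_lp_on(self):
        trains = triphasic_trains(20, 1.0)
        cycles = run_phase_pipeline(trains)
        summary = phase_summary(cycles)
        assert summary.delay_pd_off_lp_on == pytest.approx(0.21)

    def test_delay_with_advanced_phases(self):
        trains = triphasic_trains(20, 1.0, pd_span=(0.0, 0.12), lp_span=(0.29, 0.56))
        summary = phase_summary(run_phase_pipeline(trains))
        assert summary.delay_pd_off_lp_on == pytest.approx(0.17)

    def test_pd_burst_duration_ms(self):
        trains = triphasic_trains(5, 1.0, pd_span=(0.0, 0.164))
        summary = phase_summary(run_phase_pipeline(trains))
        assert summary.pd_duration_ms == pytest.approx(164.0)

    def test_duty_cycles(self):
        summary = phase_summary(run_phase_pipeline(triphasic_trains(10, 1.0)))
        assert summary.duty_cycle["LP"] == pytest.approx(0.66 - 0.40)
        assert summary.duty_cycle["PD"] == pytest.approx(0.19)

    def test_permutation_invariance(self):
        cycles = run_phase_pipeline(triphasic_trains(15, 0.9))
        shuffled = cycles.sample(frac=1.0, random_state=3)
        a, b = phase_summary(cycles), phase_summary(shuffled)
        for key in a.mean:
            assert a.mean[key] == pytest.approx(b.mean[key], rel=1e-12)
        assert a.delay_pd_off_lp_on == pytest.approx(b.delay_pd_off_lp_on, rel=1e-12)


class TestMatchPeriods:
    def test_self_match_zero_latency(self):
        cycles = run_phase_pipeline(triphasic_trains(10, 1.0))
        pairs = match_periods(cycles, cycles)
        assert len(pairs) == len(cycles)
        np.testing.assert_allclose(pairs["lp_on_latency_diff_ms"], 0.0, atol=1e-9)

    def test_within_tolerance_accepted_nearest_first(self):
        ref = run_phase_pipeline(triphasic_trains(1, 1.0))
        other_a = run_phase_pipeline(triphasic_trains(1, 1.015))
        other_b = run_phase_pipeline(triphasic_trains(1, 1.300))
        import pandas as pd

        other = pd.concat([other_a, other_b], ignore_index=True)
        pairs = match_periods(ref, other)
        assert len(pairs) == 1
        assert pairs["period_other_s"].iloc[0] == pytest.approx(1.015)

    def test_boundary_just_outside_tolerance_rejected(self):
        ref = run_phase_pipeline(triphasic_trains(1, 1.0))
        other = run_phase_pipeline(triphasic_trains(1, 1.021))
        assert match_periods(ref, other).empty

    def test_latency_difference_reflects_phase_advance(self):
        # LP fires 110 ms earlier at matched 1 s period (0.40 -> 0.29)
        ref = run_phase_pipeline(triphasic_trains(5, 1.0))
        adv = run_phase_pipeline(
            triphasic_trains(5, 1.0, pd_span=(0.0, 0.12), lp_span=(0.29, 0.56))
        )
        pairs = match_periods(ref, adv)
        np.testing.assert_allclose(pairs["lp_on_latency_diff_ms"], -110.0, atol=1e-6)
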