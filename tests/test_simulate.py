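"""Simulator physics: mass balance, reservoir accounting, limiting cases."""

import numpy as np
import pytest

import reflectsim as rs
from reflectsim.simulate import mass_balance_residual, steady_state_true_re


def short_schedule(frac=1.0, duration=600.0):
    return rs.TargetSchedule(steps=((frac, duration),))


class TestTraceShape:
    def test_full_experiment_sample_and_breath_counts(self, full_sim_long):
        assert len(full_sim_long.trace) == 96_000
        assert full_sim_long.n_breaths == 1600
        assert full_sim_long.status == "completed"

    def test_identical_seeds_bit_identical(self, vent_long, iso):
        s = short_schedule()
        a = rs.simulate_experiment(vent_long, iso, s, seed=42)
        b = rs.simulate_experiment(vent_long, iso, s, seed=42)
        assert np.array_equal(a.trace.agent_volpct, b.trace.agent_volpct)
        assert np.array_equal(a.trace.co2_mmhg, b.trace.co2_mmhg)
        assert a.device_log.equals(b.device_log)

    def test_different_seeds_differ(self, vent_long, iso):
        s = short_schedule()
        a = rs.simulate_experiment(vent_long, iso, s, seed=1)
        b = rs.simulate_experiment(vent_long, iso, s, seed=2)
        assert not np.array_equal(a.trace.agent_volpct, b.trace.agent_volpct)


class TestConservation:
    def test_mass_balance_closes(self, full_sim_long):
        assert mass_balance_residual(full_sim_long) < 1e-9

    def test_reservoir_decrement_times_f_equals_injected(self, full_sim_long, iso):
        injected = full_sim_long.ground_truth["injected_ml"].sum()
        decrement = (
            full_sim_long.initial_state.reservoir_ml - full_sim_long.final_state.reservoir_ml
        )
        assert decrement * iso.vapour_factor_f == pytest.approx(injected, rel=1e-12)

    def test_reservoir_non_increasing(self, full_sim_long):
        res = full_sim_long.ground_truth["reservoir_ml"].to_numpy()
        assert np.all(np.diff(res) <= 1e-12)


class TestLimitingCases:
    def test_disabled_injector_null(self, vent_long, iso):
        inj = rs.InjectorParams(vapour_rate_mls=0.0)
        r = rs.simulate_experiment(
            vent_long, iso, short_schedule(), injector=inj, seed=3, noise_sd=0.01
        )
        # agent channel is measurement noise only; reservoir untouched
        assert np.abs(r.trace.agent_volpct).max() < 0.08  # ~6 sigma of 0.01 noise
        assert r.final_state.reservoir_ml == r.initial_state.reservoir_ml
        assert r.ground_truth["injected_ml"].sum() == 0.0

    def test_perfect_reflection_limit(self, vent_long, iso):
        refl = rs.ReflectorParams(base_efficiency=1.0, capacity_per_breath_ml=1e9)
        r = rs.simulate_experiment(
            vent_long,
            iso,
            short_schedule(1.0, 1200.0),
            reflector=refl,
            seed=4,
            noise_sd=0.0,
            co2_noise_sd=0.0,
            device_noise_sd=0.0,
        )
        gt = r.ground_truth
        assert gt["vented_ml"].sum() == pytest.approx(0.0, abs=1e-12)
        # once the target is reached nothing is consumed any more
        second_half = gt[gt["t_start_s"] >= 600.0]
        assert second_half["injected_ml"].sum() == pytest.approx(0.0, abs=1e-9)
        assert steady_state_true_re(gt, 600.0, 1200.0) == pytest.approx(100.0)

    def test_reflector_bypass_zero_efficiency(self, vent_long, iso):
        refl = rs.ReflectorParams(base_efficiency=0.0)
        r = rs.simulate_experiment(
            vent_long, iso, short_schedule(0.6, 1200.0), reflector=refl, seed=5,
            initial_lung_volpct=0.72,
        )
        assert steady_state_true_re(r.ground_truth, 300.0, 1200.0) == pytest.approx(0.0, abs=1e-9)

    def test_eighty_percent_efficiency_recovered(self, vent_long, iso):
        # per-breath bookkeeping oracle: with capacity never binding and no
        # noise, vented/exhaled = 1 - 0.8 regardless of controller duty cycle
        refl = rs.ReflectorParams(base_efficiency=0.8, capacity_per_breath_ml=1e9)
        r = rs.simulate_experiment(
            vent_long,
            iso,
            short_schedule(1.0, 2400.0),
            reflector=refl,
            seed=6,
            noise_sd=0.0,
            co2_noise_sd=0.0,
            device_noise_sd=0.0,
            initial_lung_volpct=1.2,
        )
        assert steady_state_true_re(r.ground_truth, 600.0, 2400.0) == pytest.approx(80.0, abs=2.0)

    def test_true_re_undefined_without_exhaled_vapour(self, vent_long, iso):
        inj = rs.InjectorParams(vapour_rate_mls=0.0)
        r = rs.simulate_experiment(vent_long, iso, short_schedule(), injector=inj, seed=7)
        with pytest.raises(ValueError, match="undefined"):
            steady_state_true_re(r.ground_truth, 0.0, 600.0)


class TestFailureModes:
    def test_reservoir_exhaustion_stops_with_status(self, vent_long, iso):
        r = rs.simulate_experiment(
            vent_long, iso, short_schedule(1.4, 3600.0), seed=8, reservoir_ml=0.2
        )
        assert r.status == "reservoir_exhausted"
        assert r.n_breaths < 600
        assert len(r.trace) == r.n_breaths * 60

    def test_invalid_configs_rejected(self, vent_long, iso):
        with pytest.raises(ValueError):
            rs.ReflectorParams(base_efficiency=1.5)
        with pytest.raises(ValueError):
            rs.InjectorParams(gain=0.0)
        with pytest.raises(ValueError):
            rs.InjectorParams(mode="pid")
        with pytest.raises(ValueError, match="retention"):
            rs.simulate_experiment(
                vent_long,
                iso,
                short_schedule(),
                reflector=rs.ReflectorParams(interface_retention_time_s=5.0),
            )
        with pytest.raises(ValueError):
            rs.simulate_experiment(vent_long, iso, short_schedule(), reservoir_ml=-1.0)


class TestSpillOver:
    def test_short_flow_spills_at_high_target(self, vent_short, sevo):
        r = rs.simulate_experiment(vent_short, sevo, short_schedule(1.5, 1200.0), seed=9)
        assert (r.ground_truth["spill_ml"] > 0).any()

    def test_long_flow_spill_is_rare(self, vent_long, sevo):
        r = rs.simulate_experiment(vent_long, sevo, short_schedule(1.5, 1200.0), seed=9)
        short = rs.simulate_experiment(
            rs.VentilationSettings(inspiratory_flow_lpm=60.0), sevo, short_schedule(1.5, 1200.0), seed=9
        )
        assert r.ground_truth["spill_ml"].sum() < short.ground_truth["spill_ml"].sum()
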