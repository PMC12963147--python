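"""Breath segmentation, end-tidal extraction and injection-peak metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import reflectsim as rs
from reflectsim.breaths import ec_window, quantify_peak, segment_breaths

from conftest import make_flat_trace


class TestSegmentation:
    def test_single_hand_built_run(self):
        trace = make_flat_trace(n_samples=60, run_start=10, run_len=30)
        assert segment_breaths(trace) == [(10, 40)]

    def test_no_co2_no_runs(self):
        trace = make_flat_trace(co2_plateau=0.0)
        assert segment_breaths(trace) == []

    def test_threshold_is_strict(self):
        trace = make_flat_trace(co2_plateau=34.0)  # exactly at threshold: not expiration
        assert segment_breaths(trace) == []

    def test_debounce_discards_blips(self):
        co2 = np.zeros(100)
        co2[10:40] = 40.0
        co2[60:62] = 40.0  # 0.2 s blip
        trace = rs.GasTrace(agent_volpct=np.zeros(100), co2_mmhg=co2)
        assert segment_breaths(trace) == [(10, 40)]

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            segment_breaths(make_flat_trace(), co2_threshold=0.0)

    def test_full_simulated_experiment_yields_1600_runs(self, full_sim_long):
        assert len(segment_breaths(full_sim_long.trace)) == 1600


class TestEndTidal:
    def test_thirty_sample_run_averages_exactly_twenty(self):
        # agent samples are the sample index, so the mean identifies exactly
        # which samples entered: offset 0.2 s -> samples 12..31 of run [10, 40)
        trace = make_flat_trace(n_samples=60, run_start=10, run_len=30)
        agent = np.arange(60, dtype=float)
        trace = rs.GasTrace(agent_volpct=agent, co2_mmhg=trace.co2_mmhg)
        run = segment_breaths(trace)[0]
        win = ec_window(run, trace.sample_period_s)
        assert win == (12, 32)
        assert win[1] - win[0] == 20
        assert rs.compute_ec(trace, run) == pytest.approx(np.mean(np.arange(12, 32)))

    def test_constant_channel(self):
        trace = make_flat_trace(agent_value=1.0)
        run = segment_breaths(trace)[0]
        assert rs.compute_ec(trace, run) == pytest.approx(1.00)

    def test_ramp_mean_hand_computed(self):
        trace = make_flat_trace(n_samples=60, run_start=10, run_len=30)
        agent = np.zeros(60)
        agent[12:32] = 0.50 + 0.01 * np.arange(20)
        trace = rs.GasTrace(agent_volpct=agent, co2_mmhg=trace.co2_mmhg)
        run = segment_breaths(trace)[0]
        assert rs.compute_ec(trace, run) == pytest.approx(0.595)

    def test_short_run_flagged_incomplete(self):
        trace = make_flat_trace(run_len=15)  # cannot hold offset + 20 samples
        run = segment_breaths(trace)[0]
        assert math.isnan(rs.compute_ec(trace, run))

    @given(shift=st.floats(-1.0, 3.0))
    @settings(max_examples=50, deadline=None)
    def test_translation_invariance(self, shift):
        base = make_flat_trace(n_samples=60, run_start=10, run_len=30)
        agent = np.linspace(0.4, 1.2, 60)
        t1 = rs.GasTrace(agent_volpct=agent, co2_mmhg=base.co2_mmhg)
        t2 = rs.GasTrace(agent_volpct=agent + shift, co2_mmhg=base.co2_mmhg)
        run = segment_breaths(t1)[0]
        assert rs.compute_ec(t2, run) == pytest.approx(rs.compute_ec(t1, run) + shift)


class TestPeakQuantification:
    def _trace_with_window(self, values):
        agent = np.array(values, dtype=float)
        co2 = np.zeros(len(agent))
        return rs.GasTrace(agent_volpct=agent, co2_mmhg=co2)

    def test_hand_computed_excess(self):
        # excesses +0.5, +1.0, +0.5 above the subsequent EC, rest below
        next_ec = 1.0
        vals = [0.9, 1.5, 2.0, 1.5, 0.8, 0.9]
        trace = self._trace_with_window(vals)
        pk = quantify_peak(trace, (0, len(vals)), next_ec)
        assert pk.t_inj_s == pytest.approx(0.3)
        assert pk.auc_volpct_s == pytest.approx(0.2)
        assert pk.cpeak_volpct == pytest.approx(2.0)
        assert pk.present

    def test_no_excess_no_peak(self):
        trace = self._trace_with_window([0.5, 0.6, 0.4])
        pk = quantify_peak(trace, (0, 3), next_ec=1.0)
        assert pk.t_inj_s == 0.0 and pk.auc_volpct_s == 0.0 and not pk.present

    def test_empty_window_no_peak(self):
        trace = self._trace_with_window([1.0])
        pk = quantify_peak(trace, (1, 1), next_ec=0.5)
        assert not pk.present and pk.t_inj_s == 0.0

    def test_auc_invariant_under_sample_reordering(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.0, 3.0, size=25)
        t1 = self._trace_with_window(vals)
        t2 = self._trace_with_window(rng.permutation(vals))
        p1 = quantify_peak(t1, (0, 25), next_ec=1.0)
        p2 = quantify_peak(t2, (0, 25), next_ec=1.0)
        assert p1.auc_volpct_s == pytest.approx(p2.auc_volpct_s)
        assert p1.t_inj_s == pytest.approx(p2.t_inj_s)

    def test_min_samples_gate(self):
        trace = self._trace_with_window([0.5, 2.0, 0.5, 0.5])
        pk = quantify_peak(trace, (0, 4), next_ec=1.0, min_samples=2)
        assert not pk.present  # one positive sample only
        assert pk.t_inj_s == pytest.approx(0.1)  # duration still reported


class TestEndToEnd:
    def test_noise_free_ec_matches_lung_plateau(self, vent_long, iso, staircase):
        r = rs.simulate_experiment(
            vent_long, iso, staircase, seed=2, noise_sd=0.0, co2_noise_sd=0.0, device_noise_sd=0.0
        )
        br = rs.analyze_trace(r.trace)
        assert len(br) == r.n_breaths
        diff = np.abs(br["ec_volpct"].to_numpy() - r.ground_truth["lung_volpct"].to_numpy())
        assert np.nanmax(diff) < 0.01  # within the monitor's least significant digit

    def test_breath_count_matches_ground_truth(self, full_sim_long, full_breaths_long):
        assert len(full_breaths_long) == full_sim_long.n_breaths

    def test_detected_peak_metrics_in_calibrated_ranges(self, full_breaths_long, vent_long, sevo, staircase):
        """Bench-calibration check: detected injection peaks at the long
        inspiratory-flow time show durations of 0.4-4.3 s and areas of
        0.4-5.4 vol%*s for both agents."""
        det = full_breaths_long[full_breaths_long["peak_present"]]
        assert len(det) > 100
        r2 = rs.simulate_experiment(vent_long, sevo, staircase, seed=0)
        det2 = rs.analyze_trace(r2.trace).query("peak_present")
        for d in (det, det2):
            assert d["t_inj_s"].min() >= 0.4 and d["t_inj_s"].max() <= 4.3
            assert d["auc_volpcts"].min() >= 0.4 and d["auc_volpcts"].max() <= 5.4

    def test_peaks_cluster_in_series(self, full_breaths_long):
        det = full_breaths_long["peak_present"].to_numpy()
        # detected peaks are temporally clustered: far fewer onsets than peaks
        onsets = np.sum(det[1:] & ~det[:-1])
        assert onsets < det.sum() / 2
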