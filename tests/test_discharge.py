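"""Spike-train metrics: phase rates, ISI variability, thresholds, CST."""
import numpy as np
import pytest

from crossmu import discharge
from crossmu.types import ForceTrace, InvariantError, MotorUnitTrain, MUPTemplate

from conftest import regular_train


def train_from_isis(isis, t0=1.0, **kw):
    kw.setdefault("mu_id", "mu001")
    kw.setdefault("pnr_db", 40.0)
    return MotorUnitTrain(
        spike_times_s=t0 + np.concatenate([[0.0], np.cumsum(isis)]), **kw
    )


class TestPnrFilter:
    def test_inclusive_30_db_threshold(self):
        trains = [
            MotorUnitTrain(f"mu{i}", [0.1, 0.3], pnr) for i, pnr in
            enumerate([28.0, 30.0, 35.0])
        ]
        audit = []
        kept = discharge.filter_trains(trains, audit=audit)
        assert [t.pnr_db for t in kept] == [30.0, 35.0]
        assert audit == [("mu0", 28.0)]

    def test_all_above_threshold_is_identity(self):
        trains = [MotorUnitTrain("a", [0.1, 0.3], 31.0)]
        assert discharge.filter_trains(trains) == trains

    def test_empty_input(self):
        assert discharge.filter_trains([]) == []


class TestInstantaneousRates:
    def test_regular_train_all_rates_equal(self):
        _, _, rates = discharge.instantaneous_rates(regular_train(8.0))
        np.testing.assert_allclose(rates, 8.0)

    def test_rates_are_reciprocal_isis(self):
        tr = train_from_isis([0.2, 0.18, 0.15, 0.13, 0.12])
        _, _, rates = discharge.instantaneous_rates(tr)
        np.testing.assert_allclose(
            rates, [5.0, 5.5556, 6.6667, 7.6923, 8.3333], rtol=1e-4
        )

    def test_single_spike_yields_empty_marker(self):
        tr = MotorUnitTrain("a", [0.5], 40.0)
        _, _, rates = discharge.instantaneous_rates(tr)
        assert len(rates) == 0

    def test_out_of_bounds_isis_excluded(self):
        tr = train_from_isis([0.125, 0.9, 0.125, 0.01, 0.125])
        _, _, rates = discharge.instantaneous_rates(tr)
        np.testing.assert_allclose(rates, 8.0)


class TestPhaseRates:
    def test_constant_train_gives_equal_phases(self):
        tr = regular_train(8.0, duration_s=20.0)
        rec, plat, der = discharge.phase_firing_rates(tr, (5.0, 15.0))
        assert (rec, plat, der) == (8.0, 8.0, 8.0)

    def test_recruitment_rate_is_mean_of_first_five(self):
        isis = [0.2, 0.18, 0.15, 0.13, 0.12] + [0.125] * 40
        tr = train_from_isis(isis)
        rec, _, _ = discharge.phase_firing_rates(tr, (2.0, 6.0))
        assert rec == pytest.approx(6.6496, abs=1e-3)

    def test_derecruitment_uses_last_five(self):
        isis = [0.125] * 40 + [0.12, 0.13, 0.15, 0.18, 0.2]
        tr = train_from_isis(isis)
        _, _, der = discharge.phase_firing_rates(tr, (2.0, 5.0))
        assert der == pytest.approx(6.6496, abs=1e-3)

    def test_too_few_spikes_marks_phase_undefined(self):
        tr = train_from_isis([0.125, 0.125])
        rec, plat, der = discharge.phase_firing_rates(tr, (0.9, 1.4))
        assert np.isnan(rec) and np.isnan(der)
        assert plat == pytest.approx(8.0)

    def test_time_origin_invariance(self):
        isis = np.random.default_rng(4).uniform(0.1, 0.2, 60)
        a = discharge.phase_firing_rates(train_from_isis(isis, t0=0.0), (2.0, 6.0))
        b = discharge.phase_firing_rates(train_from_isis(isis, t0=7.0), (9.0, 13.0))
        np.testing.assert_allclose(a, b, rtol=1e-12)


class TestIsiCov:
    def test_regular_train_is_zero(self):
        assert discharge.isi_cov(regular_train(8.0), (2.0, 8.0)) == 0.0

    def test_hand_computed_value(self):
        tr = train_from_isis([0.1, 0.12, 0.11, 0.13, 0.09], t0=0.0)
        assert discharge.isi_cov(tr, (0.0, 1.0)) == pytest.approx(0.1437, abs=2e-4)

    def test_insufficient_spikes_is_nan(self):
        tr = train_from_isis([0.125])
        assert np.isnan(discharge.isi_cov(tr, (0.9, 1.3)))


class TestThresholds:
    def test_linear_ramp_interpolation(self):
        fs = 1000.0
        ramp = ForceTrace(10.0 * np.arange(int(5 * fs)) / fs, fs)
        tr = MotorUnitTrain("a", [1.2, 2.0, 3.0], 40.0)
        rec, der = discharge.recruitment_thresholds(tr, ramp)
        assert rec == pytest.approx(12.0, abs=1e-6)

    def test_flat_hold_returns_hold_force(self):
        flat = ForceTrace(np.full(5000, 25.0), 1000.0)
        tr = MotorUnitTrain("a", [1.0, 2.0, 4.0], 40.0)
        _, der = discharge.recruitment_thresholds(tr, flat)
        assert der == pytest.approx(25.0)

    def test_spike_at_zero_force_boundary(self):
        fs = 1000.0
        ramp = ForceTrace(10.0 * np.arange(int(5 * fs)) / fs, fs)
        tr = MotorUnitTrain("a", [0.0, 1.0], 40.0)
        rec, _ = discharge.recruitment_thresholds(tr, ramp)
        assert rec == 0.0

    def test_spike_outside_trace_is_fatal(self):
        flat = ForceTrace(np.full(1000, 25.0), 1000.0)
        tr = MotorUnitTrain("a", [0.5, 2.0], 40.0)
        with pytest.raises(InvariantError):
            discharge.recruitment_thresholds(tr, flat)


def _template(mu_id, waveform):
    return MUPTemplate(mu_id, waveform, 50_000.0, n_discharges=50)


class TestMatchTracks:
    def test_external_links_pass_through(self):
        pre = [MotorUnitTrain("p1", [0.1, 0.3], 40.0, track_id="T1"),
               MotorUnitTrain("p2", [0.1, 0.3], 40.0, track_id="T2")]
        post = [MotorUnitTrain("q9", [0.1, 0.3], 40.0, track_id="T2")]
        assert discharge.match_tracks(pre, post) == [("p2", "q9", 1.0)]

    def test_identical_template_sets_recover_any_permutation(self):
        rng = np.random.default_rng(2)
        shapes = [rng.normal(0, 50, 400) for _ in range(4)]
        pre = [_template(f"p{i}", s) for i, s in enumerate(shapes)]
        perm = [2, 0, 3, 1]
        post = [_template(f"q{i}", shapes[i]) for i in perm]
        matches = discharge.match_tracks([], [], pre, post)
        assert all(c == pytest.approx(1.0) for _, _, c in matches)
        assert sorted((a, b) for a, b, _ in matches) == [
            (f"p{i}", f"q{i}") for i in range(4)
        ]

    def test_pair_below_min_corr_left_untracked(self):
        rng = np.random.default_rng(3)
        shapes = [rng.normal(0, 50, 400) for _ in range(3)]
        pre = [_template(f"p{i}", s) for i, s in enumerate(shapes)]
        post = [
            _template("q0", shapes[0]),
            _template("q1", shapes[1]),
            _template("q2", rng.normal(0, 50, 400)),  # unrelated shape
        ]
        matches = discharge.match_tracks([], [], pre, post, min_corr=0.8)
        assert len(matches) == 2
        assert {(a, b) for a, b, _ in matches} == {("p0", "q0"), ("p1", "q1")}
        # exhaustive assignment oracle: best total correlation, gated at 0.8
        from itertools import permutations

        corr = np.array([
            [discharge._template_correlation(a.voltage_uV, b.voltage_uV)
             for b in post] for a in pre
        ])
        best = max(permutations(range(3)), key=lambda p: sum(
            corr[i, p[i]] for i in range(3)
        ))
        oracle = {(f"p{i}", f"q{best[i]}") for i in range(3) if corr[i, best[i]] >= 0.8}
        assert {(a, b) for a, b, _ in matches} == oracle


class TestCst:
    def test_mean_cst_equals_count_over_duration_with_rect_kernel(self):
        rng = np.random.default_rng(5)
        trains = [
            MotorUnitTrain(f"m{i}", np.sort(rng.uniform(0, 20, 150)), 40.0)
            for i in range(5)
        ]
        window = (2.0, 18.0)
        got = discharge.smoothed_cst(trains, window, kernel=None)
        count = sum(
            ((t.spike_times_s >= window[0]) & (t.spike_times_s < window[1])).sum()
            for t in trains
        )
        assert got == pytest.approx(count / (window[1] - window[0]), rel=1e-9)

    def test_three_units_at_8pps_give_24pps(self):
        trains = [regular_train(8.0, duration_s=30.0, mu_id=f"m{i}") for i in range(3)]
        got = discharge.smoothed_cst(trains, (5.0, 25.0))
        assert got == pytest.approx(24.0, rel=0.01)

    def test_identical_pre_post_gives_zero_deltas(self):
        trains = [regular_train(8.0, duration_s=20.0)]
        res = discharge.cumulative_spike_train(trains, trains, (2.0, 18.0))
        assert res.delta_abs_pps == pytest.approx(0.0, abs=1e-12)
        assert res.delta_pct == pytest.approx(0.0, abs=1e-12)

    def test_scaled_rates_give_matching_percent_delta(self):
        pre = [regular_train(8.0, duration_s=30.0, mu_id=f"m{i}") for i in range(3)]
        post = [regular_train(9.6, duration_s=30.0, mu_id=f"m{i}") for i in range(3)]
        res = discharge.cumulative_spike_train(pre, post, (5.0, 25.0))
        assert res.delta_pct == pytest.approx(20.0, abs=0.5)

    def test_no_tracked_units_is_undefined_marker(self):
        res = discharge.cumulative_spike_train([], [], (0.0, 1.0))
        assert np.isnan(res.delta_abs_pps)
        assert res.n_tracked == 0
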