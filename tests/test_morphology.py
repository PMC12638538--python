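"""MUP morphology: cursors, area, turns, peak ratio, NFM and jiggle."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossmu import morphology
from crossmu.types import Cursors, InvariantError, MUPTemplate

FS = 50_000.0
DT_MS = 1e3 / FS


def template(v, cursors=None, **kw):
    kw.setdefault("mu_id", "mup001")
    kw.setdefault("n_discharges", 50)
    return MUPTemplate(voltage_uV=np.asarray(v, float), fs=FS, cursors=cursors, **kw)


def _pad(v, pad=400):
    return np.concatenate([np.zeros(pad), v, np.zeros(pad)])


def rect_pulse(amp=100.0, width_ms=5.0, pad=400):
    return _pad(np.full(int(width_ms / DT_MS), amp), pad), pad


class TestCursors:
    def test_rectangular_pulse_edges_found(self):
        v, pad = rect_pulse()
        c = morphology.place_cursors(template(v))
        width = int(5.0 / DT_MS)
        assert abs(c.onset - pad) <= 1
        assert abs(c.end - (pad + width - 1)) <= 1

    def test_pure_noise_template_is_fatal(self):
        rng = np.random.default_rng(0)
        with pytest.raises(InvariantError):
            morphology.place_cursors(template(rng.normal(0, 2, 1000)))

    def test_manual_cursors_pass_through(self):
        v, _ = rect_pulse()
        manual = Cursors(10, 900, 500, 450)
        tpl = template(v, cursors=manual)
        assert morphology.place_cursors(tpl) == manual


class TestArea:
    def test_rectangular_pulse_area(self):
        v, _ = rect_pulse(100.0, 5.0)
        tpl = template(v)
        tpl.cursors = morphology.place_cursors(tpl)
        assert morphology.mup_area(tpl) == pytest.approx(500.0, rel=0.01)

    def test_triangular_pulse_area(self):
        half = int(2.0 / DT_MS)
        tri = 100.0 * np.concatenate([
            np.linspace(0, 1, half, endpoint=False), np.linspace(1, 0, half)
        ])
        v = _pad(tri)
        tpl = template(v)
        tpl.cursors = morphology.place_cursors(tpl)
        # 1/2 * 4 ms * 100 uV; the >10 uV cursor rule shaves the shallow tails
        assert morphology.mup_area(tpl) == pytest.approx(200.0, rel=0.02)

    def test_biphasic_lobes_add_in_absolute_value(self):
        lobe = int(2.0 / DT_MS)
        v = _pad(np.concatenate([np.full(lobe, 100.0), np.full(lobe, -100.0)]))
        tpl = template(v)
        tpl.cursors = morphology.place_cursors(tpl)
        assert morphology.mup_area(tpl) == pytest.approx(400.0, rel=0.01)

    @settings(max_examples=20, deadline=None)
    @given(k=st.floats(min_value=0.5, max_value=20))
    def test_area_scales_linearly_with_amplitude(self, k):
        v, pad = rect_pulse(50.0, 4.0)
        width = int(4.0 / DT_MS)
        cur = Cursors(pad, pad + width - 1, pad + width // 4, pad + width // 2)
        a1 = morphology.mup_area(template(v, cursors=cur))
        a2 = morphology.mup_area(template(k * v, cursors=cur))
        assert a2 == pytest.approx(k * a1, rel=1e-9)


def _extrema_waveform(values, lobe_ms=1.0):
    """Piecewise-linear waveform visiting 0 -> v1 -> v2 ... -> 0."""
    lobe = int(lobe_ms / DT_MS)
    pts = [0.0] + list(values) + [0.0]
    segs = [
        np.linspace(a, b, lobe, endpoint=False) for a, b in zip(pts, pts[1:])
    ]
    return _pad(np.concatenate(segs + [np.zeros(1)]))


class TestTurns:
    def _count(self, values):
        v = _extrema_waveform(values)
        tpl = template(v)
        tpl.cursors = morphology.place_cursors(tpl)
        return morphology.mup_turns(tpl)

    def test_monophasic_peak_is_one_turn(self):
        assert self._count([60.0]) == 1

    def test_alternating_large_extrema_all_count(self):
        assert self._count([60.0, -120.0, 40.0]) == 3

    def test_subthreshold_ripple_rejected(self):
        # +60, dip to +45, +75, then -120: the 15 uV ripple is not a turn
        assert self._count([60.0, 45.0, 75.0, -120.0]) == 2

    def test_amplitude_scaling_preserves_count_when_above_threshold(self):
        v = _extrema_waveform([60.0, -120.0, 40.0])
        tpl = template(v)
        tpl.cursors = morphology.place_cursors(tpl)
        n1 = morphology.mup_turns(tpl)
        tpl3 = template(3.0 * v, cursors=tpl.cursors)
        assert morphology.mup_turns(tpl3) == n1

    def test_added_subthreshold_ripple_never_changes_count(self):
        v = _extrema_waveform([60.0, -120.0, 40.0])
        tpl = template(v)
        tpl.cursors = morphology.place_cursors(tpl)
        n1 = morphology.mup_turns(tpl)
        # high-frequency, low-amplitude ripple: every extremum-to-extremum
        # change (slope * half-period + 2 * amplitude) stays below 20 uV
        ripple = 2.0 * np.sin(2 * np.pi * 8000.0 * np.arange(len(v)) / FS)
        tpl_r = template(v + ripple, cursors=tpl.cursors)
        assert morphology.mup_turns(tpl_r) == n1


def _trough(rise_uV, fall_uV, window_us=500.0):
    """Waveform descending rise_uV into the trough then ascending fall_uV."""
    w = int(round(window_us * 1e-6 * FS))
    down = np.linspace(0, -rise_uV, w, endpoint=False)
    up = np.linspace(-rise_uV, -rise_uV + fall_uV, w + 1)
    return _pad(np.concatenate([down, up]))


class TestNegativePeakRatio:
    def _tpl(self, v):
        tpl = template(v)
        peak = int(np.argmin(v))
        tpl.cursors = Cursors(peak - 30, peak + 30, peak + 1, peak)
        return tpl

    def test_symmetric_trough_ratio_is_one(self):
        assert morphology.negative_peak_ratio(
            self._tpl(_trough(100.0, 100.0))
        ) == pytest.approx(1.0, rel=1e-6)

    def test_asymmetric_trough(self):
        assert morphology.negative_peak_ratio(
            self._tpl(_trough(80.0, 40.0))
        ) == pytest.approx(2.0, rel=1e-6)

    def test_peak_at_edge_is_fatal(self):
        v = np.concatenate([np.linspace(0, -100, 10), np.zeros(1000)])
        tpl = template(v)
        tpl.cursors = Cursors(5, 900, 11, 9)
        with pytest.raises(InvariantError):
            morphology.negative_peak_ratio(tpl)

    def test_invariant_under_offset_and_scaling(self):
        v = _trough(80.0, 40.0)
        base = morphology.negative_peak_ratio(self._tpl(v))
        shifted = morphology.negative_peak_ratio(self._tpl(2.5 * v + 40.0))
        assert shifted == pytest.approx(base, rel=1e-9)

    def test_flat_fall_is_undefined(self):
        w = int(round(500e-6 * FS))
        v = _pad(np.concatenate([np.linspace(0, -100, w), np.full(2 * w, -100.0)]))
        tpl = template(v)
        peak = 400 + w  # first sample of the flat trough
        tpl.cursors = Cursors(peak - 30, peak + 40, peak + 1, peak)
        assert np.isnan(morphology.negative_peak_ratio(tpl))


class TestNearFibreMup:
    def test_linear_ramp_maps_to_zero(self):
        v = np.linspace(0, 100, 2000)
        nfm = morphology.near_fibre_mup(v, FS)
        assert np.max(np.abs(nfm[10:-10])) < 1e-6 * np.max(
            np.abs(np.diff(v))
        ) / (1 / FS)

    def test_gaussian_lobe_matches_analytic_second_derivative(self):
        sigma = 0.5e-3
        t = (np.arange(4000) - 2000) / FS
        g = 100.0 * np.exp(-0.5 * (t / sigma) ** 2)
        nfm = morphology.near_fibre_mup(g, FS)
        analytic = 100.0 * (t**2 / sigma**4 - 1 / sigma**2) * np.exp(
            -0.5 * (t / sigma) ** 2
        )
        rms_err = np.sqrt(np.mean((nfm - analytic) ** 2))
        assert rms_err < 0.01 * np.sqrt(np.mean(analytic**2))

    def test_linearity_over_shifted_lobes(self):
        sigma = 0.4e-3
        t = np.arange(4000) / FS
        a = 80.0 * np.exp(-0.5 * ((t - 0.03) / sigma) ** 2)
        b = -50.0 * np.exp(-0.5 * ((t - 0.05) / sigma) ** 2)
        lhs = morphology.near_fibre_mup(a + b, FS)
        rhs = morphology.near_fibre_mup(a, FS) + morphology.near_fibre_mup(b, FS)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-9, atol=1e-6)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(InvariantError):
            morphology.near_fibre_mup(np.zeros(100), 10_000.0)


class TestJiggle:
    def test_identical_realizations_give_zero(self):
        v = np.tile(np.sin(np.linspace(0, 4 * np.pi, 500)), (6, 1)) * 100
        res = morphology.nf_jiggle(v, FS, already_nfm=True)
        assert res.nf_jiggle_pct == pytest.approx(0.0, abs=1e-12)

    def test_alternating_perturbation_yields_twenty_percent(self):
        rng = np.random.default_rng(8)
        base = rng.normal(0, 50, 600)
        pert = rng.normal(0, 10, 600)
        pert *= 0.1 * np.abs(base).sum() / np.abs(pert).sum()
        reals = np.array([base + (1 if j % 2 == 0 else -1) * pert for j in range(10)])
        res = morphology.nf_jiggle(reals, FS, already_nfm=True)
        assert res.nf_jiggle_pct == pytest.approx(20.0, rel=1e-9)

    def test_invariant_to_global_amplitude_scaling(self):
        rng = np.random.default_rng(9)
        reals = rng.normal(0, 30, (8, 500)) + 100 * np.sin(
            np.linspace(0, 2 * np.pi, 500)
        )
        a = morphology.nf_jiggle(reals, FS, already_nfm=True).nf_jiggle_pct
        b = morphology.nf_jiggle(7.5 * reals, FS, already_nfm=True).nf_jiggle_pct
        assert b == pytest.approx(a, rel=1e-12)

    def test_single_realization_is_undefined(self):
        res = morphology.nf_jiggle(np.ones((1, 100)), FS, already_nfm=True)
        assert np.isnan(res.nf_jiggle_pct)


class TestMuptFilter:
    def _tpl(self, n, mu_id, contaminated=None):
        return MUPTemplate(mu_id, np.zeros(100), FS, n_discharges=n,
                           contaminated=contaminated)

    def test_fewer_than_forty_discharges_excluded(self):
        tpls = [self._tpl(n, f"m{n}") for n in (39, 40, 41)]
        audit = []
        kept = morphology.filter_mupts(tpls, audit=audit)
        assert [t.n_discharges for t in kept] == [40, 41]
        assert audit[0][0] == "m39"

    def test_clean_train_retained(self):
        assert len(morphology.filter_mupts([self._tpl(100, "m")])) == 1

    def test_poorly_correlated_realizations_flag_contamination(self):
        rng = np.random.default_rng(1)
        shape = np.sin(np.linspace(0, 4 * np.pi, 400)) * 100
        good = shape + rng.normal(0, 5, (70, 400))
        bad = rng.normal(0, 100, (30, 400))  # 30 % foreign discharges
        tpl = MUPTemplate("m", shape, FS, n_discharges=100,
                          realizations=np.vstack([good, bad]))
        assert morphology.filter_mupts([tpl]) == []

    def test_external_contamination_flag_wins(self):
        tpl = self._tpl(100, "m", contaminated=True)
        assert morphology.filter_mupts([tpl]) == []
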