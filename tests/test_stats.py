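"""Mixed-model inference: EMMs, effect sizes, R-squared, paired tests."""
import json
import shutil
import subprocess
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossmu import stats
from crossmu.simulate import sample_mu_metric, sample_subject_metric
from crossmu.types import InvariantError


@pytest.fixture(scope="module")
def mvc_fit():
    rng = np.random.default_rng(42)
    df = sample_subject_metric(
        rng, multipliers={"control": 266 / 286, "exercise": 252 / 296}
    )
    return df, stats.fit_lmm(df, stats.ModelSpec("mvc_N"))


class TestFitLmm:
    def test_noiseless_additive_cells_recovered_exactly(self):
        rng = np.random.default_rng(1)
        df = sample_subject_metric(
            rng, multipliers={"control": 0.9, "exercise": 0.8},
            between_sd=50.0, resid_sd=1e-6,
        )
        res = stats.fit_lmm(df, stats.ModelSpec("mvc_N"))
        emms = res.emms.set_index(["leg", "timepoint"])["emm"]
        raw = df.groupby(["leg", "timepoint"], observed=True)["value"].mean()
        for cell in raw.index:
            assert emms[cell] == pytest.approx(raw[cell], abs=5e-3)
        # pre -> post contrasts recover the injected multiplicative effects
        # exactly (a shared intercept tolerance cancels in the differences)
        assert emms[("control", "post")] - emms[("control", "pre")] == (
            pytest.approx(286.0 * -0.1, abs=1e-6)
        )
        assert emms[("exercise", "post")] - emms[("exercise", "pre")] == (
            pytest.approx(296.0 * -0.2, abs=1e-6)
        )

    def test_emms_equal_cell_means_on_balanced_data(self, mvc_fit):
        df, res = mvc_fit
        raw = df.groupby(["leg", "timepoint"], observed=True)["value"].mean()
        emms = res.emms.set_index(["leg", "timepoint"])["emm"]
        for cell in raw.index:
            assert emms[cell] == pytest.approx(raw[cell], rel=1e-6)

    def test_emm_ci_contains_emm_and_r2_ordering(self, mvc_fit):
        _, res = mvc_fit
        assert (res.emms["ci_lo"] <= res.emms["emm"]).all()
        assert (res.emms["emm"] <= res.emms["ci_hi"]).all()
        assert 0.0 <= res.r2_marginal <= res.r2_conditional <= 1.0

    def test_missing_factor_level_rejected(self):
        rng = np.random.default_rng(2)
        df = sample_subject_metric(rng)
        with pytest.raises(InvariantError):
            stats.fit_lmm(df[df.timepoint == "pre"], stats.ModelSpec("mvc_N"))

    def test_nested_fit_partitions_mu_variance(self):
        rng = np.random.default_rng(3)
        df = sample_mu_metric(rng, subject_sd=1.0, mu_sd=0.7, resid_sd=0.3)
        res = stats.fit_lmm(df, stats.ModelSpec("fr_plateau_pps", nested=True))
        assert res.var_mu == pytest.approx(0.7**2, rel=0.4)
        assert res.var_resid == pytest.approx(0.3**2, rel=0.4)
        assert res.n_clusters == df["mu_id"].nunique()


class TestCohensD:
    def test_hand_computed_pair(self):
        # diffs {1, 3}: mean 2, SD sqrt(2)
        assert stats.cohens_d_paired([0, 0], [1, 3]) == pytest.approx(
            np.sqrt(2), rel=1e-12
        )

    def test_no_change_is_zero(self):
        assert stats.cohens_d_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_constant_nonzero_shift_is_undefined(self):
        assert np.isnan(stats.cohens_d_paired([1.0, 2.0], [3.0, 4.0]))

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=-100, max_value=100), min_size=2, max_size=30
        )
    )
    def test_matches_brute_force_definition(self, pre):
        rng = np.random.default_rng(len(pre))
        pre = np.asarray(pre)
        post = pre + rng.normal(0, 5, len(pre))
        diff = post - pre
        sd = np.sqrt(np.sum((diff - diff.mean()) ** 2) / (len(diff) - 1))
        expected = diff.mean() / sd if sd > 0 else 0.0
        got = stats.cohens_d_paired(pre, post)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_nested_d_from_variance_components(self):
        res = SimpleNamespace(var_subject=1.0, var_mu=1.0, var_resid=2.0)
        assert stats.cohens_d_nested(res, 4.0) == pytest.approx(2.0, rel=1e-12)
        assert stats.cohens_d_nested(res, 0.0) == 0.0
        assert stats.cohens_d_nested(res, -4.0) == -2.0


class TestR2:
    def test_null_fixed_effects_give_icc_as_conditional_r2(self):
        rng = np.random.default_rng(4)
        df = sample_subject_metric(
            rng, base_means={"control": 10.0, "exercise": 10.0},
            between_sd=2.0, resid_sd=2.0, n_subjects=60,
        )
        res = stats.fit_lmm(df, stats.ModelSpec("mvc_N"))
        assert res.r2_marginal == pytest.approx(0.0, abs=0.02)
        assert res.r2_conditional == pytest.approx(0.5, abs=0.1)  # analytic ICC

    def test_no_random_variance_collapses_r2m_to_r2c(self):
        rng = np.random.default_rng(5)
        df = sample_subject_metric(
            rng, multipliers={"control": 0.7, "exercise": 0.7},
            between_sd=0.0, resid_sd=5.0, n_subjects=40,
        )
        res = stats.fit_lmm(df, stats.ModelSpec("mvc_N"))
        assert res.r2_conditional - res.r2_marginal == pytest.approx(0.0, abs=0.02)


class TestPairedTests:
    def test_identical_leg_deltas(self):
        assert stats.paired_t([1.0, 2.0], [1.0, 2.0]) == (0.0, 1.0)

    def test_hand_computed_t(self):
        t, p = stats.paired_t([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert t == pytest.approx(2 * np.sqrt(3), abs=1e-3)  # 3.464

    def test_swapping_legs_negates_t(self):
        a, b = [1.0, 2.0, 4.0], [0.5, 0.1, 0.2]
        t1, p1 = stats.paired_t(a, b)
        t2, p2 = stats.paired_t(b, a)
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)


class TestPearson:
    def test_perfect_negative_relation(self):
        x = np.arange(10.0)
        r, p = stats.pearson_delta_correlation(x, -3 * x + 2)
        assert r == pytest.approx(-1.0)
        assert p < 1e-10

    def test_orthogonal_pair_has_zero_r(self):
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, -1.0])
        r, _ = stats.pearson_delta_correlation(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_input_is_undefined(self):
        r, p = stats.pearson_delta_correlation([1, 1, 1], [1, 2, 3])
        assert np.isnan(r)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_lmm_agrees_with_lme4_reference(tmp_path, mvc_fit):
    """Fixed effects, EMMs and the interaction p-value match lme4/lmerTest."""
    df, res = mvc_fit
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(
        """
suppressMessages({library(lme4); library(lmerTest); library(emmeans); library(jsonlite)})
d <- read.csv(commandArgs(TRUE)[1])
d$leg <- factor(d$leg, levels=c("control","exercise"))
d$timepoint <- factor(d$timepoint, levels=c("pre","post"))
m <- lmer(value ~ leg*timepoint + (1|subject_id), data=d, REML=TRUE)
em <- as.data.frame(emmeans(m, ~ leg*timepoint))
a <- anova(m)  # Satterthwaite
out <- list(emm=em$emmean, leg=as.character(em$leg), tp=as.character(em$timepoint),
            p_int=a["leg:timepoint","Pr(>F)"],
            vc=as.data.frame(VarCorr(m))$vcov)
cat(toJSON(out, digits=10))
"""
    )
    proc = subprocess.run(
        ["Rscript", str(script), str(csv)], capture_output=True, text=True,
        timeout=300,
    )
    assert proc.returncode == 0, proc.stderr
    ref = json.loads(proc.stdout)
    r_emms = {
        (leg, tp): emm
        for leg, tp, emm in zip(ref["leg"], ref["tp"], ref["emm"])
    }
    ours = res.emms.set_index(["leg", "timepoint"])["emm"]
    for cell, val in r_emms.items():
        assert ours[cell] == pytest.approx(val, rel=1e-4)
    p_int = res.effect_pvalues["leg:time"]
    assert p_int == pytest.approx(ref["p_int"][0], rel=0.02, abs=1e-5)
    # variance components (subject, residual)
    assert res.var_subject == pytest.approx(ref["vc"][0], rel=1e-3)
    assert res.var_resid == pytest.approx(ref["vc"][1], rel=1e-3)
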