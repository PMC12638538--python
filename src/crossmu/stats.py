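"""Leg x time mixed-model inference with EMMs, effect sizes and R-squared.

Models follow the two-level / three-level structure used for repeated
bilateral measurements: fixed effects of leg, time and their interaction;
a random intercept per subject; and, for motor-unit-level responses, an
additional random intercept per MU nested within subject.  Fits use REML
via :class:`statsmodels.regression.mixed_linear_model.MixedLM`.

Denominator degrees of freedom use a between-within (containment)
approximation -- exact on the balanced 2 x 2 designs this pipeline
produces and the practical equivalent of Satterthwaite there.  Estimated
marginal means are model-based cell predictions averaged over the random
effects; pairwise cell contrasts are unadjusted by default.  Variance
explained is reported as marginal / conditional R-squared in the
variance-partition form: fixed / (fixed + random + residual) and
(fixed + random) / (fixed + random + residual).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import InvariantError, LEGS, TIMEPOINTS

__all__ = [
    "ModelSpec",
    "ModelResult",
    "fit_lmm",
    "emmeans",
    "cell_contrast",
    "cohens_d_paired",
    "cohens_d_nested",
    "nakagawa_r2",
    "paired_t",
    "pearson_delta_correlation",
]

_CELLS = [(leg, tp) for leg in LEGS for tp in TIMEPOINTS]


@dataclass(frozen=True)
class ModelSpec:
    """Which response to model and at which level of nesting."""

    response: str
    nested: bool = False  # MU intercepts nested within subject
    reml: bool = True


@dataclass
class ModelResult:
    spec: ModelSpec
    nobs: int
    n_subjects: int
    n_clusters: int
    converged: bool
    singular: bool
    fixed_effects: pd.DataFrame  # term, estimate, se, ddf, t, p
    emms: pd.DataFrame  # leg, timepoint, emm, se, ddf, ci_lo, ci_hi
    contrasts: pd.DataFrame  # label, estimate, se, ddf, t, p, cohens_d
    var_fixed: float
    var_subject: float
    var_mu: float
    var_resid: float
    r2_marginal: float
    r2_conditional: float
    _design_info: object = field(repr=False, default=None)
    _fit: object = field(repr=False, default=None)

    @property
    def effect_pvalues(self) -> dict:
        fe = self.fixed_effects.set_index("term")
        return {t: float(fe.loc[t, "p"]) for t in ("leg", "time", "leg:time")}


def _prepare(frame: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    df = frame
    if "metric" in df.columns:
        df = df[df["metric"] == spec.response]
    df = df.dropna(subset=["value"]).copy()
    if df.empty:
        raise InvariantError(f"no rows for response {spec.response!r}")
    df["leg"] = pd.Categorical(df["leg"], categories=list(LEGS))
    df["timepoint"] = pd.Categorical(df["timepoint"], categories=list(TIMEPOINTS))
    if df["leg"].isna().any() or df["timepoint"].isna().any():
        raise InvariantError("unknown leg/timepoint levels")
    if df["subject_id"].nunique() < 2:
        raise InvariantError("need >= 2 subjects")
    for col, levels in (("leg", LEGS), ("timepoint", TIMEPOINTS)):
        present = set(df[col].unique())
        if not set(levels) <= present:
            raise InvariantError(f"both {col} levels must be present")
    if spec.nested and ("mu_id" not in df.columns or df["mu_id"].isna().all()):
        raise InvariantError("nested model requires mu_id")
    return df


_FORMULA = "value ~ C(leg, Sum) * C(timepoint, Sum)"
_TERM_MAP = {
    "Intercept": "intercept",
    "C(leg, Sum)[S.control]": "leg",
    "C(timepoint, Sum)[S.pre]": "time",
    "C(leg, Sum)[S.control]:C(timepoint, Sum)[S.pre]": "leg:time",
}


def fit_lmm(frame: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """REML linear mixed model of ``value ~ leg * time`` with nested intercepts.

    Singular fits (a variance component on the boundary) are flagged, not
    fatal.  Non-convergence raises with diagnostics.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    df = _prepare(frame, spec)
    kwargs = dict(groups=df["subject_id"], re_formula="1")
    if spec.nested:
        kwargs["vc_formula"] = {"mu": "0 + C(mu_id)"}
    model = MixedLM.from_formula(_FORMULA, data=df, **kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(reml=spec.reml, method=["lbfgs", "cg"])
        except np.linalg.LinAlgError:
            fit = None
        if fit is None or not fit.converged:
            # boundary fits (variance component ~ 0) can make the analytic
            # score singular or stall the gradient optimizers; a
            # gradient-free restart is robust there
            fit = model.fit(reml=spec.reml, method="powell", maxiter=2000)
    if not fit.converged:
        raise RuntimeError(
            f"mixed model for {spec.response!r} did not converge "
            f"(n={len(df)}, nested={spec.nested})"
        )

    k = len(fit.fe_params)
    beta = np.asarray(fit.fe_params)
    cov_fe = np.asarray(fit.cov_params())[:k, :k]
    var_subject = float(np.asarray(fit.cov_re)[0, 0]) if fit.cov_re.size else 0.0
    var_mu = float(np.sum(fit.vcomp)) if spec.nested else 0.0
    var_resid = float(fit.scale)
    singular = bool(
        var_subject < 1e-8 * var_resid
        or (spec.nested and var_mu < 1e-8 * var_resid)
    )

    n = len(df)
    n_subjects = df["subject_id"].nunique()
    n_clusters = (
        df.loc[df["mu_id"].notna(), "mu_id"].nunique() if spec.nested else n_subjects
    )
    # between-within containment df; exact for the balanced 2x2 case
    ddf_within = max(n - n_clusters - (k - 1), 1)
    ddf_emm = max(n_subjects - 1, 1)

    design_info = model.data.design_info
    names = list(design_info.column_names)

    rows = []
    for name, est, se in zip(names, beta, np.sqrt(np.diag(cov_fe))):
        term = _TERM_MAP.get(name, name)
        ddf = ddf_emm if term == "intercept" else ddf_within
        t = est / se if se > 0 else np.nan
        p = 2 * sps.t.sf(abs(t), ddf) if np.isfinite(t) else np.nan
        rows.append((term, est, se, ddf, t, p))
    fixed = pd.DataFrame(rows, columns=["term", "estimate", "se", "ddf", "t", "p"])

    X = np.asarray(model.exog)
    var_fixed = float(np.var(X @ beta))
    denom = var_fixed + var_subject + var_mu + var_resid
    r2m = var_fixed / denom if denom > 0 else np.nan
    r2c = (var_fixed + var_subject + var_mu) / denom if denom > 0 else np.nan

    cell_rows = _cell_design(design_info)
    emm_rows = []
    for (leg, tp), x in cell_rows.items():
        emm = float(x @ beta)
        se = float(np.sqrt(x @ cov_fe @ x))
        tcrit = sps.t.ppf(0.975, ddf_emm)
        emm_rows.append(
            (leg, tp, emm, se, ddf_emm, emm - tcrit * se, emm + tcrit * se)
        )
    emms = pd.DataFrame(
        emm_rows,
        columns=["leg", "timepoint", "emm", "se", "ddf", "ci_lo", "ci_hi"],
    )

    sd_total = np.sqrt(var_subject + var_mu + var_resid)
    con_rows = []
    for (cell_a, cell_b) in combinations(_CELLS, 2):
        L = cell_rows[cell_a] - cell_rows[cell_b]
        est = float(L @ beta)
        se = float(np.sqrt(L @ cov_fe @ L))
        t = est / se if se > 0 else np.nan
        p = 2 * sps.t.sf(abs(t), ddf_within) if np.isfinite(t) else np.nan
        d = est / sd_total if sd_total > 0 else np.nan
        label = f"{cell_a[0]}_{cell_a[1]} - {cell_b[0]}_{cell_b[1]}"
        con_rows.append((label, est, se, ddf_within, t, p, d))
    contrasts = pd.DataFrame(
        con_rows, columns=["label", "estimate", "se", "ddf", "t", "p", "cohens_d"]
    )

    return ModelResult(
        spec=spec,
        nobs=n,
        n_subjects=n_subjects,
        n_clusters=n_clusters,
        converged=True,
        singular=singular,
        fixed_effects=fixed,
        emms=emms,
        contrasts=contrasts,
        var_fixed=var_fixed,
        var_subject=var_subject,
        var_mu=var_mu,
        var_resid=var_resid,
        r2_marginal=r2m,
        r2_conditional=r2c,
        _design_info=design_info,
        _fit=fit,
    )


def _cell_design(design_info) -> dict:
    """Fixed-effect design row for each (leg, timepoint) cell."""
    from patsy import build_design_matrices

    new = pd.DataFrame(
        [{"leg": leg, "timepoint": tp} for leg, tp in _CELLS]
    )
    (mat,) = build_design_matrices([design_info], new)
    return {cell: np.asarray(mat)[i] for i, cell in enumerate(_CELLS)}


def emmeans(result: ModelResult) -> pd.DataFrame:
    """EMM table (cell means averaged over random effects, with 95 % CIs)."""
    return result.emms.copy()


def cell_contrast(result: ModelResult, weights: dict) -> dict:
    """Arbitrary contrast of cell EMMs, e.g. the interaction
    ``{("exercise","post"): 1, ("exercise","pre"): -1,
       ("control","post"): -1, ("control","pre"): 1}``.
    """
    cells = _cell_design(result._design_info)
    L = sum(w * cells[c] for c, w in weights.items())
    beta = np.asarray(result._fit.fe_params)
    k = len(beta)
    cov = np.asarray(result._fit.cov_params())[:k, :k]
    est = float(L @ beta)
    se = float(np.sqrt(L @ cov @ L))
    ddf = float(result.contrasts["ddf"].iloc[0])
    t = est / se if se > 0 else np.nan
    p = 2 * sps.t.sf(abs(t), ddf) if np.isfinite(t) else np.nan
    tcrit = sps.t.ppf(0.975, ddf)
    return {
        "estimate": est,
        "se": se,
        "ddf": ddf,
        "t": t,
        "p": p,
        "ci_lo": est - tcrit * se,
        "ci_hi": est + tcrit * se,
    }


def cohens_d_paired(pre: np.ndarray, post: np.ndarray) -> float:
    """d = mean(post - pre) / SD(post - pre), n-1 SD; NaN when SD is zero."""
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.shape != post.shape or len(pre) < 2:
        raise InvariantError("paired samples of equal length >= 2 required")
    diff = post - pre
    sd = float(np.std(diff, ddof=1))
    if sd == 0:
        # all differences equal: zero change is exactly d = 0, any other
        # constant shift has no defined standardized size
        return 0.0 if np.all(diff == 0) else np.nan
    return float(np.mean(diff) / sd)


def cohens_d_nested(result: ModelResult, contrast: float) -> float:
    """EMM contrast standardized by the total random + residual SD."""
    sd = np.sqrt(result.var_subject + result.var_mu + result.var_resid)
    return float(contrast / sd) if sd > 0 else np.nan


def nakagawa_r2(result: ModelResult) -> tuple[float, float]:
    """(marginal, conditional) variance explained."""
    return result.r2_marginal, result.r2_conditional


def paired_t(
    delta_exercise: np.ndarray, delta_control: np.ndarray
) -> tuple[float, float]:
    """Repeated-measures t on per-subject deltas across legs."""
    a = np.asarray(delta_exercise, float)
    b = np.asarray(delta_control, float)
    if a.shape != b.shape or len(a) < 2:
        raise InvariantError("paired deltas of equal length >= 2 required")
    if np.all(a == b):
        return 0.0, 1.0
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p)


def pearson_delta_correlation(
    delta_fr: np.ndarray, delta_mvc: np.ndarray
) -> tuple[float, float]:
    """Pearson r (two-sided p) between per-subject delta FR and delta MVC."""
    a = np.asarray(delta_fr, float)
    b = np.asarray(delta_mvc, float)
    if len(a) != len(b) or len(a) < 3:
        raise InvariantError("need >= 3 paired observations")
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan, np.nan
    r, p = sps.pearsonr(a, b)
    return float(r), float(p)
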