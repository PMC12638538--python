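"""End-to-end orchestration: simulate -> extract -> stats -> report.

The report bundle mirrors the tabular layout used for bilateral pre/post
motor-unit studies: one row per metric, four EMM (95 % CI) cells, model-fit
columns (marginal / conditional R-squared) and p-values for leg, time and
their interaction, plus a cumulative-spike-train delta summary and the
delta-FR vs delta-MVC correlation per leg.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import discharge, force, morphology, stats
from .io import Session, read_cohort, write_metrics
from .simulate import CohortSpec, EffectConfig, PoolConfig, generate_cohort
from .types import LEGS, TIMEPOINTS, MetricRow, rows_to_frame

__all__ = [
    "RunConfig",
    "extract_session_metrics",
    "extract_cohort",
    "run_stats",
    "render_tables",
    "run_pipeline",
]

log = logging.getLogger("crossmu")

#: formatting precision per metric class (decimal places; None = integer)
_PRECISION = {
    "mvc_N": 0,
    "fs_cov": 3,
    "fr_recruitment_pps": 2,
    "fr_plateau_pps": 2,
    "fr_derecruitment_pps": 2,
    "isi_cov": 3,
    "recruit_threshold_N": 1,
    "derecruit_threshold_N": 1,
    "mup_area_uVms": 0,
    "mup_turns": 2,
    "neg_peak_ratio": 2,
    "nf_jiggle_pct": 1,
}

SUBJECT_METRICS = ["mvc_N", "fs_cov"]
MU_METRICS = [
    "fr_recruitment_pps",
    "fr_plateau_pps",
    "fr_derecruitment_pps",
    "isi_cov",
    "recruit_threshold_N",
    "derecruit_threshold_N",
]
MUP_METRICS = ["mup_area_uVms", "mup_turns", "neg_peak_ratio", "nf_jiggle_pct"]


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "crossmu_run"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    pool: PoolConfig = field(default_factory=PoolConfig)
    effects: EffectConfig = field(default_factory=EffectConfig)
    stages: tuple[str, ...] = ("simulate", "extract", "stats", "report")


# ------------------------------------------------------------------ extraction

def extract_session_metrics(
    session: Session,
) -> tuple[list[MetricRow], dict]:
    """All force, discharge and MUP metrics for one loaded session.

    Returns the long-format rows plus per-session context needed by the
    tracked-MU stages (plateau window and retained trains).
    """
    m = session.manifest
    sid, leg, tp = m.subject_id, m.leg, m.timepoint
    rows: list[MetricRow] = []

    mvc_res = None
    if session.mvc_traces:
        mvc_res = force.extract_mvc(session.mvc_traces)
        rows.append(MetricRow(sid, leg, tp, "mvc_N", mvc_res.mvc_N, "N"))

    plateau = None
    filtered = None
    if session.trapezoid is not None:
        trap = session.trapezoid
        filtered = force.lowpass_force(trap)
        target = None
        if trap.target_fraction and m.mvc_N:
            target = trap.target_fraction * m.mvc_N
        ann = trap.windows("plateau")
        if ann:
            plateau = (ann[0].start_s, ann[0].end_s)
        elif target is not None:
            p = force.find_plateau(filtered, target, prefiltered=True)
            plateau = (p.start_s, p.end_s)
        if plateau is not None:
            fs_res = force.force_steadiness(filtered, plateau, prefiltered=True)
            rows.append(MetricRow(sid, leg, tp, "fs_cov", fs_res.cov, ""))

    retained: list = []
    if session.trains and plateau is not None and filtered is not None:
        audit: list = []
        retained = discharge.filter_trains(session.trains, audit=audit)
        if audit:
            log.info("%s/%s/%s: excluded %d trains below PNR 30 dB",
                     sid, leg, tp, len(audit))
        for tr in retained:
            dm = discharge.compute_discharge_metrics(tr, filtered, plateau)
            for name, val, units in (
                ("fr_recruitment_pps", dm.fr_recruitment_pps, "pps"),
                ("fr_plateau_pps", dm.fr_plateau_pps, "pps"),
                ("fr_derecruitment_pps", dm.fr_derecruitment_pps, "pps"),
                ("isi_cov", dm.isi_cov, ""),
                ("recruit_threshold_N", dm.recruit_threshold_N, "N"),
                ("derecruit_threshold_N", dm.derecruit_threshold_N, "N"),
            ):
                rows.append(MetricRow(sid, leg, tp, name, val, units, mu_id=tr.mu_id))

    if session.templates:
        kept = morphology.filter_mupts(session.templates)
        for tpl in kept:
            noise = float(np.std(tpl.voltage_uV[: int(0.002 * tpl.fs)]))
            try:
                mm = morphology.compute_mup_metrics(tpl, noise_uV=noise)
            except Exception as exc:  # degenerate template: skip, keep going
                log.warning("%s/%s/%s MUP %s: %s", sid, leg, tp, tpl.mu_id, exc)
                continue
            rows.append(MetricRow(sid, leg, tp, "mup_area_uVms",
                                  mm.area_uVms, "uV.ms", mu_id=tpl.mu_id))
            rows.append(MetricRow(sid, leg, tp, "mup_turns",
                                  float(mm.turns), "", mu_id=tpl.mu_id))
            rows.append(MetricRow(sid, leg, tp, "neg_peak_ratio",
                                  mm.negative_peak_ratio, "", mu_id=tpl.mu_id))
            if tpl.realizations is not None and len(tpl.realizations) >= 2:
                nf = morphology.nf_jiggle_for_template(tpl, noise_uV=noise)
                rows.append(MetricRow(sid, leg, tp, "nf_jiggle_pct",
                                      nf.nf_jiggle_pct, "%", mu_id=tpl.mu_id))

    context = {
        "cell": (sid, leg, tp),
        "plateau": plateau,
        "trains": retained,
        "mvc": None if mvc_res is None else mvc_res.mvc_N,
    }
    return rows, context


def extract_cohort(
    sessions: list[Session],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Metric, CST-delta and tracked-pair tables for a cohort."""
    all_rows: list[MetricRow] = []
    ctx: dict = {}
    for session in sessions:
        rows, c = extract_session_metrics(session)
        all_rows.extend(rows)
        ctx[c["cell"]] = c

    cst_rows = []
    pair_rows = []
    subjects = sorted({cell[0] for cell in ctx})
    for sid in subjects:
        for leg in LEGS:
            pre = ctx.get((sid, leg, "pre"))
            post = ctx.get((sid, leg, "post"))
            if not pre or not post:
                continue
            links = discharge.match_tracks(pre["trains"], post["trains"])
            pair_rows.extend(
                (sid, leg, a, b, corr) for a, b, corr in links
            )
            pre_ids = {a for a, _, _ in links}
            post_ids = {b for _, b, _ in links}
            pre_tr = [t for t in pre["trains"] if t.mu_id in pre_ids]
            post_tr = [t for t in post["trains"] if t.mu_id in post_ids]
            if not pre_tr or not post_tr or pre["plateau"] is None:
                continue
            res = discharge.cumulative_spike_train(
                pre_tr, post_tr, pre["plateau"], post["plateau"]
            )
            cst_rows.append(
                (sid, leg, res.mean_pps["pre"], res.mean_pps["post"],
                 res.delta_abs_pps, res.delta_pct, res.n_tracked)
            )
    cst = pd.DataFrame(
        cst_rows,
        columns=["subject_id", "leg", "cst_pre_pps", "cst_post_pps",
                 "delta_abs_pps", "delta_pct", "n_tracked"],
    )
    pairs = pd.DataFrame(
        pair_rows,
        columns=["subject_id", "leg", "pre_mu_id", "post_mu_id", "correlation"],
    )
    return rows_to_frame(all_rows), cst, pairs


# ----------------------------------------------------------------- statistics

def run_stats(metrics: pd.DataFrame, cst: pd.DataFrame | None = None) -> dict:
    """Fit every per-metric mixed model plus the CST and correlation analyses."""
    results: dict = {"models": {}, "percent_change": {}, "cst": None,
                     "correlation": {}}
    for metric in SUBJECT_METRICS + MU_METRICS + MUP_METRICS:
        sub = metrics[metrics["metric"] == metric]
        if sub["value"].notna().sum() < 8:
            continue
        nested = metric in MU_METRICS + MUP_METRICS and sub["mu_id"].notna().any()
        spec = stats.ModelSpec(response=metric, nested=nested)
        try:
            res = stats.fit_lmm(sub, spec)
        except Exception as exc:
            log.warning("model for %s failed: %s", metric, exc)
            continue
        results["models"][metric] = res

    if "mvc_N" in results["models"]:
        emms = results["models"]["mvc_N"].emms.set_index(["leg", "timepoint"])
        for leg in LEGS:
            results["percent_change"][leg] = force.percent_change(
                emms.loc[(leg, "pre"), "emm"], emms.loc[(leg, "post"), "emm"]
            )

    if cst is not None and not cst.empty:
        wide = cst.pivot(index="subject_id", columns="leg",
                         values=["delta_abs_pps", "delta_pct"]).dropna()
        if len(wide) >= 2:
            t_abs, p_abs = stats.paired_t(
                wide[("delta_abs_pps", "exercise")], wide[("delta_abs_pps", "control")]
            )
            t_pct, p_pct = stats.paired_t(
                wide[("delta_pct", "exercise")], wide[("delta_pct", "control")]
            )
            results["cst"] = {
                "t_abs": t_abs, "p_abs": p_abs,
                "t_pct": t_pct, "p_pct": p_pct,
                "n": int(len(wide)),
                "mean_delta_abs": wide["delta_abs_pps"].mean().to_dict(),
                "mean_delta_pct": wide["delta_pct"].mean().to_dict(),
            }

    # delta FR (session-mean plateau rate) vs delta MVC per subject and leg
    fr = metrics[metrics["metric"] == "fr_plateau_pps"].dropna(subset=["value"])
    mvc = metrics[metrics["metric"] == "mvc_N"].dropna(subset=["value"])
    if not fr.empty and not mvc.empty:
        fr_cell = fr.groupby(["subject_id", "leg", "timepoint"], observed=True)[
            "value"].mean()
        mvc_cell = mvc.set_index(["subject_id", "leg", "timepoint"])["value"]
        for leg in LEGS:
            dfr, dmvc = [], []
            for sid in sorted(fr["subject_id"].unique()):
                try:
                    dfr.append(fr_cell[(sid, leg, "post")] - fr_cell[(sid, leg, "pre")])
                    dmvc.append(mvc_cell[(sid, leg, "post")] - mvc_cell[(sid, leg, "pre")])
                except KeyError:
                    continue
            if len(dfr) >= 3:
                r, p = stats.pearson_delta_correlation(dfr, dmvc)
                results["correlation"][leg] = {"r": r, "p": p, "n": len(dfr)}
    return results


# -------------------------------------------------------------------- report

def _fmt_val(metric: str, value: float) -> str:
    if value != value:
        return "NA"
    dp = _PRECISION.get(metric, 2)
    return f"{value:.{dp}f}"


def render_tables(results: dict) -> pd.DataFrame:
    """One row per metric: EMM (CI) cells, fit and p-value columns."""
    rows = []
    for metric, res in results["models"].items():
        emms = res.emms.set_index(["leg", "timepoint"])
        cells = {}
        for leg in LEGS:
            for tp in TIMEPOINTS:
                if (leg, tp) in emms.index:
                    e = emms.loc[(leg, tp)]
                    cells[f"{leg}_{tp}"] = (
                        f"{_fmt_val(metric, e['emm'])}"
                        f"({_fmt_val(metric, e['ci_lo'])}-"
                        f"{_fmt_val(metric, e['ci_hi'])})"
                    )
                else:
                    cells[f"{leg}_{tp}"] = "NA"
        pv = res.effect_pvalues
        rows.append({
            "metric": metric,
            "control_pre": cells["control_pre"],
            "exercise_pre": cells["exercise_pre"],
            "control_post": cells["control_post"],
            "exercise_post": cells["exercise_post"],
            "r2_marginal": round(res.r2_marginal, 2),
            "r2_conditional": round(res.r2_conditional, 2),
            "p_leg": round(pv["leg"], 3),
            "p_time": round(pv["time"], 3),
            "p_leg_x_time": round(pv["leg:time"], 3),
        })
    return pd.DataFrame(rows)


def _results_bundle(results: dict) -> dict:
    """JSON-serializable summary of every fitted analysis."""
    out: dict = {"models": {}, "percent_change": results["percent_change"],
                 "cst": results["cst"], "correlation": results["correlation"]}
    for metric, res in results["models"].items():
        out["models"][metric] = {
            "n_obs": res.nobs,
            "n_subjects": res.n_subjects,
            "singular": res.singular,
            "r2_marginal": res.r2_marginal,
            "r2_conditional": res.r2_conditional,
            "p": res.effect_pvalues,
            "emms": res.emms.to_dict(orient="records"),
            "contrasts": res.contrasts.to_dict(orient="records"),
            "variance": {
                "fixed": res.var_fixed,
                "subject": res.var_subject,
                "mu": res.var_mu,
                "residual": res.var_resid,
            },
        }
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Run the requested stages; returns the output directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.stages

    index = outdir / "cohort" / "cohort.json"
    if "simulate" in stages:
        log.info("simulating cohort (seed=%d)", config.seed)
        index = generate_cohort(
            config.cohort, config.pool, config.effects, config.seed,
            outdir / "cohort",
        )
    if not index.exists():
        raise FileNotFoundError(f"stage 'extract': no cohort at {index}")

    metrics_path = outdir / "metrics.csv"
    cst_path = outdir / "cst.csv"
    if "extract" in stages:
        log.info("extracting metrics")
        sessions = read_cohort(index)
        metrics, cst, pairs = extract_cohort(sessions)
        write_metrics(metrics, metrics_path)
        cst.to_csv(cst_path, index=False, float_format="%.12g")
        pairs.to_csv(outdir / "tracked_pairs.csv", index=False,
                     float_format="%.12g")

    if "stats" in stages or "report" in stages:
        if not metrics_path.exists():
            raise FileNotFoundError(f"stage 'stats': no metrics at {metrics_path}")
        metrics = pd.read_csv(metrics_path, dtype={"subject_id": str, "mu_id": str})
        cst = pd.read_csv(cst_path, dtype={"subject_id": str}) if cst_path.exists() else None
        log.info("fitting models")
        results = run_stats(metrics, cst)
        table = render_tables(results)
        table.to_csv(outdir / "model_tables.csv", index=False)
        with open(outdir / "model_tables.txt", "w") as fh:
            fh.write(table.to_string(index=False))
            fh.write("\n")
        with open(outdir / "results.json", "w") as fh:
            json.dump(_results_bundle(results), fh, indent=1, sort_keys=True,
                      default=float)
            fh.write("\n")

    import crossmu

    manifest = {
        "seed": config.seed,
        "crossmu_version": crossmu.__version__,
        "numpy_version": np.__version__,
        "stages": list(stages),
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return outdir
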