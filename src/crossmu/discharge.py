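"""Motor-unit discharge metrics from decomposed HDsEMG spike trains.

Firing rates are reciprocals of inter-spike intervals (ISIs), in pulses per
second.  Recruitment- and derecruitment-phase rates are means of the first
and last ``n_obs`` instantaneous rates; the plateau rate is the mean
instantaneous rate over ISIs falling inside the plateau window.  ISIs
outside physiological bounds (default 0.02-0.5 s, i.e. 2-50 pps) are
treated as decomposition artifacts and excluded from rate and variability
estimates, with exclusion counts available on request.

Metrics that cannot be computed (too few spikes in a phase) are returned as
NaN markers rather than raised, so a single sparse train never aborts a
session.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .types import ForceTrace, InvariantError, MotorUnitTrain, MUPTemplate

__all__ = [
    "ISI_BOUNDS_S",
    "DischargeMetrics",
    "CstResult",
    "filter_trains",
    "instantaneous_rates",
    "phase_firing_rates",
    "isi_cov",
    "recruitment_thresholds",
    "compute_discharge_metrics",
    "match_tracks",
    "smoothed_cst",
    "cumulative_spike_train",
]

#: Physiological ISI validity bounds in seconds (2-50 pps).
ISI_BOUNDS_S = (0.02, 0.5)


@dataclass(frozen=True)
class DischargeMetrics:
    mu_id: str
    fr_recruitment_pps: float
    fr_plateau_pps: float
    fr_derecruitment_pps: float
    isi_cov: float
    recruit_threshold_N: float
    derecruit_threshold_N: float
    n_spikes: int


@dataclass(frozen=True)
class CstResult:
    """Mean smoothed cumulative spike train per timepoint with deltas."""

    mean_pps: dict
    delta_abs_pps: float
    delta_pct: float
    n_tracked: int


def filter_trains(
    trains: list[MotorUnitTrain],
    pnr_min_db: float = 30.0,
    audit: list | None = None,
) -> list[MotorUnitTrain]:
    """Keep trains with pulse-to-noise ratio >= ``pnr_min_db`` (inclusive).

    Excluded mu_ids (with their PNR) are appended to ``audit`` when given.
    """
    kept = []
    for tr in trains:
        if tr.pnr_db >= pnr_min_db:
            kept.append(tr)
        elif audit is not None:
            audit.append((tr.mu_id, tr.pnr_db))
    return kept


def instantaneous_rates(
    train: MotorUnitTrain, isi_bounds_s: tuple[float, float] | None = ISI_BOUNDS_S
):
    """Per-spike instantaneous rates: rate_k = 1/(t_k - t_{k-1}).

    Returns ``(t_prev, t_cur, rates)`` for ISIs inside the validity bounds
    (``isi_bounds_s=None`` disables the bounds).  With fewer than two
    spikes all arrays are empty.
    """
    t = train.spike_times_s
    if len(t) < 2:
        empty = np.empty(0)
        return empty, empty, empty
    isis = np.diff(t)
    if isi_bounds_s is None:
        ok = np.ones(len(isis), dtype=bool)
    else:
        ok = (isis >= isi_bounds_s[0]) & (isis <= isi_bounds_s[1])
    return t[:-1][ok], t[1:][ok], 1.0 / isis[ok]


def phase_firing_rates(
    train: MotorUnitTrain,
    plateau_window: tuple[float, float] | None = None,
    n_obs: int = 5,
    isi_bounds_s: tuple[float, float] | None = ISI_BOUNDS_S,
) -> tuple[float, float, float]:
    """(recruitment, plateau, derecruitment) firing rates in pps.

    Recruitment: mean of the first ``n_obs`` instantaneous rates.
    Derecruitment: mean of the last ``n_obs``.  Plateau: mean of rates whose
    bounding spikes both fall inside ``plateau_window``.  Phases with too
    few observations are NaN.
    """
    t_prev, t_cur, rates = instantaneous_rates(train, isi_bounds_s)
    fr_rec = float(np.mean(rates[:n_obs])) if len(rates) >= n_obs else np.nan
    fr_der = float(np.mean(rates[-n_obs:])) if len(rates) >= n_obs else np.nan
    if plateau_window is None:
        fr_plat = float(np.mean(rates)) if len(rates) else np.nan
    else:
        lo, hi = plateau_window
        inside = (t_prev >= lo) & (t_cur <= hi)
        fr_plat = float(np.mean(rates[inside])) if np.any(inside) else np.nan
    return fr_rec, fr_plat, fr_der


def isi_cov(
    train: MotorUnitTrain,
    plateau_window: tuple[float, float],
    isi_bounds_s: tuple[float, float] | None = ISI_BOUNDS_S,
) -> float:
    """CoV (n-1 SD / mean) of ISIs fully inside the plateau window; NaN if < 3 spikes."""
    t = train.spike_times_s
    lo, hi = plateau_window
    isis = np.diff(t)
    inside = (t[:-1] >= lo) & (t[1:] <= hi)
    if isi_bounds_s is not None:
        inside &= (isis >= isi_bounds_s[0]) & (isis <= isi_bounds_s[1])
    isis = isis[inside]
    if len(isis) < 2:
        return np.nan
    return float(np.std(isis, ddof=1) / np.mean(isis))


def recruitment_thresholds(
    train: MotorUnitTrain, filtered_force: ForceTrace
) -> tuple[float, float]:
    """Force (linear interpolation) at the first and last observed firing."""
    t = train.spike_times_s
    if len(t) == 0:
        return np.nan, np.nan
    if t[0] < 0 or t[-1] > filtered_force.duration_s:
        raise InvariantError(
            f"MU {train.mu_id}: spikes outside the force trace span"
        )
    values = np.interp(
        [t[0], t[-1]], filtered_force.time_s, filtered_force.samples
    )
    return float(values[0]), float(values[1])


def compute_discharge_metrics(
    train: MotorUnitTrain,
    filtered_force: ForceTrace,
    plateau_window: tuple[float, float],
    n_obs: int = 5,
) -> DischargeMetrics:
    fr_rec, fr_plat, fr_der = phase_firing_rates(train, plateau_window, n_obs)
    rec_N, der_N = recruitment_thresholds(train, filtered_force)
    return DischargeMetrics(
        mu_id=train.mu_id,
        fr_recruitment_pps=fr_rec,
        fr_plateau_pps=fr_plat,
        fr_derecruitment_pps=fr_der,
        isi_cov=isi_cov(train, plateau_window),
        recruit_threshold_N=rec_N,
        derecruit_threshold_N=der_N,
        n_spikes=train.n_spikes,
    )


# ------------------------------------------------------------------ tracking

def _template_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Max normalized cross-correlation over lags (shift tolerant)."""
    a = np.asarray(a, float) - np.mean(a)
    b = np.asarray(b, float) - np.mean(b)
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    xc = np.correlate(a, b, mode="full")
    return float(np.max(xc) / denom)


def match_tracks(
    pre_trains: list[MotorUnitTrain],
    post_trains: list[MotorUnitTrain],
    pre_templates: list[MUPTemplate] | None = None,
    post_templates: list[MUPTemplate] | None = None,
    min_corr: float = 0.8,
) -> list[tuple[str, str, float]]:
    """One-to-one pre/post assignment maximizing total template correlation.

    Externally provided ``track_id`` links are honoured verbatim (correlation
    reported as 1.0).  Otherwise spike-triggered templates are matched by
    normalized cross-correlation via an optimal assignment, discarding pairs
    below ``min_corr``.  Returns (pre_mu_id, post_mu_id, correlation) tuples.
    """
    pre_links = {tr.track_id: tr.mu_id for tr in pre_trains if tr.track_id}
    post_links = {tr.track_id: tr.mu_id for tr in post_trains if tr.track_id}
    if pre_links and post_links:
        common = sorted(set(pre_links) & set(post_links))
        return [(pre_links[k], post_links[k], 1.0) for k in common]

    if not pre_templates or not post_templates:
        return []
    n, m = len(pre_templates), len(post_templates)
    corr = np.zeros((n, m))
    for i, a in enumerate(pre_templates):
        for j, b in enumerate(post_templates):
            corr[i, j] = _template_correlation(a.voltage_uV, b.voltage_uV)
    row, col = linear_sum_assignment(-corr)
    matches = []
    for i, j in zip(row, col):
        if corr[i, j] >= min_corr:
            matches.append(
                (pre_templates[i].mu_id, post_templates[j].mu_id, float(corr[i, j]))
            )
    return matches


# ----------------------------------------------------- cumulative spike train

def smoothed_cst(
    trains: list[MotorUnitTrain],
    window: tuple[float, float],
    bin_s: float = 0.001,
    smooth_s: float = 0.4,
    kernel: str = "hann",
) -> float:
    """Mean smoothed cumulative spike train over ``window``, in pps.

    Each train is binarized at ``bin_s``, summed across units, smoothed with
    a unit-area kernel (Hann by default; ``"rect"`` for a moving average,
    ``None`` for none) and averaged over the window.
    """
    if not trains:
        return np.nan
    lo, hi = window
    if hi <= lo:
        raise InvariantError("empty CST window")
    t_max = max(float(tr.spike_times_s[-1]) for tr in trains if tr.n_spikes)
    n_bins = int(np.ceil(max(t_max, hi) / bin_s)) + 1
    counts = np.zeros(n_bins)
    for tr in trains:
        idx = np.floor(tr.spike_times_s / bin_s).astype(int)
        np.add.at(counts, idx, 1.0)
    rate = counts / bin_s  # pps
    if kernel is not None:
        width = max(int(round(smooth_s / bin_s)), 1)
        if kernel == "hann":
            w = np.hanning(width + 2)[1:-1]
        elif kernel == "rect":
            w = np.ones(width)
        else:
            raise InvariantError(f"unknown CST kernel {kernel!r}")
        w = w / np.sum(w)
        rate = np.convolve(rate, w, mode="same")
    i0 = int(np.round(lo / bin_s))
    i1 = int(np.round(hi / bin_s))
    return float(np.mean(rate[i0:i1]))


def cumulative_spike_train(
    pre_trains: list[MotorUnitTrain],
    post_trains: list[MotorUnitTrain],
    pre_window: tuple[float, float],
    post_window: tuple[float, float] | None = None,
    bin_s: float = 0.001,
    smooth_s: float = 0.4,
    kernel: str = "hann",
) -> CstResult:
    """CST mean per timepoint for tracked MUs, with pre-to-post deltas."""
    if not pre_trains or not post_trains:
        return CstResult(
            mean_pps={"pre": np.nan, "post": np.nan},
            delta_abs_pps=np.nan,
            delta_pct=np.nan,
            n_tracked=0,
        )
    post_window = pre_window if post_window is None else post_window
    pre = smoothed_cst(pre_trains, pre_window, bin_s, smooth_s, kernel)
    post = smoothed_cst(post_trains, post_window, bin_s, smooth_s, kernel)
    delta = post - pre
    pct = 100.0 * delta / pre if pre > 0 else np.nan
    return CstResult(
        mean_pps={"pre": pre, "post": post},
        delta_abs_pps=delta,
        delta_pct=pct,
        n_tracked=min(len(pre_trains), len(post_trains)),
    )
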