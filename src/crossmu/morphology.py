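"""Motor-unit potential (MUP) template morphology and near-fibre metrics.

Implements the iEMG-side measurements: landmark cursor placement, MUP area
(rectified integral between onset and end), turns (significant direction
changes > 20 uV), the negative-peak rise/fall ratio over fixed 500 us
windows, the near-fibre MUP (NFM) obtained by double temporal
differentiation, and NF jiggle -- the normalized mean absolute difference
between consecutive NFM realizations, an index of neuromuscular-junction
transmission instability.

The double differentiator acts as the low-frequency emphasis of the
near-fibre transform (its magnitude rises as frequency squared); an explicit
zero-phase 10 kHz low-pass caps the response at the high end.  Both corner
choices are plain constants below.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .types import Cursors, InvariantError, MUPTemplate

__all__ = [
    "MupMetrics",
    "NfResult",
    "place_cursors",
    "mup_area",
    "mup_turns",
    "negative_peak_ratio",
    "near_fibre_mup",
    "nf_jiggle",
    "filter_mupts",
    "compute_mup_metrics",
]

#: Upper corner of the near-fibre band emphasis (Hz), zero-phase 2nd order.
NFM_LOWPASS_HZ = 10_000.0
#: Nominal lower corner of the near-fibre band (Hz); realised implicitly by
#: the f^2 rise of the double differentiator rather than a separate filter.
NFM_HIGHPASS_HZ = 500.0


@dataclass(frozen=True)
class MupMetrics:
    mu_id: str
    area_uVms: float
    turns: int
    negative_peak_ratio: float
    duration_ms: float


@dataclass(frozen=True)
class NfResult:
    nfm_template: np.ndarray
    nf_jiggle_pct: float
    n_isolated: int


def place_cursors(
    template: MUPTemplate,
    noise_uV: float = 0.0,
    min_sustained_ms: float = 0.1,
) -> Cursors:
    """Automatic onset/end/peak cursor placement.

    Peaks are the global extrema.  Onset and end are the outermost samples
    of sustained supra-threshold activity, with threshold
    ``max(10 uV, 3 * noise_uV)`` and a minimum run length of
    ``min_sustained_ms``.  Templates that already carry cursors are returned
    unchanged (manual override path).
    """
    if template.cursors is not None:
        return template.cursors
    v = template.voltage_uV
    n = len(v)
    context = int(round(0.005 * template.fs))
    if n < 2 * context:
        raise InvariantError(
            f"MUP {template.mu_id}: template needs >= 5 ms of context each side"
        )
    thr = max(10.0, 3.0 * noise_uV)
    supra = np.abs(v) > thr
    min_run = max(int(round(min_sustained_ms * 1e-3 * template.fs)), 1)
    onset = end = None
    run_start = None
    padded = np.concatenate([supra, [False]])
    for i, flag in enumerate(padded):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start >= min_run:
                if onset is None:
                    onset = run_start
                end = i - 1
            run_start = None
    if onset is None:
        raise InvariantError(
            f"MUP {template.mu_id}: no sustained activity above {thr:.3g} uV"
        )
    neg = int(np.argmin(v))
    pos = int(np.argmax(v))
    return Cursors(onset=onset, end=end, positive_peak=pos, negative_peak=neg)


def _require_cursors(template: MUPTemplate) -> Cursors:
    if template.cursors is None:
        raise InvariantError(
            f"MUP {template.mu_id}: cursors not placed (run place_cursors)"
        )
    return template.cursors


def mup_area(template: MUPTemplate) -> float:
    """Rectified area between onset and end cursors, in uV*ms."""
    c = _require_cursors(template)
    dt_ms = 1e3 / template.fs
    seg = template.voltage_uV[c.onset: c.end + 1]
    return float(np.sum(np.abs(seg)) * dt_ms)


def mup_duration_ms(template: MUPTemplate) -> float:
    c = _require_cursors(template)
    return (c.end - c.onset) * 1e3 / template.fs


def mup_turns(template: MUPTemplate, min_height_uV: float = 20.0) -> int:
    """Significant direction changes within the MUP duration.

    Threshold-hysteresis turning-point detection: starting from the onset
    value, a direction is established once the signal moves more than
    ``min_height_uV`` from the reference; thereafter a turn is counted at
    the running extreme each time the signal reverses by more than the
    threshold.  Successive accepted turns therefore always differ by more
    than ``min_height_uV`` and alternate in direction, and sub-threshold
    ripple can neither create nor destroy turns.
    """
    c = _require_cursors(template)
    seg = template.voltage_uV[c.onset: c.end + 1]
    cand = float(seg[0])
    direction = 0
    count = 0
    for x in seg[1:]:
        x = float(x)
        if direction == 0:
            if abs(x - cand) > min_height_uV:
                direction = 1 if x > cand else -1
                cand = x
        elif direction > 0:
            if x > cand:
                cand = x
            elif cand - x > min_height_uV:
                count += 1  # confirmed turn at the running maximum
                direction = -1
                cand = x
        else:
            if x < cand:
                cand = x
            elif x - cand > min_height_uV:
                count += 1  # confirmed turn at the running minimum
                direction = 1
                cand = x
    return count


def negative_peak_ratio(template: MUPTemplate, window_us: float = 500.0) -> float:
    """|rise| / |fall| of the negative peak over fixed windows.

    Rise is the amplitude change over the ``window_us`` interval before the
    negative peak, fall over the interval after it.  A flat fall yields NaN.
    """
    c = _require_cursors(template)
    v = template.voltage_uV
    w = int(round(window_us * 1e-6 * template.fs))
    p = c.negative_peak
    if p - w < 0 or p + w >= len(v):
        raise InvariantError(
            f"MUP {template.mu_id}: negative peak within {window_us} us of an edge"
        )
    rise = abs(v[p] - v[p - w])
    fall = abs(v[p + w] - v[p])
    if fall == 0:
        return np.nan
    return float(rise / fall)


def near_fibre_mup(waveform: np.ndarray | MUPTemplate, fs: float | None = None) -> np.ndarray:
    """Near-fibre MUP: scaled double difference with a 10 kHz zero-phase cap.

    The second temporal difference (scaled by 1/dt^2) emphasises fibres close
    to the electrode; output has the same length as the input.
    """
    if isinstance(waveform, MUPTemplate):
        fs = waveform.fs
        v = waveform.voltage_uV
    else:
        if fs is None:
            raise InvariantError("fs required when passing a bare waveform")
        v = np.asarray(waveform, dtype=float)
    if fs < 20_000:
        raise InvariantError(f"near-fibre MUP requires fs >= 20 kHz, got {fs}")
    dt = 1.0 / fs
    nfm = np.zeros_like(v)
    nfm[1:-1] = (v[2:] - 2 * v[1:-1] + v[:-2]) / dt**2
    if NFM_LOWPASS_HZ < fs / 2:
        sos = signal.butter(2, NFM_LOWPASS_HZ, btype="low", fs=fs, output="sos")
        nfm = signal.sosfiltfilt(sos, nfm)
    return nfm


def nf_jiggle(
    realizations: np.ndarray,
    fs: float,
    duration: tuple[int, int] | None = None,
    already_nfm: bool = False,
) -> NfResult:
    """NF jiggle (%) of consecutive NFM realizations.

    jiggle = 100 * mean_j integral|NFM_{j+1} - NFM_j| / integral|mean NFM|,
    evaluated over the NFM duration (``duration`` as a sample-index window;
    default: the full waveform).  Realizations must already be isolated
    (contaminated discharges excluded upstream).  Fewer than two
    realizations yields NaN.
    """
    realizations = np.atleast_2d(np.asarray(realizations, dtype=float))
    nfms = (
        realizations
        if already_nfm
        else np.stack([near_fibre_mup(r, fs) for r in realizations])
    )
    mean_nfm = np.mean(nfms, axis=0)
    if duration is not None:
        lo, hi = duration
        nfms_w = nfms[:, lo: hi + 1]
        mean_w = mean_nfm[lo: hi + 1]
    else:
        nfms_w, mean_w = nfms, mean_nfm
    n = len(nfms_w)
    if n < 2:
        return NfResult(nfm_template=mean_nfm, nf_jiggle_pct=np.nan, n_isolated=n)
    denom = float(np.sum(np.abs(mean_w)))
    if denom == 0:
        return NfResult(nfm_template=mean_nfm, nf_jiggle_pct=np.nan, n_isolated=n)
    diffs = np.abs(np.diff(nfms_w, axis=0)).sum(axis=1)
    jiggle = 100.0 * float(np.mean(diffs)) / denom
    return NfResult(nfm_template=mean_nfm, nf_jiggle_pct=jiggle, n_isolated=n)


def nf_jiggle_for_template(tpl: MUPTemplate, noise_uV: float = 0.0) -> NfResult:
    """NF jiggle of a template's realizations over its cursor-delimited duration."""
    if tpl.realizations is None:
        raise InvariantError(f"MUP {tpl.mu_id}: no realizations")
    cursors = tpl.cursors
    if cursors is None:
        cursors = place_cursors(tpl, noise_uV=noise_uV)
    return nf_jiggle(
        tpl.realizations, tpl.fs, duration=(cursors.onset, cursors.end)
    )


def filter_mupts(
    templates: list[MUPTemplate],
    min_mups: int = 40,
    corr_threshold: float = 0.8,
    max_poor_fraction: float = 0.2,
    audit: list | None = None,
) -> list[MUPTemplate]:
    """Exclude MUP trains with < ``min_mups`` discharges or contamination.

    A train is contaminated when its external flag says so, or -- when the
    flag is absent and realizations exist -- when more than
    ``max_poor_fraction`` of realizations correlate with the template below
    ``corr_threshold`` (the operational stand-in for 'contains MUPs from
    multiple MUs').
    """
    kept = []
    for tpl in templates:
        reason = None
        if tpl.n_discharges < min_mups:
            reason = f"n_discharges {tpl.n_discharges} < {min_mups}"
        elif _is_contaminated(tpl, corr_threshold, max_poor_fraction):
            reason = "contaminated (multi-MU)"
        if reason is None:
            kept.append(tpl)
        elif audit is not None:
            audit.append((tpl.mu_id, reason))
    return kept


def _is_contaminated(
    tpl: MUPTemplate, corr_threshold: float, max_poor_fraction: float
) -> bool:
    if tpl.contaminated is not None:
        return tpl.contaminated
    if tpl.realizations is None or len(tpl.realizations) == 0:
        return False
    t = tpl.voltage_uV - np.mean(tpl.voltage_uV)
    tnorm = np.linalg.norm(t)
    if tnorm == 0:
        return False
    poor = 0
    for r in tpl.realizations:
        r = r - np.mean(r)
        denom = np.linalg.norm(r) * tnorm
        corr = float(np.dot(r, t) / denom) if denom > 0 else 0.0
        if corr < corr_threshold:
            poor += 1
    return poor / len(tpl.realizations) > max_poor_fraction


def compute_mup_metrics(template: MUPTemplate, noise_uV: float = 0.0) -> MupMetrics:
    """Cursor placement plus the scalar morphology metrics for one template."""
    if template.cursors is None:
        cursors = place_cursors(template, noise_uV)
        template = MUPTemplate(
            mu_id=template.mu_id,
            voltage_uV=template.voltage_uV,
            fs=template.fs,
            n_discharges=template.n_discharges,
            cursors=cursors,
            realizations=template.realizations,
            contaminated=template.contaminated,
        )
    return MupMetrics(
        mu_id=template.mu_id,
        area_uVms=mup_area(template),
        turns=mup_turns(template),
        negative_peak_ratio=negative_peak_ratio(template),
        duration_ms=mup_duration_ms(template),
    )
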