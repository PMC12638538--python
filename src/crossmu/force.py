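"""Force-signal metrics: MVC, plateau detection and force steadiness.

Force traces are low-pass filtered at 20 Hz with a fourth-order Butterworth
applied forward and backward (zero phase), so the effective magnitude
response is the squared single-pass response.  Force steadiness is the
coefficient of variation (sample SD over mean, n-1 SD) of the filtered
force during a submaximal plateau.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .types import Annotation, ForceTrace, InvariantError

__all__ = [
    "lowpass_force",
    "butter_gain",
    "extract_mvc",
    "find_plateau",
    "force_steadiness",
    "percent_change",
    "MvcResult",
    "ForceSteadinessResult",
]


@dataclass(frozen=True)
class MvcResult:
    """Maximal voluntary contraction summary.

    ``mvc_N`` is the maximum of the per-trial maxima of the filtered force.
    """

    mvc_N: float
    trial_maxima_N: tuple[float, ...]
    percent_change: float | None = None


@dataclass(frozen=True)
class ForceSteadinessResult:
    cov: float
    plateau_window: tuple[float, float]
    mean_N: float
    sd_N: float


def _butter_sos(cutoff_hz: float, fs: float, order: int):
    return signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")


def lowpass_force(
    trace: ForceTrace, cutoff_hz: float = 20.0, order: int = 4
) -> ForceTrace:
    """Zero-phase Butterworth low-pass (forward-backward; DC gain 1)."""
    if trace.fs <= 2 * cutoff_hz:
        raise InvariantError(
            f"sampling rate {trace.fs} Hz too low for {cutoff_hz} Hz cutoff"
        )
    sos = _butter_sos(cutoff_hz, trace.fs, order)
    filtered = signal.sosfiltfilt(sos, trace.samples)
    return trace.with_samples(filtered)


def butter_gain(
    freq_hz: float,
    cutoff_hz: float = 20.0,
    order: int = 4,
    fs: float = 1000.0,
    passes: int = 1,
) -> float:
    """Magnitude response of the digital Butterworth at ``freq_hz``.

    ``passes=2`` gives the forward-backward (zero-phase) magnitude.
    """
    sos = _butter_sos(cutoff_hz, fs, order)
    _, h = signal.sosfreqz(sos, worN=[freq_hz], fs=fs)
    return float(np.abs(h[0]) ** passes)


def extract_mvc(
    traces: list[ForceTrace],
    reference_N: float | None = None,
    cutoff_hz: float = 20.0,
    order: int = 4,
) -> MvcResult:
    """Per-trial maxima of the filtered force inside MVC windows; overall max.

    Each trace must carry at least one ``"mvc"`` annotation; when a trace has
    several, the trial maximum is taken over all of them.  ``reference_N``
    (e.g. the pre-intervention MVC) yields ``percent_change``.
    """
    maxima = []
    for trace in traces:
        windows = trace.windows("mvc")
        if not windows:
            raise InvariantError("trace has no 'mvc' annotation")
        filt = lowpass_force(trace, cutoff_hz, order)
        maxima.append(
            max(float(np.max(filt.slice(w.start_s, w.end_s))) for w in windows)
        )
    if not maxima:
        raise InvariantError("no MVC trials supplied")
    mvc = max(maxima)
    pc = None if reference_N is None else percent_change(reference_N, mvc)
    return MvcResult(mvc_N=mvc, trial_maxima_N=tuple(maxima), percent_change=pc)


def percent_change(pre: float, post: float) -> float:
    """100 * (post - pre) / pre."""
    if pre == 0:
        raise InvariantError("percent change undefined for zero reference")
    return 100.0 * (post - pre) / pre


def find_plateau(
    trace: ForceTrace,
    target_N: float,
    tol_fraction: float = 0.05,
    min_s: float = 5.0,
    prefiltered: bool = False,
) -> Annotation:
    """Longest window where filtered force stays within +-tol of the target.

    An explicit ``"plateau"`` annotation on the trace overrides detection.
    """
    explicit = trace.windows("plateau")
    if explicit:
        return max(explicit, key=lambda a: a.end_s - a.start_s)
    filt = trace.samples if prefiltered else lowpass_force(trace).samples
    ok = np.abs(filt - target_N) <= tol_fraction * target_N
    best_len, best_start = 0, -1
    run_start = None
    padded = np.concatenate([ok, [False]])
    for i, flag in enumerate(padded):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start > best_len:
                best_len, best_start = i - run_start, run_start
            run_start = None
    if best_len / trace.fs < min_s:
        raise InvariantError(
            f"no plateau within +-{tol_fraction:.0%} of {target_N:.4g} N "
            f"lasting >= {min_s} s (longest qualifying run "
            f"{best_len / trace.fs:.2f} s)"
        )
    return Annotation(
        "plateau", best_start / trace.fs, (best_start + best_len - 1) / trace.fs
    )


def force_steadiness(
    trace: ForceTrace,
    window: Annotation | tuple[float, float],
    prefiltered: bool = False,
) -> ForceSteadinessResult:
    """CoV of the filtered force in the plateau window (n-1 SD over mean)."""
    if isinstance(window, Annotation):
        start_s, end_s = window.start_s, window.end_s
    else:
        start_s, end_s = window
    if not (0.0 <= start_s < end_s <= trace.duration_s + 0.5 / trace.fs):
        raise InvariantError("window outside trace")
    filt = trace if prefiltered else lowpass_force(trace)
    seg = filt.slice(start_s, end_s)
    mean = float(np.mean(seg))
    if mean <= 0:
        raise InvariantError("mean force in window must be > 0")
    sd = float(np.std(seg, ddof=1))
    return ForceSteadinessResult(
        cov=sd / mean, plateau_window=(start_s, end_s), mean_N=mean, sd_N=sd
    )
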