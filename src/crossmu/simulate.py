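"""Synthetic bilateral pre/post motor-unit cohort generator.

The generator is a statistical surrogate for decomposed vastus lateralis
recordings: a threshold-recruitment / rate-coding motoneuron pool with
exponentially spaced recruitment thresholds, renewal discharge with a
configurable ISI coefficient of variation, twitch-convolved force with
band-limited (1-3 Hz) tremor calibrated to a force-steadiness target, and
sum-of-Gaussian-derivative-lobe MUP templates with per-discharge latency
jitter for the near-fibre metrics.

Two deliberate calibrations make injected parameters recoverable by the
downstream estimators rather than merely approximated:

* Renewal trains are parametrised by the *expected instantaneous rate*
  E[1/ISI] (the quantity the firing-rate estimators measure), with the ISI
  mean solved by quadrature on the truncated-normal ISI density.  With
  ``isi_cov = 0`` every discharge metric is an exact closed form.
* The sub-20 Hz force fluctuation on the plateau is rescaled so the
  post-filter CoV equals the configured force-steadiness target.

Injected exercise effects (default values mirror an acute unilateral
resistance-exercise study in older adults: ~15 % MVC drop in the exercised
leg, ~7 % in the contralateral control leg, plateau firing rate raised by
8.66/7.32 in the exercised leg only, MUP morphology unchanged) are applied
as per-subject multiplicative effects to the post-intervention sessions.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy import integrate, signal, stats

from .force import lowpass_force
from .types import (
    Annotation,
    ForceTrace,
    InvariantError,
    MotorUnitTrain,
    MUPTemplate,
    SessionManifest,
    LEGS,
    TIMEPOINTS,
)
from . import io as cio

__all__ = [
    "PoolConfig",
    "EffectConfig",
    "CohortSpec",
    "ExerciseProtocol",
    "simulate_renewal_train",
    "simulate_pool_contraction",
    "simulate_trapezoid_contraction",
    "simulate_mup_train",
    "generate_cohort",
    "draw_subject_effects",
    "sample_subject_metric",
    "expected_active_fraction",
]

_TRUNC_SD = 3.0


# ---------------------------------------------------------------- renewal ISI

@lru_cache(maxsize=64)
def _isi_shape(isi_cov: float) -> tuple[float, float, float]:
    """(a, b, recip_moment) for ISI = mu * (1 + cov*Z), Z ~ TruncNorm(a, b).

    ``recip_moment`` is E[1/(1 + cov Z)], so that an ISI mean of
    ``recip_moment / rate`` yields E[1/ISI] exactly equal to ``rate``.
    """
    if not 0 <= isi_cov < 1:
        raise InvariantError(f"isi_cov must be in [0, 1), got {isi_cov}")
    if isi_cov == 0:
        return -_TRUNC_SD, _TRUNC_SD, 1.0
    a = max(-_TRUNC_SD, -0.995 / isi_cov)  # keep ISIs strictly positive
    b = _TRUNC_SD
    z_lo, z_hi = a, b
    norm = stats.norm.cdf(z_hi) - stats.norm.cdf(z_lo)
    val, _ = integrate.quad(
        lambda z: stats.norm.pdf(z) / (1.0 + isi_cov * z), z_lo, z_hi
    )
    return a, b, val / norm


def _draw_z(isi_cov: float, n: int, rng: np.random.Generator) -> np.ndarray:
    a, b, _ = _isi_shape(isi_cov)
    if isi_cov == 0:
        return np.zeros(n)
    return stats.truncnorm.ppf(rng.random(n), a, b)


def draw_isis(
    rate_pps: float, isi_cov: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """``n`` renewal ISIs with E[1/ISI] = rate_pps and CoV ~ isi_cov."""
    if rate_pps <= 0:
        raise InvariantError("rate must be > 0")
    _, _, c = _isi_shape(isi_cov)
    mu = c / rate_pps
    return mu * (1.0 + isi_cov * _draw_z(isi_cov, n, rng))


def simulate_renewal_train(
    rate_pps: float,
    isi_cov: float,
    duration_s: float,
    rng: np.random.Generator,
    t0: float = 0.0,
) -> np.ndarray:
    """Spike times of a renewal train on [t0, t0 + duration_s)."""
    n_guess = int(rate_pps * duration_s * 1.5) + 20
    times = []
    t = t0
    while True:
        isis = draw_isis(rate_pps, isi_cov, n_guess, rng)
        for isi in isis:
            t += isi
            if t >= t0 + duration_s:
                return np.asarray(times)
            times.append(t)


# ----------------------------------------------------------------------- pool

@dataclass
class PoolConfig:
    """Threshold-recruitment / rate-coding motoneuron pool parameters."""

    n_units: int = 60
    recruitment_range: float = 30.0
    onset_rate_pps: float = 5.0
    peak_rate_pps: float = 14.0
    rate_gain_pps_per_excitation: float = 15.0
    isi_cov: float = 0.15
    twitch_peak_range: float = 100.0
    twitch_tc_range_s: tuple[float, float] = (0.03, 0.09)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise InvariantError("n_units must be >= 1")
        if not 0 <= self.isi_cov < 1:
            raise InvariantError("isi_cov must be in [0, 1)")
        if not self.onset_rate_pps < self.peak_rate_pps:
            raise InvariantError("onset_rate must be < peak_rate")

    def thresholds(self) -> np.ndarray:
        """Exponentially spaced recruitment thresholds in (1/range, 1]."""
        i = np.arange(1, self.n_units + 1)
        return np.exp(i * np.log(self.recruitment_range) / self.n_units) / (
            self.recruitment_range
        )

    def twitch_params(self) -> tuple[np.ndarray, np.ndarray]:
        """(peak amplitude, contraction time) per unit; small units are slow."""
        i = np.arange(1, self.n_units + 1)
        peaks = np.exp(i * np.log(self.twitch_peak_range) / self.n_units)
        tc_lo, tc_hi = self.twitch_tc_range_s
        tcs = np.linspace(tc_hi, tc_lo, self.n_units)
        return peaks, tcs

    def rates_at(self, excitation: float, rate_scale: float = 1.0) -> np.ndarray:
        """Mean instantaneous rate per unit at a given excitation (0 if silent)."""
        th = self.thresholds()
        r = self.onset_rate_pps + self.rate_gain_pps_per_excitation * (
            excitation - th
        )
        r = np.minimum(r, self.peak_rate_pps) * rate_scale
        r[th > excitation] = 0.0
        return r


def expected_active_fraction(pool: PoolConfig, excitation: float) -> float:
    """Closed-form fraction of thresholds <= excitation under exponential spacing."""
    if excitation <= 1.0 / pool.recruitment_range:
        return 0.0
    return min(
        np.log(excitation * pool.recruitment_range)
        / np.log(pool.recruitment_range),
        1.0,
    )


def _twitch_kernel(peak: float, tc_s: float, fs: float) -> np.ndarray:
    t = np.arange(0, 5 * tc_s, 1.0 / fs)
    return peak * (t / tc_s) * np.exp(1.0 - t / tc_s)


def _bandlimited_noise(
    n: int, fs: float, lo_hz: float, hi_hz: float, rng: np.random.Generator
) -> np.ndarray:
    white = rng.standard_normal(n + int(4 * fs))
    sos = signal.butter(2, [lo_hz, hi_hz], btype="band", fs=fs, output="sos")
    band = signal.sosfiltfilt(sos, white)[int(2 * fs): int(2 * fs) + n]
    sd = np.std(band)
    return band / sd if sd > 0 else band


def _force_from_trains(
    trains: list[np.ndarray],
    peaks: np.ndarray,
    tcs: np.ndarray,
    unit_idx: np.ndarray,
    n_samples: int,
    fs: float,
) -> np.ndarray:
    force = np.zeros(n_samples)
    for k, spikes in zip(unit_idx, trains):
        if len(spikes) == 0:
            continue
        counts = np.zeros(n_samples)
        idx = np.clip((spikes * fs).astype(int), 0, n_samples - 1)
        np.add.at(counts, idx, 1.0)
        kern = _twitch_kernel(peaks[k], tcs[k], fs)
        force += signal.fftconvolve(counts, kern)[:n_samples]
    return force


def _calibrate_plateau_cov(
    force: np.ndarray,
    fs: float,
    window: tuple[float, float],
    target_cov: float,
    rng: np.random.Generator,
    taper_s: float = 0.5,
) -> np.ndarray:
    """Rescale the plateau fluctuation so the post-20-Hz-filter CoV hits target.

    Within the plateau window (cosine-tapered edges) the deviation from the
    plateau mean is scaled toward the target SD; if the intrinsic
    fluctuation falls short, calibrated 1-3 Hz tremor is added instead.
    Ramps outside the window are untouched.
    """
    sos20 = signal.butter(4, 20.0, btype="low", fs=fs, output="sos")
    f20 = signal.sosfiltfilt(sos20, force)
    i0, i1 = int(window[0] * fs), int(window[1] * fs)
    mean = float(np.mean(f20[i0:i1]))
    cur_sd = float(np.std(f20[i0:i1], ddof=1))
    target_sd = target_cov * mean
    n = len(force)
    w = np.zeros(n)
    w[i0:i1] = 1.0
    k = max(int(taper_s * fs), 1)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(k) / k))
    lo = max(i0 - k, 0)
    w[lo:i0] = ramp[-(i0 - lo):]
    hi = min(i1 + k, n)
    w[i1:hi] = ramp[::-1][: hi - i1]
    if cur_sd >= target_sd and cur_sd > 0:
        alpha = target_sd / cur_sd
        return force + (alpha - 1.0) * w * (force - mean)
    top_up_sd = np.sqrt(max(target_sd**2 - cur_sd**2, 0.0))
    tremor = _bandlimited_noise(n, fs, 1.0, 3.0, rng)
    return force + w * tremor * top_up_sd


def simulate_pool_contraction(
    pool: PoolConfig,
    excitation_fraction: float,
    duration_s: float,
    rng: np.random.Generator | int | None = None,
    mvc_N: float = 300.0,
    fs_force: float = 1000.0,
    fs_cov_target: float | None = None,
    rate_scale: float = 1.0,
) -> tuple[list[MotorUnitTrain], ForceTrace]:
    """Constant-excitation pool contraction.

    Units with recruitment threshold <= excitation are active, discharging
    as calibrated renewal processes at ``onset + gain * (e - threshold)``
    pps (capped at the peak rate).  Force is the twitch-convolved sum,
    scaled so the plateau mean equals ``excitation_fraction * mvc_N``, with
    tremor calibrated to ``fs_cov_target`` when given.  Excitation below the
    lowest threshold yields no trains and a flat noise-only trace.
    """
    if not 0 < excitation_fraction <= 1:
        raise InvariantError("excitation_fraction must be in (0, 1]")
    rng = np.random.default_rng(rng if rng is not None else pool.seed)
    rates = pool.rates_at(excitation_fraction, rate_scale)
    active = np.nonzero(rates > 0)[0]
    spike_lists = [
        simulate_renewal_train(rates[k], pool.isi_cov, duration_s, rng)
        for k in active
    ]
    trains = [
        MotorUnitTrain(
            mu_id=f"mu{k + 1:03d}",
            spike_times_s=spikes,
            pnr_db=40.0,
        )
        for k, spikes in zip(active, spike_lists)
        if len(spikes) >= 2
    ]
    n_samples = int(round(duration_s * fs_force))
    peaks, tcs = pool.twitch_params()
    force = _force_from_trains(spike_lists, peaks, tcs, active, n_samples, fs_force)
    window = (min(2.0, duration_s / 4), duration_s)
    i0, i1 = int(window[0] * fs_force), int(window[1] * fs_force)
    target_mean = excitation_fraction * mvc_N
    cur = float(np.mean(force[i0:i1]))
    if cur > 0:
        force = force * (target_mean / cur)
    else:
        force = np.full(n_samples, 0.0)
    if fs_cov_target is not None and cur > 0:
        force = _calibrate_plateau_cov(force, fs_force, window, fs_cov_target, rng)
    # wideband sensor noise, removed by the 20 Hz analysis filter
    force = force + 0.002 * target_mean * rng.standard_normal(n_samples)
    trace = ForceTrace(
        force,
        fs_force,
        annotations=[Annotation("plateau", window[0], window[1])],
        target_fraction=excitation_fraction,
    )
    return trains, trace


def _trapezoid_excitation(
    target: float, quiet_s: float, ramp_s: float, hold_s: float, fs: float
) -> tuple[np.ndarray, float]:
    dur = 2 * quiet_s + 2 * ramp_s + hold_s
    t = np.arange(int(round(dur * fs))) / fs
    e = np.zeros_like(t)
    up = (t >= quiet_s) & (t < quiet_s + ramp_s)
    hold = (t >= quiet_s + ramp_s) & (t < quiet_s + ramp_s + hold_s)
    down = (t >= quiet_s + ramp_s + hold_s) & (t < quiet_s + 2 * ramp_s + hold_s)
    e[up] = target * (t[up] - quiet_s) / ramp_s
    e[hold] = target
    e[down] = target * (1 - (t[down] - quiet_s - ramp_s - hold_s) / ramp_s)
    return e, dur


def simulate_trapezoid_contraction(
    pool: PoolConfig,
    rng: np.random.Generator,
    mvc_N: float,
    target_fraction: float = 0.25,
    quiet_s: float = 1.0,
    ramp_s: float = 5.0,
    hold_s: float = 12.0,
    fs_force: float = 1000.0,
    fs_spike: float = 2000.0,
    fs_cov_target: float = 0.025,
    plateau_fr_target: float | None = None,
) -> tuple[list[MotorUnitTrain], ForceTrace, tuple[float, float]]:
    """Ramp-hold-ramp contraction with recruitment and derecruitment.

    Each active unit fires from the moment the excitation ramp crosses its
    threshold until it falls below it again, at the instantaneous rate given
    by the pool rate law (optionally rescaled so the active-unit mean
    plateau rate equals ``plateau_fr_target``).  Returns the trains, the
    force trace (plateau annotated) and the plateau window in seconds.
    """
    th = pool.thresholds()
    rate_scale = 1.0
    if plateau_fr_target is not None:
        base = pool.rates_at(target_fraction)
        mean_rate = float(np.mean(base[base > 0])) if np.any(base > 0) else np.nan
        if not np.isfinite(mean_rate) or mean_rate <= 0:
            raise InvariantError("no active units at the requested target")
        rate_scale = plateau_fr_target / mean_rate

    t_hold0 = quiet_s + ramp_s
    t_hold1 = t_hold0 + hold_s
    dur = t_hold1 + ramp_s + quiet_s
    _, _, c_mom = _isi_shape(pool.isi_cov)

    def excitation(t: float) -> float:
        if t < quiet_s or t >= dur - quiet_s:
            return 0.0
        if t < t_hold0:
            return target_fraction * (t - quiet_s) / ramp_s
        if t < t_hold1:
            return target_fraction
        return target_fraction * (1 - (t - t_hold1) / ramp_s)

    spike_lists: list[np.ndarray] = []
    active_idx: list[int] = []
    for k, theta in enumerate(th):
        if theta > target_fraction:
            continue
        t_on = quiet_s + ramp_s * theta / target_fraction
        t_off = t_hold1 + ramp_s * (1 - theta / target_fraction)
        z_pool = _draw_z(pool.isi_cov, 512, rng)
        zi = 0
        t = t_on
        times = []
        while True:
            e = excitation(t)
            r = pool.onset_rate_pps + pool.rate_gain_pps_per_excitation * (
                e - theta
            )
            r = min(r, pool.peak_rate_pps) * rate_scale
            if r <= 0:
                break
            if zi >= len(z_pool):
                z_pool = _draw_z(pool.isi_cov, 512, rng)
                zi = 0
            isi = (c_mom / r) * (1.0 + pool.isi_cov * z_pool[zi])
            zi += 1
            t += isi
            if t > t_off:
                break
            times.append(t)
        if len(times) >= 2:
            # nominal decomposition timebase
            quant = np.round(np.asarray(times) * fs_spike) / fs_spike
            quant = quant[np.concatenate([[True], np.diff(quant) > 0])]
            spike_lists.append(quant)
            active_idx.append(k)

    trains = [
        MotorUnitTrain(mu_id=f"mu{k + 1:03d}", spike_times_s=s, pnr_db=40.0)
        for k, s in zip(active_idx, spike_lists)
    ]
    n_samples = int(round(dur * fs_force))
    peaks, tcs = pool.twitch_params()
    force = _force_from_trains(
        spike_lists, peaks, tcs, np.asarray(active_idx, int), n_samples, fs_force
    )
    plateau = (t_hold0 + 1.0, t_hold1 - 1.0)
    i0, i1 = int(plateau[0] * fs_force), int(plateau[1] * fs_force)
    target_mean = target_fraction * mvc_N
    cur = float(np.mean(force[i0:i1]))
    if cur > 0:
        force *= target_mean / cur
        force = _calibrate_plateau_cov(force, fs_force, plateau, fs_cov_target, rng)
    force = force + 0.002 * target_mean * rng.standard_normal(n_samples)
    trace = ForceTrace(
        force,
        fs_force,
        annotations=[Annotation("plateau", plateau[0], plateau[1])],
        target_fraction=target_fraction,
    )
    return trains, trace, plateau


def synthesize_steadiness_trace(
    rng: np.random.Generator,
    target_N: float = 74.0,
    cov: float = 0.025,
    duration_s: float = 20.0,
    fs: float = 1000.0,
    hf_noise_fraction: float = 0.01,
    hf_cut_hz: float = 30.0,
) -> ForceTrace:
    """Constant-target plateau with calibrated 1-3 Hz fluctuation.

    The band-limited component is scaled so its sample SD equals
    ``cov * target_N`` exactly; additive noise confined above ``hf_cut_hz``
    (removed by the 20 Hz analysis filter) rides on top.  The whole trace
    is annotated as plateau.
    """
    n = int(round(duration_s * fs))
    band = _bandlimited_noise(n, fs, 1.0, 3.0, rng)
    band = band / np.std(band, ddof=1) * cov * target_N
    white = rng.standard_normal(n + int(2 * fs))
    sos = signal.butter(4, hf_cut_hz, btype="high", fs=fs, output="sos")
    hf = signal.sosfiltfilt(sos, white)[int(fs): int(fs) + n]
    hf = hf / np.std(hf) * hf_noise_fraction * target_N
    samples = target_N + band + hf
    return ForceTrace(
        samples,
        fs,
        annotations=[Annotation("plateau", 0.0, (n - 1) / fs)],
        target_fraction=0.25,
    )


# ------------------------------------------------------------------ MUP trains

def simulate_mup_train(
    rng: np.random.Generator | int,
    jitter_us: float = 25.0,
    n_discharges: int = 60,
    noise_uV: float = 0.2,
    n_fibres: int = 6,
    fs: float = 50_000.0,
    duration_ms: float = 20.0,
    mu_id: str = "mup001",
) -> MUPTemplate:
    """MUP template plus per-discharge realizations with latency jitter.

    The template is a sum of Gaussian-first-derivative lobes (one per
    near-fibre contribution); each realization independently perturbs the
    per-fibre latencies by ``jitter_us`` (SD) and adds white noise.  With
    zero jitter and zero noise all realizations equal the template.
    """
    if n_discharges < 2:
        raise InvariantError("n_discharges must be >= 2")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    n = int(round(duration_ms * 1e-3 * fs))
    t = np.arange(n) / fs
    centre = duration_ms * 1e-3 / 2
    lat = centre + np.linspace(-1.2e-3, 1.2e-3, n_fibres) + rng.normal(
        0.0, 0.2e-3, n_fibres
    )
    amp = rng.uniform(100.0, 300.0, n_fibres) * rng.choice(
        [1.0, -1.0], n_fibres, p=[0.3, 0.7]
    )
    sigma = rng.uniform(0.3e-3, 0.5e-3, n_fibres)

    def waveform(latencies: np.ndarray) -> np.ndarray:
        v = np.zeros(n)
        for a, l, s in zip(amp, latencies, sigma):
            x = (t - l) / s
            v += a * (-x) * np.exp(-0.5 * x**2)
        return v

    template = waveform(lat)
    reals = np.empty((n_discharges, n))
    for j in range(n_discharges):
        jit = rng.normal(0.0, jitter_us * 1e-6, n_fibres)
        reals[j] = waveform(lat + jit)
    if noise_uV > 0:
        reals += rng.normal(0.0, noise_uV, reals.shape)

    contaminated = None
    from .morphology import place_cursors  # local import: avoid cycle at import time

    tpl = MUPTemplate(
        mu_id=mu_id,
        voltage_uV=template,
        fs=fs,
        n_discharges=n_discharges,
        realizations=reals,
    )
    try:
        place_cursors(tpl, noise_uV=noise_uV)
    except InvariantError:
        contaminated = True  # cursor detection failed: flag the set
    tpl.contaminated = contaminated
    return tpl


# --------------------------------------------------------------------- cohort

@dataclass(frozen=True)
class ExerciseProtocol:
    """Unilateral leg-extension bout: sets of 12 reps at 75 % 1RM to failure."""

    n_sets: int = 3
    reps_per_set: int = 12
    extra_reps: int = 4

    @property
    def total_repetitions(self) -> int:
        return self.n_sets * self.reps_per_set + self.extra_reps


@dataclass
class EffectConfig:
    """Injected post-intervention effects (multiplicative, per leg).

    Defaults encode the acute-exercise study conditions: bilateral MVC
    reduction (larger in the exercised leg), plateau firing rate raised in
    the exercised leg only, force-steadiness CoV targets per cell, and no
    change in MUP morphology.  ``fr_mvc_coupling`` correlates a subject's
    firing-rate compensation with their MVC loss (negative delta-delta
    correlation in the exercised leg).
    """

    mvc_multiplier_exercise: float = 252.0 / 296.0
    mvc_multiplier_control: float = 266.0 / 286.0
    plateau_fr_multiplier_exercise: float = 8.66 / 7.32
    plateau_fr_multiplier_control: float = 1.0
    fs_cov_targets: dict = field(
        default_factory=lambda: {
            ("control", "pre"): 0.024,
            ("exercise", "pre"): 0.025,
            ("control", "post"): 0.021,
            ("exercise", "post"): 0.027,
        }
    )
    mup_jitter_multiplier_exercise: float = 1.0
    mup_jitter_multiplier_control: float = 1.0
    mvc_multiplier_sd: float = 0.05
    fr_multiplier_sd: float = 0.08
    fr_mvc_coupling: float = 0.75

    def __post_init__(self) -> None:
        for name in (
            "mvc_multiplier_exercise",
            "mvc_multiplier_control",
            "plateau_fr_multiplier_exercise",
            "plateau_fr_multiplier_control",
            "mup_jitter_multiplier_exercise",
            "mup_jitter_multiplier_control",
        ):
            if not getattr(self, name) > 0:
                raise InvariantError(f"{name} must be > 0")

    @classmethod
    def null(cls) -> "EffectConfig":
        """All multipliers 1 and no coupling (for calibration runs)."""
        return cls(
            mvc_multiplier_exercise=1.0,
            mvc_multiplier_control=1.0,
            plateau_fr_multiplier_exercise=1.0,
            plateau_fr_multiplier_control=1.0,
            fs_cov_targets={
                (leg, tp): 0.025 for leg in LEGS for tp in TIMEPOINTS
            },
            fr_mvc_coupling=0.0,
        )

    def mvc_multiplier(self, leg: str) -> float:
        return (
            self.mvc_multiplier_exercise
            if leg == "exercise"
            else self.mvc_multiplier_control
        )

    def fr_multiplier(self, leg: str) -> float:
        return (
            self.plateau_fr_multiplier_exercise
            if leg == "exercise"
            else self.plateau_fr_multiplier_control
        )


@dataclass
class CohortSpec:
    """Cohort structure: 13 subjects, both legs, pre/post, 3 MVCs + trapezoid."""

    n_subjects: int = 13
    n_mvc_trials: int = 3
    target_fraction: float = 0.25
    quiet_s: float = 1.0
    ramp_s: float = 5.0
    hold_s: float = 12.0
    fs_force: float = 1000.0
    fs_spike: float = 2000.0
    mvc_mean_N: dict = field(
        default_factory=lambda: {"control": 286.0, "exercise": 296.0}
    )
    mvc_between_sd_N: float = 99.0
    fr_plateau_mean_pps: dict = field(
        default_factory=lambda: {"control": 7.43, "exercise": 7.32}
    )
    fr_between_sd_pps: float = 0.8
    tracked_fraction: float = 0.61
    fs_cov_between_sd: float = 0.25  # log-scale subject factor on FS targets
    fs_cov_within_sd: float = 0.08  # log-scale session-to-session factor
    n_mup_units: int = 6
    mup_discharges: int = 55
    mup_jitter_us: float = 25.0
    mup_noise_uV: float = 0.2
    mvc_trial_spread: float = 0.012
    protocol: ExerciseProtocol = field(default_factory=ExerciseProtocol)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise InvariantError("n_subjects must be >= 2")
        if self.hold_s <= 0:
            raise InvariantError("plateau duration must be > 0")


def draw_subject_effects(
    effects: EffectConfig, rng: np.random.Generator
) -> tuple[dict, dict]:
    """One subject's realized post/pre multipliers per leg.

    The exercised leg's firing-rate multiplier is negatively coupled to that
    subject's MVC multiplier (coefficient ``fr_mvc_coupling``): subjects who
    lose more force compensate with a larger firing-rate rise, producing
    the negative delta-FR vs delta-MVC correlation in the exercised leg.
    """
    z_coupled = rng.normal()
    z_free = rng.normal(size=2)
    rho = effects.fr_mvc_coupling
    mvc_mult = {}
    fr_mult = {}
    for leg in LEGS:
        mvc_mult[leg] = effects.mvc_multiplier(leg) + (
            effects.mvc_multiplier_sd
            * (z_coupled if leg == "exercise" else z_free[0])
        )
        if leg == "exercise":
            fr_mult[leg] = effects.fr_multiplier(leg) + effects.fr_multiplier_sd * (
                -rho * z_coupled + np.sqrt(max(1 - rho**2, 0.0)) * z_free[1]
            )
        else:
            fr_mult[leg] = effects.fr_multiplier(leg) + 0.03 * rng.normal()
        mvc_mult[leg] = max(mvc_mult[leg], 0.5)
        fr_mult[leg] = max(fr_mult[leg], 0.5)
    return mvc_mult, fr_mult


def _mvc_trace(
    peak_N: float, rng: np.random.Generator, fs: float = 1000.0
) -> ForceTrace:
    """One MVC effort: 1.5 s rise, 2 s hold at the peak, 1 s release."""
    rise, hold, fall = 1.5, 2.0, 1.0
    dur = rise + hold + fall + 1.0
    t = np.arange(int(dur * fs)) / fs
    f = np.zeros_like(t)
    up = t < rise
    f[up] = peak_N * (1 - np.cos(np.pi * t[up] / rise)) / 2
    hm = (t >= rise) & (t < rise + hold)
    f[hm] = peak_N
    dn = (t >= rise + hold) & (t < rise + hold + fall)
    f[dn] = peak_N * (1 + np.cos(np.pi * (t[dn] - rise - hold) / fall)) / 2
    f += 0.002 * peak_N * rng.standard_normal(len(f))
    return ForceTrace(f, fs, annotations=[Annotation("mvc", 0.0, dur - 0.5 / fs)])


def generate_cohort(
    spec: CohortSpec,
    pool: PoolConfig,
    effects: EffectConfig,
    seed: int,
    outdir: str | Path,
) -> Path:
    """Write a full synthetic session tree; returns the cohort index path.

    Per-subject random intercepts (MVC, firing rate, effect multipliers) are
    drawn once and shared across legs and timepoints; post-intervention
    sessions are regenerated with the effect multipliers applied.  Fully
    reproducible from ``seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root_ss = np.random.SeedSequence(seed)
    subj_seeds = root_ss.spawn(spec.n_subjects)
    session_rels: list[str] = []

    for s in range(spec.n_subjects):
        param_rng, disc_rng, mup_rng = (
            np.random.default_rng(ss) for ss in subj_seeds[s].spawn(3)
        )
        sid = f"S{s + 1:02d}"
        b_mvc = param_rng.normal(0.0, spec.mvc_between_sd_N)
        b_fr = param_rng.normal(0.0, spec.fr_between_sd_pps)
        fs_factor = float(np.exp(param_rng.normal(0.0, spec.fs_cov_between_sd)))
        mvc_mult, fr_mult = draw_subject_effects(effects, param_rng)

        # tracked units chosen once per leg, shared pre/post
        th = pool.thresholds()
        active_units = np.nonzero(th <= spec.target_fraction)[0]
        tracked: dict[str, set[int]] = {}
        for leg in LEGS:
            n_tr = int(round(spec.tracked_fraction * len(active_units)))
            tracked[leg] = set(
                param_rng.choice(active_units, size=n_tr, replace=False).tolist()
            )

        for leg in LEGS:
            mvc_pre = spec.mvc_mean_N[leg] + b_mvc
            for tp in TIMEPOINTS:
                mvc_true = mvc_pre * (mvc_mult[leg] if tp == "post" else 1.0)
                fr_target = (spec.fr_plateau_mean_pps[leg] + b_fr) * (
                    fr_mult[leg] if tp == "post" else 1.0
                )
                fs_cov = (
                    effects.fs_cov_targets[(leg, tp)]
                    * fs_factor
                    * float(np.exp(disc_rng.normal(0.0, spec.fs_cov_within_sd)))
                )

                spread = spec.mvc_trial_spread
                factors = 1.0 - spread * param_rng.random(spec.n_mvc_trials)
                factors[int(param_rng.integers(spec.n_mvc_trials))] = 1.0
                mvc_traces = [
                    _mvc_trace(mvc_true * f, disc_rng, spec.fs_force)
                    for f in factors
                ]

                # contractions normalised to 25 % of *baseline* MVC
                trains, trap, _ = simulate_trapezoid_contraction(
                    pool,
                    disc_rng,
                    mvc_N=mvc_pre,
                    target_fraction=spec.target_fraction,
                    quiet_s=spec.quiet_s,
                    ramp_s=spec.ramp_s,
                    hold_s=spec.hold_s,
                    fs_force=spec.fs_force,
                    fs_spike=spec.fs_spike,
                    fs_cov_target=fs_cov,
                    plateau_fr_target=fr_target,
                )
                for tr in trains:
                    unit = int(tr.mu_id[2:]) - 1
                    tr.pnr_db = float(np.round(disc_rng.uniform(26.0, 46.0), 2))
                    if unit in tracked[leg]:
                        tr.track_id = f"{sid}_{leg}_u{unit + 1:03d}"
                    tr.leg = leg
                    tr.timepoint = tp

                jit = spec.mup_jitter_us * (
                    effects.mup_jitter_multiplier_exercise
                    if (leg == "exercise" and tp == "post")
                    else effects.mup_jitter_multiplier_control
                    if (leg == "control" and tp == "post")
                    else 1.0
                )
                templates = [
                    simulate_mup_train(
                        mup_rng,
                        jitter_us=jit,
                        n_discharges=int(mup_rng.integers(45, 70)),
                        noise_uV=spec.mup_noise_uV,
                        mu_id=f"mup{u + 1:03d}",
                    )
                    for u in range(spec.n_mup_units)
                ]

                session = cio.Session(
                    manifest=SessionManifest(
                        subject_id=sid,
                        leg=leg,
                        timepoint=tp,
                        mvc_N=float(mvc_true),
                    ),
                    mvc_traces=mvc_traces,
                    trapezoid=trap,
                    trains=trains,
                    templates=templates,
                )
                rel = f"{sid}/{leg}_{tp}"
                cio.write_session(session, outdir / rel)
                session_rels.append(f"{rel}/session.json")

    index_path = outdir / "cohort.json"
    with open(index_path, "w") as fh:
        json.dump(
            {
                "seed": seed,
                "n_subjects": spec.n_subjects,
                "sessions": session_rels,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")
    return index_path


# ------------------------------------------------- metric-level cohort sampler

def sample_subject_metric(
    rng: np.random.Generator,
    base_means: dict | None = None,
    multipliers: dict | None = None,
    n_subjects: int = 13,
    between_sd: float = 99.0,
    resid_sd: float = 12.0,
    metric: str = "mvc_N",
    units: str = "N",
):
    """Subject-level metric table from the additive-cell-means model.

    value(s, leg, tp) = base[leg] * mult[leg]^{tp==post} + b_s + eps.
    This is the statistical skeleton of the signal-level cohort (shared
    subject intercept, multiplicative post effect, iid residual) and is the
    fast path for replicate-heavy calibration studies.
    """
    import pandas as pd

    base_means = base_means or {"control": 286.0, "exercise": 296.0}
    multipliers = multipliers or {"control": 1.0, "exercise": 1.0}
    rows = []
    for s in range(n_subjects):
        b = rng.normal(0.0, between_sd)
        for leg in LEGS:
            for tp in TIMEPOINTS:
                mult = multipliers[leg] if tp == "post" else 1.0
                val = base_means[leg] * mult + b + rng.normal(0.0, resid_sd)
                rows.append((f"S{s + 1:02d}", leg, tp, None, metric, val, units))
    return pd.DataFrame(
        rows,
        columns=["subject_id", "leg", "timepoint", "mu_id", "metric", "value", "units"],
    )


def sample_mu_metric(
    rng: np.random.Generator,
    base_means: dict | None = None,
    multipliers: dict | None = None,
    n_subjects: int = 13,
    mus_per_cell: int = 8,
    subject_sd: float = 0.8,
    mu_sd: float = 0.8,
    resid_sd: float = 0.8,
    metric: str = "fr_plateau_pps",
    units: str = "pps",
    tracked: bool = True,
):
    """MU-level metric table with MU-within-subject intercepts.

    With ``tracked=True`` each MU is measured at both timepoints (sharing
    its intercept); otherwise each cell gets fresh MUs.
    """
    import pandas as pd

    base_means = base_means or {"control": 7.43, "exercise": 7.32}
    multipliers = multipliers or {"control": 1.0, "exercise": 1.0}
    rows = []
    for s in range(n_subjects):
        b = rng.normal(0.0, subject_sd)
        sid = f"S{s + 1:02d}"
        for leg in LEGS:
            if tracked:
                b_mu = rng.normal(0.0, mu_sd, mus_per_cell)
                for m in range(mus_per_cell):
                    for tp in TIMEPOINTS:
                        mult = multipliers[leg] if tp == "post" else 1.0
                        val = (
                            base_means[leg] * mult
                            + b
                            + b_mu[m]
                            + rng.normal(0.0, resid_sd)
                        )
                        rows.append(
                            (sid, leg, tp, f"{sid}_{leg}_m{m}", metric, val, units)
                        )
            else:
                for tp in TIMEPOINTS:
                    for m in range(mus_per_cell):
                        mult = multipliers[leg] if tp == "post" else 1.0
                        val = (
                            base_means[leg] * mult
                            + b
                            + rng.normal(0.0, mu_sd)
                            + rng.normal(0.0, resid_sd)
                        )
                        rows.append(
                            (sid, leg, tp, f"{sid}_{leg}_{tp}_m{m}", metric, val, units)
                        )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "leg", "timepoint", "mu_id", "metric", "value", "units"],
    )
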