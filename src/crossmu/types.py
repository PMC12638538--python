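"""Domain containers shared by every pipeline stage.

All quantities are held in canonical units after loading: time in seconds,
force in newtons, voltage in microvolts.  Loaders are responsible for unit
normalisation; the containers only validate.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "Annotation",
    "Cursors",
    "ForceTrace",
    "MotorUnitTrain",
    "MUPTemplate",
    "SessionManifest",
    "MetricRow",
    "InvariantError",
    "LEGS",
    "TIMEPOINTS",
]

LEGS = ("control", "exercise")
TIMEPOINTS = ("pre", "post")


class InvariantError(ValueError):
    """A domain invariant was violated by input data."""


class Annotation(NamedTuple):
    """A labelled time window ``[start_s, end_s]`` on a force trace."""

    label: str
    start_s: float
    end_s: float


class Cursors(NamedTuple):
    """MUP landmark sample indices (0-based)."""

    onset: int
    end: int
    positive_peak: int
    negative_peak: int


@dataclass
class ForceTrace:
    """Uniformly sampled force signal with trial annotations.

    Parameters
    ----------
    samples
        Force in N.
    fs
        Sampling rate in Hz.
    annotations
        Labelled windows, e.g. ``("mvc", 1.0, 4.0)`` or
        ``("plateau", 5.0, 25.0)``.
    target_fraction
        Target force as a fraction of MVC for submaximal trapezoids
        (e.g. 0.25); ``None`` for MVC efforts.
    """

    samples: np.ndarray
    fs: float
    annotations: list[Annotation] = field(default_factory=list)
    target_fraction: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.annotations = [Annotation(*a) for a in self.annotations]
        if not self.fs > 0:
            raise InvariantError(f"fs must be > 0, got {self.fs}")
        if self.samples.ndim != 1:
            raise InvariantError("force samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise InvariantError("force samples must be finite")
        dur = self.duration_s
        by_label: dict[str, list[Annotation]] = {}
        for a in self.annotations:
            if not (0.0 <= a.start_s <= a.end_s <= dur + 0.5 / self.fs):
                raise InvariantError(
                    f"annotation {a.label!r} window ({a.start_s}, {a.end_s}) "
                    f"outside trace of duration {dur:.6g} s"
                )
            by_label.setdefault(a.label, []).append(a)
        for label, anns in by_label.items():
            anns = sorted(anns, key=lambda a: a.start_s)
            for prev, cur in zip(anns, anns[1:]):
                if cur.start_s < prev.end_s:
                    raise InvariantError(
                        f"overlapping {label!r} annotations at {cur.start_s} s"
                    )

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs

    def windows(self, label: str) -> list[Annotation]:
        return [a for a in self.annotations if a.label == label]

    def slice(self, start_s: float, end_s: float) -> np.ndarray:
        """Samples with start_s <= t <= end_s."""
        i0 = int(np.ceil(start_s * self.fs - 1e-9))
        i1 = int(np.floor(end_s * self.fs + 1e-9)) + 1
        return self.samples[max(i0, 0): i1]

    def with_samples(self, samples: np.ndarray) -> "ForceTrace":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass
class MotorUnitTrain:
    """Ordered discharge times of one motor unit in one contraction."""

    mu_id: str
    spike_times_s: np.ndarray
    pnr_db: float
    leg: str = "exercise"
    timepoint: str = "pre"
    track_id: str | None = None

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        if self.spike_times_s.ndim != 1:
            raise InvariantError(f"MU {self.mu_id}: spike times must be 1-D")
        d = np.diff(self.spike_times_s)
        if np.any(d <= 0):
            raise InvariantError(
                f"MU {self.mu_id}: spike times must be strictly increasing"
            )
        if not np.isfinite(self.pnr_db):
            raise InvariantError(f"MU {self.mu_id}: pnr_db must be finite")
        if self.leg not in LEGS:
            raise InvariantError(f"MU {self.mu_id}: unknown leg {self.leg!r}")
        if self.timepoint not in TIMEPOINTS:
            raise InvariantError(
                f"MU {self.mu_id}: unknown timepoint {self.timepoint!r}"
            )

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times_s)

    def isis(self) -> np.ndarray:
        return np.diff(self.spike_times_s)


@dataclass
class MUPTemplate:
    """Motor-unit potential template waveform with landmark cursors.

    ``realizations`` optionally holds the per-discharge waveforms aligned to
    the template (rows = discharges), used for near-fibre jiggle.
    """

    mu_id: str
    voltage_uV: np.ndarray
    fs: float
    n_discharges: int = 1
    cursors: Cursors | None = None
    realizations: np.ndarray | None = None
    contaminated: bool | None = None

    def __post_init__(self) -> None:
        self.voltage_uV = np.asarray(self.voltage_uV, dtype=float)
        if not self.fs > 0:
            raise InvariantError(f"MUP {self.mu_id}: fs must be > 0")
        if self.n_discharges < 1:
            raise InvariantError(f"MUP {self.mu_id}: n_discharges must be >= 1")
        if self.cursors is not None:
            self.cursors = Cursors(*(int(c) for c in self.cursors))
            c = self.cursors
            n = len(self.voltage_uV)
            if not (0 <= c.onset < c.negative_peak < c.end < n):
                raise InvariantError(
                    f"MUP {self.mu_id}: cursor order must be "
                    f"onset < negative_peak < end within the template"
                )
            if not (c.onset < c.positive_peak < c.end):
                raise InvariantError(
                    f"MUP {self.mu_id}: positive peak must lie between "
                    f"onset and end"
                )
        if self.realizations is not None:
            self.realizations = np.atleast_2d(
                np.asarray(self.realizations, dtype=float)
            )
            if self.realizations.shape[1] != len(self.voltage_uV):
                raise InvariantError(
                    f"MUP {self.mu_id}: realizations must match template length"
                )

    @property
    def dt_s(self) -> float:
        return 1.0 / self.fs


@dataclass
class SessionManifest:
    """Bookkeeping for one subject x leg x timepoint recording session."""

    subject_id: str
    leg: str
    timepoint: str
    mvc_paths: list[str] = field(default_factory=list)
    trapezoid_path: str | None = None
    trains_path: str | None = None
    train_meta_path: str | None = None
    template_paths: list[str] = field(default_factory=list)
    mvc_N: float | None = None

    def __post_init__(self) -> None:
        if self.leg not in LEGS:
            raise InvariantError(f"unknown leg {self.leg!r}")
        if self.timepoint not in TIMEPOINTS:
            raise InvariantError(f"unknown timepoint {self.timepoint!r}")
        if self.mvc_N is not None and not self.mvc_N > 0:
            raise InvariantError("mvc_N must be > 0 once resolved")


@dataclass(frozen=True)
class MetricRow:
    """One value in the long-format metric table fed to the models."""

    subject_id: str
    leg: str
    timepoint: str
    metric: str
    value: float
    units: str = ""
    mu_id: str | None = None


def rows_to_frame(rows: Sequence[MetricRow]):
    """Long-format DataFrame from MetricRows (stable column order)."""
    import pandas as pd

    cols = ["subject_id", "leg", "timepoint", "mu_id", "metric", "value", "units"]
    data = [
        (r.subject_id, r.leg, r.timepoint, r.mu_id, r.metric, r.value, r.units)
        for r in rows
    ]
    return pd.DataFrame(data, columns=cols)


def frame_to_rows(frame) -> list[MetricRow]:
    rows = []
    for rec in frame.itertuples(index=False):
        mu = rec.mu_id
        if mu is not None and (mu != mu or mu == ""):  # NaN or empty
            mu = None
        rows.append(
            MetricRow(
                subject_id=str(rec.subject_id),
                leg=str(rec.leg),
                timepoint=str(rec.timepoint),
                metric=str(rec.metric),
                value=float(rec.value),
                units="" if rec.units != rec.units else str(rec.units),
                mu_id=None if mu is None else str(mu),
            )
        )
    return rows
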