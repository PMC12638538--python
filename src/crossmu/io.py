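"""Reading and writing the session data layout.

A *session* is one subject x leg x timepoint recording, described by a JSON
manifest that points at delimited-text force and spike-train files and
JSON (or HDF5) motor-unit potential templates.  Everything is normalised to
canonical units on load: seconds, newtons, microvolts.  Sample indices are
0-based; spike times may be given as seconds or as sample indices plus a
sampling rate and are converted to seconds.

Text is the canonical carrier.  Floats are written with 12 significant
digits so that a write -> read -> write cycle is byte-identical.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    Annotation,
    Cursors,
    ForceTrace,
    InvariantError,
    MetricRow,
    MotorUnitTrain,
    MUPTemplate,
    SessionManifest,
    frame_to_rows,
    rows_to_frame,
)

__all__ = [
    "Session",
    "read_session",
    "write_session",
    "read_cohort",
    "write_metrics",
    "read_metrics",
]

_FMT = "%.12g"


def _fmt(x: float) -> str:
    return _FMT % float(x)


@dataclass
class Session:
    """A fully loaded session: manifest plus invariant-checked records."""

    manifest: SessionManifest
    mvc_traces: list[ForceTrace] = field(default_factory=list)
    trapezoid: ForceTrace | None = None
    trains: list[MotorUnitTrain] = field(default_factory=list)
    templates: list[MUPTemplate] = field(default_factory=list)
    root: Path | None = None

    @property
    def cell(self) -> tuple[str, str, str]:
        m = self.manifest
        return (m.subject_id, m.leg, m.timepoint)


# ---------------------------------------------------------------- force files

def _read_force_csv(path: Path) -> tuple[np.ndarray, float]:
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "time_s" in cols:
        t = df[cols["time_s"]].to_numpy(float)
    elif "time_ms" in cols:
        t = df[cols["time_ms"]].to_numpy(float) / 1000.0
    else:
        raise InvariantError(f"{path}: no time_s/time_ms column")
    if "force_n" not in cols:
        raise InvariantError(f"{path}: no force_N column")
    f = df[cols["force_n"]].to_numpy(float)
    if len(t) < 2:
        raise InvariantError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise InvariantError(f"{path}: force trace is not uniformly sampled")
    return f, 1.0 / dt[0]


def _write_force_csv(path: Path, trace: ForceTrace) -> None:
    with open(path, "w") as fh:
        fh.write("time_s,force_N\n")
        dt = 1.0 / trace.fs
        for i, v in enumerate(trace.samples):
            fh.write(f"{_fmt(i * dt)},{_fmt(v)}\n")


# ---------------------------------------------------------------- train files

def _read_trains(
    path: Path,
    meta_path: Path | None,
    leg: str,
    timepoint: str,
    time_unit: str = "s",
    fs: float | None = None,
) -> list[MotorUnitTrain]:
    df = pd.read_csv(path, dtype={"mu_id": str})
    if "mu_id" not in df.columns:
        raise InvariantError(f"{path}: no mu_id column")
    if "spike_time_s" in df.columns:
        times = df["spike_time_s"].to_numpy(float)
    elif "spike_sample" in df.columns:
        if time_unit != "samples" or not fs:
            raise InvariantError(
                f"{path}: spike_sample column requires time_unit='samples' and fs"
            )
        times = df["spike_sample"].to_numpy(float) / fs
    else:
        raise InvariantError(f"{path}: no spike_time_s/spike_sample column")
    if time_unit == "samples" and "spike_time_s" in df.columns:
        raise InvariantError(f"{path}: ambiguous spike time units")
    df = df.assign(_t_s=times)

    meta = {}
    if meta_path is not None:
        mdf = pd.read_csv(meta_path, dtype={"mu_id": str, "track_id": str})
        for rec in mdf.itertuples(index=False):
            track = getattr(rec, "track_id", None)
            if track is not None and (track != track or track == ""):
                track = None
            meta[str(rec.mu_id)] = (float(rec.pnr_db), track)

    trains = []
    for mu_id, grp in df.groupby("mu_id", sort=True):
        # no metadata: assume decomposition quality above any plausible gate
        pnr, track = meta.get(str(mu_id), (60.0, None))
        trains.append(
            MotorUnitTrain(
                mu_id=str(mu_id),
                spike_times_s=grp["_t_s"].to_numpy(float),
                pnr_db=pnr,
                leg=leg,
                timepoint=timepoint,
                track_id=track,
            )
        )
    return trains


def _write_trains(path: Path, meta_path: Path, trains: list[MotorUnitTrain]) -> None:
    with open(path, "w") as fh:
        fh.write("mu_id,spike_time_s\n")
        for tr in trains:
            for t in tr.spike_times_s:
                fh.write(f"{tr.mu_id},{_fmt(t)}\n")
    with open(meta_path, "w") as fh:
        fh.write("mu_id,pnr_db,track_id\n")
        for tr in trains:
            track = "" if tr.track_id is None else tr.track_id
            fh.write(f"{tr.mu_id},{_fmt(tr.pnr_db)},{track}\n")


# ------------------------------------------------------------- template files

def _template_to_dict(tpl: MUPTemplate) -> dict:
    d = {
        "mu_id": tpl.mu_id,
        "fs": float(tpl.fs),
        "n_discharges": int(tpl.n_discharges),
        "cursors": None if tpl.cursors is None else list(tpl.cursors),
        "contaminated": tpl.contaminated,
        "template_uV": [float(_fmt(v)) for v in tpl.voltage_uV],
    }
    if tpl.realizations is not None:
        d["realizations_uV"] = [
            [float(_fmt(v)) for v in row] for row in tpl.realizations
        ]
    return d


def _template_from_dict(d: dict) -> MUPTemplate:
    cur = d.get("cursors")
    return MUPTemplate(
        mu_id=str(d["mu_id"]),
        voltage_uV=np.asarray(d["template_uV"], dtype=float),
        fs=float(d["fs"]),
        n_discharges=int(d["n_discharges"]),
        cursors=None if cur is None else Cursors(*cur),
        realizations=(
            np.asarray(d["realizations_uV"], dtype=float)
            if "realizations_uV" in d
            else None
        ),
        contaminated=d.get("contaminated"),
    )


def read_template(path: Path) -> MUPTemplate:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        return _read_template_h5(path)
    with open(path) as fh:
        return _template_from_dict(json.load(fh))


def write_template(path: Path, tpl: MUPTemplate) -> None:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        _write_template_h5(path, tpl)
        return
    with open(path, "w") as fh:
        json.dump(_template_to_dict(tpl), fh, indent=None, separators=(",", ":"))
        fh.write("\n")


def _read_template_h5(path: Path) -> MUPTemplate:
    import h5py

    with h5py.File(path, "r") as h5:
        cur = h5.attrs.get("cursors")
        return MUPTemplate(
            mu_id=str(h5.attrs["mu_id"]),
            voltage_uV=np.asarray(h5["template_uV"], dtype=float),
            fs=float(h5.attrs["fs"]),
            n_discharges=int(h5.attrs["n_discharges"]),
            cursors=None if cur is None else Cursors(*np.asarray(cur, int)),
            realizations=(
                np.asarray(h5["realizations_uV"], dtype=float)
                if "realizations_uV" in h5
                else None
            ),
        )


def _write_template_h5(path: Path, tpl: MUPTemplate) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["mu_id"] = tpl.mu_id
        h5.attrs["fs"] = float(tpl.fs)
        h5.attrs["n_discharges"] = int(tpl.n_discharges)
        if tpl.cursors is not None:
            h5.attrs["cursors"] = np.asarray(tpl.cursors, dtype=int)
        h5.create_dataset("template_uV", data=tpl.voltage_uV)
        if tpl.realizations is not None:
            h5.create_dataset("realizations_uV", data=tpl.realizations)


# ------------------------------------------------------------------ manifests

def read_session(manifest_path: str | Path) -> Session:
    """Load and invariant-check one session from its JSON manifest."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(manifest_path)
    root = manifest_path.parent
    with open(manifest_path) as fh:
        m = json.load(fh)

    manifest = SessionManifest(
        subject_id=str(m["subject_id"]),
        leg=str(m["leg"]),
        timepoint=str(m["timepoint"]),
        mvc_paths=[e["path"] for e in m.get("mvc_trials", [])],
        trapezoid_path=(m.get("trapezoid") or {}).get("path"),
        trains_path=(m.get("trains") or {}).get("path"),
        train_meta_path=(m.get("trains") or {}).get("meta"),
        template_paths=list(m.get("templates", [])),
        mvc_N=m.get("mvc_N"),
    )

    def resolve(rel: str) -> Path:
        p = root / rel
        if not p.exists():
            raise FileNotFoundError(f"{manifest_path}: missing record {rel}")
        return p

    mvc_traces = []
    for entry in m.get("mvc_trials", []):
        samples, fs = _read_force_csv(resolve(entry["path"]))
        mvc_traces.append(
            ForceTrace(
                samples,
                fs,
                annotations=[Annotation(*a) for a in entry.get("annotations", [])],
            )
        )

    trapezoid = None
    if m.get("trapezoid"):
        entry = m["trapezoid"]
        samples, fs = _read_force_csv(resolve(entry["path"]))
        trapezoid = ForceTrace(
            samples,
            fs,
            annotations=[Annotation(*a) for a in entry.get("annotations", [])],
            target_fraction=entry.get("target_fraction"),
        )

    trains: list[MotorUnitTrain] = []
    if m.get("trains"):
        entry = m["trains"]
        trains = _read_trains(
            resolve(entry["path"]),
            resolve(entry["meta"]) if entry.get("meta") else None,
            leg=manifest.leg,
            timepoint=manifest.timepoint,
            time_unit=entry.get("time_unit", "s"),
            fs=entry.get("fs"),
        )

    templates = [read_template(resolve(p)) for p in m.get("templates", [])]

    return Session(
        manifest=manifest,
        mvc_traces=mvc_traces,
        trapezoid=trapezoid,
        trains=trains,
        templates=templates,
        root=root,
    )


def write_session(session: Session, outdir: str | Path) -> Path:
    """Write a session tree; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    m = session.manifest
    doc: dict = {
        "subject_id": m.subject_id,
        "leg": m.leg,
        "timepoint": m.timepoint,
    }
    if m.mvc_N is not None:
        doc["mvc_N"] = float(_fmt(m.mvc_N))

    entries = []
    for i, trace in enumerate(session.mvc_traces, start=1):
        rel = f"mvc_{i}.csv"
        _write_force_csv(outdir / rel, trace)
        entries.append(
            {"path": rel, "annotations": [list(a) for a in trace.annotations]}
        )
    if entries:
        doc["mvc_trials"] = entries

    if session.trapezoid is not None:
        rel = "trapezoid.csv"
        _write_force_csv(outdir / rel, session.trapezoid)
        doc["trapezoid"] = {
            "path": rel,
            "annotations": [list(a) for a in session.trapezoid.annotations],
            "target_fraction": session.trapezoid.target_fraction,
        }

    if session.trains:
        _write_trains(outdir / "trains.csv", outdir / "mu_meta.csv", session.trains)
        doc["trains"] = {"path": "trains.csv", "meta": "mu_meta.csv", "time_unit": "s"}

    if session.templates:
        tdir = outdir / "templates"
        tdir.mkdir(exist_ok=True)
        rels = []
        for tpl in session.templates:
            rel = f"templates/{tpl.mu_id}.json"
            write_template(outdir / rel, tpl)
            rels.append(rel)
        doc["templates"] = rels

    manifest_path = outdir / "session.json"
    with open(manifest_path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest_path


def read_cohort(index_path: str | Path) -> list[Session]:
    """Load every session listed in a cohort index JSON."""
    index_path = Path(index_path)
    with open(index_path) as fh:
        idx = json.load(fh)
    root = index_path.parent
    return [read_session(root / rel) for rel in idx["sessions"]]


# -------------------------------------------------------------- metric tables

def write_metrics(rows: list[MetricRow] | pd.DataFrame, path: str | Path) -> Path:
    """Write long-format metric rows as delimited text."""
    frame = rows if isinstance(rows, pd.DataFrame) else rows_to_frame(rows)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format=_FMT)
    return path


def read_metrics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "mu_id": str})
    return df


def read_metric_rows(path: str | Path) -> list[MetricRow]:
    return frame_to_rows(read_metrics(path))
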