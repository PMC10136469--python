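"""On-disk formats for dyad sessions.

Primary format is an inspectable CSV/TSV bundle: one directory per
session holding ``metadata.tsv`` (one row), ``layout.tsv``,
``segments.tsv`` + ``trials.tsv`` (the timeline), ``behavior.tsv`` and
long-format signal tables per member, plus a ``manifest.json`` listing
every artifact with a SHA-256 checksum.  Floats are written with 17
significant digits so read(write(s)) reproduces the session exactly.

A SNIRF (HDF5) pair is supported as a secondary dialect for raw
intensity recordings: two ``.snirf`` files (one per member, with a
synthetic line-array probe geometry, since the generator carries no real
optode coordinates) plus the same TSV sidecars for behavior and
metadata.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .session import (
    BehavioralTrials,
    DyadSession,
    ParticipantRecording,
    ProbeLayout,
    Segment,
    TaskTimeline,
    Trial,
    ValidationError,
)

__all__ = ["write_session", "read_session", "write_cohort", "read_cohort"]

_FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    pass


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# CSV bundle

def _signals_frame(rec: ParticipantRecording) -> pd.DataFrame:
    frames = []
    if rec.intensity is not None:
        for w, wl in enumerate(rec.wavelengths_nm):
            arr = rec.intensity[:, w, :]
            frames.append((f"wl{int(wl)}", arr))
    else:
        frames.append(("hbo", rec.hbo))
        if rec.hbr is not None:
            frames.append(("hbr", rec.hbr))
    rows = []
    for kind, arr in frames:
        n_ch, n_t = arr.shape
        rows.append(pd.DataFrame({
            "channel": np.repeat(np.arange(1, n_ch + 1), n_t),
            "kind": kind,
            "sample": np.tile(np.arange(n_t), n_ch),
            "value": arr.reshape(-1),
        }))
    return pd.concat(rows, ignore_index=True)


def _signals_from_frame(df: pd.DataFrame, fname: str):
    kinds = sorted(df["kind"].unique())
    mats = {}
    for kind in kinds:
        sub = df[df["kind"] == kind]
        n_ch = int(sub["channel"].max())
        n_t = int(sub["sample"].max()) + 1
        if len(sub) != n_ch * n_t:
            raise ParseError(f"{fname}: incomplete channel x sample grid for {kind}")
        mat = np.empty((n_ch, n_t))
        mat[sub["channel"].to_numpy() - 1, sub["sample"].to_numpy()] = \
            sub["value"].to_numpy()
        mats[kind] = mat
    return mats


def write_session(session: DyadSession, path: str | Path,
                  format: str = "csv_bundle") -> dict:
    """Write a session; returns the manifest (file -> sha256)."""
    session.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if format == "csv_bundle":
        files = _write_csv_bundle(session, path)
    elif format == "snirf_pair":
        files = _write_snirf_pair(session, path)
    else:
        raise ValueError(f"unknown format {format!r}")
    manifest = {"format": format, "dyad_id": session.dyad_id,
                "files": {f: _sha256(path / f) for f in sorted(files)}}
    (path / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest


def _write_csv_bundle(session: DyadSession, path: Path) -> list[str]:
    meta = {"dyad_id": session.dyad_id, "group": session.group,
            "participant_id_m": session.member_m.participant_id,
            "participant_id_f": session.member_f.participant_id,
            "fs_hz": session.member_m.fs_hz,
            "wavelength1_nm": session.member_m.wavelengths_nm[0],
            "wavelength2_nm": session.member_m.wavelengths_nm[1],
            "distance_cm": session.member_m.source_detector_distance_cm}
    for k, v in sorted(session.covariates.items()):
        meta[f"cov_{k}"] = v
    _write_tsv(pd.DataFrame([meta]), path / "metadata.tsv")
    _write_tsv(pd.DataFrame({
        "channel_id": session.layout.channel_ids,
        "region_label": session.layout.region_labels,
        "roi": session.layout.rois}), path / "layout.tsv")
    _write_tsv(pd.DataFrame(
        [(s.kind, s.onset_s, s.duration_s,
          -1 if s.block_index is None else s.block_index)
         for s in session.timeline.segments],
        columns=["kind", "onset_s", "duration_s", "block_index"]),
        path / "segments.tsv")
    _write_tsv(pd.DataFrame(
        [(t.block_index, t.trial_index, t.cue_onset_s, t.go_onset_s,
          t.response_window_s, t.feedback_onset_s, t.blank_onset_s)
         for t in session.timeline.trials],
        columns=["block_index", "trial_index", "cue_onset_s", "go_onset_s",
                 "response_window_s", "feedback_onset_s", "blank_onset_s"]),
        path / "trials.tsv")
    b = session.behavior
    _write_tsv(pd.DataFrame({
        "block_index": b.block_index, "trial_index": b.trial_index,
        "rt_ms_member1": b.rt_ms_member1, "rt_ms_member2": b.rt_ms_member2,
        "winner": b.winner, "points_delta": b.points_delta}),
        path / "behavior.tsv")
    sm = _signals_frame(session.member_m)
    sf = _signals_frame(session.member_f)
    sm.to_csv(path / "signals_m.csv", index=False, float_format=_FLOAT_FMT)
    sf.to_csv(path / "signals_f.csv", index=False, float_format=_FLOAT_FMT)
    return ["metadata.tsv", "layout.tsv", "segments.tsv", "trials.tsv",
            "behavior.tsv", "signals_m.csv", "signals_f.csv"]


def read_session(path: str | Path, format: str = "csv_bundle") -> DyadSession:
    """Read a session bundle; structural problems raise ``ParseError``
    naming the offending file, invariant violations raise
    ``ValidationError``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv_bundle":
        session = _read_csv_bundle(path)
    elif format == "snirf_pair":
        session = _read_snirf_pair(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    session.validate()
    return session


def _read_table(path: Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t" if path.suffix == ".tsv" else ",",
                           float_precision="round_trip")
    except Exception as exc:  # surface the file name
        raise ParseError(f"{path.name}: {exc}") from exc


def _read_meta_sidecars(path: Path):
    meta = _read_table(path / "metadata.tsv").iloc[0].to_dict()
    lay = _read_table(path / "layout.tsv")
    layout = ProbeLayout(tuple(int(c) for c in lay["channel_id"]),
                         tuple(lay["region_label"]), tuple(lay["roi"]))
    beh_df = _read_table(path / "behavior.tsv")
    if (beh_df[["rt_ms_member1", "rt_ms_member2"]] <= 0).any().any():
        raise ValidationError("behavior.tsv: non-positive response time")
    behavior = BehavioralTrials(
        str(meta["dyad_id"]),
        beh_df["block_index"].to_numpy(int), beh_df["trial_index"].to_numpy(int),
        beh_df["rt_ms_member1"].to_numpy(float), beh_df["rt_ms_member2"].to_numpy(float),
        beh_df["winner"].to_numpy(int), beh_df["points_delta"].to_numpy(int))
    covariates = {k[4:]: float(v) for k, v in meta.items() if k.startswith("cov_")}
    return meta, layout, behavior, covariates


def _read_timeline(path: Path) -> TaskTimeline:
    seg_df = _read_table(path / "segments.tsv")
    segments = tuple(
        Segment(r.kind, float(r.onset_s), float(r.duration_s),
                None if int(r.block_index) < 0 else int(r.block_index))
        for r in seg_df.itertuples())
    tr_df = _read_table(path / "trials.tsv")
    trials = tuple(
        Trial(int(r.block_index), int(r.trial_index), float(r.cue_onset_s),
              float(r.go_onset_s), float(r.response_window_s),
              float(r.feedback_onset_s), float(r.blank_onset_s))
        for r in tr_df.itertuples())
    return TaskTimeline(segments, trials)


def _read_csv_bundle(path: Path) -> DyadSession:
    meta, layout, behavior, covariates = _read_meta_sidecars(path)
    timeline = _read_timeline(path)
    wls = (float(meta["wavelength1_nm"]), float(meta["wavelength2_nm"]))
    members = []
    for suffix, sex in (("m", "M"), ("f", "F")):
        fname = f"signals_{suffix}.csv"
        mats = _signals_from_frame(_read_table(path / fname), fname)
        kw = {}
        wl_keys = [k for k in mats if k.startswith("wl")]
        if wl_keys:
            inten = np.stack([mats[f"wl{int(w)}"] for w in wls], axis=1)
            kw["intensity"] = inten
        else:
            kw["hbo"] = mats.get("hbo")
            kw["hbr"] = mats.get("hbr")
        members.append(ParticipantRecording(
            str(meta[f"participant_id_{suffix}"]), sex, float(meta["fs_hz"]),
            wavelengths_nm=wls,
            source_detector_distance_cm=float(meta["distance_cm"]), **kw))
    return DyadSession(str(meta["dyad_id"]), str(meta["group"]), members[0],
                       members[1], timeline, behavior, layout, covariates)


# ---------------------------------------------------------------------------
# SNIRF pair

def _write_snirf(rec: ParticipantRecording, timeline: TaskTimeline,
                 path: Path) -> None:
    if rec.intensity is None:
        raise ValidationError("snirf_pair supports raw-intensity recordings only")
    n_ch, _, n_t = rec.intensity.shape
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data=np.bytes_("1.0"))
        nirs = f.create_group("nirs")
        tags = nirs.create_group("metaDataTags")
        for k, v in (("SubjectID", rec.participant_id),
                     ("MeasurementDate", "2000-01-01"),
                     ("MeasurementTime", "00:00:00"),
                     ("LengthUnit", "m"), ("TimeUnit", "s"),
                     ("FrequencyUnit", "Hz")):
            tags.create_dataset(k, data=np.bytes_(v))
        data = nirs.create_group("data1")
        # measurement columns: channel-major, wavelength-minor
        series = rec.intensity.transpose(2, 0, 1).reshape(n_t, n_ch * 2)
        data.create_dataset("dataTimeSeries", data=series)
        data.create_dataset("time", data=np.arange(n_t) / rec.fs_hz)
        k = 1
        for ch in range(1, n_ch + 1):
            for wl in (1, 2):
                ml = data.create_group(f"measurementList{k}")
                ml.create_dataset("sourceIndex", data=np.int32(ch))
                ml.create_dataset("detectorIndex", data=np.int32(ch))
                ml.create_dataset("wavelengthIndex", data=np.int32(wl))
                ml.create_dataset("dataType", data=np.int32(1))
                ml.create_dataset("dataTypeIndex", data=np.int32(1))
                k += 1
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths_nm))
        d = rec.source_detector_distance_cm / 100.0
        xs = 0.04 * np.arange(n_ch)
        src = np.column_stack([xs, np.zeros(n_ch), np.zeros(n_ch)])
        det = np.column_stack([xs, np.full(n_ch, d), np.zeros(n_ch)])
        probe.create_dataset("sourcePos3D", data=src)
        probe.create_dataset("detectorPos3D", data=det)
        probe.create_dataset(
            "sourceLabels", data=np.array([f"S{i+1}".encode() for i in range(n_ch)]))
        probe.create_dataset(
            "detectorLabels", data=np.array([f"D{i+1}".encode() for i in range(n_ch)]))
        for i, seg in enumerate(timeline.segments, start=1):
            stim = nirs.create_group(f"stim{i}")
            name = seg.kind if seg.block_index is None else f"block{seg.block_index}"
            stim.create_dataset("name", data=np.bytes_(name))
            stim.create_dataset(
                "data", data=np.array([[seg.onset_s, seg.duration_s, 1.0]]))


def _write_snirf_pair(session: DyadSession, path: Path) -> list[str]:
    files = _write_csv_bundle(session, path)
    files = [f for f in files if not f.startswith("signals_")]
    for suffix, rec in (("m", session.member_m), ("f", session.member_f)):
        fname = f"{session.dyad_id}_{suffix}.snirf"
        _write_snirf(rec, session.timeline, path / fname)
        files.append(fname)
    return files


def _read_snirf(path: Path, sex: str, distance_cm: float) -> ParticipantRecording:
    with h5py.File(path, "r") as f:
        nirs = f["nirs"] if "nirs" in f else f["nirs1"]
        series = np.asarray(nirs["data1/dataTimeSeries"])
        time = np.asarray(nirs["data1/time"])
        fs = 1.0 / float(np.median(np.diff(time)))
        wls = tuple(float(w) for w in np.asarray(nirs["probe/wavelengths"]))
        n_meas = series.shape[1]
        n_ch = n_meas // 2
        inten = series.reshape(-1, n_ch, 2).transpose(1, 2, 0)
        pid = nirs["metaDataTags/SubjectID"][()]
        pid = pid.decode() if isinstance(pid, bytes) else str(pid)
    return ParticipantRecording(pid, sex, fs, intensity=inten,
                                wavelengths_nm=wls,
                                source_detector_distance_cm=distance_cm)


def _read_snirf_pair(path: Path) -> DyadSession:
    meta, layout, behavior, covariates = _read_meta_sidecars(path)
    timeline = _read_timeline(path)
    dyad_id = str(meta["dyad_id"])
    dist = float(meta["distance_cm"])
    rec_m = _read_snirf(path / f"{dyad_id}_m.snirf", "M", dist)
    rec_f = _read_snirf(path / f"{dyad_id}_f.snirf", "F", dist)
    return DyadSession(dyad_id, str(meta["group"]), rec_m, rec_f, timeline,
                       behavior, layout, covariates)


# ---------------------------------------------------------------------------
# cohorts

def write_cohort(sessions, root: str | Path, format: str = "csv_bundle") -> dict:
    """One bundle per dyad under ``root`` plus a cohort manifest."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    entries = {}
    for s in sessions:
        m = write_session(s, root / s.dyad_id, format)
        entries[s.dyad_id] = m["files"]
    manifest = {"format": format, "dyads": entries}
    (root / "cohort.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest


def read_cohort(root: str | Path, format: str = "csv_bundle") -> list[DyadSession]:
    root = Path(root)
    manifest = json.loads((root / "cohort.json").read_text())
    return [read_session(root / dyad_id, manifest["format"])
            for dyad_id in sorted(manifest["dyads"])]
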