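"""Plain-text serialisation of recordings, segment sets and distance
matrices: delimited matrices plus JSON sidecars, so every artifact of the
pipeline is inspectable and diffable."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .datatypes import HemoRecording, SegmentSet
from .geometry import DistanceMatrix
from .simulate import GroundTruth


def write_session(
    prefix: str | Path, rec: HemoRecording, truth: GroundTruth | None = None
) -> None:
    """Write one session as <prefix>.tsv (Δ[HbO₂] rows stacked over Δ[Hb]
    rows, columns = samples) and a <prefix>.json sidecar with sampling
    rate, channel indices, per-sample labels and any artifact ground
    truth."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(prefix.with_suffix(".tsv"), rec.stacked(), delimiter="\t",
               fmt="%.6g")
    meta = {
        "sampling_rate": rec.sampling_rate,
        "retained_channels": rec.retained_channels.tolist(),
        "labels_per_sample": rec.labels_per_sample.tolist(),
        "session_id": rec.session_id,
        "subject_id": rec.subject_id,
    }
    if truth is not None:
        meta["injected_spikes"] = [list(e) for e in truth.injected_spikes]
        meta["injected_steps"] = [list(e) for e in truth.injected_steps]
    prefix.with_suffix(".json").write_text(json.dumps(meta))


def read_session(prefix: str | Path) -> HemoRecording:
    """Inverse of :func:`write_session` (ground truth fields ignored)."""
    prefix = Path(prefix)
    data = np.loadtxt(prefix.with_suffix(".tsv"), delimiter="\t", ndmin=2)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    half = data.shape[0] // 2
    return HemoRecording(
        dHbO2=data[:half],
        dHb=data[half:],
        sampling_rate=float(meta["sampling_rate"]),
        labels_per_sample=np.asarray(meta["labels_per_sample"], dtype=int),
        retained_channels=np.asarray(meta["retained_channels"], dtype=int),
        session_id=meta.get("session_id", ""),
        subject_id=meta.get("subject_id", ""),
    )


def write_segments(directory: str | Path, segments: SegmentSet) -> None:
    """Write a segment set as one .tsv per segment plus manifest.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i in range(segments.n_segments):
        np.savetxt(directory / f"segment_{i:04d}.tsv",
                   segments.segments[i], delimiter="\t", fmt="%.6g")
    manifest = {
        "labels": segments.labels.tolist(),
        "window": segments.window,
        "sampling_rate": segments.sampling_rate,
        "d": segments.d,
        "session_id": segments.session_id,
        "subject_id": segments.subject_id,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest))


def read_segments(directory: str | Path) -> SegmentSet:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    labels = np.asarray(manifest["labels"], dtype=int)
    arrs = [
        np.loadtxt(directory / f"segment_{i:04d}.tsv", delimiter="\t",
                   ndmin=2)
        for i in range(labels.shape[0])
    ]
    return SegmentSet(
        segments=(np.stack(arrs) if arrs
                  else np.empty((0, manifest["d"], manifest["window"]))),
        labels=labels,
        window=int(manifest["window"]),
        sampling_rate=float(manifest["sampling_rate"]),
        session_id=manifest.get("session_id", ""),
        subject_id=manifest.get("subject_id", ""),
    )


def write_distance_matrix(prefix: str | Path, dm: DistanceMatrix) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(prefix.with_suffix(".tsv"), dm.values, delimiter="\t",
               fmt="%.9g")
    prefix.with_suffix(".json").write_text(json.dumps({
        "kind": dm.kind, "d_norm": dm.d_norm,
        "session_id": dm.session_id, "subject_id": dm.subject_id,
    }))


def read_distance_matrix(prefix: str | Path) -> DistanceMatrix:
    prefix = Path(prefix)
    values = np.loadtxt(prefix.with_suffix(".tsv"), delimiter="\t", ndmin=2)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return DistanceMatrix(
        values=values, kind=meta["kind"], d_norm=int(meta["d_norm"]),
        session_id=meta.get("session_id", ""),
        subject_id=meta.get("subject_id", ""),
    )
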