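"""Plain-text file formats and model persistence.

Recordings travel as CSV with header ``t,ch1,...,ch8`` (time in seconds to
6 decimals) plus an optional JSON sidecar (``<name>.meta.json``) carrying
the sampling rate and labels; features as CSV with layout-derived column
names and a ``label`` column, written at 12 significant digits so
round-trips are exact to well below any test tolerance.  Trained models
are persisted with joblib together with their spec, class list and a
format version that is checked on load.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from .classify import ClassifierSpec, TrainedClassifier
from .features import DEFAULT_AR_ORDER, FeatureVector, feature_names
from .synth import N_CHANNELS, EmgRecording, GestureLabel

__all__ = [
    "FormatError",
    "read_recording",
    "write_recording",
    "read_features",
    "write_features",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

_CHANNEL_COLS = [f"ch{i}" for i in range(1, N_CHANNELS + 1)]
_HEADER = ["t", *_CHANNEL_COLS]


class FormatError(ValueError):
    """Malformed recording, feature or model file."""


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_recording(path: str | Path, recording: EmgRecording) -> None:
    """Write a recording as CSV plus a JSON metadata sidecar."""
    path = Path(path)
    n = recording.n_samples
    df = pd.DataFrame(recording.samples, columns=_CHANNEL_COLS)
    df.insert(0, "t", np.arange(n) / recording.fs)
    df.to_csv(path, index=False, float_format="%.6f")
    meta = {
        "fs": recording.fs,
        "label": recording.label.name.lower() if recording.label is not None else None,
        "participant_id": recording.participant_id,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2) + "\n")


def read_recording(path: str | Path) -> EmgRecording:
    """Read a CSV recording; sampling rate comes from the sidecar when
    present, otherwise from the median timestamp increment.

    Out-of-range samples are clipped to [-128, 127] with a logged warning;
    a malformed header or non-monotonic time column is an error.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != _HEADER:
        raise FormatError(f"{path}: expected header {','.join(_HEADER)}, got {','.join(df.columns)}")
    if len(df) == 0:
        raise FormatError(f"{path}: recording has no samples")
    t = df["t"].to_numpy(dtype=float)
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise FormatError(f"{path}: time column must be strictly increasing")

    fs = None
    label = None
    participant_id = None
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fs = meta.get("fs")
        if meta.get("label") is not None:
            label = GestureLabel[meta["label"].upper()]
        participant_id = meta.get("participant_id")
    if fs is None:
        if len(t) < 2:
            raise FormatError(f"{path}: cannot infer fs from a single sample")
        fs = 1.0 / float(np.median(np.diff(t)))

    samples = df[_CHANNEL_COLS].to_numpy()
    if not np.issubdtype(samples.dtype, np.integer):
        if not np.allclose(samples, np.round(samples)):
            raise FormatError(f"{path}: channel values must be integers")
        samples = np.round(samples).astype(np.int64)
    if samples.size and (samples.min() < -128 or samples.max() > 127):
        logger.warning("%s: samples outside [-128, 127]; clipping", path)
        samples = np.clip(samples, -128, 127)
    return EmgRecording(
        samples=samples.astype(np.int16), fs=float(fs), label=label, participant_id=participant_id
    )


def write_features(
    path: str | Path,
    vectors: list[FeatureVector],
    labels: list[GestureLabel] | None = None,
) -> None:
    """Write feature vectors as a labeled CSV table.

    Labels default to each vector's own label; unlabeled rows are stored
    with an empty label field.
    """
    path = Path(path)
    if labels is not None and len(labels) != len(vectors):
        raise ValueError("labels must match vectors in length")
    m = vectors[0].ar_order if vectors else DEFAULT_AR_ORDER
    if any(v.ar_order != m for v in vectors):
        raise ValueError("all feature vectors must share one AR order")
    rows = np.vstack([v.values for v in vectors]) if vectors else np.empty((0, len(feature_names(m))))
    df = pd.DataFrame(rows, columns=feature_names(m))
    eff_labels = labels if labels is not None else [v.label for v in vectors]
    df["label"] = [lab.name.lower() if lab is not None else "" for lab in eff_labels]
    df.to_csv(path, index=False, float_format="%.12g")


def read_features(path: str | Path) -> tuple[list[FeatureVector], list[GestureLabel | None]]:
    """Read a feature table; infers the AR order from the column count."""
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=False)
    if "label" not in df.columns:
        raise FormatError(f"{path}: missing label column")
    n_feat = len(df.columns) - 1
    if n_feat % N_CHANNELS != 0 or n_feat // N_CHANNELS < 3:
        raise FormatError(f"{path}: {n_feat} feature columns do not fit the channel layout")
    m = n_feat // N_CHANNELS - 2
    if list(df.columns[:-1]) != feature_names(m):
        raise FormatError(f"{path}: feature column names do not match the m={m} layout")
    labels: list[GestureLabel | None] = [
        GestureLabel[str(s).upper()] if str(s) else None for s in df["label"]
    ]
    vectors = [
        FeatureVector(values=row, ar_order=m, label=lab)
        for row, lab in zip(df.iloc[:, :-1].to_numpy(dtype=float), labels)
    ]
    return vectors, labels


def save_model(path: str | Path, model: TrainedClassifier) -> None:
    """Persist a trained classifier (pipeline, scaler state, spec, classes)."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "spec": model.spec.__dict__,
        "classes": [int(c) for c in model.classes],
        "pipeline": model.pipeline,
    }
    joblib.dump(payload, Path(path))


def load_model(path: str | Path) -> TrainedClassifier:
    """Load a persisted classifier, validating format version and contents."""
    path = Path(path)
    try:
        payload = joblib.load(path)
    except Exception as exc:  # truncated/corrupted pickle
        raise FormatError(f"{path}: corrupted or unreadable model file ({exc})") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise FormatError(f"{path}: not a recognized model file")
    if payload["format_version"] != MODEL_FORMAT_VERSION:
        raise FormatError(
            f"{path}: model format version {payload['format_version']} "
            f"not supported (expected {MODEL_FORMAT_VERSION})"
        )
    missing = {"spec", "classes", "pipeline"} - payload.keys()
    if missing:
        raise FormatError(f"{path}: model file missing fields {sorted(missing)}")
    spec = ClassifierSpec(**payload["spec"])
    classes = [GestureLabel(c) for c in payload["classes"]]
    return TrainedClassifier(spec=spec, pipeline=payload["pipeline"], classes=classes)
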