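"""Desk-scale emulation of online operation: activity segmentation,
sliding-window classification with debouncing, and the gesture→hand-action
map used to drive the prosthesis actuators.

A continuous 8-channel stream is preprocessed, the max-channel envelope is
thresholded against a rest baseline estimated from the first half second,
and classifier decisions on trailing windows are debounced: a gesture
event is emitted only once ``vote_k`` consecutive windows agree while the
segmenter marks activity, emulating stable actuation commands.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .classify import TrainedClassifier, predict
from .dsp import DEFAULT_ENVELOPE_CUTOFF_HZ, FilterSpec, preprocess
from .features import extract_features
from .synth import EmgRecording, GestureLabel

__all__ = [
    "HandAction",
    "SegmentationSpec",
    "GestureEvent",
    "ACTION_MAP",
    "map_action",
    "segment",
    "stream_classify",
    "windowed_training_set",
]


class HandAction(IntEnum):
    """Prosthetic hand actions, one per trained gesture."""

    CLOSED_HAND_AND_FINGERS = 0
    OPEN_HAND_AND_FINGERS = 1
    CLOSING_ONE_FINGER = 2
    CLOSING_TWO_FINGERS = 3


#: Bijective gesture → actuator-action map.
ACTION_MAP: dict[GestureLabel, HandAction] = {
    GestureLabel.CLOSE: HandAction.CLOSED_HAND_AND_FINGERS,
    GestureLabel.OPEN: HandAction.OPEN_HAND_AND_FINGERS,
    GestureLabel.WAVE_IN: HandAction.CLOSING_ONE_FINGER,
    GestureLabel.WAVE_OUT: HandAction.CLOSING_TWO_FINGERS,
}


def map_action(label: GestureLabel) -> HandAction:
    """Hand action commanded by a recognized gesture."""
    return ACTION_MAP[GestureLabel(label)]


@dataclass(frozen=True)
class SegmentationSpec:
    """Envelope-threshold activity detector parameters.

    ``onset_threshold`` is a multiple of the rest-baseline RMS;
    ``baseline_s`` seconds at the start of the stream are assumed rest.
    Active runs shorter than ``min_active_s`` are dropped, and runs
    separated by gaps shorter than ``hangover_s`` are merged first.
    """

    onset_threshold: float = 3.0
    min_active_s: float = 0.3
    hangover_s: float = 0.3
    baseline_s: float = 0.5

    def __post_init__(self) -> None:
        if self.onset_threshold <= 1:
            raise ValueError("onset_threshold must be > 1")
        if self.min_active_s <= 0:
            raise ValueError("min_active_s must be positive")
        if self.hangover_s < 0 or self.baseline_s <= 0:
            raise ValueError("hangover_s must be >= 0 and baseline_s > 0")


@dataclass(frozen=True)
class GestureEvent:
    """A recognized gesture occupying ``[start_s, end_s)`` of the stream."""

    start_s: float
    end_s: float
    label: GestureLabel
    action: HandAction

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError("event must have start_s < end_s")
        if self.action != map_action(self.label):
            raise ValueError("action must follow the gesture→action map")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True in a boolean mask."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(np.int8), [0]))))
    return [(int(idx[i]), int(idx[i + 1])) for i in range(0, idx.size, 2)]


def segment(processed, spec: SegmentationSpec | None = None) -> list[tuple[float, float]]:
    """Detect active intervals of a processed recording.

    The detector runs on the max-across-channels envelope; the baseline is
    the RMS of that trace over the first ``baseline_s`` seconds, which the
    acquisition protocol guarantees to be rest.
    """
    spec = spec if spec is not None else SegmentationSpec()
    env = np.max(processed.envelope, axis=1)
    fs = processed.fs
    n_base = int(round(spec.baseline_s * fs))
    if env.size < n_base:
        raise ValueError(
            f"stream too short for a {spec.baseline_s} s rest baseline"
        )
    baseline_rms = float(np.sqrt(np.mean(env[:n_base] ** 2)))
    mask = env > spec.onset_threshold * baseline_rms

    runs = _runs(mask)
    # merge across short gaps, then drop short runs
    merged: list[tuple[int, int]] = []
    gap = spec.hangover_s * fs
    for start, stop in runs:
        if merged and start - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], stop)
        else:
            merged.append((start, stop))
    min_len = spec.min_active_s * fs
    return [(s / fs, e / fs) for s, e in merged if e - s >= min_len]


def stream_classify(
    stream: EmgRecording,
    model: TrainedClassifier,
    window_s: float = 1.0,
    hop_s: float = 0.1,
    vote_k: int = 3,
    seg_spec: SegmentationSpec | None = None,
    filter_spec: FilterSpec | None = None,
    envelope_cutoff: float = DEFAULT_ENVELOPE_CUTOFF_HZ,
    ar_order: int = 8,
    feature_source: str = "envelope",
) -> list[GestureEvent]:
    """Sliding-window streaming recognition with debouncing.

    Every ``hop_s`` the trailing ``window_s`` of raw samples is run through
    the preprocessing chain and feature extractor and classified.  Only
    windows lying fully inside an active segment count; within each
    segment the first run of ``vote_k`` consecutive agreeing decisions
    triggers a single event carrying that label, which then extends to the
    segment end (one stable actuation command per detected gesture).
    Events are non-overlapping and time-ordered by construction; emission
    latency is at most ``window_s + vote_k*hop_s`` after segment onset.
    """
    if window_s < 0.25:
        raise ValueError("window_s must be >= 0.25 s")
    if not 0 < hop_s <= window_s:
        raise ValueError("need 0 < hop_s <= window_s")
    if vote_k < 1:
        raise ValueError("vote_k must be >= 1")
    fs = stream.fs
    n_win = int(round(window_s * fs))
    if n_win <= 2 * ar_order:
        raise ValueError("window too short for the AR order (need window_s*fs > 2*m)")
    n = stream.n_samples
    if n < n_win:
        raise ValueError("stream shorter than one window")

    processed_full = preprocess(stream, filter_spec, envelope_cutoff)
    segments = segment(processed_full, seg_spec)
    if not segments:
        return []

    hop = int(round(hop_s * fs))
    ends = np.arange(n_win, n + 1, hop)
    events: list[GestureEvent] = []
    prev_end = -np.inf
    for seg_start, seg_end in segments:
        # windows fully inside the active segment (a window straddling the
        # onset mixes rest and activity and only adds label flicker)
        in_seg = [
            int(end)
            for end in ends
            if end / fs - window_s >= seg_start and end / fs <= seg_end
        ]
        run_label: int | None = None
        run_len = 0
        for end in in_seg:
            window = EmgRecording(samples=stream.samples[end - n_win : end], fs=fs)
            proc = preprocess(window, filter_spec, envelope_cutoff)
            vec = extract_features(proc, m=ar_order, source=feature_source)
            decided = int(predict(model, vec.values))
            if decided == run_label:
                run_len += 1
            else:
                run_label, run_len = decided, 1
            if run_len >= vote_k:
                label = GestureLabel(run_label)
                start = max(prev_end, seg_start)
                if start < seg_end:
                    events.append(
                        GestureEvent(
                            start_s=start, end_s=seg_end, label=label, action=map_action(label)
                        )
                    )
                    prev_end = seg_end
                break
    return events


def windowed_training_set(
    recordings: list[EmgRecording],
    window_s: float = 1.0,
    filter_spec: FilterSpec | None = None,
    envelope_cutoff: float = DEFAULT_ENVELOPE_CUTOFF_HZ,
    ar_order: int = 8,
    feature_source: str = "envelope",
    seg_spec: SegmentationSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Build a training matrix matched to streaming windows.

    For each labeled trial the longest active segment is located and a
    ``window_s`` crop centred on it is preprocessed and featurized, so the
    training distribution matches what :func:`stream_classify` sees at run
    time (plateau windows, not whole trials with rest padding).
    """
    X_rows = []
    y_rows = []
    for rec in recordings:
        if rec.label is None:
            raise ValueError("all recordings must be labeled")
        n_win = int(round(window_s * rec.fs))
        proc = preprocess(rec, filter_spec, envelope_cutoff)
        segs = segment(proc, seg_spec)
        if segs:
            s, e = max(segs, key=lambda se: se[1] - se[0])
            centre = int(round((s + e) / 2 * rec.fs))
        else:
            centre = rec.n_samples // 2
        start = int(np.clip(centre - n_win // 2, 0, rec.n_samples - n_win))
        crop = EmgRecording(
            samples=rec.samples[start : start + n_win],
            fs=rec.fs,
            label=rec.label,
            participant_id=rec.participant_id,
        )
        vec = extract_features(
            preprocess(crop, filter_spec, envelope_cutoff), m=ar_order, source=feature_source
        )
        X_rows.append(vec.values)
        y_rows.append(int(rec.label))
    return np.vstack(X_rows), np.array(y_rows)
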