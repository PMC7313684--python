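"""Preprocessing chain for raw sEMG: mean removal, band-pass, rectification,
envelope extraction.

The band-pass targets the 20–450 Hz surface-EMG band.  At the armband's
200 Hz sampling rate a 450 Hz edge is unrealizable, so the upper cutoff is
clamped to 0.45*fs (90 Hz at fs=200) with a logged warning; the
physiologically critical 20 Hz low edge is always preserved.  All filters
are Butterworth, applied zero-phase (forward-backward) by default with
reflective padding so 4 s records show no startup transients or group
delay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .synth import EmgRecording, GestureLabel, N_CHANNELS

__all__ = [
    "FilterSpec",
    "ProcessedRecording",
    "effective_highcut",
    "remove_dc",
    "bandpass",
    "rectify",
    "envelope",
    "preprocess",
    "DEFAULT_ENVELOPE_CUTOFF_HZ",
]

logger = logging.getLogger(__name__)

#: Default cutoff of the linear-envelope low-pass (Hz).
DEFAULT_ENVELOPE_CUTOFF_HZ = 6.0

_PADTYPE = "even"  # reflective padding for zero-phase application


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass design: Butterworth of the given design order.

    ``high_cut`` is a *requested* edge; the edge actually realized at a
    sampling rate ``fs`` is ``min(high_cut, 0.45*fs)`` (see
    :func:`effective_highcut`).
    """

    low_cut: float = 20.0
    high_cut: float = 450.0
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.low_cut < self.high_cut:
            raise ValueError("need 0 < low_cut < high_cut")
        if self.order < 1:
            raise ValueError("order must be >= 1")


@dataclass
class ProcessedRecording:
    """All stages of the preprocessing chain, retained for inspection.

    The four matrices share the shape ``(n_samples, 8)``; ``envelope`` is
    the stage normally fed to feature extraction.
    """

    centered: np.ndarray
    filtered: np.ndarray
    rectified: np.ndarray
    envelope: np.ndarray
    fs: float
    label: GestureLabel | None = None
    participant_id: int | None = None

    @property
    def n_samples(self) -> int:
        return self.envelope.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


_warned_clamps: set[tuple[float, float]] = set()


def effective_highcut(spec: FilterSpec, fs: float) -> float:
    """Upper cutoff realized at sampling rate ``fs``, clamping at 0.45*fs.

    Clamping is reported through a logged warning, once per distinct
    (requested cutoff, fs) combination to keep batch runs readable.
    """
    ceiling = 0.45 * fs
    if spec.high_cut > ceiling:
        key = (spec.high_cut, fs)
        first = key not in _warned_clamps
        _warned_clamps.add(key)
        if first:
            logger.warning(
                "band-pass high cutoff %.6g Hz exceeds 0.45*fs=%.6g Hz at fs=%.6g; "
                "clamping to %.6g Hz",
                spec.high_cut,
                ceiling,
                fs,
                ceiling,
            )
        return ceiling
    return spec.high_cut


def remove_dc(x: np.ndarray) -> np.ndarray:
    """Subtract the mean of ``x`` (AC coupling)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot remove DC from an empty signal")
    return x - x.mean(axis=0)


def _design_bandpass(fs: float, spec: FilterSpec) -> np.ndarray:
    if fs <= 2 * spec.low_cut:
        raise ValueError(
            f"fs={fs} Hz cannot support a band-pass with low_cut={spec.low_cut} Hz "
            "(need fs > 2*low_cut)"
        )
    high = effective_highcut(spec, fs)
    return _sig.butter(spec.order, [spec.low_cut, high], btype="bandpass", fs=fs, output="sos")


def bandpass(x: np.ndarray, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Band-pass ``x``; zero-phase (forward-backward) when requested."""
    spec = spec if spec is not None else FilterSpec()
    x = np.asarray(x, dtype=float)
    sos = _design_bandpass(fs, spec)
    if spec.zero_phase:
        return _sig.sosfiltfilt(sos, x, axis=0, padtype=_PADTYPE)
    return _sig.sosfilt(sos, x, axis=0)


def rectify(x: np.ndarray) -> np.ndarray:
    """Full-wave rectification: elementwise absolute value."""
    return np.abs(np.asarray(x, dtype=float))


def envelope(
    rectified: np.ndarray, fs: float, cutoff: float = DEFAULT_ENVELOPE_CUTOFF_HZ
) -> np.ndarray:
    """Linear envelope: zero-phase 2nd-order Butterworth low-pass of the
    rectified signal, clipped at zero from below."""
    if not 0 < cutoff < 0.45 * fs:
        raise ValueError(f"envelope cutoff must lie in (0, 0.45*fs); got {cutoff} at fs={fs}")
    rectified = np.asarray(rectified, dtype=float)
    sos = _sig.butter(2, cutoff, btype="lowpass", fs=fs, output="sos")
    env = _sig.sosfiltfilt(sos, rectified, axis=0, padtype=_PADTYPE)
    return np.clip(env, 0.0, None)


def preprocess(
    recording: EmgRecording,
    filter_spec: FilterSpec | None = None,
    envelope_cutoff: float = DEFAULT_ENVELOPE_CUTOFF_HZ,
) -> ProcessedRecording:
    """Run the full chain per channel: mean removal → band-pass →
    rectification → envelope."""
    filter_spec = filter_spec if filter_spec is not None else FilterSpec()
    raw = np.asarray(recording.samples, dtype=float)
    if raw.ndim != 2 or raw.shape[1] != N_CHANNELS:
        raise ValueError(f"expected (n, {N_CHANNELS}) samples, got {raw.shape}")
    centered = remove_dc(raw)
    filtered = bandpass(centered, recording.fs, filter_spec)
    rect = rectify(filtered)
    env = envelope(rect, recording.fs, envelope_cutoff)
    return ProcessedRecording(
        centered=centered,
        filtered=filtered,
        rectified=rect,
        envelope=env,
        fs=recording.fs,
        label=recording.label,
        participant_id=recording.participant_id,
    )
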