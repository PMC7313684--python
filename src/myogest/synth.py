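"""Synthetic surface-EMG generation.

Emulates an 8-channel armband acquisition: each trial starts at rest,
ramps into a sustained gesture, and returns to rest.  Channel activity is
modelled as band-limited Gaussian noise ("carrier") whose RMS amplitude is
modulated by a trapezoidal activation envelope and a per-gesture,
per-channel gain pattern, on top of a constant noise floor.  Samples are
quantized to the 8-bit integer range of the armband stream.

All amplitudes (``noise_floor``, profile ``gains``) are expressed as RMS in
quantization counts, because carriers are normalized to unit RMS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Mapping

import numpy as np
from scipy import signal as _sig

__all__ = [
    "GestureLabel",
    "ChannelProfile",
    "TrialSpec",
    "EmgRecording",
    "N_CHANNELS",
    "bandlimited_noise",
    "default_channel_profiles",
    "generate_gesture_trial",
    "generate_dataset",
]

N_CHANNELS = 8

#: Low edge of the physiological surface-EMG band used for the carrier (Hz).
CARRIER_LOW_HZ = 20.0

#: Duration of the linear rise/fall of the activation envelope (s).
RAMP_S = 0.25


class GestureLabel(IntEnum):
    """The four trained hand gestures, with stable integer codes."""

    CLOSE = 0      # fist
    OPEN = 1       # spread fingers
    WAVE_IN = 2
    WAVE_OUT = 3


@dataclass(frozen=True)
class ChannelProfile:
    """Per-channel RMS gain pattern of one gesture (dimensionless, >= 0)."""

    gesture: GestureLabel
    gains: np.ndarray

    def __post_init__(self) -> None:
        gains = np.asarray(self.gains, dtype=float)
        if gains.shape != (N_CHANNELS,):
            raise ValueError(f"gains must have length {N_CHANNELS}, got {gains.shape}")
        if np.any(gains < 0):
            raise ValueError("gains must be non-negative")
        object.__setattr__(self, "gains", gains)


@dataclass(frozen=True)
class TrialSpec:
    """Acquisition parameters of a single rest→gesture→rest trial.

    Parameters
    ----------
    duration_s
        Total trial length in seconds (the protocol uses ~4 s).
    fs
        Sampling rate in Hz (the armband streams at 200 Hz).
    rest_fraction
        Fraction of the trial spent at rest at *each* end, in [0, 0.5).
    noise_floor
        RMS of the rest-state noise, in quantization counts.
    seed
        Seed of the trial's random generator; identical seeds give
        bit-identical recordings.
    """

    duration_s: float = 4.0
    fs: float = 200.0
    rest_fraction: float = 0.25
    noise_floor: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not 0 <= self.rest_fraction < 0.5:
            raise ValueError("rest_fraction must be in [0, 0.5)")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass
class EmgRecording:
    """Raw multi-channel integer sEMG recording.

    ``samples`` is an ``(n_samples, 8)`` integer matrix with values in
    [-128, 127]; ``label`` and ``participant_id`` are optional metadata.
    """

    samples: np.ndarray
    fs: float
    label: GestureLabel | None = None
    participant_id: int | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples)
        if samples.ndim != 2 or samples.shape[1] != N_CHANNELS:
            raise ValueError(f"samples must be (n, {N_CHANNELS}), got {samples.shape}")
        if not np.issubdtype(samples.dtype, np.integer):
            raise ValueError("samples must be integers")
        if samples.size and (samples.min() < -128 or samples.max() > 127):
            raise ValueError("samples must lie in [-128, 127]")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.samples = samples

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


# Default per-gesture gain patterns (RMS counts per channel).  The armband's
# electrodes ring the forearm, so each gesture activates a contiguous group
# of channels; close/open deliberately share their dominant flexor-side
# channels (their confusion is the common failure mode in practice), while
# wave-in/wave-out sit on partially overlapping extensor-side groups.
_DEFAULT_GAINS: dict[GestureLabel, tuple[float, ...]] = {
    GestureLabel.CLOSE: (28, 20, 10, 4, 2, 4, 12, 22),
    GestureLabel.OPEN: (22, 26, 14, 6, 2, 2, 6, 12),
    GestureLabel.WAVE_IN: (4, 8, 18, 28, 22, 10, 4, 2),
    GestureLabel.WAVE_OUT: (6, 4, 8, 16, 26, 28, 14, 6),
}


def default_channel_profiles() -> dict[GestureLabel, ChannelProfile]:
    """Return the four built-in gesture gain profiles.

    The patterns are pairwise linearly independent (no profile is a scalar
    multiple of another) so the classes are separable in principle, yet
    close/open overlap strongly enough that noise and inter-participant
    variability produce realistic confusions.
    """
    return {
        g: ChannelProfile(gesture=g, gains=np.array(v, dtype=float))
        for g, v in _DEFAULT_GAINS.items()
    }


def bandlimited_noise(
    rng: np.random.Generator,
    n: int,
    fs: float,
    low: float = CARRIER_LOW_HZ,
    high: float | None = None,
) -> np.ndarray:
    """Zero-mean Gaussian noise band-limited to [low, high] Hz, unit RMS.

    ``high`` defaults to 0.45*fs.  A one-second burn-in is generated and
    discarded so the returned segment is stationary.  Raises if the band is
    empty at the given sampling rate (fs <= 2*low).
    """
    if fs <= 2 * low:
        raise ValueError(f"fs={fs} too low for a [{low}, 0.45*fs] Hz carrier band")
    if high is None:
        high = 0.45 * fs
    high = min(high, 0.45 * fs)
    burn = int(round(fs))
    white = rng.standard_normal(n + burn)
    sos = _sig.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    shaped = _sig.sosfilt(sos, white)[burn:]
    rms = np.sqrt(np.mean(shaped**2))
    return shaped / rms if rms > 0 else shaped


def _activation_envelope(spec: TrialSpec) -> np.ndarray:
    """Trapezoidal activation profile: rest, linear ramp, plateau, ramp, rest."""
    n = spec.n_samples
    t = np.arange(n) / spec.fs
    t_on = spec.rest_fraction * spec.duration_s
    t_off = (1 - spec.rest_fraction) * spec.duration_s
    active = t_off - t_on
    ramp = min(RAMP_S, active / 2)
    env = np.zeros(n)
    if ramp > 0:
        env = np.clip(np.minimum(t - t_on, t_off - t) / ramp, 0.0, 1.0)
    else:
        env = ((t >= t_on) & (t < t_off)).astype(float)
    return env


def _quantize(x: np.ndarray) -> np.ndarray:
    """Round half away from zero, then clip to the 8-bit signed range."""
    rounded = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return np.clip(rounded, -128, 127).astype(np.int16)


def generate_gesture_trial(
    gesture: GestureLabel,
    spec: TrialSpec | None = None,
    profile: ChannelProfile | None = None,
    participant_id: int | None = None,
) -> EmgRecording:
    """Generate one rest→gesture→rest trial.

    Each channel is ``noise_floor*w(t) + gain*A(t)*w'(t)`` where ``w`` and
    ``w'`` are independent unit-RMS carriers band-limited to
    [20, 0.45*fs] Hz and ``A(t)`` is the trapezoidal activation envelope,
    quantized to [-128, 127].  Deterministic in ``spec.seed``.
    """
    spec = spec if spec is not None else TrialSpec()
    if profile is None:
        profile = default_channel_profiles()[gesture]
    if profile.gesture != gesture:
        raise ValueError(f"profile is for {profile.gesture!r}, not {gesture!r}")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    env = _activation_envelope(spec)
    out = np.empty((n, N_CHANNELS), dtype=np.int16)
    for c in range(N_CHANNELS):
        rest_carrier = bandlimited_noise(rng, n, spec.fs)
        burst_carrier = bandlimited_noise(rng, n, spec.fs)
        analog = spec.noise_floor * rest_carrier + profile.gains[c] * env * burst_carrier
        out[:, c] = _quantize(analog)
    return EmgRecording(samples=out, fs=spec.fs, label=gesture, participant_id=participant_id)


def generate_dataset(
    n_participants: int,
    reps_per_gesture: int,
    spec: TrialSpec | None = None,
    participant_variability: float = 0.3,
    trial_variability: float = 0.35,
    seed: int = 0,
) -> list[EmgRecording]:
    """Generate a balanced labeled dataset across participants.

    Each participant receives a private copy of the default profiles whose
    gains are jittered by a per-channel multiplicative log-normal factor
    with scale ``participant_variability`` (0 disables jitter), emulating
    electrode placement and anatomy differences.  On top of that, every
    repetition scales the whole profile by a common log-normal effort
    factor with scale ``trial_variability``: contraction strength varies
    from repetition to repetition, so absolute channel amplitudes drift
    between trials while the relative cross-channel pattern of a gesture
    is preserved.  Returns ``n_participants * 4 * reps_per_gesture``
    recordings, exactly balanced over the four gestures.  The master
    ``seed`` deterministically spawns one child seed per participant
    (profile jitter) and one per trial (effort factor + carriers), so any
    single trial is reproducible in isolation.
    """
    if n_participants < 1 or reps_per_gesture < 1:
        raise ValueError("n_participants and reps_per_gesture must be >= 1")
    if participant_variability < 0 or trial_variability < 0:
        raise ValueError("variability scales must be non-negative")
    spec = spec if spec is not None else TrialSpec()
    base = default_channel_profiles()
    master = np.random.SeedSequence(seed)
    participant_seqs = master.spawn(n_participants)
    recordings: list[EmgRecording] = []
    for pid, pseq in enumerate(participant_seqs):
        jitter_rng = np.random.default_rng(pseq.spawn(1)[0])
        profiles: dict[GestureLabel, ChannelProfile] = {}
        for g, prof in base.items():
            factor = (
                jitter_rng.lognormal(0.0, participant_variability, size=N_CHANNELS)
                if participant_variability > 0
                else np.ones(N_CHANNELS)
            )
            profiles[g] = ChannelProfile(gesture=g, gains=prof.gains * factor)
        trial_seqs = pseq.spawn(len(base) * reps_per_gesture)
        i = 0
        for g in base:
            for _ in range(reps_per_gesture):
                tseq = trial_seqs[i]
                i += 1
                effort = (
                    float(np.random.default_rng(tseq).lognormal(0.0, trial_variability))
                    if trial_variability > 0
                    else 1.0
                )
                sub_seed = int(tseq.generate_state(1)[0] & 0x7FFFFFFF)
                trial_profile = ChannelProfile(gesture=g, gains=profiles[g].gains * effort)
                recordings.append(
                    generate_gesture_trial(
                        g,
                        replace(spec, seed=sub_seed),
                        trial_profile,
                        participant_id=pid,
                    )
                )
    return recordings
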