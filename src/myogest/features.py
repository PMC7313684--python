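"""Feature extraction: per-channel AR(8) coefficients, MAV and SD.

Each channel of a processed recording is summarized by the coefficients of
an autoregressive model

    x(t) = sum_{k=1..m} a_k x(t-k) + e(t),

fitted with Burg's recursion, plus the mean absolute value (MAV) and the
sample standard deviation (SD) of the same signal.  With m=8 over 8
channels this yields the 80-entry classifier input, laid out as
``[a_1..a_m, MAV, SD]`` per channel, channels 1..8 concatenated.

Burg's method is used because it produces stable models (all roots of the
characteristic polynomial strictly inside the unit circle) even on short
records; a Yule-Walker / least-squares fit serves as an independent
cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dsp import ProcessedRecording
from .synth import N_CHANNELS, GestureLabel

__all__ = [
    "ARModel",
    "FeatureVector",
    "fit_ar",
    "mav",
    "sd",
    "extract_features",
    "feature_names",
    "feature_matrix",
    "DEFAULT_AR_ORDER",
    "FEATURE_SOURCES",
]

DEFAULT_AR_ORDER = 8

#: Processing stage the features are computed on.  The envelope is the
#: default: it is the stage that tracks muscle force, and a single
#: convention keeps AR, MAV and SD comparable across channels.
FEATURE_SOURCES = ("envelope", "rectified", "filtered")


@dataclass(frozen=True)
class ARModel:
    """Autoregressive model of order ``m`` under the convention
    ``x(t) = sum a_k x(t-k) + e(t)``."""

    order: int
    coefficients: np.ndarray
    residual_variance: float

    def __post_init__(self) -> None:
        coeffs = np.asarray(self.coefficients, dtype=float)
        if coeffs.shape != (self.order,):
            raise ValueError("coefficient vector length must equal the order")
        if self.residual_variance < 0:
            raise ValueError("residual_variance must be non-negative")
        object.__setattr__(self, "coefficients", coeffs)

    def poles(self) -> np.ndarray:
        """Roots of the characteristic polynomial z^m - a_1 z^{m-1} - ... - a_m."""
        return np.roots(np.concatenate(([1.0], -self.coefficients)))


def fit_ar(signal: np.ndarray, m: int = DEFAULT_AR_ORDER) -> ARModel:
    """Fit an AR(m) model by Burg's recursion.

    The reflection coefficients minimize the sum of forward and backward
    prediction-error powers at each stage, which keeps |k| <= 1 and hence
    the model stable.  ``residual_variance`` is the final prediction-error
    power.  An exactly constant signal is a defined degenerate case: all
    coefficients 0 and residual variance 0.
    """
    x = np.asarray(signal, dtype=float).ravel()
    n = x.size
    if m < 1:
        raise ValueError("AR order must be >= 1")
    if n <= 2 * m:
        raise ValueError(f"signal of length {n} too short for AR({m}); need > {2 * m}")
    if np.ptp(x) == 0:
        return ARModel(order=m, coefficients=np.zeros(m), residual_variance=0.0)

    # a holds the prediction-error filter [1, c_1, ..., c_k]; Eq. coefficients
    # are a_k = -c_k.
    a = np.ones(1)
    energy = float(x @ x) / n
    ef = x.copy()  # forward prediction error, indexed by t
    eb = x.copy()  # backward prediction error, indexed by t
    for k in range(1, m + 1):
        f = ef[k:]
        b = eb[k - 1 : n - 1]
        den = float(f @ f + b @ b)
        kref = 0.0 if den == 0 else -2.0 * float(f @ b) / den
        a = np.concatenate((a, [0.0]))
        a = a + kref * a[::-1]
        energy *= 1.0 - kref * kref
        new_f = f + kref * b
        new_b = b + kref * f
        ef = ef.copy()
        eb = eb.copy()
        ef[k:] = new_f
        eb[k:] = new_b
    return ARModel(order=m, coefficients=-a[1:], residual_variance=max(energy, 0.0))


def mav(signal: np.ndarray) -> float:
    """Mean absolute value of a signal window."""
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("mav of an empty signal is undefined")
    return float(np.mean(np.abs(x)))


def sd(signal: np.ndarray) -> float:
    """Sample standard deviation (divisor n-1)."""
    x = np.asarray(signal, dtype=float)
    if x.size < 2:
        raise ValueError("sd needs at least 2 samples")
    return float(np.std(x, ddof=1))


def feature_names(m: int = DEFAULT_AR_ORDER) -> list[str]:
    """Column names matching the committed feature layout."""
    names: list[str] = []
    for c in range(1, N_CHANNELS + 1):
        names.extend(f"ch{c}_a{k}" for k in range(1, m + 1))
        names.append(f"ch{c}_mav")
        names.append(f"ch{c}_sd")
    return names


@dataclass(frozen=True)
class FeatureVector:
    """Flat feature vector of length ``8*(m+2)`` (80 for m=8).

    Layout per channel: ``[a_1..a_m, MAV, SD]``; channels concatenated in
    order 1..8.
    """

    values: np.ndarray
    ar_order: int = DEFAULT_AR_ORDER
    label: GestureLabel | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        expected = N_CHANNELS * (self.ar_order + 2)
        if values.shape != (expected,):
            raise ValueError(f"expected {expected} entries for m={self.ar_order}, got {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature vector must be finite")
        object.__setattr__(self, "values", values)

    def channel_blocks(self) -> np.ndarray:
        """Unpack into an ``(8, m+2)`` array of per-channel blocks."""
        return self.values.reshape(N_CHANNELS, self.ar_order + 2)

    @classmethod
    def from_channel_blocks(
        cls,
        blocks: np.ndarray,
        ar_order: int = DEFAULT_AR_ORDER,
        label: GestureLabel | None = None,
    ) -> "FeatureVector":
        blocks = np.asarray(blocks, dtype=float)
        if blocks.shape != (N_CHANNELS, ar_order + 2):
            raise ValueError(f"expected ({N_CHANNELS}, {ar_order + 2}) blocks, got {blocks.shape}")
        return cls(values=blocks.ravel(), ar_order=ar_order, label=label)


def extract_features(
    processed: ProcessedRecording,
    m: int = DEFAULT_AR_ORDER,
    source: str = "envelope",
) -> FeatureVector:
    """Assemble the classifier input for one recording."""
    if source not in FEATURE_SOURCES:
        raise ValueError(f"source must be one of {FEATURE_SOURCES}")
    data = getattr(processed, source)
    blocks = np.empty((N_CHANNELS, m + 2))
    for c in range(N_CHANNELS):
        chan = data[:, c]
        model = fit_ar(chan, m)
        blocks[c, :m] = model.coefficients
        blocks[c, m] = mav(chan)
        blocks[c, m + 1] = sd(chan)
    return FeatureVector.from_channel_blocks(blocks, ar_order=m, label=processed.label)


def feature_matrix(
    processed_list: list[ProcessedRecording],
    m: int = DEFAULT_AR_ORDER,
    source: str = "envelope",
) -> tuple[np.ndarray, np.ndarray]:
    """Stack features of many recordings into ``(X, y)`` arrays.

    ``y`` holds integer gesture codes; raises if any recording is unlabeled.
    """
    vectors = [extract_features(p, m=m, source=source) for p in processed_list]
    if any(v.label is None for v in vectors):
        raise ValueError("all recordings must be labeled to build a training matrix")
    X = np.vstack([v.values for v in vectors])
    y = np.array([int(v.label) for v in vectors])
    return X, y
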