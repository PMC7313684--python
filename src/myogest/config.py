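"""Pipeline-wide configuration with the published defaults."""

from __future__ import annotations

from dataclasses import dataclass, field

from .classify import ClassifierSpec
from .dsp import DEFAULT_ENVELOPE_CUTOFF_HZ, FilterSpec
from .features import DEFAULT_AR_ORDER, FEATURE_SOURCES


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end settings: 200 Hz sampling, 20–450 Hz band (clamped to
    Nyquist headroom at low rates), 6 Hz envelope, AR order 8, features on
    the envelope, 80/20 stratified splits, 30 trials."""

    fs: float = 200.0
    filter: FilterSpec = field(default_factory=FilterSpec)
    envelope_cutoff: float = DEFAULT_ENVELOPE_CUTOFF_HZ
    ar_order: int = DEFAULT_AR_ORDER
    feature_source: str = "envelope"
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    test_fraction: float = 0.2
    n_trials: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.feature_source not in FEATURE_SOURCES:
            raise ValueError(f"feature_source must be one of {FEATURE_SOURCES}")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.ar_order < 1 or self.n_trials < 1:
            raise ValueError("ar_order and n_trials must be >= 1")
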