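"""Frequency-band definitions."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["BandSpec", "CANONICAL_BANDS", "FEATURE_NAMES"]


@dataclass(frozen=True)
class BandSpec:
    """A band-pass frequency band with inclusive edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"invalid band edges {self.low}-{self.high} Hz")

    def validate_against(self, fs: float) -> None:
        if self.high >= fs / 2:
            raise ValueError(
                f"band '{self.name}' upper edge {self.high} Hz is not below "
                f"the Nyquist frequency {fs / 2} Hz"
            )


#: The canonical six-band bank.
CANONICAL_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 0.5, 4.0),
    BandSpec("theta", 6.0, 12.0),
    BandSpec("beta", 15.0, 30.0),
    BandSpec("gamma", 40.0, 80.0),
    BandSpec("high_gamma", 80.0, 120.0),
    BandSpec("ripple", 150.0, 210.0),
)

#: Feature ordering used along the last axis of feature arrays:
#: the six band envelopes followed by the windowed mean LFP amplitude.
FEATURE_NAMES: tuple[str, ...] = tuple(b.name for b in CANONICAL_BANDS) + ("alfp",)
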