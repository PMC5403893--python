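"""Frequency-band definitions for resting-state oscillatory analysis."""

from __future__ import annotations

from dataclasses import dataclass


class BandConfigurationError(ValueError):
    """Raised when a frequency band is invalid for the sampling rate."""


@dataclass(frozen=True)
class FrequencyBand:
    """A named frequency band with inclusive passband edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0.0 < self.low < self.high):
            raise BandConfigurationError(
                f"band {self.name!r}: require 0 < low < high, "
                f"got low={self.low}, high={self.high}"
            )

    def validate(self, sampling_rate: float) -> None:
        """Check the band fits below the Nyquist frequency."""
        nyquist = sampling_rate / 2.0
        if self.high >= nyquist:
            raise BandConfigurationError(
                f"band {self.name!r}: high edge {self.high} Hz is at or above "
                f"Nyquist ({nyquist} Hz for fs={sampling_rate} Hz)"
            )


#: The canonical six resting-state bands (Hz).
CANONICAL_BANDS: tuple[FrequencyBand, ...] = (
    FrequencyBand("delta", 0.5, 4.0),
    FrequencyBand("theta", 4.0, 8.0),
    FrequencyBand("lower_alpha", 8.0, 10.0),
    FrequencyBand("upper_alpha", 10.0, 13.0),
    FrequencyBand("beta", 13.0, 30.0),
    FrequencyBand("gamma", 30.0, 48.0),
)

BAND_BY_NAME = {b.name: b for b in CANONICAL_BANDS}


def get_band(name: str) -> FrequencyBand:
    try:
        return BAND_BY_NAME[name]
    except KeyError:
        raise BandConfigurationError(
            f"unknown band {name!r}; canonical bands are "
            f"{sorted(BAND_BY_NAME)}"
        ) from None
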