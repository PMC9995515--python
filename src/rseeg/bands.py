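"""Canonical EEG frequency bands.

Band intervals are half-open, ``f_low <= f < f_high``, so the five default
bands tile the 1-50 Hz analysis range exactly and every spectral bin is
counted once: delta [1, 4), theta [4, 8), alpha [8, 13), beta [13, 30),
gamma [30, 50).
"""

from __future__ import annotations

from dataclasses import dataclass

ANALYSIS_LOW_HZ = 1.0
ANALYSIS_HIGH_HZ = 50.0


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with half-open limits [f_low, f_high) in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not 0 < self.f_low < self.f_high:
            raise ValueError(
                f"band {self.name!r}: need 0 < f_low < f_high, "
                f"got [{self.f_low}, {self.f_high})"
            )

    def contains(self, freq: float) -> bool:
        return self.f_low <= freq < self.f_high


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 50.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)


def band_by_name(name: str, bands: tuple[BandDefinition, ...] = DEFAULT_BANDS) -> BandDefinition:
    for band in bands:
        if band.name == name:
            return band
    raise KeyError(f"unknown band {name!r}; known: {[b.name for b in bands]}")
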