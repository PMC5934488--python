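"""Frequency-band definitions.

The four analysis bands tile 4-30 Hz. Edges are half-open ``[lo, hi)`` so
the shared 8, 12 and 20 Hz boundaries are never double-counted.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandSpec:
    """A frequency band ``[f_lo, f_hi)`` in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError(
                f"band {self.name!r}: need 0 < f_lo < f_hi, "
                f"got [{self.f_lo}, {self.f_hi})"
            )

    def contains(self, freq) -> bool:
        return self.f_lo <= freq < self.f_hi


def default_bands() -> tuple[BandSpec, ...]:
    """The four standard EEG analysis bands: theta, alpha, beta1, beta2."""
    return (
        BandSpec("theta", 4.0, 8.0),
        BandSpec("alpha", 8.0, 12.0),
        BandSpec("beta1", 12.0, 20.0),
        BandSpec("beta2", 20.0, 30.0),
    )


def band_by_name(name: str) -> BandSpec:
    for band in default_bands():
        if band.name == name:
            return band
    raise KeyError(f"unknown band name: {name!r}")
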