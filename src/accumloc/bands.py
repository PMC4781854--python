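"""Frequency-band definitions and the wavelet frequency grid.

Six oscillatory bands plus the raw broadband amplitude make up the seven
per-electrode features.  Band membership on the wavelet grid is half-open
[lo, hi), so a 4 Hz grid frequency belongs to theta, not delta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BandDefinition", "BANDS", "FEATURES", "RAW_FEATURE", "morlet_freqs", "band_members"]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float | None
    hi: float | None

    @property
    def is_raw(self) -> bool:
        return self.lo is None

    def carrier_frequency(self) -> float:
        """Geometric-mean frequency of the band (used by the signal generator)."""
        if self.is_raw:
            raise ValueError("raw feature has no carrier frequency")
        return float(np.sqrt(self.lo * self.hi))


BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 2.0, 4.0),
    BandDefinition("theta", 4.0, 9.0),
    BandDefinition("alpha", 9.0, 14.0),
    BandDefinition("beta", 14.0, 28.0),
    BandDefinition("low_gamma", 28.0, 48.0),
    BandDefinition("high_gamma", 48.0, 90.0),
)

RAW_FEATURE = BandDefinition("raw", None, None)

#: The seven features: six band-power tracks plus raw broadband amplitude.
FEATURES: tuple[str, ...] = tuple(b.name for b in BANDS) + ("raw",)

_BAND_BY_NAME = {b.name: b for b in BANDS + (RAW_FEATURE,)}


def get_band(name: str) -> BandDefinition:
    try:
        return _BAND_BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown feature {name!r}; expected one of {FEATURES}") from None


def morlet_freqs(n: int = 53, lo: float = 1.0, hi: float = 100.0) -> np.ndarray:
    """53 frequencies uniform in log10 between 1 and 100 Hz inclusive."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


def band_members(freqs: np.ndarray, band: BandDefinition) -> np.ndarray:
    """Boolean membership of grid frequencies in [lo, hi)."""
    if band.is_raw:
        raise ValueError("raw feature has no grid members")
    members = (freqs >= band.lo) & (freqs < band.hi)
    # cannot happen with the default 53-point grid
    assert members.any(), f"band {band.name} contains no grid frequency"
    return members
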