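"""Canonical EEG frequency band definitions (Hz)."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A half-open frequency interval [f_lo, f_hi) in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not self.f_lo < self.f_hi:
            raise ValueError(f"band {self.name}: need f_lo < f_hi")

    def contains(self, freq: float) -> bool:
        return self.f_lo <= freq < self.f_hi


DELTA = BandDefinition("delta", 0.5, 4.0)
THETA = BandDefinition("theta", 4.0, 8.0)
ALPHA = BandDefinition("alpha", 8.0, 13.0)
BETA = BandDefinition("beta", 13.0, 30.0)
GAMMA = BandDefinition("gamma", 30.0, 100.0)

#: The five canonical bands in fixed order (delta, theta, alpha, beta, gamma).
CANONICAL_BANDS: tuple[BandDefinition, ...] = (DELTA, THETA, ALPHA, BETA, GAMMA)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in CANONICAL_BANDS)


def band_by_name(name: str) -> BandDefinition:
    for band in CANONICAL_BANDS:
        if band.name == name:
            return band
    raise KeyError(f"unknown band {name!r}; expected one of {BAND_NAMES}")
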