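"""Poincare-plot descriptors: SD1, SD2, their product and ratio at lag 1.

With the lagged pairs (x_i, x_{i+lag}):

* SD1 = sample std of (x_{i+lag} - x_i) / sqrt(2)   (ellipse width)
* SD2 = sample std of (x_{i+lag} + x_i) / sqrt(2)   (ellipse length)

which satisfy the standard identities SD1^2 = SDSD^2 / 2 and
SD2^2 = 2 SD^2 - SDSD^2 / 2 up to the finite-sample mean terms.  Standard
deviations use the N-1 denominator; the ratio is defined as 0 when SD2 = 0.

Feature code layout: ND1 = SD1, ND2 = SD2, ND3 = SD1*SD2, ND4 = SD1/SD2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureVector, domain_ids
from .segments import N_CHANNELS, EEGSegment

_SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class PoincareMeasures:
    sd1: float
    sd2: float
    lag: int

    @property
    def product(self) -> float:
        return self.sd1 * self.sd2

    @property
    def ratio(self) -> float:
        """SD1/SD2, defined as 0 for the degenerate SD2 = 0 case."""
        return self.sd1 / self.sd2 if self.sd2 > 0 else 0.0


def poincare(signal: np.ndarray, lag: int = 1) -> PoincareMeasures:
    """Ellipse descriptors of the lag-``lag`` Poincare plot."""
    signal = np.asarray(signal, dtype=float)
    if lag < 1:
        raise ValueError("lag must be a positive integer")
    if signal.size <= lag + 1:
        raise ValueError(f"need more than lag + 1 = {lag + 1} samples")
    ahead, behind = signal[lag:], signal[:-lag]

    def _sd(series: np.ndarray) -> float:
        # exact zero for degenerate (constant) series, no mean round-off
        if np.ptp(series) == 0.0:
            return 0.0
        return float(np.std(series / _SQRT2, ddof=1))

    return PoincareMeasures(sd1=_sd(ahead - behind), sd2=_sd(ahead + behind), lag=lag)


def extract_nd(segment: EEGSegment, lag: int = 1) -> FeatureVector:
    """4 measures x 19 channels = 76 features."""
    values: list[float] = []
    for ch in range(1, N_CHANNELS + 1):
        m = poincare(segment.channel(ch), lag=lag)
        values.extend((m.sd1, m.sd2, m.product, m.ratio))
    return FeatureVector(ids=domain_ids("ND"), values=np.array(values))
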