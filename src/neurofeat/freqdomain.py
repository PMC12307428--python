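"""Fourier-band features: energy, variance and spectral entropy per band.

For a 1000-sample signal at 1000 Hz the one-sided FFT grid has exactly 1 Hz
resolution; each canonical band keeps the bins whose frequency falls in its
half-open interval [f_lo, f_hi).  The delta band therefore starts at the
1 Hz bin (0.5 Hz is not on the grid and DC is excluded), and no bin is
shared between bands.

Per band, over the kept magnitude values y(1..M):

* energy    = sum |y(i)|^2
* variance  = sample variance of the magnitudes (M - 1 denominator)
* entropy   = normalized Shannon entropy of the within-band power
  distribution P(i) = |y(i)|^2 / sum |y(j)|^2, i.e.
  -(1/log M) * sum P(i) log P(i), in [0, 1], with 0 log 0 = 0 and an
  all-zero band defined as 0.

Feature code layout (configurable convention): FD1-FD5 energy of
delta..gamma, FD6-FD10 variance, FD11-FD15 entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bands import CANONICAL_BANDS, BandDefinition
from .features import FeatureVector, domain_ids
from .segments import FS, N_CHANNELS, N_SAMPLES, EEGSegment


@dataclass(frozen=True)
class BandSpectrum:
    """One-sided FFT magnitudes restricted to a single band."""

    y: np.ndarray
    frequencies: np.ndarray
    band: BandDefinition

    def __post_init__(self) -> None:
        if self.y.size != self.frequencies.size or self.y.size < 1:
            raise ValueError("spectrum and frequency grids must match and be non-empty")
        if np.any(self.frequencies < self.band.f_lo) or np.any(
            self.frequencies >= self.band.f_hi
        ):
            raise ValueError("frequencies outside band interval")

    @property
    def M(self) -> int:
        return self.y.size


def band_spectrum(
    signal: np.ndarray,
    fs: float = FS,
    band: BandDefinition | None = None,
    window: str | None = None,
    detrend: bool = False,
) -> BandSpectrum:
    """One-sided FFT magnitudes of ``signal`` at bins inside ``band``.

    Windowing/detrending are off by default (plain FFT of the raw epoch);
    pass ``window="hann"`` or ``detrend=True`` to enable them.
    """
    if band is None:
        raise ValueError("band is required")
    signal = np.asarray(signal, dtype=float)
    if detrend:
        signal = signal - signal.mean()
    if window is not None:
        from scipy.signal import get_window

        signal = signal * get_window(window, signal.size)
    spec = np.abs(np.fft.rfft(signal))
    freqs = np.fft.rfftfreq(signal.size, d=1.0 / fs)
    mask = (freqs >= band.f_lo) & (freqs < band.f_hi)
    if not np.any(mask):
        raise ValueError(f"no FFT bins fall inside band {band.name}")
    return BandSpectrum(y=spec[mask], frequencies=freqs[mask], band=band)


def band_energy(spec: BandSpectrum) -> float:
    """sum_{i=1..M} |y(i)|^2."""
    return float(np.sum(spec.y**2))


def band_variance(spec: BandSpectrum) -> float:
    """Sample variance (M - 1 denominator) of the band magnitudes."""
    if spec.M < 2:
        raise ValueError("band variance needs at least 2 bins")
    return float(np.var(spec.y, ddof=1))


def band_spectral_entropy(spec: BandSpectrum) -> float:
    """Normalized Shannon entropy of within-band power, in [0, 1]."""
    if spec.M < 2:
        raise ValueError("spectral entropy needs at least 2 bins")
    power = spec.y**2
    total = power.sum()
    if total == 0.0:
        return 0.0
    p = power / total
    nz = p > 0
    h = -float(np.sum(p[nz] * np.log(p[nz]))) / float(np.log(spec.M))
    # clip tiny negative round-off at the degenerate end
    return min(max(h, 0.0), 1.0)


def extract_fd(
    segment: EEGSegment,
    bands: tuple[BandDefinition, ...] = CANONICAL_BANDS,
    window: str | None = None,
    detrend: bool = False,
) -> FeatureVector:
    """5 bands x 3 statistics x 19 channels = 285 features.

    Vectorized over channels; agrees with the per-channel
    :func:`band_spectrum` route exactly (asserted by the dual-route tests).
    """
    X = segment.data
    if detrend:
        X = X - X.mean(axis=1, keepdims=True)
    if window is not None:
        from scipy.signal import get_window

        X = X * get_window(window, X.shape[1])
    spec = np.abs(np.fft.rfft(X, axis=1))
    freqs = np.fft.rfftfreq(X.shape[1], d=1.0 / segment.fs)

    energies = np.empty((N_CHANNELS, len(bands)))
    variances = np.empty_like(energies)
    entropies = np.empty_like(energies)
    for bi, band in enumerate(bands):
        mask = (freqs >= band.f_lo) & (freqs < band.f_hi)
        if not np.any(mask):
            raise ValueError(f"no FFT bins fall inside band {band.name}")
        y = spec[:, mask]
        power = y**2
        energies[:, bi] = power.sum(axis=1)
        variances[:, bi] = y.var(axis=1, ddof=1)
        total = power.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(total > 0, power / np.where(total > 0, total, 1.0), 0.0)
            term = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
        h = -term.sum(axis=1) / np.log(y.shape[1])
        entropies[:, bi] = np.clip(np.where(total[:, 0] > 0, h, 0.0), 0.0, 1.0)

    values = np.concatenate([energies, variances, entropies], axis=1).ravel()
    return FeatureVector(ids=domain_ids("FD"), values=values)
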