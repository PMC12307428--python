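"""Synthetic EEG generator with class-dependent band-power structure.

Each epoch is built as::

    subject_gain * [ 1/f-shaped background
                     + sum over bands ( band-limited noise * sqrt(multiplier) ) ]

where the multiplier is per-class and applied only on a configurable channel
subset (multiplier 1 elsewhere, mirroring ERD/ERS-style band-power
modulation).  The no-mental-task class (6) is the all-ones baseline.

Band-limited components are produced by masking the rFFT of white noise to
the band's half-open interval, so a multiplier ``m`` scales the component's
expected band power by exactly ``m``.  Everything is a pure function of
(parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bands import BAND_NAMES, CANONICAL_BANDS, BandDefinition
from .segments import (
    CLASS_IDS,
    FS,
    N_CHANNELS,
    N_SAMPLES,
    NOMT_CLASS,
    EEGSegment,
    SegmentCollection,
)

#: Central-region stand-in channels that carry the class effect by default
#: (1-based indices into the stored montage order).
DEFAULT_AFFECTED_CHANNELS: tuple[int, ...] = (8, 9, 10)


def _default_class_multipliers() -> dict[int, dict[str, float]]:
    return {c: {name: 1.0 for name in BAND_NAMES} for c in CLASS_IDS}


@dataclass
class EffectConfig:
    """Class-dependent band-power structure of the generator.

    ``class_multipliers[class_id][band_name]`` is a band-*power* multiplier
    applied on ``affected_channels``.  The NoMT class must stay at 1.
    """

    class_multipliers: dict[int, dict[str, float]] = field(
        default_factory=_default_class_multipliers
    )
    affected_channels: tuple[int, ...] = DEFAULT_AFFECTED_CHANNELS
    subject_gain_sd: float = 0.2
    background_exponent: float = 1.0
    background_scale: float = 10.0
    # microvolt-scale band amplitudes (unit-variance band noise x amplitude)
    band_amplitudes: dict[str, float] = field(
        default_factory=lambda: {"delta": 20.0, "theta": 15.0, "alpha": 20.0, "beta": 10.0, "gamma": 5.0}
    )
    band_defs: tuple[BandDefinition, ...] = CANONICAL_BANDS

    def __post_init__(self) -> None:
        for cid, mults in self.class_multipliers.items():
            if cid not in CLASS_IDS:
                raise ValueError(f"unknown class id {cid}")
            for name, m in mults.items():
                if m <= 0:
                    raise ValueError(f"multiplier for class {cid}/{name} must be > 0")
        nomt = self.class_multipliers.get(NOMT_CLASS, {})
        if any(m != 1.0 for m in nomt.values()):
            raise ValueError("NoMT class multipliers must all be 1 (baseline)")
        for ch in self.affected_channels:
            if not 1 <= ch <= N_CHANNELS:
                raise ValueError(f"affected channel {ch} out of range [1, {N_CHANNELS}]")

    def multiplier(self, class_id: int, band_name: str) -> float:
        return self.class_multipliers.get(class_id, {}).get(band_name, 1.0)

    @classmethod
    def planted(
        cls,
        band: str = "alpha",
        multiplier: float = 4.0,
        classes: tuple[int, ...] = (1, 2, 3, 4, 5),
        channels: tuple[int, ...] = DEFAULT_AFFECTED_CHANNELS,
        **kwargs,
    ) -> "EffectConfig":
        """Config with one band's power boosted for the given classes."""
        mults = _default_class_multipliers()
        for cid in classes:
            if cid == NOMT_CLASS:
                raise ValueError("cannot plant an effect on the NoMT baseline class")
            mults[cid][band] = multiplier
        return cls(class_multipliers=mults, affected_channels=channels, **kwargs)

    @classmethod
    def per_class_bands(
        cls,
        multiplier: float = 4.0,
        channels: tuple[int, ...] = DEFAULT_AFFECTED_CHANNELS,
        **kwargs,
    ) -> "EffectConfig":
        """Config where each task class boosts a different band.

        Class 1 -> alpha, 2 -> beta, 3 -> theta, 4 -> delta, 5 -> gamma;
        class 6 stays at baseline.  Makes the six classes mutually
        discriminable for classifier sanity checks.
        """
        assignment = {1: "alpha", 2: "beta", 3: "theta", 4: "delta", 5: "gamma"}
        mults = _default_class_multipliers()
        for cid, band in assignment.items():
            mults[cid][band] = multiplier
        return cls(class_multipliers=mults, affected_channels=channels, **kwargs)


def _one_over_f_noise(rng: np.random.Generator, exponent: float, rows: int, n: int) -> np.ndarray:
    """Per-row unit-variance Gaussian noise spectrally shaped to 1/f^exponent."""
    white = rng.standard_normal((rows, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / FS)
    shape = np.zeros_like(freqs)  # DC removed: no drift
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * shape, n=n, axis=1)
    sd = shaped.std(axis=1, keepdims=True)
    return np.divide(shaped, sd, out=shaped, where=sd > 0)


def _band_noise(rng: np.random.Generator, band: BandDefinition, rows: int, n: int) -> np.ndarray:
    """Per-row unit-variance noise band-limited to [f_lo, f_hi) via rFFT masking."""
    white = rng.standard_normal((rows, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / FS)
    mask = (freqs >= band.f_lo) & (freqs < band.f_hi)
    spec[:, ~mask] = 0.0
    out = np.fft.irfft(spec, n=n, axis=1)
    sd = out.std(axis=1, keepdims=True)
    return np.divide(out, sd, out=out, where=sd > 0)


def generate_segment(
    class_id: int,
    subject_gain: float,
    cfg: EffectConfig,
    seed: int | np.random.SeedSequence,
    subject: str = "S1",
    segment_id: int = 0,
) -> EEGSegment:
    """Generate one deterministic 19 x 1000 epoch for the given class."""
    if class_id not in CLASS_IDS:
        raise ValueError(f"class id must be in {CLASS_IDS}, got {class_id}")
    if subject_gain <= 0:
        raise ValueError("subject gain must be positive")
    rng = np.random.default_rng(seed)

    affected = np.zeros(N_CHANNELS, dtype=bool)
    affected[[ch - 1 for ch in cfg.affected_channels]] = True
    data = cfg.background_scale * _one_over_f_noise(
        rng, cfg.background_exponent, N_CHANNELS, N_SAMPLES
    )
    for band in cfg.band_defs:
        amp = cfg.band_amplitudes.get(band.name, 1.0)
        mult = np.where(affected, cfg.multiplier(class_id, band.name), 1.0)
        data += (amp * np.sqrt(mult))[:, None] * _band_noise(rng, band, N_CHANNELS, N_SAMPLES)
    data *= subject_gain
    return EEGSegment(
        data=data, label=class_id, subject=subject, segment_id=segment_id
    )


def generate_collection(
    subject: str,
    subject_gain: float,
    n_per_class: int,
    cfg: EffectConfig,
    seed: int | np.random.SeedSequence,
    segment_id_offset: int = 0,
) -> SegmentCollection:
    """Generate one subject's balanced collection (n_per_class per class)."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    root = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    children = root.spawn(len(CLASS_IDS) * n_per_class)
    segments = []
    sid = segment_id_offset
    k = 0
    for class_id in CLASS_IDS:
        for _ in range(n_per_class):
            segments.append(
                generate_segment(
                    class_id,
                    subject_gain,
                    cfg,
                    children[k],
                    subject=subject,
                    segment_id=sid,
                )
            )
            sid += 1
            k += 1
    return SegmentCollection(segments=segments, subject=subject)


def generate_dataset(
    n_subjects: int,
    n_per_class: int,
    cfg: EffectConfig,
    seed: int,
) -> list[SegmentCollection]:
    """Generate one balanced collection per subject, fully seeded.

    Subject gains are drawn once per subject from a log-normal with the
    configured relative dispersion (``cfg.subject_gain_sd``).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    root = np.random.SeedSequence(seed)
    gain_rng = np.random.default_rng(root.spawn(1)[0])
    gains = np.exp(gain_rng.normal(0.0, cfg.subject_gain_sd, size=n_subjects))
    collections = []
    children = root.spawn(n_subjects + 1)[1:]
    for i in range(n_subjects):
        collections.append(
            generate_collection(
                subject=f"S{i + 1}",
                subject_gain=float(gains[i]),
                n_per_class=n_per_class,
                cfg=cfg,
                seed=children[i],
                segment_id_offset=i * len(CLASS_IDS) * n_per_class,
            )
        )
    return collections
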