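"""Feature identity scheme shared by all four extraction domains.

A feature column is identified by (domain, type code, channel), rendered as
``"<domain>:<code>:ch<channel>"`` in tables, e.g. ``"TD:TD7:ch3"``.  Column
ordering is channel-major: all of channel 1's types, then channel 2, etc.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .segments import N_CHANNELS

DOMAINS = ("TD", "FD", "TF", "ND")

#: feature types per domain (24 + 15 + 15 + 4)
DOMAIN_SIZES = {"TD": 24, "FD": 15, "TF": 15, "ND": 4}


@dataclass(frozen=True)
class FeatureId:
    domain: str
    type_code: str
    channel: int

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        if not self.type_code.startswith(self.domain):
            raise ValueError(
                f"type code {self.type_code!r} inconsistent with domain {self.domain!r}"
            )
        idx = int(self.type_code[len(self.domain):])
        if not 1 <= idx <= DOMAIN_SIZES[self.domain]:
            raise ValueError(f"type code {self.type_code!r} out of range")
        if not 1 <= self.channel <= N_CHANNELS:
            raise ValueError(f"channel {self.channel} out of [1, {N_CHANNELS}]")

    @property
    def type_index(self) -> int:
        """1-based index of the type within its domain (TD7 -> 7)."""
        return int(self.type_code[len(self.domain):])

    def __str__(self) -> str:
        return f"{self.domain}:{self.type_code}:ch{self.channel}"

    @classmethod
    def parse(cls, text: str) -> "FeatureId":
        domain, code, ch = text.split(":")
        if not ch.startswith("ch"):
            raise ValueError(f"bad feature id {text!r}")
        return cls(domain=domain, type_code=code, channel=int(ch[2:]))


@lru_cache(maxsize=None)
def _domain_ids_cached(domain: str) -> tuple[FeatureId, ...]:
    n_types = DOMAIN_SIZES[domain]
    return tuple(
        FeatureId(domain, f"{domain}{t}", ch)
        for ch in range(1, N_CHANNELS + 1)
        for t in range(1, n_types + 1)
    )


def domain_ids(domain: str) -> list[FeatureId]:
    """All feature ids of a domain in channel-major order."""
    return list(_domain_ids_cached(domain))


@dataclass
class FeatureVector:
    """Parallel (ids, values) for one segment; values always finite."""

    ids: list[FeatureId]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.ids) != self.values.size:
            raise ValueError("ids and values length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate feature ids")
        if not np.all(np.isfinite(self.values)):
            bad = [str(i) for i, v in zip(self.ids, self.values) if not np.isfinite(v)]
            raise ValueError(f"non-finite feature values at {bad[:5]}")

    def __len__(self) -> int:
        return len(self.ids)

    @staticmethod
    def concat(vectors: list["FeatureVector"]) -> "FeatureVector":
        ids = [i for v in vectors for i in v.ids]
        values = np.concatenate([v.values for v in vectors]) if vectors else np.empty(0)
        return FeatureVector(ids=ids, values=values)
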