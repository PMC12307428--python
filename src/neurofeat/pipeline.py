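"""End-to-end orchestration: generate -> extract -> select -> map -> classify.

A :class:`RunConfig` fully determines a run (defaults mirror the study
design: alpha 0.05, 5 folds, 8 subjects, 100 segments per class).  Both the
selection branch (ANOVA-reduced tables) and the no-selection branch are
executed, and every artifact plus all seeds land in a machine-readable
manifest so a run is reproducible from the manifest alone.

Subject-independent scope pools all subjects into one table (subject column
retained) and yields binary distribution maps; subject-dependent scope
loops per subject and yields count maps over subjects.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import ClassifierSpec, all_specs, best_per_family, run_grid
from .features import DOMAINS
from .segments import CLASS_IDS, SegmentCollection, write_collection
from .selection import (
    FEATURE_SETS,
    EmptyFeatureSetError,
    FeatureTable,
    build_feature_table,
    distribution_map,
    reduce_table,
    select_features,
)
from .synth import EffectConfig, generate_dataset

log = logging.getLogger("neurofeat")

SCOPES = ("subject_dependent", "subject_independent")


@dataclass
class RunConfig:
    scope: str = "subject_independent"
    feature_sets: list[str] = field(default_factory=lambda: ["TD+FD+TF+ND"])
    alpha: float = 0.05
    k: int = 5
    seed: int = 0
    n_subjects: int = 8
    n_per_class: int = 100
    effect: str = "per_class"  # null | planted | per_class
    effect_multiplier: float = 4.0
    families: list[str] | None = None
    variants: list[str] | None = None  # restrict to these variant names
    out: str = "runs/latest"

    def __post_init__(self) -> None:
        if self.scope not in SCOPES:
            raise ValueError(f"scope must be one of {SCOPES}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        for s in self.feature_sets:
            if s not in FEATURE_SETS:
                raise ValueError(f"unknown feature set {s!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)

    def effect_config(self) -> EffectConfig:
        if self.effect == "null":
            return EffectConfig()
        if self.effect == "planted":
            return EffectConfig.planted(multiplier=self.effect_multiplier)
        if self.effect == "per_class":
            return EffectConfig.per_class_bands(multiplier=self.effect_multiplier)
        raise ValueError(f"unknown effect {self.effect!r}")

    def classifier_specs(self) -> list[ClassifierSpec]:
        specs = all_specs(self.families)
        if self.variants:
            specs = [s for s in specs if s.variant in self.variants]
        if not specs:
            raise ValueError("classifier selection matched no catalog entry")
        return specs


def _timed(name: str, manifest: dict, fn, *args, **kwargs):
    t0 = time.perf_counter()
    out = fn(*args, **kwargs)
    dt = time.perf_counter() - t0
    manifest["timings_s"][name] = round(dt, 3)
    log.info("stage %-12s %.2fs", name, dt)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "timings_s": {},
        "artifacts": [],
        "feature_counts": {},
        "partial": False,
    }

    def record(path: Path) -> Path:
        manifest["artifacts"].append(str(path.relative_to(out)))
        return path

    try:
        cfg = config.effect_config()
        collections = _timed(
            "synth", manifest, generate_dataset,
            config.n_subjects, config.n_per_class, cfg, config.seed,
        )
        log.info("generated %d collections x %d segments", len(collections),
                 len(collections[0]))

        specs = config.classifier_specs()
        for set_name in config.feature_sets:
            safe = set_name.replace("+", "_")
            table = _timed(
                f"extract[{set_name}]", manifest, build_feature_table,
                collections, set_name,
            )
            manifest["feature_counts"][set_name] = table.n_features
            record(table.to_csv(out / "tables" / f"{safe}__full.csv"))

            domains_in_set = [d for d in DOMAINS if d in FEATURE_SETS[set_name]]

            if config.scope == "subject_independent":
                mask = _timed(f"select[{set_name}]", manifest,
                              select_features, table, config.alpha)
                record(mask.to_json(out / "masks" / f"{safe}__SI.json"))
                try:
                    reduced = reduce_table(table, mask)
                    record(reduced.to_csv(out / "tables" / f"{safe}__reduced.csv"))
                except EmptyFeatureSetError:
                    log.warning("set %s: selection left no features", set_name)
                for d in domains_in_set:
                    dm = distribution_map(mask.for_domain(d), d)
                    record(dm.to_csv(out / "maps" / f"{safe}__{d}__binary.csv"))
                    record(dm.to_json(out / "maps" / f"{safe}__{d}__binary.json"))
                results = _timed(
                    f"classify[{set_name}]", manifest, run_grid,
                    {set_name: table}, specs, config.k, config.seed,
                    config.alpha, config.scope,
                )
            else:
                subject_masks = []
                per_subject_tables: dict[str, FeatureTable] = {}
                for coll in collections:
                    sub_table = table.for_subject(coll.subject)
                    m = select_features(sub_table, config.alpha)
                    subject_masks.append(m)
                    record(m.to_json(out / "masks" / f"{safe}__{coll.subject}.json"))
                    per_subject_tables[f"{set_name}[{coll.subject}]"] = sub_table
                for d in domains_in_set:
                    dm = distribution_map([m.for_domain(d) for m in subject_masks], d)
                    record(dm.to_csv(out / "maps" / f"{safe}__{d}__count.csv"))
                    record(dm.to_json(out / "maps" / f"{safe}__{d}__count.json"))
                results = _timed(
                    f"classify[{set_name}]", manifest, run_grid,
                    per_subject_tables, specs, config.k, config.seed,
                    config.alpha, config.scope,
                )

            record(out / "results" / f"{safe}__results.csv")
            (out / "results").mkdir(exist_ok=True)
            results.to_csv(out / "results" / f"{safe}__results.csv", index=False)
            best = best_per_family(results)
            best.to_csv(out / "results" / f"{safe}__best_per_family.csv", index=False)
            record(out / "results" / f"{safe}__best_per_family.csv")
    except Exception:
        manifest["partial"] = True
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def make_fixtures(seed: int = 0, out: str | Path = "fixtures") -> SegmentCollection:
    """Write a tiny deterministic collection (1 subject, 4 per class).

    Used by the test suite; regeneration with the same seed is idempotent.
    """
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    cfg = EffectConfig.per_class_bands(multiplier=4.0)
    collections = generate_dataset(1, 4, cfg, seed)
    coll = collections[0]
    write_collection(coll, out / "tiny")
    table = build_feature_table(coll, "TD")
    table.to_csv(out / "tiny_td_table.csv")
    return coll
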