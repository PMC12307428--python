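"""Feature-table assembly, ANOVA significance selection, distribution maps.

The feature table is a pandas DataFrame with a ``subject`` column, a
``label`` column (class ids 1..6), and one column per feature id formatted
``<domain>:<type_code>:ch<channel>`` (e.g. ``"FD:FD3:ch11"``), assembled in
the fixed domain order TD, FD, TF, ND and channel-major within a domain.

Selection runs one classical one-way fixed-effects ANOVA per feature
column across the six class labels; a feature is significant iff its
p-value is below alpha (0.05 by default, no multiple-testing correction —
a Benjamini-Hochberg option exists but is off by default).  Degenerate
columns with zero total variance get p = 1 so they are never selected.

Distribution maps tabulate significance on a feature-type x channel grid:
binary mode from a single (pooled, subject-independent) mask, count mode
from per-subject masks, with per-row, per-column and grand totals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .features import DOMAIN_SIZES, DOMAINS, FeatureId
from .poincare import extract_nd
from .segments import CLASS_IDS, EEGSegment, SegmentCollection
from .timedomain import TDFeatureCatalog, extract_td
from .freqdomain import extract_fd
from .wavelet import extract_tf

SCHEMA_VERSION = 1

#: canonical feature-set names and the domains they concatenate
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "TD": ("TD",),
    "FD": ("FD",),
    "TF": ("TF",),
    "ND": ("ND",),
    "TD+FD+TF": ("TD", "FD", "TF"),
    "TD+FD+TF+ND": ("TD", "FD", "TF", "ND"),
}

_EXTRACTORS = {
    "TD": lambda seg: extract_td(seg, TDFeatureCatalog()),
    "FD": extract_fd,
    "TF": extract_tf,
    "ND": extract_nd,
}


class EmptyFeatureSetError(ValueError):
    """Raised when a reduction leaves zero feature columns."""


@dataclass
class FeatureTable:
    """Segments x features matrix with subject/label row identity."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("subject", "label"):
            if col not in self.df.columns:
                raise ValueError(f"feature table missing {col!r} column")
        if self.df[self.feature_columns].isna().any().any():
            raise ValueError("feature table contains missing values")

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in ("subject", "label")]

    @property
    def n_features(self) -> int:
        return len(self.feature_columns)

    @property
    def values(self) -> np.ndarray:
        return self.df[self.feature_columns].to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return self.df["label"].to_numpy(dtype=int)

    @property
    def subjects(self) -> np.ndarray:
        return self.df["subject"].to_numpy(dtype=str)

    def __len__(self) -> int:
        return len(self.df)

    def for_subject(self, subject: str) -> "FeatureTable":
        return FeatureTable(self.df[self.df["subject"] == subject].reset_index(drop=True))

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.df.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        return cls(pd.read_csv(path))

    @staticmethod
    def concat_rows(tables: list["FeatureTable"]) -> "FeatureTable":
        if not tables:
            raise ValueError("nothing to concatenate")
        cols = tables[0].df.columns
        for t in tables[1:]:
            if not t.df.columns.equals(cols):
                raise ValueError("tables have mismatched columns")
        return FeatureTable(pd.concat([t.df for t in tables], ignore_index=True))


def build_feature_table(
    collection: SegmentCollection | list[SegmentCollection],
    sets: str | tuple[str, ...] = "TD+FD+TF+ND",
) -> FeatureTable:
    """Extract and concatenate the requested domains for every segment.

    ``sets`` is either a canonical feature-set name (e.g. ``"TD+FD+TF"``)
    or an explicit tuple of domains; domains are always assembled in the
    fixed order TD, FD, TF, ND.  Accepts one collection or a list (pooled
    rows, subject column retained).
    """
    if isinstance(sets, str):
        if sets not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {sets!r}; expected one of {list(FEATURE_SETS)}")
        domains = FEATURE_SETS[sets]
    else:
        bad = [d for d in sets if d not in DOMAINS]
        if bad:
            raise ValueError(f"unknown domains {bad}; expected subset of {DOMAINS}")
        domains = tuple(d for d in DOMAINS if d in sets)

    collections = [collection] if isinstance(collection, SegmentCollection) else list(collection)
    if not collections or not any(len(c) for c in collections):
        raise ValueError("empty collection")

    rows = []
    ids: list[str] | None = None
    for coll in collections:
        for seg in coll:
            vectors = [_EXTRACTORS[d](seg) for d in domains]
            seg_ids = [str(i) for v in vectors for i in v.ids]
            if ids is None:
                ids = seg_ids
            values = np.concatenate([v.values for v in vectors])
            rows.append((seg.subject, seg.label, *values))
    df = pd.DataFrame(rows, columns=["subject", "label", *ids])
    return FeatureTable(df)


def anova_pvalue(groups: list[np.ndarray]) -> float:
    """One-way fixed-effects ANOVA F-test p-value across >= 2 groups.

    Zero total variance (all values identical everywhere) yields p = 1 by
    convention, so degenerate features are never selected.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0.0:
        return 1.0
    # within-group degeneracy with distinct means -> F = inf, p = 0
    if all(np.ptp(g) == 0.0 for g in groups):
        return 0.0
    _, p = stats.f_oneway(*groups)
    return float(p)


@dataclass
class SelectionMask:
    """Per-feature p-values and significance flags at a fixed alpha."""

    ids: list[str]
    p_values: np.ndarray
    alpha: float = 0.05
    corrected: bool = False

    def __post_init__(self) -> None:
        self.p_values = np.asarray(self.p_values, dtype=float)
        if len(self.ids) != self.p_values.size:
            raise ValueError("ids / p-values length mismatch")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")

    @property
    def significant(self) -> np.ndarray:
        return self.p_values < self.alpha

    @property
    def n_selected(self) -> int:
        return int(self.significant.sum())

    def __len__(self) -> int:
        return len(self.ids)

    def for_domain(self, domain: str) -> "SelectionMask":
        """Sub-mask restricted to one domain's feature columns."""
        keep = [k for k, i in enumerate(self.ids) if FeatureId.parse(i).domain == domain]
        if not keep:
            raise ValueError(f"mask holds no {domain} features")
        return SelectionMask(
            ids=[self.ids[k] for k in keep],
            p_values=self.p_values[keep],
            alpha=self.alpha,
            corrected=self.corrected,
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        doc = {
            "schema_version": SCHEMA_VERSION,
            "alpha": self.alpha,
            "corrected": self.corrected,
            "features": [
                {"id": i, "p_value": float(p), "significant": bool(s)}
                for i, p, s in zip(self.ids, self.p_values, self.significant)
            ],
        }
        path.write_text(json.dumps(doc, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionMask":
        doc = json.loads(Path(path).read_text())
        return cls(
            ids=[f["id"] for f in doc["features"]],
            p_values=np.array([f["p_value"] for f in doc["features"]]),
            alpha=doc["alpha"],
            corrected=doc.get("corrected", False),
        )


def select_features(
    table: FeatureTable,
    alpha: float = 0.05,
    correction: str | None = None,
) -> SelectionMask:
    """One ANOVA p-value per feature column, grouping rows by class label.

    ``correction="bh"`` applies Benjamini-Hochberg to the p-values before
    thresholding (off by default: the raw per-feature p < alpha rule).
    """
    labels = table.labels
    present = set(labels)
    missing = [c for c in CLASS_IDS if c not in present]
    if missing:
        raise ValueError(f"classes absent from table: {missing}")
    for c in CLASS_IDS:
        if (labels == c).sum() < 2:
            raise ValueError(f"class {c} has fewer than 2 segments")

    X = table.values
    masks = [labels == c for c in CLASS_IDS]
    p_values = np.array(
        [anova_pvalue([X[m, j] for m in masks]) for j in range(X.shape[1])]
    )
    if correction == "bh":
        from statsmodels.stats.multitest import multipletests

        _, p_values, _, _ = multipletests(p_values, alpha=alpha, method="fdr_bh")
        return SelectionMask(table.feature_columns, p_values, alpha, corrected=True)
    if correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    return SelectionMask(table.feature_columns, p_values, alpha)


def reduce_table(table: FeatureTable, mask: SelectionMask) -> FeatureTable:
    """Keep only the mask's significant columns (order preserved)."""
    if mask.ids != table.feature_columns:
        raise ValueError("mask does not match the table's feature columns")
    keep = [i for i, s in zip(mask.ids, mask.significant) if s]
    if not keep:
        raise EmptyFeatureSetError("no feature survived selection")
    return FeatureTable(table.df[["subject", "label", *keep]].copy())


@dataclass
class DistributionMap:
    """Feature-type x channel significance grid with totals.

    ``grid[t, c]`` covers type code ``<domain><t+1>`` on channel ``c+1``;
    binary cells are 0/1, count cells range 0..n_subjects.
    """

    domain: str
    mode: str
    grid: np.ndarray
    n_subjects: int = 1

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.mode not in ("binary", "count"):
            raise ValueError("mode must be 'binary' or 'count'")
        self.grid = np.asarray(self.grid, dtype=int)
        expected = (DOMAIN_SIZES[self.domain], 19)
        if self.grid.shape != expected:
            raise ValueError(f"grid must be {expected}, got {self.grid.shape}")
        hi = 1 if self.mode == "binary" else self.n_subjects
        if self.grid.min() < 0 or self.grid.max() > hi:
            raise ValueError(f"cell values must lie in [0, {hi}]")

    @property
    def row_totals(self) -> np.ndarray:
        return self.grid.sum(axis=1)

    @property
    def column_totals(self) -> np.ndarray:
        return self.grid.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.grid.sum())

    def to_frame(self) -> pd.DataFrame:
        """Grid as a table shaped like the published maps (with totals)."""
        codes = [f"{self.domain}{t}" for t in range(1, DOMAIN_SIZES[self.domain] + 1)]
        df = pd.DataFrame(self.grid, index=codes, columns=[str(c) for c in range(1, 20)])
        df["Total"] = self.row_totals
        total_row = pd.Series(
            [*self.column_totals, self.grand_total], index=df.columns, name="Total"
        )
        return pd.concat([df, total_row.to_frame().T])

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index_label="Features")
        return path

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        doc = {
            "schema_version": SCHEMA_VERSION,
            "domain": self.domain,
            "mode": self.mode,
            "n_subjects": self.n_subjects,
            "grid": self.grid.tolist(),
            "row_totals": self.row_totals.tolist(),
            "column_totals": self.column_totals.tolist(),
            "grand_total": self.grand_total,
        }
        path.write_text(json.dumps(doc, indent=1))
        return path


def _mask_grid(mask: SelectionMask, domain: str) -> np.ndarray:
    grid = np.full((DOMAIN_SIZES[domain], 19), -1, dtype=int)
    sig = mask.significant
    for i, s in zip(mask.ids, sig):
        fid = FeatureId.parse(i)
        if fid.domain != domain:
            raise ValueError(
                f"mask mixes domains: found {fid.domain} while mapping {domain}"
            )
        grid[fid.type_index - 1, fid.channel - 1] = int(s)
    if (grid < 0).any():
        raise ValueError(f"mask does not cover the full {domain} type x channel grid")
    return grid


def distribution_map(
    masks: SelectionMask | list[SelectionMask],
    domain: str,
) -> DistributionMap:
    """Binary map from one pooled mask, count map from per-subject masks."""
    if isinstance(masks, SelectionMask):
        return DistributionMap(domain=domain, mode="binary", grid=_mask_grid(masks, domain))
    if not masks:
        raise ValueError("need at least one mask")
    total = sum(_mask_grid(m, domain) for m in masks)
    return DistributionMap(
        domain=domain, mode="count", grid=total, n_subjects=len(masks)
    )
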