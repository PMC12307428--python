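import json

import numpy as np
import pytest
from scipy import stats

from neurofeat import (
    DistributionMap,
    FeatureTable,
    SelectionMask,
    anova_pvalue,
    build_feature_table,
    distribution_map,
    reduce_table,
    select_features,
)
from neurofeat.selection import FEATURE_SETS, EmptyFeatureSetError


@pytest.fixture(scope="module")
def full_table(tiny_collection) -> FeatureTable:
    return build_feature_table(tiny_collection, "TD+FD+TF+ND")


class TestBuildFeatureTable:
    @pytest.mark.parametrize(
        "name,expected",
        [("TD", 456), ("FD", 285), ("TF", 285), ("ND", 76),
         ("TD+FD+TF", 1026), ("TD+FD+TF+ND", 1102)],
    )
    def test_canonical_column_counts(self, tiny_collection, name, expected):
        assert build_feature_table(tiny_collection, name).n_features == expected

    def test_nd_table_shape(self, tiny_collection):
        table = build_feature_table(tiny_collection, "ND")
        assert len(table) == 24
        assert table.n_features == 76

    def test_unknown_set(self, tiny_collection):
        with pytest.raises(ValueError, match="unknown feature set"):
            build_feature_table(tiny_collection, "XX")

    def test_domain_order_fixed(self, full_table):
        domains = [c.split(":")[0] for c in full_table.feature_columns]
        boundaries = [domains.index(d) for d in ("TD", "FD", "TF", "ND")]
        assert boundaries == sorted(boundaries)

    def test_column_count_conservation(self):
        assert 456 + 285 + 285 + 76 == 1102
        assert len(FEATURE_SETS["TD+FD+TF+ND"]) == 4

    def test_csv_roundtrip(self, full_table, tmp_path):
        path = full_table.to_csv(tmp_path / "table.csv")
        back = FeatureTable.from_csv(path)
        assert back.feature_columns == full_table.feature_columns
        np.testing.assert_allclose(back.values, full_table.values, rtol=1e-9)


class TestAnovaPvalue:
    def test_identical_groups_p_one(self):
        g = np.array([1.0, 2.0, 3.0])
        assert anova_pvalue([g, g]) == 1.0

    def test_textbook_sums_of_squares_oracle(self):
        groups = [
            np.array([6.0, 8.0, 4.0, 5.0, 3.0, 4.0]),
            np.array([8.0, 12.0, 9.0, 11.0, 6.0, 8.0]),
            np.array([13.0, 9.0, 11.0, 8.0, 7.0, 12.0]),
        ]
        # by-hand between/within sums of squares
        all_vals = np.concatenate(groups)
        grand = all_vals.mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        dfb, dfw = len(groups) - 1, all_vals.size - len(groups)
        f = (ssb / dfb) / (ssw / dfw)
        p_oracle = float(stats.f.sf(f, dfb, dfw))
        assert anova_pvalue(groups) == pytest.approx(p_oracle, rel=1e-12)

    def test_null_pvalues_uniform(self, rng):
        """Six same-normal groups, 2000 replicates: p ~ Uniform[0,1] (KS)."""
        ps = []
        for _ in range(2000):
            groups = [rng.standard_normal(10) for _ in range(6)]
            ps.append(anova_pvalue(groups))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_argument_checks(self):
        with pytest.raises(ValueError):
            anova_pvalue([np.array([1.0, 2.0])])
        with pytest.raises(ValueError):
            anova_pvalue([np.array([1.0]), np.array([2.0, 3.0])])


class TestSelectFeatures:
    def test_mask_covers_all_columns(self, full_table):
        mask = select_features(full_table, alpha=0.05)
        assert len(mask) == 1102
        assert np.all((mask.p_values >= 0) & (mask.p_values <= 1))

    def test_significance_iff_below_alpha(self, full_table):
        mask = select_features(full_table, alpha=0.05)
        np.testing.assert_array_equal(mask.significant, mask.p_values < 0.05)

    def test_alpha_zero_selects_nothing(self, full_table):
        mask = select_features(full_table, alpha=1e-300)
        assert mask.n_selected == 0

    def test_missing_class_rejected(self, full_table):
        broken = FeatureTable(full_table.df[full_table.df["label"] != 3].copy())
        with pytest.raises(ValueError, match="absent"):
            select_features(broken)

    def test_bh_correction_never_selects_more(self, full_table):
        raw = select_features(full_table, alpha=0.05)
        bh = select_features(full_table, alpha=0.05, correction="bh")
        assert bh.n_selected <= raw.n_selected
        assert bh.corrected

    def test_json_roundtrip(self, full_table, tmp_path):
        mask = select_features(full_table)
        path = mask.to_json(tmp_path / "mask.json")
        doc = json.loads(path.read_text())
        assert doc["schema_version"] == 1
        back = SelectionMask.from_json(path)
        assert back.ids == mask.ids
        np.testing.assert_allclose(back.p_values, mask.p_values)


class TestReduceTable:
    def test_all_true_identity(self, full_table):
        mask = SelectionMask(full_table.feature_columns,
                             np.zeros(full_table.n_features), alpha=0.05)
        reduced = reduce_table(full_table, mask)
        assert reduced.feature_columns == full_table.feature_columns

    def test_all_false_signals_empty(self, full_table):
        mask = SelectionMask(full_table.feature_columns,
                             np.ones(full_table.n_features), alpha=0.05)
        with pytest.raises(EmptyFeatureSetError):
            reduce_table(full_table, mask)

    def test_column_count_conservation(self, full_table):
        mask = select_features(full_table)
        if mask.n_selected == 0:
            pytest.skip("nothing selected on this draw")
        reduced = reduce_table(full_table, mask)
        assert reduced.n_features == mask.n_selected

    def test_mismatched_mask_rejected(self, full_table):
        mask = SelectionMask(["TD:TD1:ch1"], np.array([0.5]))
        with pytest.raises(ValueError, match="match"):
            reduce_table(full_table, mask)


def _mask_for_domain(domain, n_types, significant_ids=()):
    ids, ps = [], []
    for ch in range(1, 20):
        for t in range(1, n_types + 1):
            fid = f"{domain}:{domain}{t}:ch{ch}"
            ids.append(fid)
            ps.append(0.01 if fid in significant_ids else 0.5)
    return SelectionMask(ids, np.array(ps), alpha=0.05)


class TestDistributionMap:
    def test_all_false_map_zero(self):
        dm = distribution_map(_mask_for_domain("ND", 4), "ND")
        assert dm.grand_total == 0
        assert np.all(dm.grid == 0)

    def test_binary_grand_total_conservation(self, full_table):
        mask = select_features(full_table)
        for domain in ("TD", "FD", "TF", "ND"):
            sub = mask.for_domain(domain)
            dm = distribution_map(sub, domain)
            assert dm.grand_total == sub.n_selected
            assert dm.row_totals.sum() == dm.grand_total
            assert dm.column_totals.sum() == dm.grand_total

    def test_count_mode_all_true(self):
        ids = [f"ND:ND{t}:ch{c}" for c in range(1, 20) for t in range(1, 5)]
        mask = SelectionMask(ids, np.zeros(76), alpha=0.05)
        dm = distribution_map([mask] * 8, "ND")
        assert dm.mode == "count"
        assert np.all(dm.grid == 8)
        assert dm.grand_total == 8 * 76

    def test_cell_placement(self):
        dm = distribution_map(
            _mask_for_domain("FD", 15, {"FD:FD3:ch11"}), "FD"
        )
        assert dm.grid[2, 10] == 1
        assert dm.grand_total == 1

    def test_mixed_domains_rejected(self, full_table):
        mask = select_features(full_table)
        with pytest.raises(ValueError):
            distribution_map(mask, "TD")  # mask spans all domains

    def test_frame_layout_matches_published_tables(self):
        dm = distribution_map(_mask_for_domain("ND", 4, {"ND:ND2:ch1"}), "ND")
        frame = dm.to_frame()
        assert list(frame.columns) == [str(c) for c in range(1, 20)] + ["Total"]
        assert list(frame.index) == ["ND1", "ND2", "ND3", "ND4", "Total"]
        assert frame.loc["ND2", "1"] == 1
        assert frame.loc["Total", "Total"] == 1

    def test_json_export(self, tmp_path):
        dm = distribution_map(_mask_for_domain("ND", 4), "ND")
        doc = json.loads(dm.to_json(tmp_path / "map.json").read_text())
        assert doc["mode"] == "binary"
        assert doc["grand_total"] == 0

    def test_invalid_mode_and_shape(self):
        with pytest.raises(ValueError):
            DistributionMap(domain="ND", mode="weird", grid=np.zeros((4, 19)))
        with pytest.raises(ValueError):
            DistributionMap(domain="ND", mode="binary", grid=np.zeros((3, 19)))
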