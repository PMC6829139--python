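"""Framework extraction, interval/block statistics and map comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import haplink as hl
from haplink.grouping import CosegregationBins
from haplink.mapbuild import LinkageMap


def toy_map(entries):
    df = pd.DataFrame(entries, columns=["marker_id", "lg", "position_cM"])
    return LinkageMap(entries=df)


class TestSelectFramework:
    def test_one_marker_per_bin(self):
        bins = CosegregationBins(
            assignment=pd.Series({"a": "b1", "b": "b1", "c": "b1",
                                  "d": "b2", "e": "b3", "f": "b3"}),
            representatives=pd.Series({"b1": "a", "b2": "d", "b3": "e"}))
        chosen = hl.select_framework_markers(bins, seed=0)
        assert len(chosen) == 3
        assert sum(m in {"a", "b", "c"} for m in chosen) == 1
        assert "d" in chosen

    def test_all_singletons_full_set(self):
        bins = CosegregationBins(
            assignment=pd.Series({"a": "b1", "b": "b2"}),
            representatives=pd.Series({"b1": "a", "b2": "b"}))
        assert hl.select_framework_markers(bins, seed=1) == ["a", "b"]

    def test_framework_count_equals_bins(self, clean_fit):
        fw = clean_fit.framework(seed=2)
        assert fw.map_.n_markers == clean_fit.bins.n_bins


class TestIntervalStats:
    def test_toy_intervals_and_max_gap(self):
        lmap = toy_map([("a", "LG01", 0.0), ("b", "LG01", 0.0),
                        ("c", "LG01", 5.0), ("d", "LG01", 15.0)])
        st_ = hl.interval_stats(lmap)
        row = st_.per_lg.iloc[0]
        assert row.max_gap_cM == 10.0
        assert row.length_cM == 15.0
        assert st_.n_intervals == 3
        assert st_.n_below == 1   # the zero-length co-segregating interval
        assert st_.n_above == 2

    def test_uniform_half_cM_spacing_no_small_intervals(self):
        entries = [(f"m{i}", "LG01", 0.5 * i) for i in range(50)]
        st_ = hl.interval_stats(toy_map(entries))
        assert st_.pct_below == 0.0

    def test_single_marker_lg_zero_intervals(self):
        st_ = hl.interval_stats(toy_map([("a", "LG01", 0.0)]))
        assert st_.n_intervals == 0

    def test_mean_interval_matches_published_framework_column(self):
        """length / (markers - 1) reproduces the published per-LG mean
        adjacent interval at the printed rounding."""
        table = hl.datasets.porientalis_map_summary()
        for row in table.itertuples():
            mean = hl.mean_interval(row.fw_length_cM, row.fw_n_markers)
            assert round(mean, 2) == pytest.approx(
                row.fw_mean_interval_cM, abs=0.005)


class TestBlockDistribution:
    def test_mu_on_toy_map(self):
        # 20 markers over an LG spanning 10 blocks of 10 cM
        entries = [(f"m{i}", "LG01", 99.9 * i / 19) for i in range(20)]
        bd = hl.block_distribution(toy_map(entries), block_cM=10)
        assert bd.n_blocks == 10
        assert bd.mu == pytest.approx(2.0)

    def test_poisson_pmf_closed_form(self):
        assert hl.poisson_pmf(2, 2.0) == pytest.approx(2 * np.exp(-2),
                                                       rel=1e-12)

    def test_pmf_normalises(self):
        xs = np.arange(200)
        assert hl.poisson_pmf(xs, 7.3).sum() == pytest.approx(1.0,
                                                              abs=1e-12)

    def test_counts_conserve_markers(self, clean_fit):
        bd = clean_fit.block_distribution()
        assert bd.per_block["n_markers"].sum() == clean_fit.map_.n_markers
        assert bd.classes["observed"].sum() == bd.n_blocks
        assert bd.classes["expected"].sum() == pytest.approx(bd.n_blocks,
                                                             rel=1e-6)

    def test_expected_pooled_min_five(self, clean_fit):
        bd = clean_fit.block_distribution()
        if len(bd.classes) > 2:
            assert (bd.classes["expected"].iloc[-1] >= 5.0 or
                    len(bd.classes) == 2)
        assert bd.gof_df == max(len(bd.classes) - 2, 1)
        assert 0.0 <= bd.gof_p <= 1.0


class TestCompareMaps:
    def test_map_vs_itself_perfect(self, clean_fit):
        cmp_res = clean_fit.compare(clean_fit)
        assert cmp_res.n_shared == clean_fit.map_.n_markers
        assert np.allclose(cmp_res.lg_pairs["spearman"].dropna(), 1.0)

    def test_reversed_lgs_still_perfect(self, clean_fit):
        entries = clean_fit.map_.entries.copy()
        lengths = entries.groupby("lg")["position_cM"].transform("max")
        entries["position_cM"] = lengths - entries["position_cM"]
        entries = entries.sort_values(["lg", "position_cM"])
        reversed_map = LinkageMap(entries=entries.reset_index(drop=True))
        cmp_res = hl.compare_maps(clean_fit.map_, reversed_map)
        assert np.allclose(cmp_res.lg_pairs["spearman"].dropna(), 1.0)
        assert cmp_res.lg_pairs["reversed"].all()

    def test_no_shared_markers_warns_empty(self):
        a = toy_map([("a", "LG01", 0.0), ("b", "LG01", 1.0)])
        b = toy_map([("x", "LG01", 0.0), ("y", "LG01", 1.0)])
        with pytest.warns(UserWarning, match="no shared markers"):
            cmp_res = hl.compare_maps(a, b)
        assert cmp_res.n_shared == 0

    def test_framework_vs_full_high_concordance(self, clean_fit):
        fw = clean_fit.framework(seed=3)
        cmp_res = clean_fit.compare(fw)
        assert (cmp_res.lg_pairs["spearman"].dropna() >= 0.99).all()


class TestMapSummary:
    def test_totals_row_conserves_counts(self, clean_fit):
        fw = clean_fit.framework(seed=4)
        table = clean_fit.summary(framework=fw)
        totals = table[table["lg"] == "Total"].iloc[0]
        body = table[table["lg"] != "Total"]
        assert totals["n_markers"] == body["n_markers"].sum()
        assert totals["length_cM"] == pytest.approx(body["length_cM"].sum())
        assert totals["fw_n_markers"] == body["fw_n_markers"].sum()

    def test_published_inflation_and_average(self):
        """Derived figures recomputed from the published per-LG rows:
        4.4% inflation of the full map over the framework map, and a
        136.98 cM average LG length."""
        table = hl.datasets.porientalis_map_summary()
        full_total = table["full_length_cM"].sum()
        fw_total = table["fw_length_cM"].sum()
        infl = hl.map_inflation_percent(full_total, fw_total)
        assert round(infl, 1) == 4.4
        assert round(full_total / len(table), 2) == 136.98
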