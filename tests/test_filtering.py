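"""Locus classification and the filter funnel."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import haplink as hl
from conftest import het_mother, make_matrix


class TestClassifyLoci:
    def test_allele_count_classes(self):
        mat = make_matrix({
            "mono": ["A", "A", "A", None],
            "poly": ["A", "B", "A", "B"],
            "rep": ["A", "B", "C", "A"],
        })
        labels = hl.classify_loci(mat)
        assert labels["mono"] == "monomorphic"
        assert labels["poly"] == "polymorphic"
        assert labels["rep"] == "repetitive"

    def test_all_missing_locus_excluded_with_warning(self):
        mat = make_matrix({"ok": ["A", "B"], "empty": [None, None]})
        with pytest.warns(UserWarning, match="no non-missing"):
            labels = hl.classify_loci(mat)
        assert "empty" not in labels.index

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.sampled_from(["A", "B", "C", None]),
                    min_size=2, max_size=30))
    def test_invariant_to_relabelling_and_gamete_order(self, calls):
        if all(c is None for c in calls):
            return
        mat = make_matrix({"L": calls})
        base = hl.classify_loci(mat)["L"]
        relabel = {"A": "x", "B": "y", "C": "z", None: None}
        mat2 = make_matrix({"L": [relabel[c] for c in calls]})
        assert hl.classify_loci(mat2)["L"] == base
        mat3 = make_matrix({"L": calls[::-1]})
        assert hl.classify_loci(mat3)["L"] == base


class TestMotherConcordance:
    def test_heterozygous_match_kept(self):
        mat = make_matrix({"L": ["A", "B", "A", "B"]})
        kept = hl.mother_concordance_filter(mat, ["L"], het_mother(["L"]))
        assert list(kept) == ["L"]

    def test_homozygous_mother_dropped(self):
        mat = make_matrix({"L": ["A", "B", "A", "B"]})
        mother = het_mother(["L"], a1="A", a2="A")
        assert len(hl.mother_concordance_filter(mat, ["L"], mother)) == 0

    def test_mismatching_pair_dropped(self):
        mat = make_matrix({"L": ["A", "B", "A", "B"]})
        mother = het_mother(["L"], a1="A", a2="C")
        assert len(hl.mother_concordance_filter(mat, ["L"], mother)) == 0

    def test_unknown_mother_dropped(self):
        mat = make_matrix({"L": ["A", "B"]})
        mother = hl.MotherGenotype(pd.DataFrame(
            {"allele1": [np.nan], "allele2": ["B"]}, index=["L"]))
        assert len(hl.mother_concordance_filter(mat, ["L"], mother)) == 0


class TestMissingRateFilter:
    @pytest.mark.parametrize("n_missing,expect_keep", [
        (0, True), (27, True), (28, False),  # 27/139 < 0.20 < 28/139
    ])
    def test_threshold_at_139_gametes(self, n_missing, expect_keep):
        calls = ["A"] * (139 - n_missing) + [None] * n_missing
        mat = make_matrix({"L": calls})
        kept = hl.missing_rate_filter(mat, ["L"], threshold=0.20)
        assert ("L" in kept) is expect_keep

    def test_boundary_configurable(self):
        calls = ["A"] * 8 + [None] * 2  # exactly 20% missing
        mat = make_matrix({"L": calls})
        assert "L" in hl.missing_rate_filter(mat, ["L"], 0.20, "le")
        assert "L" not in hl.missing_rate_filter(mat, ["L"], 0.20, "lt")


class TestSegregationFilter:
    @pytest.mark.parametrize("n1,n2,expect", [
        (70, 69, "keep"),     # chi2 ~ 0.0072, p ~ 0.932
        (70, 70, "keep"),     # chi2 = 0, p = 1
        (100, 39, "discard"),  # chi2 ~ 26.77, p < 1e-6
    ])
    def test_closed_form_decisions(self, n1, n2, expect):
        calls = ["A"] * n1 + ["B"] * n2
        mat = make_matrix({"L": calls})
        kept, table = hl.segregation_filter(mat, ["L"])
        chi2 = (n1 - n2) ** 2 / (n1 + n2)
        assert table.loc["L", "chi2"] == pytest.approx(chi2)
        assert table.loc["L", "p"] == pytest.approx(
            stats.chi2.sf(chi2, 1), rel=1e-12)
        assert table.loc["L", "decision"] == expect

    def test_exact_binomial_option(self):
        calls = ["A"] * 12 + ["B"] * 2
        mat = make_matrix({"L": calls})
        _, table = hl.segregation_filter(mat, ["L"], exact=True)
        assert table.loc["L", "p"] == pytest.approx(
            stats.binomtest(12, 14, 0.5).pvalue)


class TestFunnel:
    def test_clean_dataset_survives_intact(self, clean_dataset):
        filtered, report, _ = hl.run_filter_funnel(clean_dataset.matrix,
                                                   clean_dataset.mother)
        assert report.total == clean_dataset.matrix.n_loci
        assert report.polymorphic == report.total
        # a 1:1 test on genuinely fair loci still rejects ~4% by chance
        assert report.pass_segregation >= 0.9 * report.total
        assert filtered.n_loci == report.pass_segregation

    def test_injected_classes_counted(self):
        cfg0 = hl.SimulationConfig(n_gametes=80, seed=31)
        base = hl.simulate_dataset(n_lgs=1, lg_lengths=[120], n_markers=500,
                                   config=cfg0).matrix
        cfg = hl.SimulationConfig(n_gametes=80, frac_repetitive=0.10,
                                  frac_monomorphic=0.10, seed=31)
        ds = hl.degrade(base, cfg)
        _, report, _ = hl.run_filter_funnel(ds.matrix, ds.mother)
        assert report.repetitive == 50
        assert report.monomorphic == 50
        assert report.polymorphic == 400

    def test_funnel_monotone_nonincreasing(self):
        cfg = hl.SimulationConfig(n_gametes=60, missing_rate=0.15,
                                  error_rate=0.01, frac_monomorphic=0.05,
                                  frac_repetitive=0.05,
                                  frac_mother_discordant=0.05, seed=37)
        ds = hl.simulate_dataset(n_lgs=2, lg_lengths=[80, 80],
                                 n_markers=300, config=cfg)
        _, r, _ = hl.run_filter_funnel(ds.matrix, ds.mother)
        assert r.polymorphic + r.monomorphic + r.repetitive + \
            r.all_missing == r.total
        assert r.polymorphic >= r.mother_concordant >= r.pass_missing \
            >= r.pass_segregation

    def test_filter_order_independence(self):
        """Missing-rate and concordance filters commute (per-locus and
        independent), so the final kept set is order-stable."""
        cfg = hl.SimulationConfig(n_gametes=60, missing_rate=0.2,
                                  frac_mother_discordant=0.1, seed=41)
        ds = hl.simulate_dataset(n_lgs=1, lg_lengths=[100], n_markers=200,
                                 config=cfg)
        labels = hl.classify_loci(ds.matrix)
        poly = labels.index[labels == "polymorphic"]
        a = hl.missing_rate_filter(
            ds.matrix, hl.mother_concordance_filter(ds.matrix, poly,
                                                    ds.mother), 0.20)
        b = hl.mother_concordance_filter(
            ds.matrix, hl.missing_rate_filter(ds.matrix, poly, 0.20),
            ds.mother)
        assert sorted(a) == sorted(b)
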