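"""Crossover simulator and noise injection against sampling oracles."""

import numpy as np
import pandas as pd
import pytest

import haplink as hl


def mismatch_fraction(matrix, locus_a, locus_b):
    a = matrix.calls.loc[locus_a]
    b = matrix.calls.loc[locus_b]
    return float((a != b).mean())


class TestSimulateTrueMap:
    def test_positions_within_range(self):
        tm = hl.simulate_true_map(1, [100.0], 3, seed=1)
        assert tm.n_markers == 3
        pos = tm.markers["position_cM"]
        assert ((pos >= 0) & (pos <= 100)).all()

    def test_counts_proportional_to_length(self):
        lengths = hl.datasets.porientalis_lg_lengths("framework")
        tm = hl.simulate_true_map(11, lengths, 7559, seed=2)
        counts = tm.markers.groupby("lg_id").size()
        total = sum(lengths)
        for (lg, L), c in zip(tm.linkage_groups, counts[
                sorted(counts.index)]):
            assert c == pytest.approx(7559 * L / total, abs=1.0)
        assert counts.sum() == 7559

    def test_deterministic_under_seed(self):
        a = hl.simulate_true_map(3, [50, 80, 120], 60, seed=9)
        b = hl.simulate_true_map(3, [50, 80, 120], 60, seed=9)
        pd.testing.assert_frame_equal(a.markers, b.markers)

    def test_clustered_placement_concentrates_centre(self):
        tm = hl.simulate_true_map(1, [100.0], 4000, placement="clustered",
                                  seed=3)
        pos = tm.markers["position_cM"]
        centre = ((pos >= 40) & (pos < 60)).mean()
        assert centre > 0.35  # uniform would give 0.20

    def test_rejects_zero_length_lg(self):
        with pytest.raises(ValueError):
            hl.simulate_true_map(2, [100.0, 0.0], 10, seed=0)


class TestSimulateGametes:
    def test_cosegregation_at_identical_position(self):
        mk = pd.DataFrame({"marker_id": ["m1", "m2"], "lg_id": "LG01",
                           "position_cM": [10.0, 10.0]})
        tm = hl.TrueMap(linkage_groups=(("LG01", 50.0),), markers=mk)
        mat = hl.simulate_gametes(tm, 200, seed=1)
        assert mismatch_fraction(mat, "m1", "m2") == 0.0

    def test_different_lgs_segregate_independently(self):
        mk = pd.DataFrame({"marker_id": ["m1", "m2"],
                           "lg_id": ["LG01", "LG02"],
                           "position_cM": [0.0, 0.0]})
        tm = hl.TrueMap(linkage_groups=(("LG01", 10.0), ("LG02", 10.0)),
                        markers=mk)
        mat = hl.simulate_gametes(tm, 10_000, seed=2)
        se = np.sqrt(0.25 / 10_000)
        assert mismatch_fraction(mat, "m1", "m2") == pytest.approx(
            0.5, abs=3 * se)

    def test_interval_recombination_matches_kosambi_inverse(self):
        # 27.465 cM under Kosambi corresponds to r = 0.25 exactly
        d_cM = 25 * np.log(3)
        mk = pd.DataFrame({"marker_id": ["m1", "m2"], "lg_id": "LG01",
                           "position_cM": [5.0, 5.0 + d_cM]})
        tm = hl.TrueMap(linkage_groups=(("LG01", 50.0),), markers=mk)
        mat = hl.simulate_gametes(tm, 10_000, seed=3)
        se = np.sqrt(0.25 * 0.75 / 10_000)
        assert mismatch_fraction(mat, "m1", "m2") == pytest.approx(
            0.25, abs=3 * se)

    def test_distortion_skews_allele_ratio(self):
        mk = pd.DataFrame({"marker_id": ["m1"], "lg_id": "LG01",
                           "position_cM": [0.0]})
        tm = hl.TrueMap(linkage_groups=(("LG01", 10.0),), markers=mk)
        mat = hl.simulate_gametes(tm, 4000, seed=4,
                                  distortion=(["m1"], 0.5))
        frac_b = float((mat.calls.loc["m1"] == "B").mean())
        # viability w: expected B fraction w/(1+w) = 1/3
        assert frac_b == pytest.approx(1 / 3, abs=0.03)


class TestDegrade:
    def test_identity_when_all_rates_zero(self, clean_dataset):
        cfg = hl.SimulationConfig(n_gametes=139, seed=5)
        mat = clean_dataset.matrix
        ds = hl.degrade(mat, cfg)
        pd.testing.assert_frame_equal(ds.matrix.calls, mat.calls)
        assert (ds.truth_labels == "polymorphic").all()
        assert ds.error_positions == set()

    def test_injection_counts_exact(self):
        cfg0 = hl.SimulationConfig(n_gametes=60, seed=6)
        base = hl.simulate_dataset(n_lgs=2, lg_lengths=[100, 100],
                                   n_markers=1000, config=cfg0).matrix
        cfg = hl.SimulationConfig(n_gametes=60, frac_monomorphic=0.10,
                                  frac_repetitive=0.05,
                                  frac_mother_discordant=0.02, seed=6)
        ds = hl.degrade(base, cfg)
        counts = ds.truth_labels.value_counts()
        assert counts["monomorphic"] == 100
        assert counts["repetitive"] == 50
        assert counts["mother_discordant"] == 20
        # repetitive loci really show >2 alleles
        n_alleles = ds.matrix.n_alleles()
        rep = ds.truth_labels.index[ds.truth_labels == "repetitive"]
        assert (n_alleles[rep] > 2).all()

    def test_missing_rate_binomial(self):
        cfg0 = hl.SimulationConfig(n_gametes=139, seed=7)
        base = hl.simulate_dataset(n_lgs=1, lg_lengths=[100],
                                   n_markers=1000, config=cfg0).matrix
        cfg = hl.SimulationConfig(n_gametes=139, missing_rate=0.10, seed=7)
        ds = hl.degrade(base, cfg)
        frac = ds.matrix.calls.isna().to_numpy().mean()
        assert frac == pytest.approx(0.10, abs=0.01)

    def test_error_positions_recorded_and_applied(self):
        cfg0 = hl.SimulationConfig(n_gametes=50, seed=8)
        base = hl.simulate_dataset(n_lgs=1, lg_lengths=[100],
                                   n_markers=200, config=cfg0).matrix
        cfg = hl.SimulationConfig(n_gametes=50, error_rate=0.02, seed=8)
        ds = hl.degrade(base, cfg)
        assert len(ds.error_positions) > 0
        flip = {"A": "B", "B": "A"}
        for locus, gamete in list(ds.error_positions)[:20]:
            assert ds.matrix.calls.loc[locus, gamete] == \
                flip[base.calls.loc[locus, gamete]]

    def test_rejects_overfull_pool(self):
        with pytest.raises(ValueError):
            hl.SimulationConfig(n_gametes=10, frac_monomorphic=0.6,
                                frac_repetitive=0.5)

    def test_dataset_determinism(self):
        cfg = hl.SimulationConfig(n_gametes=40, missing_rate=0.1,
                                  error_rate=0.01, frac_monomorphic=0.1,
                                  seed=13)
        a = hl.simulate_dataset(n_lgs=2, lg_lengths=[60, 90], n_markers=80,
                                config=cfg)
        b = hl.simulate_dataset(n_lgs=2, lg_lengths=[60, 90], n_markers=80,
                                config=cfg)
        pd.testing.assert_frame_equal(a.matrix.calls, b.matrix.calls)
        assert a.error_positions == b.error_positions
        pd.testing.assert_series_equal(a.truth_labels, b.truth_labels)
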