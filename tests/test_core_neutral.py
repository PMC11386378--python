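import warnings

import numpy as np
import pandas as pd
import pytest

import granulecology as g


def planted_core_matrix(seed=3, n_core=10, n_sparse=290):
    """Omnipresent high-abundance core plus sparse low-occupancy background."""
    frame = g.SampleFrame.default_design()
    rng = np.random.default_rng(seed)
    n_s = len(frame.sample_ids)
    counts = np.zeros((n_core + n_sparse, n_s), dtype=int)
    counts[:n_core] = rng.poisson(500, (n_core, n_s)) + 1
    present = rng.random((n_sparse, n_s)) < 0.15
    counts[n_core:][present] = rng.poisson(20, int(present.sum())) + 1
    taxa = [f"ASV_{i:04d}" for i in range(n_core + n_sparse)]
    return g.CountMatrix(taxa, frame.sample_ids, counts), frame, taxa[:n_core]


class TestOccupancyIndex:
    def test_omnipresent_taxon_tops_ranking(self):
        m, frame, core = planted_core_matrix()
        ranking = g.occupancy_index(m, frame)
        assert ranking["index"].iloc[0] == pytest.approx(1.0)
        assert ranking.index[0] in core

    def test_single_group_taxon_forced_index(self, default_frame):
        n_s = len(default_frame.sample_ids)
        counts = np.ones((2, n_s), dtype=int)
        c1 = [i for i, s in enumerate(default_frame.sample_ids)
              if s.startswith("C1_")]
        counts[1] = 0
        counts[1, c1] = 5
        m = g.CountMatrix(["everywhere", "c1_only"],
                          default_frame.sample_ids, counts)
        ranking = g.occupancy_index(m, default_frame)
        expected = 0.5 * (3 / 43) + 0.5 * (1 / 10)
        assert ranking.loc["c1_only", "index"] == pytest.approx(expected)

    def test_sample_order_invariant(self):
        m, frame, _ = planted_core_matrix(seed=5)
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(m.sample_ids))
        a = g.occupancy_index(m, frame)
        b = g.occupancy_index(m.select_samples(perm), frame)
        assert list(a.index) == list(b.index)

    def test_duplicated_omnipresent_sample_keeps_core_ranking(self):
        m, frame, core = planted_core_matrix(seed=7)
        dup_col = m.counts[:, [0]]
        counts2 = np.hstack([m.counts, dup_col])
        table = frame.table.copy()
        table.loc["C1_R4"] = table.loc["C1_R1"]
        frame2 = g.SampleFrame(table)
        m2 = g.CountMatrix(m.taxon_ids, m.sample_ids + ["C1_R4"], counts2)
        a = g.occupancy_index(m, frame)
        b = g.occupancy_index(m2, frame2)
        assert (b.loc[core, "occ_all"] == 1.0).all()
        assert set(a.index[:10]) == set(b.index[:10])


class TestContributionCurve:
    def test_reaches_exactly_hundred(self):
        m, frame, _ = planted_core_matrix()
        curve = g.bc_contribution_curve(list(g.occupancy_index(m, frame).index), m)
        assert curve[-1] == pytest.approx(100.0, abs=1e-9)
        assert (np.diff(curve) >= -1e-9).all()

    def test_identical_pair_hand_computation(self):
        # two identical samples with proportions [0.5, 0.3, 0.2]: the top
        # taxon's share of total similarity is 0.5
        counts = np.array([[5, 5], [3, 3], [2, 2]])
        m = g.CountMatrix(["a", "b", "c"], ["s1", "s2"], counts)
        curve = g.bc_contribution_curve(["a", "b", "c"], m)
        assert curve[0] == pytest.approx(50.0)
        assert curve[1] == pytest.approx(80.0)
        assert curve[2] == pytest.approx(100.0)

    def test_ranking_must_cover_matrix(self, small_counts):
        with pytest.raises(ValueError):
            g.bc_contribution_curve(["A", "B"], small_counts)


class TestSelectCore:
    def test_forced_example(self):
        assert g.select_core([50, 80, 95, 96, 96.5]) == 3

    def test_all_gains_large_keeps_everything(self):
        assert g.select_core([10, 20, 30, 40]) == 4

    def test_flat_curve_keeps_first(self):
        assert g.select_core([99.0, 99.5, 99.9, 100.0]) == 1

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            g.select_core([1, 2, 3], threshold=0)

    def test_planted_core_recovered(self):
        m, frame, core = planted_core_matrix()
        ranking = list(g.occupancy_index(m, frame).index)
        curve = g.bc_contribution_curve(ranking, m)
        members = g.select_core(curve, ranking)
        assert len(set(members) - set(core)) <= 2
        assert len(set(core) - set(members)) == 0


def neutral_counts(seed, m=0.1, n_taxa=200, n_samples=30, depth=20_000):
    rng = np.random.default_rng(seed)
    logp = rng.normal(0, 2.0, n_taxa)
    p = np.exp(logp) / np.exp(logp).sum()
    return g.simulate_neutral_community(p, m, n_samples, depth,
                                        seed=seed + 1000), p


class TestFitNeutralModel:
    def test_migration_recovered_on_neutral_data(self):
        counts, _ = neutral_counts(0)
        fit = g.fit_neutral_model(counts)
        assert abs(fit.m - 0.1) / 0.1 < 0.2
        assert fit.r_squared > 0.85

    def test_abundant_taxa_predicted_omnipresent(self):
        counts, p = neutral_counts(1)
        fit = g.fit_neutral_model(counts)
        abundant = fit.mean_abundance > 100 * fit.detection_limit
        assert (fit.predicted[abundant] > 0.999).all()

    def test_invalid_detection_limit(self, small_counts):
        with pytest.raises(ValueError):
            g.fit_neutral_model(small_counts, detection_limit=-1)

    def test_threshold_model_available(self):
        counts, _ = neutral_counts(2)
        fit = g.fit_neutral_model(counts, occupancy_model="threshold")
        assert fit.Nm > 0 and fit.occupancy_model == "threshold"


class TestClassifyNeutrality:
    def test_partitions_subset(self):
        counts, _ = neutral_counts(3)
        fit = g.fit_neutral_model(counts)
        classes = g.classify_neutrality(fit)
        assert set(classes.unique()) <= {"above", "neutral", "below"}
        assert len(classes) == len(fit.taxon_ids)

    def test_boosted_occupancy_classified_above(self):
        counts, _ = neutral_counts(4)
        occ = (counts.counts > 0).mean(axis=1)
        mid = np.flatnonzero((occ > 0.15) & (occ < 0.7))[:10]
        boosted = counts.counts.copy()
        for i in mid:
            row = boosted[i]
            row[row == 0] = 1
        m2 = g.CountMatrix(counts.taxon_ids, counts.sample_ids, boosted)
        fit = g.fit_neutral_model(m2)
        classes = g.classify_neutrality(fit, [counts.taxon_ids[i] for i in mid])
        assert (classes == "above").mean() >= 0.8

    def test_unknown_asv_rejected(self):
        counts, _ = neutral_counts(5)
        fit = g.fit_neutral_model(counts)
        with pytest.raises(KeyError):
            g.classify_neutrality(fit, ["nonexistent"])
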