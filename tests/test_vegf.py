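import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pathmeta.io import ExpressionDataset
from pathmeta.scoring import compare_groups
from pathmeta.simulate import SimulationConfig, generate_huvec_experiment
from pathmeta.vegf import (
    VEGF_PANEL,
    DerivedScoreModel,
    PerturbationExperiment,
    apply_derived_score,
    centroid_permutation_test,
    correlate_with_time,
    fit_pca_panel,
)

from conftest import make_dataset


def make_experiment(values, genes, labels, times=None, name="exp"):
    ds = make_dataset(values, genes=genes, name=name)
    treatment = pd.Series(labels, index=ds.sample_ids)
    time = pd.Series(times, index=ds.sample_ids) if times is not None else None
    return PerturbationExperiment(dataset=ds, treatment=treatment, time=time)


def exhaustive_centroid_p(coords, n_a):
    """Exact permutation p over all C(n, n_a) class assignments."""
    coords = np.asarray(coords, float)
    n = len(coords)

    def dist(idx_a):
        mask = np.zeros(n, bool)
        mask[list(idx_a)] = True
        return np.linalg.norm(coords[mask].mean(0) - coords[~mask].mean(0))

    observed = dist(range(n_a))
    dists = [dist(c) for c in itertools.combinations(range(n), n_a)]
    return sum(d >= observed - 1e-12 for d in dists) / len(dists), observed


class TestFitPcaPanel:
    def test_rank_one_pair_loads_equally(self, rng):
        g1 = rng.normal(8, 1, 6)
        exp = make_experiment(
            np.vstack([g1, g1 + 1.0]),
            genes=["a", "b"],
            labels=["treated"] * 3 + ["naive"] * 3,
        )
        model, embedding = fit_pca_panel(exp, ["a", "b"], informative=False)
        np.testing.assert_allclose(np.abs(model.loadings), [1 / math.sqrt(2)] * 2, atol=1e-10)
        # the second component carries no variance
        assert np.allclose(embedding["PC2"], 0.0, atol=1e-9)

    def test_loadings_match_eigendecomposition_oracle(self, rng):
        values = rng.normal(8, 1, (3, 5))
        exp = make_experiment(
            values, genes=["a", "b", "c"], labels=["treated", "treated", "naive", "naive", "naive"]
        )
        model, _ = fit_pca_panel(exp, ["a", "b", "c"], informative=False)
        cov = np.cov(values)  # gene-gene covariance, n-1 denominator
        evals, evecs = np.linalg.eigh(cov)
        lead = evecs[:, np.argmax(evals)]
        cos = abs(float(np.dot(model.loadings, lead)))
        assert cos == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("direction", [1.0, -1.0])
    def test_orientation_puts_treated_above_naive(self, direction, rng):
        base = rng.normal(8, 0.3, (4, 12))
        base[:, :6] += direction * 2.0  # first six samples are treated
        exp = make_experiment(
            base, genes=list("abcd"), labels=["treated"] * 6 + ["naive"] * 6
        )
        model, embedding = fit_pca_panel(exp, list("abcd"), informative=False)
        assert embedding["PC1"][:6].mean() >= embedding["PC1"][6:].mean()
        scores = apply_derived_score(model, exp.dataset)
        assert np.median(scores.raw[:6]) > np.median(scores.raw[6:])

    def test_embedding_is_centered_and_loadings_unit_norm(self, rng):
        exp = make_experiment(
            rng.normal(8, 1, (5, 9)),
            genes=list("abcde"),
            labels=["treated"] * 4 + ["naive"] * 5,
        )
        model, embedding = fit_pca_panel(exp, list("abcde"), informative=False)
        assert np.linalg.norm(model.loadings) == pytest.approx(1.0)
        np.testing.assert_allclose(embedding.mean(axis=0), [0.0, 0.0], atol=1e-9)

    def test_too_few_panel_genes_listed_in_error(self, rng):
        exp = make_experiment(
            rng.normal(8, 1, (2, 5)),
            genes=["a", "b"],
            labels=["treated"] * 2 + ["naive"] * 3,
        )
        with pytest.raises(ValueError, match="missing.*zz"):
            fit_pca_panel(exp, ["a", "zz"], informative=False)


class TestCentroidPermutationTest:
    def test_identical_centroids_give_p_one(self):
        coords = np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 1.0], [0.0, 0.0]])
        res = centroid_permutation_test(coords, ["a", "a", "b", "b"], B=200, seed=1)
        assert res.observed_distance == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_on_six_points(self, rng):
        B = 10_000
        for trial in range(3):
            coords = np.random.default_rng(trial).normal(0, 1, (6, 2))
            labels = ["a"] * 3 + ["b"] * 3
            exact_p, _ = exhaustive_centroid_p(coords, 3)
            res = centroid_permutation_test(coords, labels, B=B, seed=trial)
            mc_se = math.sqrt(exact_p * (1 - exact_p) / B)
            assert abs(res.p_value - exact_p) <= 2 * mc_se + 2 / (B + 1)

    def test_reproducible_and_bounded(self, rng):
        coords = rng.normal(0, 1, (10, 2))
        labels = ["a"] * 5 + ["b"] * 5
        r1 = centroid_permutation_test(coords, labels, B=500, seed=7)
        r2 = centroid_permutation_test(coords, labels, B=500, seed=7)
        assert r1.p_value == r2.p_value
        assert 1 / 501 <= r1.p_value <= 1.0

    def test_invalid_inputs_rejected(self, rng):
        coords = rng.normal(0, 1, (4, 2))
        with pytest.raises(ValueError, match="B"):
            centroid_permutation_test(coords, ["a", "a", "b", "b"], B=0)
        with pytest.raises(ValueError, match="labels"):
            centroid_permutation_test(coords, ["a"] * 4)


class TestApplyDerivedScore:
    def test_single_gene_passthrough(self):
        model = DerivedScoreModel(name="m", genes=["a"], loadings=[1.0])
        ds = make_dataset([[2.0, 5.0, 9.0]], genes=["a"])
        np.testing.assert_allclose(apply_derived_score(model, ds).raw, [2.0, 5.0, 9.0])

    def test_hand_weighted_sum(self):
        model = DerivedScoreModel(name="m", genes=["a", "b"], loadings=[0.6, 0.8])
        ds = make_dataset([[5.0], [2.5]], genes=["a", "b"])
        # 0.6*5 + 0.8*2.5 = 5.0
        np.testing.assert_allclose(apply_derived_score(model, ds).raw, [5.0])

    def test_zero_overlap_rejected(self):
        model = DerivedScoreModel(name="m", genes=["zz"], loadings=[1.0])
        with pytest.raises(ValueError, match="no genes"):
            apply_derived_score(model, make_dataset([[1.0]], genes=["a"]))

    def test_orientation_flip_inverts_scores_but_not_group_test(self, rng):
        model = DerivedScoreModel(
            name="m", genes=["a", "b"], loadings=np.array([0.6, 0.8])
        )
        ds = make_dataset(rng.normal(8, 1, (2, 10)), genes=["a", "b"])
        labels = ["x"] * 5 + ["y"] * 5
        s_pos = apply_derived_score(model, ds)
        s_neg = apply_derived_score(model.flipped(), ds)
        np.testing.assert_allclose(s_neg.raw, -s_pos.raw)
        assert compare_groups(s_pos, labels).p_value == pytest.approx(
            compare_groups(s_neg, labels).p_value
        )


class TestCorrelateWithTime:
    def test_proportional_scores_give_unit_correlation(self):
        from pathmeta.scoring import ActivationScoreSet

        times = np.array([0.0, 4.0, 8.0, 24.0])
        s = ActivationScoreSet(
            signature="m", sample_ids=list("abcd"), raw=3.0 * times + 1.0
        )
        assert correlate_with_time(s, times).estimate == pytest.approx(1.0)
        s_rev = ActivationScoreSet(
            signature="m", sample_ids=list("abc"), raw=np.array([3.0, 2.0, 1.0])
        )
        assert correlate_with_time(s_rev, [1.0, 2.0, 3.0]).estimate == pytest.approx(-1.0)

    def test_eight_point_oracle(self, rng):
        from pathmeta.scoring import ActivationScoreSet

        raw = rng.normal(0, 1, 8)
        times = rng.uniform(0, 24, 8)
        s = ActivationScoreSet(signature="m", sample_ids=[f"s{i}" for i in range(8)], raw=raw)
        rec = correlate_with_time(s, times)
        assert rec.estimate == pytest.approx(np.corrcoef(raw, times)[0, 1], abs=1e-12)

    def test_needs_three_timed_samples(self):
        from pathmeta.scoring import ActivationScoreSet

        s = ActivationScoreSet(signature="m", sample_ids=["a", "b"], raw=[1.0, 2.0])
        with pytest.raises(ValueError, match="3 samples"):
            correlate_with_time(s, [1.0, 2.0])


class TestSyntheticDerivationPipeline:
    """End-to-end behaviour on the simulated treated-vs-naive time course."""

    def test_treated_separate_from_naive(self):
        hits = 0
        for seed in range(10):
            exp = generate_huvec_experiment(SimulationConfig(seed=200 + seed))
            panel = [g for g in exp.dataset.gene_ids if g.startswith("PG")]
            model, embedding = fit_pca_panel(exp, panel)
            scores = apply_derived_score(model, exp.dataset)
            cmp = compare_groups(scores, exp.treatment.to_numpy())
            hits += cmp.p_value < 0.01
        assert hits >= 9

    def test_score_tracks_incubation_time(self):
        hits = 0
        for seed in range(10):
            exp = generate_huvec_experiment(SimulationConfig(seed=300 + seed))
            panel = [g for g in exp.dataset.gene_ids if g.startswith("PG")]
            model, _ = fit_pca_panel(exp, panel)
            scores = apply_derived_score(model, exp.dataset)
            hits += correlate_with_time(scores, exp.time).estimate > 0.5
        assert hits >= 9

    def test_panel_fixture_names_ten_genes(self):
        assert len(VEGF_PANEL) == 10
        assert "VEGF" in VEGF_PANEL and "ANGPTL4" in VEGF_PANEL
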