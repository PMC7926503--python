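import numpy as np
import pandas as pd
import pytest

from claudinlow import (
    CL_LABEL,
    OTHER_LABEL,
    CentroidModel,
    CentroidSubtypeClassifier,
    LabeledReference,
    SimulationConfig,
    assign_subtype,
    build_centroids,
    identify_cl_cluster,
    simulate_cohort,
    simulate_reference_panel,
    ward_cluster,
)
from conftest import make_matrix
from oracles import centroid_assign_brute, ward_agglomerate_brute


def reference_from(values, labels, genes=None):
    m = make_matrix(values, genes=genes)
    return LabeledReference(m, pd.Series(labels, index=m.samples))


class TestBuildCentroids:
    def test_hand_mean(self):
        ref = reference_from(
            np.array([[1.0, 3.0, 0.0], [3.0, 5.0, 0.0]]),
            [CL_LABEL, CL_LABEL, OTHER_LABEL],
        )
        model = build_centroids(ref)
        np.testing.assert_allclose(model.centroid_cl, [2.0, 4.0])
        np.testing.assert_allclose(model.centroid_other, [0.0, 0.0])
        assert model.n_cl == 2 and model.n_other == 1

    def test_single_sample_groups_equal_their_vectors(self):
        ref = reference_from(np.array([[1.0, 9.0], [2.0, 8.0]]), [CL_LABEL, OTHER_LABEL])
        model = build_centroids(ref)
        np.testing.assert_array_equal(model.centroid_cl, [1.0, 2.0])
        np.testing.assert_array_equal(model.centroid_other, [9.0, 8.0])

    def test_missing_genes_reported_not_fatal(self, rng):
        genes = [f"G{i}" for i in range(8)]
        ref = reference_from(
            rng.normal(size=(8, 4)), [CL_LABEL, CL_LABEL, OTHER_LABEL, OTHER_LABEL],
            genes=genes,
        )
        model = build_centroids(ref, gene_list=genes + ["ABSENT1", "ABSENT2"])
        assert model.missing_genes == ["ABSENT1", "ABSENT2"]
        assert model.gene_list == genes

    def test_too_many_missing_genes_fails(self, rng):
        ref = reference_from(rng.normal(size=(2, 2)), [CL_LABEL, OTHER_LABEL],
                             genes=["A", "B"])
        with pytest.raises(ValueError, match="centroid genes present"):
            build_centroids(ref, gene_list=["A", "B", "X", "Y", "Z"])

    def test_one_class_reference_rejected(self):
        ref = reference_from(np.ones((2, 2)), [CL_LABEL, CL_LABEL])
        with pytest.raises(ValueError):
            build_centroids(ref)


class TestAssignSubtype:
    def model(self):
        return CentroidModel(
            gene_list=["A", "B", "C"],
            centroid_cl=np.zeros(3),
            centroid_other=np.full(3, 2.0),
            n_cl=9,
            n_other=43,
        )

    def test_exact_centroid_match(self):
        m = make_matrix(np.zeros((3, 1)), genes=["A", "B", "C"])
        calls = assign_subtype(self.model(), m)
        assert calls.iloc[0]["label"] == CL_LABEL
        assert calls.iloc[0]["d_cl"] == 0.0

    def test_hand_euclidean_toy(self):
        m = make_matrix(np.full((3, 1), 1.2), genes=["A", "B", "C"])
        calls = assign_subtype(self.model(), m)
        assert calls.iloc[0]["label"] == OTHER_LABEL
        assert calls.iloc[0]["d_cl"] == pytest.approx(np.sqrt(3) * 1.2)
        assert calls.iloc[0]["d_other"] == pytest.approx(np.sqrt(3) * 0.8)

    def test_exact_tie_goes_to_other(self):
        m = make_matrix(np.full((3, 1), 1.0), genes=["A", "B", "C"])
        calls = assign_subtype(self.model(), m)
        assert calls.iloc[0]["margin"] == 0.0
        assert calls.iloc[0]["label"] == OTHER_LABEL

    def test_agrees_with_brute_force(self, rng):
        genes = [f"G{i}" for i in range(11)]
        model = CentroidModel(
            gene_list=genes,
            centroid_cl=rng.normal(size=11),
            centroid_other=rng.normal(size=11),
            n_cl=5,
            n_other=7,
        )
        m = make_matrix(rng.normal(size=(11, 30)), genes=genes)
        calls = assign_subtype(model, m)
        labels, d_cl, d_other = centroid_assign_brute(
            m.values.T, model.centroid_cl, model.centroid_other
        )
        assert list(calls["label"]) == labels
        np.testing.assert_allclose(calls["d_cl"], d_cl, atol=1e-10)
        np.testing.assert_allclose(calls["d_other"], d_other, atol=1e-10)

    def test_missing_genes_dropped_from_both_sides(self):
        m = make_matrix(np.zeros((2, 1)), genes=["A", "B"])
        calls = assign_subtype(self.model(), m)  # gene C absent
        assert calls.iloc[0]["d_other"] == pytest.approx(np.sqrt(8))

    def test_hard_fail_below_gene_fraction(self):
        m = make_matrix(np.zeros((1, 1)), genes=["A"])
        with pytest.raises(ValueError, match="model genes present"):
            assign_subtype(self.model(), m)


class TestCentroidEstimator:
    def test_sklearn_interface(self, rng):
        X = rng.normal(size=(10, 4))
        y = np.array([CL_LABEL] * 5 + [OTHER_LABEL] * 5)
        clf = CentroidSubtypeClassifier().fit(X, y)
        assert clf.get_params() == {"positive_label": CL_LABEL}
        assert set(clf.predict(X)) <= {CL_LABEL, OTHER_LABEL}
        assert clf.score(X, y) >= 0.0

    def test_requires_two_classes(self, rng):
        with pytest.raises(ValueError, match="2 classes"):
            CentroidSubtypeClassifier().fit(rng.normal(size=(3, 2)), ["a"] * 3)


class TestWardCluster:
    def test_two_samples_single_merge_cost(self, signature):
        cfg = SimulationConfig(n_genes=17, n_samples=2, cl_fraction=0.5, seed=1)
        expr, _, _ = simulate_cohort(cfg)
        result = ward_cluster(expr, signature, k=2, standardize=False)
        a, b = expr.values[:, 0], expr.values[:, 1]
        expected = np.sum((a - b) ** 2) / 2.0
        assert result.merge_costs[0] == pytest.approx(expected)

    def test_duplicate_samples_merge_first_at_zero(self, signature, rng):
        values = rng.normal(size=(17, 4))
        values[:, 1] = values[:, 0]
        m = make_matrix(values, genes=signature.genes)
        result = ward_cluster(m, signature, standardize=False)
        assert result.merge_costs[0] == pytest.approx(0.0, abs=1e-20)
        assert set(result.linkage[0, :2]) == {0.0, 1.0}

    def test_merge_costs_monotone(self, signature, rng):
        m = make_matrix(rng.normal(size=(17, 25)), genes=signature.genes)
        result = ward_cluster(m, signature)
        assert (np.diff(result.merge_costs) >= -1e-12).all()

    def test_two_blob_recovery(self, signature, rng):
        blob = np.zeros((17, 5))
        blob[:, 3:] = 10.0
        m = make_matrix(blob + 0.01 * rng.normal(size=(17, 5)), genes=signature.genes)
        result = ward_cluster(m, signature, k=2, standardize=False)
        labels = result.labels.to_numpy()
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[4]

    def test_matches_exhaustive_oracle_on_small_instances(self, signature, rng):
        for _ in range(10):
            n = int(rng.integers(3, 7))
            values = rng.normal(size=(17, n))
            m = make_matrix(values, genes=signature.genes)
            result = ward_cluster(m, signature, k=2, standardize=False)
            costs, partition = ward_agglomerate_brute(values.T, k=2)
            np.testing.assert_allclose(result.merge_costs, costs, atol=1e-8)
            ours = {
                frozenset(np.where(result.labels.to_numpy() == c)[0])
                for c in set(result.labels)
            }
            assert ours == partition

    def test_sample_permutation_equivariance(self, signature, rng):
        cfg = SimulationConfig(n_genes=40, n_samples=60, seed=9)
        expr, labels, _ = simulate_cohort(cfg)
        perm = rng.permutation(expr.samples)
        permuted = expr.subset_samples(list(perm))
        calls = ward_cluster(expr, signature).calls
        calls_perm = ward_cluster(permuted, signature).calls
        pd.testing.assert_series_equal(calls.loc[calls_perm.index], calls_perm)

    def test_fewer_than_two_samples_rejected(self, signature):
        m = make_matrix(np.ones((17, 1)), genes=signature.genes)
        with pytest.raises(ValueError, match="2 samples"):
            ward_cluster(m, signature)


class TestIdentifyClCluster:
    def test_planted_cluster_recovered(self, small_study, signature):
        cohort = small_study.cohorts[0]
        result = ward_cluster(cohort.expression, signature)
        assert result.cl_cluster is not None
        assert (result.calls == cohort.labels).mean() == 1.0
        best, scores = identify_cl_cluster(result, cohort.expression, signature)
        assert best == result.cl_cluster
        assert scores[best] > 0

    def test_null_cohorts_rarely_called(self, signature):
        calls = 0
        for seed in range(10):
            cfg = SimulationConfig(n_genes=17, n_samples=100, effect_size=0.0, seed=seed)
            expr, _, _ = simulate_cohort(cfg)
            result = ward_cluster(expr, signature)
            calls += result.cl_cluster is not None
        assert calls <= 2

    def test_single_cluster_cut_reports_score_without_call(self, signature):
        cfg = SimulationConfig(n_genes=17, n_samples=50, effect_size=0.0, seed=3)
        expr, _, _ = simulate_cohort(cfg)
        result = ward_cluster(expr, signature, k=1)
        assert set(result.cluster_scores) == {1}
        assert result.cl_cluster is None  # |score| ~ 0 under the null
        assert abs(result.cluster_scores[1]) < 0.5


class TestLabelRecovery:
    def test_both_callers_recover_planted_labels(self, signature):
        """delta=4, sigma=1: centroid and cluster callers recover the truth."""
        total = centroid_ok = cluster_ok = 0
        for seed in range(5):
            cfg = SimulationConfig(
                n_genes=60, n_samples=200, cl_fraction=0.1, effect_size=4.0,
                noise_sd=1.0, n_cohorts=1, seed=seed,
            )
            rng = np.random.default_rng(seed)
            from claudinlow.simulate import _draw_baselines, _gene_names

            baselines = _draw_baselines(rng, _gene_names(cfg.n_genes, signature))
            panel = simulate_reference_panel(cfg, rng=rng, baselines=baselines)
            expr, truth, _ = simulate_cohort(cfg, rng=rng, baselines=baselines)
            model = build_centroids(panel)
            centroid_calls = assign_subtype(model, expr)["label"]
            cluster_calls = ward_cluster(expr, signature).calls
            total += len(truth)
            centroid_ok += int((centroid_calls.to_numpy() == truth.to_numpy()).sum())
            cluster_ok += int((cluster_calls.to_numpy() == truth.to_numpy()).sum())
        assert centroid_ok / total >= 0.95
        assert cluster_ok / total >= 0.95
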