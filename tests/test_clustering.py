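"""Density-peak merging: oracle recovery on separated blobs and invariants."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from sfcmpipe.clustering import assign_to_clusters, cluster_summary, flowpeaks_cluster
from sfcmpipe.config import ClusterParams
from sfcmpipe.errors import DomainError
from sfcmpipe.preprocess import TraitMatrix


def blobs(rng, centers, n_per=500, sd=1.0):
    """Spherical Gaussian blobs; returns (matrix, true labels)."""
    centers = np.asarray(centers, dtype=float)
    points, labels = [], []
    for i, c in enumerate(centers):
        points.append(rng.normal(c, sd, size=(n_per, centers.shape[1])))
        labels += [i] * n_per
    data = pd.DataFrame(np.vstack(points), columns=[f"d{j}" for j in range(centers.shape[1])])
    return TraitMatrix(data), np.array(labels)


class TestBlobOracle:
    def test_two_distant_blobs_exact(self, rng):
        m, truth = blobs(rng, [[0, 0], [10, 10]], n_per=1000)
        model = flowpeaks_cluster(m, ClusterParams(seed=0))
        assert model.n_clusters == 2
        assert adjusted_rand_score(truth, model.labels) == 1.0

    def test_single_blob_one_cluster(self, rng):
        m, _ = blobs(rng, [[0.0, 0.0, 0.0]], n_per=2000)
        model = flowpeaks_cluster(m, ClusterParams(k0=20, seed=0))
        assert model.n_clusters == 1

    def test_matches_nearest_center_partition(self, rng):
        """On k well-separated blobs the partition equals the brute-force
        nearest-true-center assignment."""
        centers = np.array(
            [[0, 0, 0], [8, 0, 0], [0, 8, 0], [0, 0, 8], [8, 8, 8]], dtype=float
        )
        m, truth = blobs(rng, centers, n_per=400)
        model = flowpeaks_cluster(m, ClusterParams(seed=1))
        nearest = np.argmin(
            ((m.data.to_numpy()[:, None, :] - centers[None]) ** 2).sum(-1), axis=1
        )
        assert model.n_clusters == len(centers)
        assert adjusted_rand_score(nearest, model.labels) == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_stability_over_seeds(self, seed):
        rng = np.random.default_rng(123)
        m, truth = blobs(rng, [[0, 0], [10, 10]], n_per=400)
        model = flowpeaks_cluster(m, ClusterParams(seed=seed))
        assert model.n_clusters == 2
        assert adjusted_rand_score(truth, model.labels) == 1.0


class TestInvariants:
    def test_cluster_count_monotone_in_h(self, rng):
        m, _ = blobs(rng, [[0, 0], [3.5, 0], [0, 3.5]], n_per=400)
        counts = [
            flowpeaks_cluster(m, ClusterParams(h=h, seed=2)).n_clusters
            for h in (0.5, 1.0, 2.0, 4.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_row_permutation_same_partition(self, rng):
        m, _ = blobs(rng, [[0, 0], [9, 9]], n_per=300)
        model = flowpeaks_cluster(m, ClusterParams(seed=3))
        perm = rng.permutation(len(m.data))
        m2 = TraitMatrix(m.data.iloc[perm].reset_index(drop=True))
        model2 = flowpeaks_cluster(m2, ClusterParams(seed=3))
        assert adjusted_rand_score(model.labels[perm], model2.labels) == 1.0

    def test_determinism(self, rng):
        m, _ = blobs(rng, [[0, 0], [10, 0]], n_per=300)
        a = flowpeaks_cluster(m, ClusterParams(seed=4))
        b = flowpeaks_cluster(m, ClusterParams(seed=4))
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_allclose(a.peaks, b.peaks)

    def test_weights_sum_to_one(self, rng):
        m, _ = blobs(rng, [[0, 0], [10, 0]], n_per=300)
        model = flowpeaks_cluster(m, ClusterParams(seed=0))
        assert model.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_discrete_trait_column_handled(self, rng):
        """A trait constant within components (zero variance) must not
        break the smoothed density."""
        m, _ = blobs(rng, [[0, 0], [10, 0]], n_per=300)
        data = m.data.copy()
        data["count"] = np.where(data["d0"] > 5, 1.0, 0.0)
        model = flowpeaks_cluster(TraitMatrix(data), ClusterParams(seed=0))
        assert model.n_clusters == 2


class TestErrors:
    def test_k0_exceeding_rows(self, rng):
        m, _ = blobs(rng, [[0, 0]], n_per=10)
        with pytest.raises(DomainError):
            flowpeaks_cluster(m, ClusterParams(k0=50, seed=0))

    def test_single_column_rejected(self, rng):
        m = TraitMatrix(pd.DataFrame({"a": rng.normal(size=100)}))
        with pytest.raises(DomainError):
            flowpeaks_cluster(m, ClusterParams(seed=0))


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(5)
    m, truth = blobs(rng, [[0, 0], [10, 10]], n_per=500)
    return m, truth, flowpeaks_cluster(m, ClusterParams(seed=5))


class TestAssignment:
    def test_self_assignment_identical(self, fitted):
        m, _, model = fitted
        np.testing.assert_array_equal(assign_to_clusters(model, m), model.labels)

    def test_component_mean_maps_to_its_cluster(self, fitted):
        m, _, model = fitted
        raw = model.means * model.standardize_sd + model.standardize_mean
        points = TraitMatrix(pd.DataFrame(raw, columns=model.columns))
        labels = assign_to_clusters(model, points)
        np.testing.assert_array_equal(labels, model.merge_map)

    def test_column_mismatch_rejected(self, fitted):
        m, _, model = fitted
        with pytest.raises(DomainError):
            assign_to_clusters(model, TraitMatrix(m.data.rename(columns={"d0": "x"})))

    def test_far_outlier_low_density(self, fitted):
        m, _, model = fitted
        out = TraitMatrix(pd.DataFrame([[50.0, -40.0]], columns=model.columns))
        label = assign_to_clusters(model, out)[0]
        assert label in set(model.merge_map)
        X = model._standardize(out.data)
        assert model.density().log_density(X)[0] < model.peak_log_density.min() - 10


class TestSummary:
    def test_centroids_and_fractions(self, rng):
        m, truth = blobs(rng, [[0, 0], [10, 10]], n_per=2500)
        model = flowpeaks_cluster(m, ClusterParams(seed=6))
        summary = cluster_summary(model, m)
        assert summary.fractions.sum() == pytest.approx(1.0, abs=1e-9)
        meds = summary.medians.to_numpy()
        expected = np.array([[0.0, 0.0], [10.0, 10.0]])
        # clusters relabelled by size; allow either order
        err = min(
            np.abs(meds - expected).max(), np.abs(meds[::-1] - expected).max()
        )
        assert err < 0.1

    def test_serialization_round_trip(self, rng):
        from sfcmpipe.clustering import ClusterModel

        m, _ = blobs(rng, [[0, 0], [10, 10]], n_per=300)
        model = flowpeaks_cluster(m, ClusterParams(seed=7))
        back = ClusterModel.from_dict(model.to_dict())
        np.testing.assert_array_equal(
            assign_to_clusters(back, m), assign_to_clusters(model, m)
        )
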