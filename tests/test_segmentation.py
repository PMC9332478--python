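"""PCA correctness and k-means segmentation behavior."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA as SkPCA
from sklearn.metrics import adjusted_rand_score

from aromadrivers.consumer_panel import filter_completers
from aromadrivers.oav_profile import compute_oav
from aromadrivers.segmentation import (
    adjusted_rand_index,
    cluster_profiles,
    pca,
    segment_consumers,
)
from aromadrivers.synthetic_data import PanelSpec, gen_liking_panel


def random_frame(rng, n=12, m=6):
    return pd.DataFrame(
        rng.normal(size=(n, m)),
        index=[f"r{i}" for i in range(n)],
        columns=[f"c{j}" for j in range(m)],
    )


class TestPCA:
    def test_rank_one_data_explains_everything_on_pc1(self):
        u = np.arange(1.0, 7.0)
        v = np.array([2.0, -1.0, 0.5])
        frame = pd.DataFrame(np.outer(u, v))
        res = pca(frame, scale=False)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)
        assert np.all(res.explained_variance_ratio[1:] < 1e-12)

    def test_ratios_match_covariance_eigenvalues(self):
        rng = np.random.default_rng(0)
        frame = random_frame(rng)
        res = pca(frame, scale=False)
        # independent oracle: eigenvalues of the sample covariance matrix
        eig = np.linalg.eigvalsh(np.cov(frame.to_numpy().T))[::-1]
        assert np.allclose(res.explained_variance_ratio, eig / eig.sum(), atol=1e-12)

    def test_matches_sklearn_up_to_sign(self):
        rng = np.random.default_rng(1)
        frame = random_frame(rng)
        res = pca(frame, scale=False)
        sk = SkPCA().fit(frame.to_numpy())
        assert np.allclose(
            np.abs(res.loadings.to_numpy().T), np.abs(sk.components_), atol=1e-10
        )
        assert np.allclose(
            res.explained_variance_ratio, sk.explained_variance_ratio_, atol=1e-12
        )

    def test_full_reconstruction(self):
        rng = np.random.default_rng(2)
        frame = random_frame(rng)
        res = pca(frame, scale=True)
        centered = (frame - frame.mean()) / frame.std(ddof=1)
        assert np.allclose(
            res.reconstruct().to_numpy(), centered.to_numpy(), atol=1e-10
        )

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(3)
        frame = random_frame(rng)
        res = pca(frame)
        for col in res.loadings.columns:
            v = res.loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_zero_variance_column_named_in_error(self):
        frame = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            pca(frame, scale=True)

    def test_oav_fixture_separates_samples_like_reported_quadrants(
        self, bundle, oav_implied
    ):
        # B3/B5 (acid-rich) fall on the opposite side of the first component
        # from B2/B6 in the reported score plot
        oav = oav_implied.oav.fillna(0.0)
        oav = oav.loc[:, (oav != 0).any()]
        scores = pca(oav, scale=False).scores["PC1"]
        assert np.sign(scores["B3"]) == np.sign(scores["B5"])
        assert np.sign(scores["B2"]) == np.sign(scores["B6"])
        assert np.sign(scores["B3"]) != np.sign(scores["B2"])


class TestSegmentation:
    def test_three_distant_points_become_singletons(self):
        liking = pd.DataFrame(
            [[1.0, 1.0], [4.0, 4.0], [7.0, 7.0]],
            index=["a", "b", "c"], columns=["B1", "B2"],
        )
        res = segment_consumers(liking, k=3, n_init=10, seed=0)
        assert res.inertia == pytest.approx(0.0)
        assert sorted(res.sizes()) == [1, 1, 1]

    def test_identical_seed_identical_result(self, toy_liking):
        a = segment_consumers(toy_liking, k=3, seed=42)
        b = segment_consumers(toy_liking, k=3, seed=42)
        pd.testing.assert_series_equal(a.labels, b.labels)
        assert a.inertia == b.inertia

    def test_inertia_never_increases_within_a_lloyd_run(self):
        rng = np.random.default_rng(8)
        liking = pd.DataFrame(
            np.clip(rng.normal(4, 1.5, size=(40, 6)), 1, 7),
            index=[f"C{i}" for i in range(40)],
            columns=[f"B{j + 1}" for j in range(6)],
        )
        res = segment_consumers(liking, k=3, n_init=5, seed=1)
        history = res.inertia_history[0]
        assert np.all(np.diff(history) <= 1e-9)

    def test_matches_sklearn_inertia_on_fixture(self, toy_liking):
        ours = segment_consumers(toy_liking, k=3, n_init=20, seed=0)
        sk = KMeans(n_clusters=3, n_init=20, random_state=0).fit(
            toy_liking.to_numpy()
        )
        assert ours.inertia == pytest.approx(sk.inertia_, rel=1e-9)
        assert adjusted_rand_score(ours.labels, sk.labels_) == pytest.approx(1.0)

    def test_best_inertia_non_increasing_in_k(self, toy_liking):
        inertias = [
            segment_consumers(toy_liking, k=k, n_init=20, seed=0).inertia
            for k in (1, 2, 3)
        ]
        assert inertias[0] >= inertias[1] >= inertias[2]

    def test_planted_archetypes_recovered(self):
        aris = []
        for seed in range(5):
            panel, truth = gen_liking_panel(PanelSpec(seed=seed))
            completers = filter_completers(panel)
            res = segment_consumers(completers.liking, seed=seed)
            aris.append(
                adjusted_rand_index(
                    res.labels, truth.loc[completers.liking.index]
                )
            )
        assert np.median(aris) >= 0.9

    def test_labels_canonical_by_size_then_first_index(self, toy_liking):
        # equal sizes: ties broken by first consumer position, so the first
        # consumer always lands in cluster 1
        res = segment_consumers(toy_liking, k=3, seed=7)
        assert res.labels.iloc[0] == 1

    def test_k_larger_than_panel_rejected(self, toy_liking):
        with pytest.raises(ValueError, match="exceeds"):
            segment_consumers(toy_liking.head(2), k=3)


class TestAdjustedRandIndex:
    def test_identical_partitions_score_one(self):
        assert adjusted_rand_index([1, 1, 2, 2], [5, 5, 9, 9]) == 1.0

    def test_matches_sklearn_on_random_labelings(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = rng.integers(0, 4, 30)
            b = rng.integers(0, 3, 30)
            assert adjusted_rand_index(a, b) == pytest.approx(
                adjusted_rand_score(a, b), abs=1e-12
            )


class TestClusterProfiles:
    def test_single_cluster_profile_equals_liking_summary(self):
        panel, _ = gen_liking_panel(PanelSpec(seed=3))
        completers = filter_completers(panel)
        res = segment_consumers(completers.liking, k=1, n_init=1, seed=0)
        prof = cluster_profiles(completers, res)
        assert prof.sizes.sum() == completers.n_consumers
        assert np.allclose(
            prof.liking_means.loc[1], completers.liking.mean(axis=0)
        )

    def test_planted_archetype_top_products_recovered(self):
        spec = PanelSpec(seed=6)
        panel, truth = gen_liking_panel(spec)
        completers = filter_completers(panel)
        res = segment_consumers(completers.liking, seed=6)
        prof = cluster_profiles(completers, res)
        # each cluster's empirical mean-liking row must correlate best with
        # the archetype of its majority truth label
        for cl in prof.liking_means.index:
            members = res.labels.index[res.labels == cl]
            majority = truth.loc[members].mode().iloc[0]
            empirical = prof.liking_means.loc[cl].to_numpy()
            corrs = [
                np.corrcoef(empirical, arch)[0, 1] for arch in spec.archetypes
            ]
            assert int(np.argmax(corrs)) + 1 == majority

    def test_sizes_conserve_completer_count(self):
        panel, _ = gen_liking_panel(PanelSpec(seed=10))
        completers = filter_completers(panel)
        res = segment_consumers(completers.liking, seed=10)
        assert res.sizes().sum() == completers.n_consumers
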