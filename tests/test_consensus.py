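import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from d3ns.autoencoder import EncodedMatrix
from d3ns.consensus import (
    ConsensusConfig,
    ConsensusMatrix,
    SubtypeAssignment,
    consensus_cdf,
    consensus_cluster,
    consensus_diagnostics,
    kmeans,
    render_heatmap,
)


def planted_em(n_per_group=20, d=6, sep=3.0, seed=0):
    """Three well-separated Gaussian clouds in latent space.

    Group centers are sign patterns spread over every dimension, so any 80%
    feature subsample preserves all pairwise separations.
    """
    rng = np.random.default_rng(seed)
    patterns = np.array(
        [[1, 1, 1, 1, 1, 1], [1, 1, 1, -1, -1, -1], [1, -1, -1, 1, 1, -1]], dtype=float
    )
    centers = sep * patterns[:, :d]
    X = np.vstack(
        [rng.normal(centers[g], 1.0, (n_per_group, d)) for g in range(3)]
    )
    truth = np.repeat([1, 2, 3], n_per_group)
    patients = [f"p{i:03d}" for i in range(3 * n_per_group)]
    return EncodedMatrix(patients, [f"z{j}" for j in range(d)], X), truth


class TestKmeans:
    def test_separable_clouds_recovered(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.5, (15, 2)), rng.normal(10, 0.5, (15, 2))])
        labels = kmeans(X, 2, seed=0)
        truth = np.repeat([0, 1], 15)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_single_cluster_wcss_is_total_scatter(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 3))
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=1, n_init=1, random_state=0).fit(X)
        total = ((X - X.mean(axis=0)) ** 2).sum()
        assert km.inertia_ == pytest.approx(total)

    def test_wcss_beats_random_assignments(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 4))
        labels = kmeans(X, 3, restarts=10, seed=0)

        def wcss(lab):
            return sum(
                ((X[lab == c] - X[lab == c].mean(axis=0)) ** 2).sum()
                for c in np.unique(lab)
            )

        best = wcss(labels)
        for _ in range(100):
            assert best <= wcss(rng.integers(0, 3, size=30)) + 1e-9

    def test_k_above_items_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            kmeans(np.zeros((3, 2)), 4)


class TestConsensusCluster:
    def test_planted_groups_give_block_consensus(self):
        em, truth = planted_em()
        cfg = ConsensusConfig(k_min=3, k_max=3, repetitions=200, seed=0)
        cm, assignment = consensus_cluster(em, cfg)[3]
        same = truth[:, None] == truth[None, :]
        iu = np.triu_indices(len(truth), k=1)
        assert cm.values[iu][same[iu]].mean() >= 0.9
        assert cm.values[iu][~same[iu]].mean() <= 0.1
        assert adjusted_rand_score(truth, assignment.label_array(cm.patients)) >= 0.9

    def test_degenerate_consensus_is_binary_and_matches_single_kmeans(self):
        em, _ = planted_em(n_per_group=10)
        cfg = ConsensusConfig(
            k_min=3, k_max=3, repetitions=1, patient_fraction=1.0, feature_fraction=1.0,
            seed=4,
        )
        cm, assignment = consensus_cluster(em, cfg)[3]
        assert set(np.unique(cm.values)) <= {0.0, 1.0}
        from d3ns.consensus import _scale_features

        direct = kmeans(_scale_features(em.values, "zscore"), 3,
                        restarts=cfg.kmeans_restarts, seed=cfg.seed)
        assert adjusted_rand_score(direct, assignment.label_array(cm.patients)) == 1.0

    def test_symmetry_and_unit_diagonal(self):
        em, _ = planted_em(n_per_group=8)
        cfg = ConsensusConfig(k_min=2, k_max=3, repetitions=25, seed=1)
        for cm, _a in consensus_cluster(em, cfg).values():
            np.testing.assert_array_equal(cm.values, cm.values.T)
            np.testing.assert_allclose(np.diag(cm.values), 1.0)
            assert cm.values.min() >= 0 and cm.values.max() <= 1

    def test_bit_reproducible_under_seed(self):
        em, _ = planted_em(n_per_group=8)
        cfg = ConsensusConfig(k_min=2, k_max=3, repetitions=20, seed=9)
        r1 = consensus_cluster(em, cfg)
        r2 = consensus_cluster(em, cfg)
        for k in r1:
            np.testing.assert_array_equal(r1[k][0].values, r2[k][0].values)
            assert r1[k][1].labels == r2[k][1].labels

    def test_permuting_patients_permutes_consensus(self):
        # checked in the exhaustive-sampling regime where resampling noise is off
        em, _ = planted_em(n_per_group=8)
        cfg = ConsensusConfig(
            k_min=3, k_max=3, repetitions=1, patient_fraction=1.0, feature_fraction=1.0,
            seed=0,
        )
        cm, _ = consensus_cluster(em, cfg)[3]
        perm = np.random.default_rng(5).permutation(len(em.patients))
        em_p = EncodedMatrix(
            [em.patients[i] for i in perm], em.features, em.values[perm]
        )
        cm_p, _ = consensus_cluster(em_p, cfg)[3]
        np.testing.assert_array_equal(cm_p.values, cm.values[np.ix_(perm, perm)])

    def test_too_few_patients_rejected(self):
        em, _ = planted_em(n_per_group=1)
        with pytest.raises(Exception, match="k_max"):
            consensus_cluster(em, ConsensusConfig(k_min=2, k_max=6, repetitions=1))


class TestDiagnostics:
    def block_cm(self, value_between=0.0):
        vals = np.full((10, 10), value_between)
        vals[:5, :5] = 1.0
        vals[5:, 5:] = 1.0
        patients = [f"p{i}" for i in range(10)]
        cm = ConsensusMatrix(patients=patients, values=vals, k=2)
        labels = {p: 1 if i < 5 else 2 for i, p in enumerate(patients)}
        return cm, SubtypeAssignment(k=2, labels=labels, sizes={1: 5, 2: 5})

    def test_perfect_blocks_pac_zero(self):
        cm, a = self.block_cm()
        diag = consensus_diagnostics({2: (cm, a)})
        assert diag.loc[0, "pac"] == 0.0

    def test_all_ambiguous_pac_one(self):
        vals = np.full((6, 6), 0.5)
        np.fill_diagonal(vals, 1.0)
        patients = [f"p{i}" for i in range(6)]
        cm = ConsensusMatrix(patients=patients, values=vals, k=2)
        a = SubtypeAssignment(k=2, labels={p: 1 for p in patients}, sizes={1: 6})
        assert consensus_diagnostics({2: (cm, a)}).loc[0, "pac"] == 1.0

    def test_pac_minimized_at_true_k(self):
        em, _ = planted_em()
        cfg = ConsensusConfig(k_min=2, k_max=6, repetitions=100, seed=2)
        diag = consensus_diagnostics(consensus_cluster(em, cfg))
        best_k = int(diag.loc[diag["pac"].idxmin(), "k"])
        assert best_k == 3

    def test_cdf_monotone(self):
        cm, _ = self.block_cm(0.3)
        cdf = consensus_cdf(cm)
        assert (np.diff(cdf["cdf"]) >= 0).all()


class TestHeatmap:
    def test_block_structure_visible_in_pixels(self, tmp_path):
        from PIL import Image

        cm, a = TestDiagnostics().block_cm()
        path = render_heatmap(cm, a, tmp_path / "cm.png")
        img = np.asarray(Image.open(path).convert("L"), dtype=float)
        h, w = img.shape
        q_h, q_w = h // 3, w // 3
        within = img[q_h : 2 * q_h, q_h : 2 * q_h].mean()  # central block region
        corner = img[q_h : 2 * q_h, -q_w:].mean()  # off-diagonal region
        assert within < corner  # blue block is darker than white background

    def test_single_patient_no_crash(self, tmp_path):
        cm = ConsensusMatrix(patients=["p0"], values=np.ones((1, 1)), k=2)
        a = SubtypeAssignment(k=2, labels={"p0": 1}, sizes={1: 1})
        assert render_heatmap(cm, a, tmp_path / "one.png").exists()

    def test_deterministic_bytes(self, tmp_path):
        cm, a = TestDiagnostics().block_cm(0.2)
        p1 = render_heatmap(cm, a, tmp_path / "a.png")
        p2 = render_heatmap(cm, a, tmp_path / "b.png")
        assert p1.read_bytes() == p2.read_bytes()
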