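import numpy as np
import pytest

from hopes.affinity import layer_affinity
from hopes.clustering import spectral_cluster
from hopes.evaluation import nmi
from hopes.datatypes import OmicsLayer
from hopes.simulate import (
    LayerSpec,
    SimulationConfig,
    _effective_map,
    noise_sweep,
    simulate_multiomics,
    svd_seed_layers,
)


def small_config(**overrides):
    base = dict(
        n_samples=80,
        n_clusters=4,
        layer_specs=[
            LayerSpec(n_features=60, merge=[(0, 1)], name="a"),
            LayerSpec(n_features=60, merge=[(1, 2)], name="b"),
            LayerSpec(n_features=40, merge=[(2, 3)], name="c"),
        ],
        noise_sd=1.0,
        seed=0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestEffectiveMap:
    def test_merge_pairs(self):
        np.testing.assert_array_equal(_effective_map(4, [(2, 3)]), [0, 1, 2, 2])
        np.testing.assert_array_equal(_effective_map(4, [(0, 1), (2, 3)]), [0, 0, 1, 1])

    def test_chained_groups_collapse(self):
        np.testing.assert_array_equal(_effective_map(4, [(0, 1), (1, 2)]), [0, 0, 0, 1])

    def test_no_merge_identity(self):
        np.testing.assert_array_equal(_effective_map(3, []), [0, 1, 2])


class TestSimulateMultiomics:
    def test_label_proportions(self):
        sim = simulate_multiomics(small_config())
        counts = np.bincount(sim.true_labels.labels, minlength=4)
        assert counts.tolist() == [20, 20, 20, 20]

    def test_uneven_proportions_within_rounding(self):
        cfg = small_config(cluster_proportions=[0.4, 0.3, 0.2, 0.1])
        sim = simulate_multiomics(cfg)
        counts = np.bincount(sim.true_labels.labels, minlength=4)
        assert counts.sum() == 80
        np.testing.assert_allclose(counts, [32, 24, 16, 8], atol=1)

    def test_layer_shapes_and_names(self):
        sim = simulate_multiomics(small_config())
        assert [l.name for l in sim.dataset] == ["a", "b", "c"]
        assert [l.n_features for l in sim.dataset] == [60, 60, 40]

    def test_bit_identical_under_same_seed(self):
        a = simulate_multiomics(small_config(seed=5))
        b = simulate_multiomics(small_config(seed=5))
        for la, lb in zip(a.dataset, b.dataset):
            np.testing.assert_array_equal(la.values, lb.values)
        np.testing.assert_array_equal(a.true_labels.labels, b.true_labels.labels)

    def test_zero_noise_no_merge_single_layer_recovers_truth(self):
        cfg = small_config(
            noise_sd=0.0,
            layer_specs=[LayerSpec(n_features=50, merge=[], name="full")],
        )
        sim = simulate_multiomics(cfg)
        # identical points within clusters: kernel degenerates benignly
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            P, _, _ = layer_affinity(sim.dataset[0], K=8)
            pred = spectral_cluster(P, 4, seed=0)
        assert nmi(pred.labels, sim.true_labels.labels) == pytest.approx(1.0)

    @pytest.mark.filterwarnings("ignore:true clusters")
    def test_merged_layer_nmi_bound(self):
        # a layer merging clusters {2,3} cannot beat the analytic NMI of
        # the merged partition; checked over 20 noise realisations
        cfg = SimulationConfig(
            n_samples=200,
            n_clusters=4,
            layer_specs=[LayerSpec(n_features=100, merge=[(2, 3)], name="m")],
            noise_sd=1.0,
            seed=0,
        )
        truth = simulate_multiomics(cfg).true_labels.labels
        merged = np.where(truth == 3, 2, truth)
        bound = nmi(truth, merged)
        # entropy oracle for 4 equal clusters of 50 with one pair merged
        h4 = np.log(4)
        h3 = -(0.25 * np.log(0.25) * 2 + 0.5 * np.log(0.5))
        assert bound == pytest.approx(h3 / ((h4 + h3) / 2), abs=1e-12)
        for trial in range(20):
            sim = simulate_multiomics(
                SimulationConfig(
                    n_samples=200,
                    n_clusters=4,
                    layer_specs=[LayerSpec(n_features=100, merge=[(2, 3)], name="m")],
                    noise_sd=1.0,
                    seed=trial,
                )
            )
            P, _, _ = layer_affinity(sim.dataset[0], K=20)
            pred = spectral_cluster(P, 4, seed=trial)
            assert nmi(pred.labels, sim.true_labels.labels) <= bound + 1e-9

    def test_invalid_merge_rejected(self):
        with pytest.raises(ValueError, match="unknown cluster"):
            small_config(
                layer_specs=[LayerSpec(n_features=10, merge=[(0, 7)], name="bad")]
            )

    def test_inseparable_pair_warns(self):
        with pytest.warns(UserWarning, match="merged in every layer"):
            small_config(
                layer_specs=[
                    LayerSpec(n_features=10, merge=[(0, 1)], name="x"),
                    LayerSpec(n_features=10, merge=[(0, 1)], name="y"),
                ]
            )

    def test_fuzzy_fraction_moves_samples_between_means(self):
        clear = simulate_multiomics(small_config(noise_sd=0.0))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fuzzy = simulate_multiomics(
                small_config(noise_sd=0.0, fuzzy_fraction=0.25, fuzzy_mix=0.4)
            )
        # a fuzzy sample's shift may be invisible in a layer that merges its
        # cluster with the partner's, but shows in at least one other layer
        diff = sum(
            np.abs(lc.values - lf.values).sum(axis=1)
            for lc, lf in zip(clear.dataset, fuzzy.dataset)
        )
        assert (diff > 1e-9).sum() == int(0.25 * 80)


@pytest.mark.filterwarnings("ignore:true clusters")
class TestSvdSeeding:
    def _real_layer(self, rng, p=30, r=6):
        # synthetic stand-in for a real omics matrix: low-rank + noise
        U = rng.normal(size=(50, r)) * np.sqrt(np.arange(r, 0, -1))
        V = rng.normal(size=(p, r))
        X = U @ V.T + 0.05 * rng.normal(size=(50, p))
        return OmicsLayer(X, [f"r{i}" for i in range(50)], [f"g{j}" for j in range(p)], "real")

    def test_feature_count_from_seeding_matrix(self, rng):
        real = self._real_layer(rng)
        cfg = small_config(
            layer_specs=[LayerSpec(n_features=30, merge=[(0, 1)], name="a", n_components=4)]
        )
        sim = svd_seed_layers([real], cfg)
        assert sim.dataset[0].n_features == 30
        assert sim.dataset[0].feature_ids == real.feature_ids

    def test_identity_loadings_reduce_to_plain_generator(self):
        # a "real" matrix whose right-singular vectors are the standard
        # basis at (near-)unit scale reproduces the plain generator column
        # for column (up to the SVD's arbitrary column signs)
        p = 25
        cfg = SimulationConfig(
            n_samples=40,
            n_clusters=4,
            layer_specs=[
                LayerSpec(n_features=p, merge=[(0, 1)], name="a", n_components=p)
            ],
            noise_sd=0.0,
            seed=9,
        )
        n_real = 60
        s = np.sqrt(n_real / 2) * (1 + 1e-3 * np.arange(p, 0, -1))
        ident = OmicsLayer(
            np.vstack([np.diag(s), -np.diag(s), np.zeros((n_real - 2 * p, p))]),
            [f"r{i}" for i in range(n_real)],
            [f"g{j}" for j in range(p)],
            "ident",
        )
        plain = simulate_multiomics(cfg)
        seeded = svd_seed_layers([ident], cfg)
        A, B = plain.dataset[0].values, seeded.dataset[0].values
        assert A.shape == B.shape
        for j in range(p):
            if A[:, j].std() == 0:
                np.testing.assert_allclose(B[:, j], A[:, j], atol=1e-6)
            else:
                c = np.corrcoef(A[:, j], B[:, j])[0, 1]
                assert abs(c) > 0.999
                np.testing.assert_allclose(
                    np.abs(B[:, j]), np.abs(A[:, j]) * (1 + 1e-3 * (p - j)), rtol=1e-9
                )

    def test_column_space_preserved_at_zero_noise(self, rng):
        real = self._real_layer(rng, p=40, r=5)
        cfg = SimulationConfig(
            n_samples=60,
            n_clusters=4,
            layer_specs=[LayerSpec(n_features=40, merge=[], name="a", n_components=3)],
            noise_sd=0.0,
            seed=2,
        )
        sim = svd_seed_layers([real], cfg)
        _, _, Vt_real = np.linalg.svd(real.values - real.values.mean(0), full_matrices=False)
        _, _, Vt_gen = np.linalg.svd(sim.dataset[0].values, full_matrices=False)
        # every generated top direction lies in the seeding top-3 subspace
        proj = Vt_real[:3] @ Vt_gen[:3].T
        sv = np.linalg.svd(proj, compute_uv=False)
        assert sv.min() > 0.9

    def test_rank_deficient_rejected(self, rng):
        flat = OmicsLayer(
            np.ones((20, 10)), [f"r{i}" for i in range(20)], [f"g{j}" for j in range(10)], "flat"
        )
        cfg = small_config(
            layer_specs=[LayerSpec(n_features=10, merge=[], name="a", n_components=4)]
        )
        with pytest.raises(ValueError, match="rank"):
            svd_seed_layers([flat], cfg)


@pytest.fixture(scope="module")
def sweep_table():
    cfg = small_config(seed=1)
    return noise_sweep(cfg, sigmas=[1.0, 2.0, 3.0], trials=4, methods=("snf", "single"))


class TestNoiseSweep:
    def test_table_shape(self, sweep_table):
        # 3 sigmas x 4 trials x (1 snf + 3 single layers)
        assert len(sweep_table) == 3 * 4 * 4
        assert set(sweep_table.columns) == {"method", "sigma", "trial", "nmi"}

    def test_median_nmi_nonincreasing_in_sigma(self, sweep_table):
        for method, sub in sweep_table.groupby("method"):
            med = sub.groupby("sigma").nmi.median()
            assert (np.diff(med.values) <= 1e-9).all(), method

    def test_deterministic_under_seed(self):
        cfg = small_config(seed=3)
        t1 = noise_sweep(cfg, sigmas=[1.0], trials=2, methods=("single",))
        t2 = noise_sweep(cfg, sigmas=[1.0], trials=2, methods=("single",))
        assert t1.equals(t2)
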