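"""Ring SOM: topology, online updates, assignment, grid selection, naming."""

import numpy as np
import pytest

from metabotyper.som import (MetabotypeLabeling, SOMConfig, SOMModel, assign,
                             name_clusters, ring_distance, select_grid,
                             train_som)


class TestRingDistance:
    @pytest.mark.parametrize("i,j,m,expect", [(0, 3, 4, 1), (2, 2, 5, 0),
                                              (0, 1, 3, 1), (1, 4, 6, 3)])
    def test_known_values(self, i, j, m, expect):
        assert ring_distance(i, j, m) == expect

    def test_exhaustive_m6_against_brute_force(self):
        m = 6
        for i in range(m):
            for j in range(m):
                oracle = min((i - j) % m, (j - i) % m)
                assert ring_distance(i, j, m) == oracle

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ring_distance(0, 6, 6)


def reference_som(X, m, iterations, a0, a1, s0, s1, seed):
    """Plain-loop online SOM with the update rule written out (oracle)."""
    n, p = X.shape
    rng = np.random.default_rng(seed)
    codebook = X[rng.choice(n, size=m, replace=False)].copy()
    total = iterations * n
    t = 0
    for _ in range(iterations):
        for i in rng.permutation(n):
            frac = t / max(total - 1, 1)
            alpha = a0 + (a1 - a0) * frac
            sigma = s0 + (s1 - s0) * frac
            d2 = [sum((X[i, k] - codebook[u, k]) ** 2 for k in range(p))
                  for u in range(m)]
            bmu = int(np.argmin(d2))
            for u in range(m):
                rd = min(abs(u - bmu), m - abs(u - bmu))
                h = alpha * np.exp(-(rd ** 2) / (2 * sigma ** 2))
                for k in range(p):
                    codebook[u, k] += h * (X[i, k] - codebook[u, k])
            t += 1
    return codebook


class TestTrainSOM:
    def test_matches_plain_loop_reference(self, rng):
        X = rng.standard_normal((30, 4))
        cfg = SOMConfig(grid_length=4, iterations=3, seed=5)
        model = train_som(X, cfg)
        oracle = reference_som(X, 4, 3, cfg.alpha_start, cfg.alpha_end,
                               cfg.sigma0, cfg.sigma_end, seed=5)
        np.testing.assert_allclose(model.codebook, oracle, atol=1e-12)

    def test_fixed_point_on_repeated_distinct_points(self, rng):
        anchors = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        X = np.repeat(anchors, 60, axis=0)
        # ample iterations and a vanishing final radius so each unit relaxes
        # onto its own anchor
        model = train_som(X, SOMConfig(grid_length=3, iterations=300,
                                       sigma_end=0.05, seed=2))
        # each anchor must own exactly one codebook vector, within 1e-3
        d = np.linalg.norm(model.codebook[:, None, :] - anchors[None], axis=2)
        matched = d.min(axis=1)
        assert (matched < 1e-3).all()
        assert len(set(d.argmin(axis=1))) == 3

    def test_tiny_radius_touches_only_bmu(self, rng):
        # with sigma ~ 0 the neighborhood factor vanishes for rd >= 1, so a
        # unit never chosen as BMU must keep its initial codebook exactly
        X = np.vstack([rng.normal(0, 0.1, (40, 2)),
                       np.array([[50.0, 50.0]])])  # isolated far point
        cfg = SOMConfig(grid_length=3, iterations=5, sigma_start=1e-6,
                        sigma_end=1e-7, seed=3)
        model = train_som(X, cfg)
        init = X[np.random.default_rng(3).choice(len(X), size=3, replace=False)]
        if any((init == [50.0, 50.0]).all(axis=1)):
            far_unit = int(np.flatnonzero((init == [50.0, 50.0]).all(axis=1))[0])
            np.testing.assert_array_equal(model.codebook[far_unit], [50.0, 50.0])
        # every codebook stays where only its own basin's points can pull it
        assert (np.abs(model.codebook[:, 0]) < 0.5).sum() >= 2

    def test_same_seed_identical_codebooks(self, rng):
        X = rng.standard_normal((50, 3))
        cfg = SOMConfig(grid_length=3, iterations=10, seed=9)
        np.testing.assert_array_equal(train_som(X, cfg).codebook,
                                      train_som(X, cfg).codebook)

    def test_codebook_inside_bounding_box(self, rng):
        X = rng.uniform(-3, 7, size=(120, 5))
        model = train_som(X, SOMConfig(grid_length=4, iterations=20, seed=4))
        assert (model.codebook >= X.min(0) - 1e-12).all()
        assert (model.codebook <= X.max(0) + 1e-12).all()

    def test_nan_rejected(self):
        X = np.full((10, 2), np.nan)
        with pytest.raises(ValueError):
            train_som(X, SOMConfig(grid_length=3))

    @pytest.mark.parametrize("bad", [dict(grid_length=1), dict(iterations=0),
                                     dict(alpha_start=0.01, alpha_end=0.05),
                                     dict(sigma_end=0.0)])
    def test_invalid_config(self, bad):
        with pytest.raises(ValueError):
            SOMConfig(**bad)


class TestAssign:
    @pytest.fixture()
    def model(self):
        codebook = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 4.0]])
        return SOMModel(codebook=codebook, feature_names=["u", "v"],
                        config=SOMConfig(grid_length=3))

    def test_codebook_rows_map_to_their_units(self, model):
        np.testing.assert_array_equal(assign(model, model.codebook), [0, 1, 2])

    def test_equidistant_tie_breaks_to_lowest_unit(self, model):
        midpoint = np.array([[2.0, 0.0]])  # exactly between units 0 and 1
        assert assign(model, midpoint)[0] == 0

    def test_matches_brute_force_argmin(self, model, rng):
        X = rng.uniform(-2, 6, size=(200, 2))
        oracle = np.array([int(np.argmin([np.sum((x - c) ** 2)
                                          for c in model.codebook])) for x in X])
        np.testing.assert_array_equal(assign(model, X), oracle)

    def test_feature_name_mismatch_rejected(self, model):
        with pytest.raises(ValueError):
            assign(model, np.zeros((1, 2)), feature_names=["v", "u"])


class TestSelectGrid:
    @pytest.fixture(scope="class")
    def blobs(self):
        from sklearn.datasets import make_blobs
        X, _ = make_blobs(n_samples=240, centers=3, cluster_std=0.6,
                          random_state=0)
        return (X - X.mean(0)) / X.std(0)

    def test_three_clusters_select_three_units(self, blobs):
        model, sils = select_grid(blobs, SOMConfig(seed=1, iterations=30))
        assert model.m == 3
        assert max(sils, key=sils.get) == 3

    def test_row_permutation_invariance(self, blobs, rng):
        cfg = SOMConfig(seed=1, iterations=30)
        _, sils = select_grid(blobs, cfg)
        _, sils_perm = select_grid(blobs[rng.permutation(len(blobs))], cfg)
        assert sils == sils_perm

    def test_degenerate_single_point_errors(self):
        X = np.zeros((50, 4))
        with pytest.raises(RuntimeError):
            select_grid(X, SOMConfig(seed=1, iterations=5))


class TestNameClusters:
    def _toy(self):
        # unit 0: lipid-high, unit 1: flat, unit 2: amino-acid-high
        features = np.array(
            [[2.0, 2.0, 2.0, 0, 0, 0, 0, 0]] * 10
            + [[0.0] * 8] * 10
            + [[0, 0, 0, 0, 0.5, 2.5, 1.5, 1.5]] * 10)
        labels = np.array([0] * 10 + [1] * 10 + [2] * 10)
        names = ["glucose", "tag", "tc", "c0", "aci", "aai", "cit", "orn"]
        model = SOMModel(codebook=np.zeros((3, 8)), feature_names=names,
                         config=SOMConfig(grid_length=3))
        return model, features, labels

    def test_characterization_rule(self):
        model, features, labels = self._toy()
        labeling = name_clusters(model, features, labels)
        assert labeling.unit_names == {0: "METLI", 1: "METBA", 2: "METAA"}

    def test_invariant_to_unit_relabeling(self):
        model, features, labels = self._toy()
        base = name_clusters(model, features, labels)
        perm = np.array([2, 0, 1])           # new unit id for old unit i
        relabeled = perm[labels]
        swapped = name_clusters(model, features, relabeled)
        # the same children get the same metabotype names
        np.testing.assert_array_equal(base.names_for(labels),
                                      swapped.names_for(relabeled))

    def test_non_three_grids_get_generic_names(self, rng):
        model = SOMModel(codebook=np.zeros((4, 8)),
                         feature_names=["glucose", "tag", "tc", "c0",
                                        "aci", "aai", "cit", "orn"],
                         config=SOMConfig(grid_length=4))
        X = rng.standard_normal((40, 8))
        labeling = name_clusters(model, X, rng.integers(0, 4, 40))
        assert set(labeling.unit_names.values()) == {f"unit_{u}" for u in range(4)}
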