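"""Schoener's D, occupancy density grids and the randomization tests."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import nicheevo as ne
from nicheevo.overlap import DensityLattice, classify_overlap, schoener_d


class TestSchoenerD:
    def test_hand_oracle_four_cells(self):
        z1 = np.array([0.5, 0.5, 0.0, 0.0])
        z2 = np.array([0.0, 0.5, 0.5, 0.0])
        assert schoener_d(z1, z2) == pytest.approx(0.5)

    def test_identical_grids_give_one(self):
        z = np.array([[0.25, 0.25], [0.25, 0.25]])
        assert schoener_d(z, z) == pytest.approx(1.0)

    def test_disjoint_supports_give_zero(self):
        z1 = np.array([1.0, 0.0, 0.0])
        z2 = np.array([0.0, 0.0, 1.0])
        assert schoener_d(z1, z2) == pytest.approx(0.0)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a = rng.random(20)
        a /= a.sum()
        b = rng.random(20)
        b /= b.sum()
        assert schoener_d(a, b) == pytest.approx(schoener_d(b, a))
        assert 0.0 <= schoener_d(a, b) <= 1.0

    def test_lattice_mismatch_raises(self):
        with pytest.raises(ValueError):
            schoener_d(np.ones(4) / 4, np.ones(5) / 5)


class TestClassification:
    @pytest.mark.parametrize(
        "d,label",
        [
            (0.03, "none"),
            (0.12, "none"),
            (0.26, "low"),
            (0.2, "low"),
            (0.43, "moderate"),
            (0.6, "high"),
            (0.8, "very high"),
            (1.0, "very high"),
        ],
    )
    def test_bins(self, d, label):
        assert classify_overlap(d) == label

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            classify_overlap(1.2)
        with pytest.raises(ValueError):
            classify_overlap(-0.1)


class TestDensityGrid:
    def test_lattice_resolution(self, pooled_scores):
        occ1, _, bg = pooled_scores
        grid = ne.density_grid(occ1, bg, r=100)
        assert grid.z.shape == (100, 100)
        assert grid.r == 100

    def test_z_nonnegative_and_normalised(self, pooled_scores):
        occ1, occ2, bg = pooled_scores
        for occ in (occ1, occ2):
            grid = ne.density_grid(occ, bg, r=80)
            assert np.all(grid.z >= 0)
            assert grid.z.sum() == pytest.approx(1.0)

    def test_occurrences_matching_background_give_flat_occupancy(self):
        rng = np.random.default_rng(1)
        bg = rng.uniform(-1, 1, size=(4000, 2))
        occ = bg[rng.choice(len(bg), 500, replace=False)]
        grid = ne.density_grid(occ, bg, r=60)
        occupied = grid.z[grid.z > 0]
        # o/e cancels: z should be near-uniform over the occupied envelope
        assert occupied.max() / occupied.mean() < 4.0

    def test_tight_cluster_mode_location(self):
        rng = np.random.default_rng(2)
        bg = rng.uniform(-5, 5, size=(3000, 2))
        occ = rng.normal([2.0, -1.0], 0.2, size=(80, 2))
        grid = ne.density_grid(occ, bg, r=100)
        i, j = np.unravel_index(np.argmax(grid.z), grid.z.shape)
        assert grid.x_centers[i] == pytest.approx(2.0, abs=0.5)
        assert grid.y_centers[j] == pytest.approx(-1.0, abs=0.5)

    def test_degenerate_cloud_raises(self):
        bg = np.tile([[1.0, 2.0]], (50, 1))
        with pytest.raises(ValueError, match="degenerate"):
            ne.density_grid(np.random.default_rng(3).normal(size=(20, 2)), bg)

    def test_too_few_occurrences_raise(self, pooled_scores):
        _, _, bg = pooled_scores
        with pytest.raises(ValueError, match="at least"):
            ne.density_grid(np.zeros((3, 2)), bg)


class TestEquivalencyTest:
    def test_divergent_clades_hit_p_floor(self, pooled_scores):
        occ1, occ2, bg = pooled_scores
        lattice = DensityLattice(bg, r=100)
        res = ne.equivalency_test(occ1, occ2, lattice, n_reps=100, seed=0)
        assert np.all(res.simulated_d > res.observed_d)
        assert res.p_value == pytest.approx(2.0 / 101.0)
        assert round(res.p_value, 2) == 0.02
        assert res.rejected

    def test_null_split_not_rejected(self, pooled_scores):
        occ1, _, bg = pooled_scores
        rng = np.random.default_rng(4)
        pool = rng.normal([0.0, 0.0], 1.0, size=(160, 2))
        a, b = pool[:80], pool[80:]
        lattice = DensityLattice(bg, r=100)
        res = ne.equivalency_test(a, b, lattice, n_reps=100, seed=5)
        assert not res.rejected

    def test_seed_reproducibility(self, pooled_scores):
        occ1, occ2, bg = pooled_scores
        lattice = DensityLattice(bg, r=60)
        r1 = ne.equivalency_test(occ1, occ2, lattice, n_reps=20, seed=7)
        r2 = ne.equivalency_test(occ1, occ2, lattice, n_reps=20, seed=7)
        np.testing.assert_array_equal(r1.simulated_d, r2.simulated_d)

    def test_invalid_reps_raise(self, pooled_scores):
        occ1, occ2, bg = pooled_scores
        with pytest.raises(ValueError):
            ne.equivalency_test(occ1, occ2, DensityLattice(bg, r=40), n_reps=0)


class TestSimilarityTest:
    def test_matching_background_not_rejected(self):
        rng = np.random.default_rng(8)
        bg = rng.uniform(-3, 3, size=(2000, 2))
        occ_focal = bg[rng.choice(len(bg), 60)]
        lattice = DensityLattice(bg, r=80)
        other_occ = bg[rng.choice(len(bg), 60)]
        observed = ne.schoener_d(lattice.grid(occ_focal), lattice.grid(other_occ))
        res = ne.similarity_test(
            occ_focal, bg, n_other=60, lattice=lattice, n_reps=100, seed=9, observed_d=observed
        )
        assert not res.rejected

    def test_shared_cluster_more_similar_than_expected(self):
        rng = np.random.default_rng(10)
        bg = rng.uniform(-5, 5, size=(3000, 2))
        focal = rng.normal([1.0, 1.0], 0.3, size=(70, 2))
        other = rng.normal([1.0, 1.0], 0.3, size=(70, 2))
        lattice = DensityLattice(bg, r=80)
        observed = ne.schoener_d(lattice.grid(focal), lattice.grid(other))
        res = ne.similarity_test(
            focal, bg, n_other=70, lattice=lattice, n_reps=100, seed=11, observed_d=observed
        )
        assert res.rejected
        assert observed > res.ci[1]  # more similar than the random expectation

    def test_empty_background_raises(self, pooled_scores):
        occ1, _, bg = pooled_scores
        lattice = DensityLattice(bg, r=40)
        with pytest.raises(ValueError, match="background"):
            ne.similarity_test(
                occ1, np.empty((0, 2)), n_other=10, lattice=lattice, observed_d=0.5
            )


class TestMonotonicSeparation:
    def test_overlap_decreases_with_niche_distance(self):
        rng = np.random.default_rng(12)
        bg = rng.uniform(-8, 8, size=(4000, 2))
        lattice = DensityLattice(bg, r=80)
        separations = [0.0, 1.0, 2.0, 3.0, 4.0]
        ds = []
        for sep in separations:
            rng_sep = np.random.default_rng(99)  # fixed seed per distance
            a = rng_sep.normal([-sep / 2, 0.0], 0.6, size=(80, 2))
            b = rng_sep.normal([sep / 2, 0.0], 0.6, size=(80, 2))
            ds.append(ne.schoener_d(lattice.grid(a), lattice.grid(b)))
        rho, _ = spearmanr(separations, ds)
        assert rho < -0.8
        assert ds[0] > 0.6 and ds[-1] < 0.2
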