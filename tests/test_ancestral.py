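"""PNO profiles and Brownian-motion ancestral tolerance reconstruction."""

import subprocess

import numpy as np
import pytest

import nicheevo as ne
from nicheevo.ancestral import central_density_interval
from nicheevo.trees import TreeNode


def star_tree(labels, age=1.0):
    root = TreeNode(age=age)
    for lab in labels:
        root.add_child(TreeNode(age=0.0, label=lab))
    return ne.UltrametricTree(root)


def three_tip_tree():
    """((A:1,B:1):1,C:2): the hand-oracle root is (2a + 2b + 3c)/7."""
    root = TreeNode(age=2.0)
    ab = root.add_child(TreeNode(age=1.0))
    ab.add_child(TreeNode(age=0.0, label="A"))
    ab.add_child(TreeNode(age=0.0, label="B"))
    root.add_child(TreeNode(age=0.0, label="C"))
    return ne.UltrametricTree(root)


def two_tip_tree():
    root = TreeNode(age=1.5)
    root.add_child(TreeNode(age=0.0, label="A"))
    root.add_child(TreeNode(age=0.0, label="B"))
    return ne.UltrametricTree(root)


class TestPNOProfile:
    def test_hand_normalisation_two_bins(self):
        suitability = np.array([[0.1, 0.1, 0.4, 0.4]])
        pc = np.array([[0.1, 0.2, 0.8, 0.9]])
        prof = ne.pno_profile(suitability, pc, n_bins=2, value_range=(0.0, 1.0))
        np.testing.assert_allclose(prof.mass, [0.2, 0.8])

    def test_point_mass_single_bin(self):
        suitability = np.array([[0.0, 1.0, 0.0]])
        pc = np.array([[0.0, 0.5, 1.0]])
        prof = ne.pno_profile(suitability, pc, n_bins=10, value_range=(0.0, 1.0))
        assert prof.mass[5] == pytest.approx(1.0)
        assert prof.mass.sum() == pytest.approx(1.0)

    def test_uniform_suitability_approximately_uniform(self):
        pc = np.linspace(0, 1, 1000).reshape(10, 100)
        prof = ne.pno_profile(np.ones_like(pc), pc, n_bins=10)
        np.testing.assert_allclose(prof.mass, 0.1, atol=0.01)

    def test_default_hundred_bins(self):
        rng = np.random.default_rng(0)
        pc = rng.normal(size=(20, 20))
        prof = ne.pno_profile(rng.random((20, 20)), pc)
        assert len(prof.bin_centers) == 100

    def test_all_zero_suitability_raises(self):
        with pytest.raises(ValueError):
            ne.pno_profile(np.zeros((3, 3)), np.ones((3, 3)))

    def test_geometry_mismatch_raises(self):
        with pytest.raises(ValueError):
            ne.pno_profile(np.ones((2, 2)), np.ones((3, 3)))


class TestSamplePNO:
    def test_single_bin_profile_constant_draws(self):
        prof = ne.PNOProfile(pc=1, clade="I", bin_centers=np.array([3.0]), mass=np.array([1.0]))
        draws = ne.sample_pno(prof, n=50, seed=1)
        assert np.all(draws == 3.0)

    def test_default_thousand_draws(self):
        prof = ne.PNOProfile(
            pc=1, clade="I", bin_centers=np.array([0.0, 1.0]), mass=np.array([0.4, 0.6])
        )
        assert len(ne.sample_pno(prof, seed=2)) == 1000

    def test_sample_mean_matches_profile_mean(self):
        rng = np.random.default_rng(3)
        mass = rng.random(20)
        mass /= mass.sum()
        prof = ne.PNOProfile(pc=1, clade="I", bin_centers=np.arange(20.0), mass=mass)
        draws = ne.sample_pno(prof, n=1000, seed=4)
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - prof.mean) < 3 * se


class TestBMAncestralGLS:
    def test_star_tree_root_is_tip_mean(self):
        tree = star_tree(["A", "B", "C", "D"])
        est = ne.bm_ancestral_gls(tree, {"A": 1.0, "B": 2.0, "C": 3.0, "D": 6.0})
        assert est["A|B|C|D"] == pytest.approx(3.0)

    def test_three_tip_hand_oracle(self):
        tree = three_tip_tree()
        est = ne.bm_ancestral_gls(tree, {"A": 0.0, "B": 0.0, "C": 7.0})
        assert est["A|B|C"] == pytest.approx(3.0)
        est2 = ne.bm_ancestral_gls(tree, {"A": 1.0, "B": 2.0, "C": 3.0})
        assert est2["A|B|C"] == pytest.approx((2 * 1 + 2 * 2 + 3 * 3) / 7)

    def test_constant_tips_give_constant_nodes(self, reference_tree):
        est = ne.bm_ancestral_gls(reference_tree, {t: 4.2 for t in reference_tree.tip_labels})
        assert all(v == pytest.approx(4.2) for v in est.values())

    def test_tip_permutation_invariance(self, reference_tree):
        values = {"I": 1.2, "II": -0.5, "III": 0.3, "IV": 2.0, "V": -1.1, "VI": 0.7}
        est1 = ne.bm_ancestral_gls(reference_tree, values)
        est2 = ne.bm_ancestral_gls(reference_tree, dict(reversed(list(values.items()))))
        assert est1 == est2

    def test_estimates_convex_in_tip_values(self, reference_tree):
        rng = np.random.default_rng(5)
        for _ in range(20):
            values = dict(zip(reference_tree.tip_labels, rng.normal(size=6) * 3))
            est = ne.bm_ancestral_gls(reference_tree, values)
            lo, hi = min(values.values()), max(values.values())
            assert all(lo - 1e-9 <= v <= hi + 1e-9 for v in est.values())

    def test_missing_tip_raises_with_name(self, reference_tree):
        with pytest.raises(ValueError, match="VI"):
            ne.bm_ancestral_gls(reference_tree, {t: 0.0 for t in ["I", "II", "III", "IV", "V"]})

    def test_matches_phytools_fastanc(self, reference_tree, tmp_path):
        """Independent oracle: R phytools::fastAnc on the same tree/values."""
        values = {"I": 1.2, "II": -0.5, "III": 0.3, "IV": 2.0, "V": -1.1, "VI": 0.7}
        ours = ne.bm_ancestral_gls(reference_tree, values)
        script = tmp_path / "fastanc.R"
        script.write_text(
            'suppressMessages(library(phytools))\n'
            f'tree <- read.tree(text="{reference_tree.to_newick()}")\n'
            "x <- c(I=1.2, II=-0.5, III=0.3, IV=2.0, V=-1.1, VI=0.7)\n"
            "a <- fastAnc(tree, x)\n"
            'cat(sprintf("%.10f", as.numeric(a)), sep="\\n")\n'
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        r_values = [float(v) for v in out.stdout.strip().splitlines()]
        # fastAnc reports nodes in preorder, matching internal_nodes order
        ours_ordered = [ours[n.label] for n in reference_tree.internal_nodes]
        np.testing.assert_allclose(ours_ordered, r_values, atol=1e-8)

    def test_bm_parameter_recovery(self, reference_tree):
        """Simulating BM from a known root and re-estimating recovers it."""
        rng = np.random.default_rng(6)
        x0, sigma2 = 1.5, 0.8
        v, labels = reference_tree.vcv()
        root_name = reference_tree.root.label
        estimates = []
        for _ in range(200):
            tips = rng.multivariate_normal(np.full(6, x0), sigma2 * v)
            est = ne.bm_ancestral_gls(reference_tree, dict(zip(labels, tips)))
            estimates.append(est[root_name])
        estimates = np.array(estimates)
        se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - x0) < 2 * se + 1e-12


class TestCentralDensityInterval:
    def test_percentile_oracle_1_to_100(self):
        lo, hi = central_density_interval(np.arange(1.0, 101.0), mass=0.8)
        assert lo == pytest.approx(10.9)
        assert hi == pytest.approx(90.1)

    def test_constant_samples_zero_width(self):
        lo, hi = central_density_interval(np.full(50, 2.5))
        assert lo == hi == 2.5

    def test_mass_near_one_approaches_range(self):
        samples = np.arange(1.0, 101.0)
        lo, hi = central_density_interval(samples, mass=1 - 1e-9)
        assert lo == pytest.approx(1.0, abs=1e-5)
        assert hi == pytest.approx(100.0, abs=1e-5)

    @pytest.mark.parametrize("mass", [0.0, 1.0, -0.2, 1.5])
    def test_invalid_mass_raises(self, mass):
        with pytest.raises(ValueError):
            central_density_interval(np.arange(20.0), mass=mass)

    def test_too_few_samples_raise(self):
        with pytest.raises(ValueError):
            central_density_interval(np.arange(5.0))


def point_mass_profile(value, pc=1, clade=""):
    return ne.PNOProfile(pc=pc, clade=clade, bin_centers=np.array([value]), mass=np.array([1.0]))


class TestAncestralNicheHistory:
    def test_point_mass_profiles_give_exact_history(self, reference_tree):
        profiles = {t: {1: point_mass_profile(2.0, clade=t)} for t in reference_tree.tip_labels}
        hist = ne.ancestral_niche_history(reference_tree, profiles, n_samples=20, seed=0)
        assert np.allclose(hist.table["mean"], 2.0)
        assert np.allclose(hist.table["lo80"], 2.0)
        assert np.allclose(hist.table["hi80"], 2.0)

    def test_two_tip_root_mean_of_point_masses(self):
        tree = two_tip_tree()
        profiles = {"A": {1: point_mass_profile(1.0)}, "B": {1: point_mass_profile(5.0)}}
        hist = ne.ancestral_niche_history(tree, profiles, n_samples=20, seed=1)
        root_row = hist.table[(hist.table["node"] == "A|B") & (hist.table["pc"] == 1)]
        assert root_row["mean"].iloc[0] == pytest.approx(3.0)

    def test_sample_cloud_sizes(self, reference_tree):
        rng = np.random.default_rng(2)
        profiles = {}
        for t in reference_tree.tip_labels:
            mass = rng.random(10)
            mass /= mass.sum()
            profiles[t] = {
                1: ne.PNOProfile(pc=1, clade=t, bin_centers=np.linspace(0, 1, 10), mass=mass)
            }
        hist = ne.ancestral_niche_history(reference_tree, profiles, n_samples=250, seed=3)
        assert hist.n_samples == 250
        for (node, pc), draws in hist.node_samples.items():
            assert len(draws) == 250

    def test_tree_cycling_over_posterior_sample(self, reference_tree):
        trees = ne.perturb_tree_posterior(reference_tree, n_trees=4, age_jitter_sd=0.05, seed=4)
        profiles = {t: {1: point_mass_profile(1.0, clade=t)} for t in reference_tree.tip_labels}
        hist = ne.ancestral_niche_history(trees, profiles, n_samples=40, seed=5)
        assert np.allclose(hist.table["mean"], 1.0)

    def test_missing_profile_raises(self, reference_tree):
        profiles = {t: {1: point_mass_profile(0.0)} for t in ["I", "II", "III", "IV", "V"]}
        with pytest.raises(ValueError, match="VI"):
            ne.ancestral_niche_history(reference_tree, profiles, n_samples=10)
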