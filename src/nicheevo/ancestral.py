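"""Predicted niche occupancy profiles and ancestral climatic tolerances.

A PNO profile converts a clade's suitability surface into a probability
distribution over one PC axis: suitability mass is binned into 100 evenly
spaced categories of the axis's observed range. Repeatedly sampling one
tolerance value per clade from its profile and reconstructing internal
node states on the calibrated tree under Brownian motion (generalized
least squares) yields, per node and axis, a cloud of ancestral tolerance
estimates summarised by its mean and 80% central density interval.

The internal-node GLS estimate is obtained by the re-rooting identity:
the BM estimate at any node equals the GLS root estimate
(1'V⁻¹1)⁻¹ 1'V⁻¹ y computed with the covariance V of tip values about
that node, which is exact under Brownian motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees import UltrametricTree


@dataclass
class PNOProfile:
    """Suitability-weighted distribution of one clade over one PC axis."""

    pc: int  # 1-based axis id
    clade: str
    bin_centers: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.bin_centers.shape != self.mass.shape:
            raise ValueError("bin_centers and mass must have equal length")
        if np.any(self.mass < 0):
            raise ValueError("negative probability mass")
        total = self.mass.sum()
        if not np.isclose(total, 1.0, atol=1e-8):
            raise ValueError(f"profile mass sums to {total}, expected 1")

    @property
    def mean(self) -> float:
        return float(np.sum(self.bin_centers * self.mass))


def pno_profile(
    suitability: np.ndarray,
    pc_grid: np.ndarray,
    n_bins: int = 100,
    pc: int = 1,
    clade: str = "",
    value_range: tuple[float, float] | None = None,
) -> PNOProfile:
    """Bin a suitability surface over a PC-score raster into a PNO profile.

    Bin edges span the observed range of the PC raster (or `value_range`),
    divided into `n_bins` evenly spaced categories; each cell contributes
    its suitability to the bin containing its PC value; masses normalise
    to 1.
    """
    suit = np.asarray(suitability, dtype=float)
    pcv = np.asarray(pc_grid, dtype=float)
    if suit.shape != pcv.shape:
        raise ValueError("suitability and PC rasters must share geometry")
    valid = np.isfinite(suit) & np.isfinite(pcv)
    s = suit[valid]
    v = pcv[valid]
    if s.size == 0 or s.sum() <= 0:
        raise ValueError("suitability is zero or masked everywhere")
    if value_range is None:
        lo, hi = float(v.min()), float(v.max())
    else:
        lo, hi = value_range
    if hi <= lo:
        hi = lo + 1.0  # degenerate single-value axis: one occupied bin
    edges = np.linspace(lo, hi, n_bins + 1)
    mass, _ = np.histogram(v, bins=edges, weights=s)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mass = mass / mass.sum()
    return PNOProfile(pc=pc, clade=clade, bin_centers=centers, mass=mass)


def sample_pno(
    profile: PNOProfile, n: int = 1000, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """n i.i.d. draws of bin centers with probability equal to bin mass."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.choice(profile.bin_centers, size=n, p=profile.mass)


def bm_ancestral_gls(
    tree: UltrametricTree, tip_values: dict[str, float]
) -> dict[str, float]:
    """GLS/Brownian-motion ancestral estimates for every internal node.

    Returns {node_name: estimate}; internal node names are the sorted tip
    labels of the clade joined by '|'. The estimate at a node is
    (1'V⁻¹1)⁻¹ 1'V⁻¹ y with V the tip covariance about that node
    (re-rooting identity).
    """
    order = tree.tip_labels
    missing = [t for t in order if t not in tip_values]
    if missing:
        raise ValueError(f"missing tip values for {missing}")
    y = np.array([float(tip_values[t]) for t in order])
    out: dict[str, float] = {}
    for node in tree.internal_nodes:
        v = tree.rerooted_vcv(node, order)
        w = np.linalg.solve(v, np.ones(len(order)))
        out[node.label] = float(w @ y / w.sum())
    return out


def central_density_interval(
    samples: np.ndarray, mass: float = 0.80
) -> tuple[float, float]:
    """Equal-tail central interval: the (1-mass)/2 and 1-(1-mass)/2
    sample percentiles (linear interpolation)."""
    if not (0.0 < mass < 1.0):
        raise ValueError("mass must be in (0, 1)")
    samples = np.asarray(samples, dtype=float)
    if samples.size < 10:
        raise ValueError("need at least 10 samples for a stable interval")
    tail = 100.0 * (1.0 - mass) / 2.0
    lo, hi = np.percentile(samples, [tail, 100.0 - tail])
    return float(lo), float(hi)


@dataclass
class AncestralProfile:
    """Per-node tolerance summaries over the sampling iterations.

    `table` columns: node, pc, kind (tip/internal), mean, lo80, hi80.
    `node_samples[(node, pc)]` keeps the raw per-iteration estimates.
    """

    table: pd.DataFrame
    node_samples: dict[tuple[str, int], np.ndarray]
    n_samples: int


def ancestral_niche_history(
    trees: UltrametricTree | list[UltrametricTree],
    profiles: dict[str, dict[int, PNOProfile]],  # clade -> pc -> profile
    n_samples: int = 1000,
    seed: int | np.random.Generator = 0,
    interval_mass: float = 0.80,
) -> AncestralProfile:
    """Monte-Carlo history of climatic tolerances on the calibrated tree.

    Per iteration and PC axis: draw one tolerance value per tip from its
    PNO profile, reconstruct every internal node by BM-GLS on one of the
    supplied trees (cycled deterministically across iterations to absorb
    topological/age uncertainty), and accumulate the estimates. Tips are
    summarised from their own profile draws.
    """
    tree_list = trees if isinstance(trees, list) else [trees]
    if not tree_list:
        raise ValueError("need at least one tree")
    tips = tree_list[0].tip_labels
    for t in tree_list[1:]:
        if sorted(t.tip_labels) != sorted(tips):
            raise ValueError("trees disagree on tip labels")
    for tip in tips:
        if tip not in profiles:
            raise ValueError(f"no PNO profiles supplied for tip {tip!r}")
    pcs = sorted(next(iter(profiles.values())).keys())
    for clade, by_pc in profiles.items():
        if sorted(by_pc.keys()) != pcs:
            raise ValueError(f"clade {clade!r} missing profiles for some PC axes")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    node_names = [n.label for n in tree_list[0].internal_nodes]
    store: dict[tuple[str, int], list[float] | np.ndarray] = {
        (name, pc): [] for name in node_names for pc in pcs
    }
    tip_draws: dict[tuple[str, int], np.ndarray] = {}
    for pc in pcs:
        for tip in tips:
            tip_draws[(tip, pc)] = sample_pno(profiles[tip][pc], n=n_samples, seed=rng)

    for i in range(n_samples):
        tree = tree_list[i % len(tree_list)]
        for pc in pcs:
            tip_values = {tip: tip_draws[(tip, pc)][i] for tip in tips}
            est = bm_ancestral_gls(tree, tip_values)
            for name, value in est.items():
                store[(name, pc)].append(value)

    rows = []
    samples_out: dict[tuple[str, int], np.ndarray] = {}
    for pc in pcs:
        for tip in tips:
            draws = tip_draws[(tip, pc)]
            lo, hi = central_density_interval(draws, interval_mass)
            rows.append(
                {"node": tip, "pc": pc, "kind": "tip", "mean": float(draws.mean()), "lo80": lo, "hi80": hi}
            )
            samples_out[(tip, pc)] = draws
        for name in node_names:
            draws = np.asarray(store[(name, pc)])
            lo, hi = central_density_interval(draws, interval_mass)
            rows.append(
                {"node": name, "pc": pc, "kind": "internal", "mean": float(draws.mean()), "lo80": lo, "hi80": hi}
            )
            samples_out[(name, pc)] = draws
    return AncestralProfile(
        table=pd.DataFrame(rows), node_samples=samples_out, n_samples=n_samples
    )
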