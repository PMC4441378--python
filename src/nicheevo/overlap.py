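"""Realized-niche overlap in a shared 2-D environmental ordination.

Occurrences and available backgrounds of two clades are projected onto the
first two components of a PCA trained on their pooled backgrounds. Kernel
density surfaces of records (o) and of the available background (e) are
evaluated on an r x r lattice spanning the pooled environmental envelope;
the occupancy-corrected density z is proportional to o/e where background
is available and zero elsewhere, normalised to unit mass. Overlap between
two clades is Schoener's D = 1 - 0.5 * sum|z1 - z2|, ranging from 0 (no
overlap) to 1 (identical niches).

Two randomization tests accompany D:

* niche equivalency — are the two sets of records interchangeable? The
  pooled records are randomly re-split (preserving sample sizes) and D is
  recomputed; the observed D is compared with the simulated 95% band.
* niche (background) similarity — is the observed overlap more or less
  than expected from the other clade's available environment? Random
  pseudo-records are drawn uniformly from the other clade's background
  cells and compared with the focal clade's records; run in both
  directions.

P-values use the add-one permutation correction, two-sided, so with 100
replicates the most extreme attainable p-value is 2/101 ~ 0.02.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DENSITY_FLOOR = 1e-12

OVERLAP_CLASSES = (
    (0.0, 0.2, "none"),
    (0.2, 0.4, "low"),
    (0.4, 0.6, "moderate"),
    (0.6, 0.8, "high"),
    (0.8, 1.0 + 1e-12, "very high"),
)


def classify_overlap(d: float) -> str:
    """Verbal overlap class for a Schoener's D value.

    Bins: [0,0.2) none/very limited, [0.2,0.4) low, [0.4,0.6) moderate,
    [0.6,0.8) high, [0.8,1] very high.
    """
    if not (0.0 <= d <= 1.0):
        raise ValueError(f"D must be in [0, 1], got {d}")
    for lo, hi, label in OVERLAP_CLASSES:
        if lo <= d < hi:
            return label
    return "very high"


def silverman_bandwidth(values: np.ndarray, d: int = 2) -> float:
    """Normal-reference (Silverman) bandwidth for one axis of a d-dim KDE."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    sigma = values.std(ddof=1)
    if sigma == 0 or n < 2:
        raise ValueError("degenerate (zero-variance) score cloud")
    return sigma * (4.0 / (d + 2.0)) ** (1.0 / (d + 4.0)) * n ** (-1.0 / (d + 4.0))


def _separable_kde(
    points: np.ndarray, x_centers: np.ndarray, y_centers: np.ndarray, bw: tuple[float, float]
) -> np.ndarray:
    """Gaussian product-kernel density on the lattice; shape (len(x), len(y))."""
    hx, hy = bw
    ax = np.exp(-0.5 * ((x_centers[:, None] - points[None, :, 0]) / hx) ** 2)
    ay = np.exp(-0.5 * ((y_centers[:, None] - points[None, :, 1]) / hy) ** 2)
    dens = ax @ ay.T
    return dens / (len(points) * 2.0 * np.pi * hx * hy)


@dataclass
class DensityGrid:
    """Occupancy-corrected density of one clade on the shared lattice."""

    x_centers: np.ndarray
    y_centers: np.ndarray
    occurrence_density: np.ndarray  # o
    background_density: np.ndarray  # e
    z: np.ndarray  # corrected occupancy, sums to 1
    r: int

    def same_lattice(self, other: "DensityGrid") -> bool:
        return (
            self.r == other.r
            and np.array_equal(self.x_centers, other.x_centers)
            and np.array_equal(self.y_centers, other.y_centers)
        )


class DensityLattice:
    """Shared environmental lattice for a pair of clades.

    Built once from the pooled background scores; exposes `grid(points)`
    to turn any set of occurrence scores into an occupancy-corrected
    DensityGrid on the same lattice (the background density is computed
    once and reused).
    """

    def __init__(
        self,
        background_scores: np.ndarray,
        r: int = 100,
        margin: float = 0.05,
        bandwidth: tuple[float, float] | None = None,
        occupancy_corrected: bool = True,
    ):
        bg = np.asarray(background_scores, dtype=float)[:, :2]
        if len(bg) < 2:
            raise ValueError("background must contain at least 2 cells")
        lo = bg.min(axis=0)
        hi = bg.max(axis=0)
        span = hi - lo
        if np.any(span == 0):
            raise ValueError("degenerate (zero-variance) background cloud")
        lo = lo - margin * span
        hi = hi + margin * span
        self.r = int(r)
        if self.r < 2:
            raise ValueError("lattice resolution r must be >= 2")
        self.x_centers = np.linspace(lo[0], hi[0], self.r)
        self.y_centers = np.linspace(lo[1], hi[1], self.r)
        self.background_scores = bg
        self.occupancy_corrected = occupancy_corrected
        self.bg_bandwidth = (
            bandwidth if bandwidth is not None else (silverman_bandwidth(bg[:, 0]), silverman_bandwidth(bg[:, 1]))
        )
        self.fixed_bandwidth = bandwidth
        self.background_density = _separable_kde(bg, self.x_centers, self.y_centers, self.bg_bandwidth)
        # environmental space actually available: lattice cells holding >= 1
        # background point; occupancy is only defined there (the smoothed
        # background density alone decays into never-observed environments,
        # where the o/e ratio would be pure noise)
        xi = np.clip(
            np.searchsorted(0.5 * (self.x_centers[1:] + self.x_centers[:-1]), bg[:, 0]),
            0, self.r - 1,
        )
        yi = np.clip(
            np.searchsorted(0.5 * (self.y_centers[1:] + self.y_centers[:-1]), bg[:, 1]),
            0, self.r - 1,
        )
        self.available = np.zeros((self.r, self.r), dtype=bool)
        self.available[xi, yi] = True

    def grid(self, occ_scores: np.ndarray, min_points: int = 5) -> DensityGrid:
        occ = np.asarray(occ_scores, dtype=float)[:, :2]
        if len(occ) < min_points:
            raise ValueError(f"need at least {min_points} occurrence points, got {len(occ)}")
        bw = self.fixed_bandwidth
        if bw is None:
            bw = (silverman_bandwidth(occ[:, 0]), silverman_bandwidth(occ[:, 1]))
        o = _separable_kde(occ, self.x_centers, self.y_centers, bw)
        e = self.background_density
        if self.occupancy_corrected:
            with np.errstate(divide="ignore", invalid="ignore"):
                z = np.where(
                    self.available & (e > DENSITY_FLOOR),
                    o / np.maximum(e, DENSITY_FLOOR),
                    0.0,
                )
        else:
            z = o.copy()
        total = z.sum()
        if total <= 0:
            raise ValueError("occupancy density is zero everywhere on the lattice")
        z = z / total
        return DensityGrid(
            x_centers=self.x_centers,
            y_centers=self.y_centers,
            occurrence_density=o,
            background_density=e,
            z=z,
            r=self.r,
        )


def density_grid(
    occ_scores: np.ndarray,
    bg_scores: np.ndarray,
    r: int = 100,
    bandwidth: tuple[float, float] | None = None,
    occupancy_corrected: bool = True,
) -> DensityGrid:
    """One-shot occupancy-corrected density grid (see DensityLattice)."""
    lattice = DensityLattice(
        bg_scores, r=r, bandwidth=bandwidth, occupancy_corrected=occupancy_corrected
    )
    return lattice.grid(occ_scores)


def schoener_d(z1: DensityGrid | np.ndarray, z2: DensityGrid | np.ndarray) -> float:
    """Schoener's D = 1 - 0.5 * sum|z1 - z2| over the shared lattice."""
    if isinstance(z1, DensityGrid) and isinstance(z2, DensityGrid):
        if not z1.same_lattice(z2):
            raise ValueError("density grids are on different lattices")
        a, b = z1.z, z2.z
    else:
        a = z1.z if isinstance(z1, DensityGrid) else np.asarray(z1, dtype=float)
        b = z2.z if isinstance(z2, DensityGrid) else np.asarray(z2, dtype=float)
        if a.shape != b.shape:
            raise ValueError("density grids are on different lattices")
    d = 1.0 - 0.5 * np.abs(a - b).sum()
    return float(np.clip(d, 0.0, 1.0))


@dataclass
class OverlapResult:
    """Observed overlap plus the randomization reference distribution."""

    observed_d: float
    test: str  # 'equivalency' or 'similarity'
    simulated_d: np.ndarray
    p_value: float
    n_reps: int
    rejected: bool  # outside the 95% band of the simulated values
    direction: str | None = None  # similarity: '1->2' or '2->1'
    ci: tuple[float, float] = field(default=(np.nan, np.nan))

    def __post_init__(self) -> None:
        if not (0.0 <= self.observed_d <= 1.0):
            raise ValueError("observed D outside [0, 1]")
        if len(self.simulated_d) != self.n_reps:
            raise ValueError("simulated values inconsistent with n_reps")


def _permutation_p(observed: float, simulated: np.ndarray) -> float:
    """Two-sided add-one permutation p-value, capped at 1."""
    n = len(simulated)
    n_le = int(np.sum(simulated <= observed))
    n_ge = int(np.sum(simulated >= observed))
    p = 2.0 * (min(n_le, n_ge) + 1) / (n + 1)
    return min(p, 1.0)


def _band(simulated: np.ndarray) -> tuple[float, float]:
    return (
        float(np.percentile(simulated, 2.5)),
        float(np.percentile(simulated, 97.5)),
    )


def equivalency_test(
    occ1_scores: np.ndarray,
    occ2_scores: np.ndarray,
    lattice: DensityLattice,
    n_reps: int = 100,
    seed: int | np.random.Generator = 0,
) -> OverlapResult:
    """Niche equivalency by pooling and re-splitting the two record sets.

    The observed D is compared with D values from `n_reps` random splits
    of the pooled records that preserve the two sample sizes; the null of
    equivalent niches is rejected when the observed D falls outside the
    95% band of the simulated values.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    occ1 = np.asarray(occ1_scores, dtype=float)[:, :2]
    occ2 = np.asarray(occ2_scores, dtype=float)[:, :2]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = schoener_d(lattice.grid(occ1), lattice.grid(occ2))
    pooled = np.vstack([occ1, occ2])
    n1 = len(occ1)
    sims = np.empty(n_reps)
    for i in range(n_reps):
        perm = rng.permutation(len(pooled))
        a, b = pooled[perm[:n1]], pooled[perm[n1:]]
        sims[i] = schoener_d(lattice.grid(a), lattice.grid(b))
    lo, hi = _band(sims)
    return OverlapResult(
        observed_d=observed,
        test="equivalency",
        simulated_d=sims,
        p_value=_permutation_p(observed, sims),
        n_reps=n_reps,
        rejected=bool(observed < lo or observed > hi),
        ci=(lo, hi),
    )


def similarity_test(
    occ_focal_scores: np.ndarray,
    other_background_scores: np.ndarray,
    n_other: int,
    lattice: DensityLattice,
    n_reps: int = 100,
    seed: int | np.random.Generator = 0,
    direction: str | None = None,
    observed_d: float | None = None,
) -> OverlapResult:
    """Niche background-similarity test in one direction.

    Simulated overlaps pair the focal clade's records with `n_other`
    pseudo-records drawn uniformly from the other clade's background
    cells. The null (overlap explained by the available environment) is
    rejected when the observed D is greater or smaller than 95% of the
    simulated values (two-sided band).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    other_bg = np.asarray(other_background_scores, dtype=float)[:, :2]
    if len(other_bg) == 0:
        raise ValueError("empty background for the other clade")
    occ = np.asarray(occ_focal_scores, dtype=float)[:, :2]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z_focal = lattice.grid(occ)
    if observed_d is None:
        raise ValueError("observed_d (the clade-vs-clade overlap) is required")
    sims = np.empty(n_reps)
    for i in range(n_reps):
        idx = rng.integers(0, len(other_bg), size=n_other)
        sims[i] = schoener_d(z_focal, lattice.grid(other_bg[idx]))
    lo, hi = _band(sims)
    return OverlapResult(
        observed_d=observed_d,
        test="similarity",
        simulated_d=sims,
        p_value=_permutation_p(observed_d, sims),
        n_reps=n_reps,
        rejected=bool(observed_d < lo or observed_d > hi),
        direction=direction,
        ci=(lo, hi),
    )


@dataclass
class PairwiseComparison:
    """Full overlap analysis of one clade pair."""

    clade1: str
    clade2: str
    d: float
    overlap_class: str
    equivalency: OverlapResult
    similarity_2_to_1: OverlapResult
    similarity_1_to_2: OverlapResult


def compare_clades(
    clade1: str,
    clade2: str,
    occ1_scores: np.ndarray,
    occ2_scores: np.ndarray,
    bg1_scores: np.ndarray,
    bg2_scores: np.ndarray,
    r: int = 100,
    n_reps: int = 100,
    seed: int | np.random.Generator = 0,
    bandwidth: tuple[float, float] | None = None,
) -> PairwiseComparison:
    """D, overlap class, equivalency and both similarity directions.

    All densities share one lattice built from the pooled backgrounds of
    the two clades.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pooled_bg = np.vstack([bg1_scores, bg2_scores])
    lattice = DensityLattice(pooled_bg, r=r, bandwidth=bandwidth)
    z1 = lattice.grid(occ1_scores)
    z2 = lattice.grid(occ2_scores)
    d = schoener_d(z1, z2)
    eq = equivalency_test(occ1_scores, occ2_scores, lattice, n_reps=n_reps, seed=rng)
    sim21 = similarity_test(
        occ1_scores,
        bg2_scores,
        n_other=len(np.atleast_2d(occ2_scores)),
        lattice=lattice,
        n_reps=n_reps,
        seed=rng,
        direction="2->1",
        observed_d=d,
    )
    sim12 = similarity_test(
        occ2_scores,
        bg1_scores,
        n_other=len(np.atleast_2d(occ1_scores)),
        lattice=lattice,
        n_reps=n_reps,
        seed=rng,
        direction="1->2",
        observed_d=d,
    )
    return PairwiseComparison(
        clade1=clade1,
        clade2=clade2,
        d=d,
        overlap_class=classify_overlap(d),
        equivalency=eq,
        similarity_2_to_1=sim21,
        similarity_1_to_2=sim12,
    )
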