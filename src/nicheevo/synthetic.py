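"""Synthetic study systems: seasonal raster stacks, clade occurrences, trees.

Emulates the three inputs the analysis pipeline consumes so every stage can
be exercised without remote-sensing downloads:

* five monthly environmental stacks (MIR, daytime/night-time land-surface
  temperature, NDVI, EVI) — 12 layers each, 60 layers total — built as a
  smooth spatial field plus a sinusoidal seasonal cycle plus spatially
  autocorrelated noise;
* clade-labelled occurrence records sampled from axis-aligned Gaussian
  suitability surfaces in environmental space, so the amount of niche
  overlap between clades is controlled analytically (identical / nested /
  disjoint scenarios);
* the six-clade reference tree with its published divergence times, and
  age-jittered pseudo-posterior samples of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .grids import GridGeometry
from .trees import TreeNode, UltrametricTree

VARIABLE_KINDS = ("MIR", "DTLST", "NTLST", "NDVI", "EVI")

# per-variable baseline level, amplitude multiplier relative to the
# seasonal_amplitude argument, and seasonal phase (month of the maximum)
_VARIABLE_PROFILES = {
    "MIR": {"level": 0.30, "amp_scale": 0.012, "phase_month": 7, "grad_scale": 0.008},
    "NTLST": {"level": 12.0, "amp_scale": 1.0, "phase_month": 7, "grad_scale": 1.0},
    "NDVI": {"level": 0.45, "amp_scale": 0.015, "phase_month": 4, "grad_scale": -0.012},
    "EVI": {"level": 0.35, "amp_scale": 0.015, "phase_month": 4, "grad_scale": -0.012},
}
_DIURNAL_RANGE = {"level": 9.0, "amp_scale": 0.4, "phase_month": 7, "grad_scale": 0.3}


@dataclass
class MonthlyStack:
    """Twelve ordered monthly layers of one environmental variable."""

    variable_kind: str
    layers: np.ndarray  # shape (12, nrows, ncols); NaN = masked
    geometry: GridGeometry

    def __post_init__(self) -> None:
        if self.variable_kind not in VARIABLE_KINDS:
            raise ValueError(f"unknown variable kind {self.variable_kind!r}")
        self.layers = np.asarray(self.layers, dtype=float)
        if self.layers.shape != (12, *self.geometry.shape):
            raise ValueError(
                f"{self.variable_kind}: expected 12 layers of shape {self.geometry.shape}, "
                f"got {self.layers.shape}"
            )
        masks = np.isnan(self.layers)
        if not (masks == masks[0]).all():
            raise ValueError(f"{self.variable_kind}: monthly layers disagree on the valid-cell mask")

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.layers[0])


@dataclass
class OccurrenceSet:
    """Clade-labelled point records (WGS84 decimal degrees)."""

    lon: np.ndarray
    lat: np.ndarray
    clade: np.ndarray  # string labels

    def __post_init__(self) -> None:
        self.lon = np.atleast_1d(np.asarray(self.lon, dtype=float))
        self.lat = np.atleast_1d(np.asarray(self.lat, dtype=float))
        self.clade = np.atleast_1d(np.asarray(self.clade, dtype=object))
        if not (len(self.lon) == len(self.lat) == len(self.clade)):
            raise ValueError("lon, lat and clade must have equal length")

    def __len__(self) -> int:
        return len(self.lon)

    @property
    def clade_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.clade:
            seen.setdefault(str(c), None)
        return list(seen)

    def subset(self, label: str) -> "OccurrenceSet":
        keep = self.clade == label
        return OccurrenceSet(self.lon[keep], self.lat[keep], self.clade[keep])

    def counts(self) -> dict[str, int]:
        return {label: int((self.clade == label).sum()) for label in self.clade_labels}

    def duplicate_cell_records(self, geometry: GridGeometry) -> np.ndarray:
        """Boolean flag per record: shares its raster cell with an earlier record."""
        row, col = geometry.index_of(self.lon, self.lat)
        seen: set[tuple[str, int, int]] = set()
        dup = np.zeros(len(self), dtype=bool)
        for i, key in enumerate(zip(self.clade, row, col)):
            if key in seen:
                dup[i] = True
            seen.add(key)
        return dup


@dataclass
class CladeNiche:
    """Truncated-Gaussian niche of one clade in environmental space.

    Suitability is exp(-0.5 * ||(env - center) / breadth||^2) within
    `truncate_sd` breadths of the center and exactly 0 beyond, so a
    clade's realized environmental range is bounded by construction
    (centers more than 2 * truncate_sd breadths apart yield disjoint
    realized niches at any seed).
    """

    center: tuple[float, ...]
    breadth: tuple[float, ...]
    n_records: int
    truncate_sd: float = 3.0

    def __post_init__(self) -> None:
        if len(self.center) != len(self.breadth):
            raise ValueError("center and breadth must have equal dimension")
        if any(b <= 0 for b in self.breadth):
            raise ValueError("niche breadths must be positive")
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        if self.truncate_sd <= 0:
            raise ValueError("truncate_sd must be positive")


@dataclass
class ScenarioSpec:
    """Controlled niche structure for a set of synthetic clades.

    `env_axes` names the environmental axes the Gaussian niches live on;
    the default two axes are mean land-surface temperature (mean of the
    day/night monthly means) and mean NDVI, the temperature and humidity
    proxies of the study system.
    """

    clades: dict[str, CladeNiche]
    env_axes: tuple[str, ...] = ("LST_mean", "NDVI_mean")
    jitter_within_cell: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.clades:
            raise ValueError("scenario needs at least one clade")


# --------------------------------------------------------------------------
# raster stacks
# --------------------------------------------------------------------------


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], sd: float) -> np.ndarray:
    """Spatially autocorrelated Gaussian field with marginal SD ~ sd."""
    if sd == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    smooth = gaussian_filter(white, sigma=2.0, mode="nearest")
    s = smooth.std()
    if s > 0:
        smooth *= sd / s
    return smooth


def generate_monthly_stacks(
    extent: tuple[float, float, float, float] = (-10.0, 5.0, 28.0, 44.0),
    resolution: float = 0.25,
    seasonal_amplitude: float = 8.0,
    spatial_gradient: float = 10.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> dict[str, MonthlyStack]:
    """Generate the five seasonal raster stacks (60 layers in total).

    Parameters
    ----------
    extent : (lon_min, lon_max, lat_min, lat_max) in degrees.
    resolution : cell size in degrees.
    seasonal_amplitude : peak-to-mean seasonal swing of night LST
        (other variables scale proportionally), in variable units.
    spatial_gradient : total south-to-north change of night LST across the
        extent; other variables scale proportionally.
    noise_sd : SD of the spatially autocorrelated noise field added to
        each variable's annual-mean surface (scaled per variable).

    Night and day LST are built jointly: day = night + a strictly positive
    diurnal-range field, so DTLST >= NTLST at every cell and month.
    """
    lon_min, lon_max, lat_min, lat_max = extent
    if not (lon_max > lon_min and lat_max > lat_min):
        raise ValueError("degenerate extent")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if seasonal_amplitude < 0 or noise_sd < 0:
        raise ValueError("seasonal_amplitude and noise_sd must be non-negative")

    ncols = max(1, int(round((lon_max - lon_min) / resolution)))
    nrows = max(1, int(round((lat_max - lat_min) / resolution)))
    geom = GridGeometry(lon_min, lat_min, resolution, nrows, ncols)
    lat = geom.lat_centers()[:, None]
    lat_frac = (lat - lat_min) / (lat_max - lat_min)  # 0 south .. 1 north
    months = np.arange(12)

    rng = np.random.default_rng(seed)
    stacks: dict[str, MonthlyStack] = {}

    def build(profile: dict, amp: float, grad: float, sd: float) -> np.ndarray:
        base = (
            profile["level"]
            - profile["grad_scale"] * grad * (lat_frac - 0.5)
            + _smooth_noise(rng, geom.shape, sd)
        )
        season = amp * profile["amp_scale"] * np.cos(
            2 * np.pi * (months - (profile["phase_month"] - 1)) / 12.0
        )
        layers = base[None, :, :] + season[:, None, None]
        if sd > 0:
            layers = layers + np.stack(
                [_smooth_noise(rng, geom.shape, sd * 0.3) for _ in months]
            )
        return layers

    for kind in ("MIR", "NTLST", "NDVI", "EVI"):
        prof = _VARIABLE_PROFILES[kind]
        # reflectance-like variables get proportionally smaller noise
        sd = noise_sd if kind == "NTLST" else noise_sd * prof["amp_scale"] * 0.3
        layers = build(prof, seasonal_amplitude, spatial_gradient, sd)
        if kind in ("MIR", "NDVI", "EVI"):
            layers = np.clip(layers, 0.0, None)
        stacks[kind] = MonthlyStack(kind, layers, geom)

    diurnal = build(_DIURNAL_RANGE, seasonal_amplitude, spatial_gradient, noise_sd * 0.2)
    diurnal = np.clip(diurnal, 0.1, None)  # keeps day strictly above night
    stacks["DTLST"] = MonthlyStack("DTLST", stacks["NTLST"].layers + diurnal, geom)
    return {k: stacks[k] for k in VARIABLE_KINDS}


# --------------------------------------------------------------------------
# occurrences
# --------------------------------------------------------------------------


def scenario_environment(stacks: dict[str, MonthlyStack], axes: tuple[str, ...]) -> np.ndarray:
    """Per-cell values of the named scenario environmental axes.

    Supported axes: '<VAR>_mean' for any stack and 'LST_mean' for the
    day/night average of land-surface temperature.
    """
    fields = []
    for axis in axes:
        if axis == "LST_mean":
            f = 0.5 * (
                stacks["DTLST"].layers.mean(axis=0) + stacks["NTLST"].layers.mean(axis=0)
            )
        elif axis.endswith("_mean") and axis[:-5] in stacks:
            f = stacks[axis[:-5]].layers.mean(axis=0)
        else:
            raise ValueError(f"unknown scenario environmental axis {axis!r}")
        fields.append(f)
    return np.stack(fields, axis=-1)  # (nrows, ncols, n_axes)


def generate_clade_occurrences(
    stacks: dict[str, MonthlyStack], scenario: ScenarioSpec
) -> OccurrenceSet:
    """Sample clade occurrence records from Gaussian suitability surfaces.

    Each clade's suitability at a cell is exp(-0.5 * sum(((env - center) /
    breadth)^2)) over the scenario's environmental axes; cells are drawn
    with probability proportional to suitability and records are placed at
    the cell center (jittered uniformly within the cell by default).
    """
    first = next(iter(stacks.values()))
    geom = first.geometry
    env = scenario_environment(stacks, scenario.env_axes)
    valid = np.isfinite(env).all(axis=-1)
    flat_env = env[valid]
    lon_mesh, lat_mesh = geom.center_mesh()
    flat_lon = lon_mesh[valid]
    flat_lat = lat_mesh[valid]

    rng = np.random.default_rng(scenario.seed)
    lons, lats, labels = [], [], []
    for label, niche in scenario.clades.items():
        if len(niche.center) != env.shape[-1]:
            raise ValueError(
                f"clade {label}: niche dimension {len(niche.center)} != "
                f"{env.shape[-1]} scenario axes"
            )
        z = (flat_env - np.asarray(niche.center)) / np.asarray(niche.breadth)
        r2 = (z**2).sum(axis=-1)
        suit = np.where(r2 <= niche.truncate_sd**2, np.exp(-0.5 * r2), 0.0)
        total = suit.sum()
        if not np.isfinite(total) or total <= 1e-300 or suit.max() <= 1e-12:
            raise ValueError(
                f"clade {label}: niche has no achievable suitability anywhere on the grid"
            )
        idx = rng.choice(len(suit), size=niche.n_records, p=suit / total)
        jitter_lon = jitter_lat = np.zeros(niche.n_records)
        if scenario.jitter_within_cell:
            jitter_lon = rng.uniform(-0.5, 0.5, niche.n_records) * geom.cell_size
            jitter_lat = rng.uniform(-0.5, 0.5, niche.n_records) * geom.cell_size
        lons.append(flat_lon[idx] + jitter_lon)
        lats.append(flat_lat[idx] + jitter_lat)
        labels.extend([label] * niche.n_records)
    return OccurrenceSet(np.concatenate(lons), np.concatenate(lats), np.array(labels, dtype=object))


# canonical per-clade record counts of the study system
REFERENCE_COUNTS = {"I": 40, "II": 47, "III": 121, "IV": 15, "V": 21, "VI": 17}


def reference_scenario(
    stacks: dict[str, MonthlyStack],
    spread: float = 1.0,
    seed: int = 0,
) -> ScenarioSpec:
    """Six clades with the study's per-clade record counts, niches spread
    across the realised environmental range of the synthetic grids."""
    env = scenario_environment(stacks, ("LST_mean", "NDVI_mean"))
    flat = env[np.isfinite(env).all(axis=-1)]
    lo = np.percentile(flat, 5, axis=0)
    hi = np.percentile(flat, 95, axis=0)
    span = hi - lo

    def center_at(q: float) -> tuple[float, float]:
        lo_q, hi_q = np.percentile(flat[:, 0], [max(q - 0.05, 0) * 100, min(q + 0.05, 1) * 100])
        band = flat[(flat[:, 0] >= lo_q) & (flat[:, 0] <= hi_q)]
        return tuple(np.median(band, axis=0))

    # six niches spread along the realized temperature gradient, with the
    # phylogenetically close pairs (I, IV) and (II, III) kept adjacent
    quantiles = {"I": 0.30, "II": 0.48, "III": 0.65, "IV": 0.35, "V": 0.88, "VI": 0.55}
    breadth = tuple(0.12 * spread * span)
    clades = {
        label: CladeNiche(center_at(q), breadth, REFERENCE_COUNTS[label])
        for label, q in quantiles.items()
    }
    return ScenarioSpec(clades=clades, seed=seed)


def two_clade_scenario(
    stacks: dict[str, MonthlyStack],
    kind: str = "identical",
    n_records: int = 120,
    seed: int = 0,
) -> ScenarioSpec:
    """Two-clade scenarios with known niche structure.

    kind='identical': both clades share one Gaussian niche.
    kind='nested': clade B's niche sits inside A's (half the breadth).
    kind='disjoint': centers separated by 8x the niche breadth.
    """
    env = scenario_environment(stacks, ("LST_mean", "NDVI_mean"))
    flat = env[np.isfinite(env).all(axis=-1)]
    lo = np.percentile(flat, 5, axis=0)
    hi = np.percentile(flat, 95, axis=0)
    span = hi - lo

    def center_at(q: float) -> np.ndarray:
        """Median environment of the cells in a +-5% quantile band of the
        first (temperature) axis — a point on the realized environmental
        manifold, so nearby cells always exist."""
        lo_q, hi_q = np.percentile(flat[:, 0], [max(q - 0.05, 0) * 100, min(q + 0.05, 1) * 100])
        band = flat[(flat[:, 0] >= lo_q) & (flat[:, 0] <= hi_q)]
        return np.median(band, axis=0)

    breadth = tuple(0.10 * span)
    mid = center_at(0.5)
    if kind == "identical":
        centers = {"A": tuple(mid), "B": tuple(mid)}
        breadths = {"A": breadth, "B": breadth}
    elif kind == "nested":
        centers = {"A": tuple(mid), "B": tuple(mid)}
        breadths = {"A": breadth, "B": tuple(0.5 * b for b in breadth)}
    elif kind == "disjoint":
        c_a, c_b = center_at(0.12), center_at(0.88)
        # scale the separation axis so the centers sit 8 breadths apart:
        # with 3-breadth truncation the realized ranges stay disjoint
        sep_breadth = abs(c_b[0] - c_a[0]) / 8.0
        b = (sep_breadth, breadth[1])
        centers = {"A": tuple(c_a), "B": tuple(c_b)}
        breadths = {"A": b, "B": b}
    else:
        raise ValueError(f"unknown scenario kind {kind!r}")
    clades = {
        label: CladeNiche(centers[label], breadths[label], n_records) for label in ("A", "B")
    }
    return ScenarioSpec(clades=clades, seed=seed)


# --------------------------------------------------------------------------
# trees
# --------------------------------------------------------------------------

REFERENCE_NODE_AGES = (5.88, 4.82, 4.32, 4.14, 2.47)


def build_reference_tree() -> UltrametricTree:
    """Six-clade calibrated tree: (VI,(V,(I,(IV,(II,III))))).

    Divergence times (Ma): root 5.88, then 4.82, 4.32, 4.14 and the
    youngest split (clades II vs III) at 2.47.
    """
    a_root, a_v, a_i, a_iv, a_iiiii = REFERENCE_NODE_AGES
    root = TreeNode(age=a_root)
    root.add_child(TreeNode(age=0.0, label="VI"))
    n1 = root.add_child(TreeNode(age=a_v))
    n1.add_child(TreeNode(age=0.0, label="V"))
    n2 = n1.add_child(TreeNode(age=a_i))
    n2.add_child(TreeNode(age=0.0, label="I"))
    n3 = n2.add_child(TreeNode(age=a_iv))
    n3.add_child(TreeNode(age=0.0, label="IV"))
    n4 = n3.add_child(TreeNode(age=a_iiiii))
    n4.add_child(TreeNode(age=0.0, label="II"))
    n4.add_child(TreeNode(age=0.0, label="III"))
    return UltrametricTree(root)


def perturb_tree_posterior(
    tree: UltrametricTree,
    n_trees: int = 1000,
    age_jitter_sd: float = 0.1,
    seed: int = 0,
    max_attempts: int = 1000,
) -> list[UltrametricTree]:
    """Pseudo-posterior sample of trees: same topology, jittered node ages.

    Each internal node age receives independent Gaussian jitter; a draw is
    rejected and resampled if it violates parent > child ordering (or a
    non-positive root age). Deterministic for a fixed seed.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    rng = np.random.default_rng(seed)
    internal = tree.internal_nodes
    out: list[UltrametricTree] = []
    for _ in range(n_trees):
        for attempt in range(max_attempts + 1):
            jitter = {id(n): rng.normal(0.0, age_jitter_sd) for n in internal}
            new_ages = {id(n): n.age + jitter[id(n)] for n in internal}
            ok = all(
                new_ages[id(n)] > (new_ages[id(c)] if not c.is_tip else 0.0)
                for n in internal
                for c in n.children
            )
            if ok:
                break
        else:
            raise RuntimeError(
                f"could not draw a valid age configuration in {max_attempts} attempts"
            )

        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(
                age=new_ages[id(node)] if not node.is_tip else 0.0, label=node.label
            )
            for c in node.children:
                new.add_child(clone(c))
            return new

        out.append(UltrametricTree(clone(tree.root)))
    return out
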