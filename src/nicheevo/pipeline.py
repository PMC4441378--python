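"""End-to-end orchestration of the niche-evolution analysis.

Stages: monthly stacks -> 30 bioclim-style predictors -> global PCA ->
per-clade envelope SDMs -> pairwise PCA-env overlap tests -> PNO profiles
-> ancestral tolerance history. Every stage logs its parameters and the
derived seed it consumed; rerunning with the same config and seed
reproduces every output byte for byte.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ancestral as anc
from . import env_space, envelope, io, overlap
from .biovars import PredictorSet, build_predictor_set
from .grids import write_ascii_grid
from .synthetic import MonthlyStack, OccurrenceSet
from .trees import UltrametricTree

log = logging.getLogger("nicheevo")

_STAGES = ("synthetic", "overlap", "pno", "ancestral")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out from the single global seed."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_STAGES.index(stage),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


@dataclass
class PipelineConfig:
    """Declarative configuration of a full run."""

    stacks_dir: str | None = None
    occurrences_csv: str | None = None
    tree_files: list[str] = field(default_factory=list)
    output_dir: str = "nicheevo_out"
    buffer_km: float = 100.0
    r: int = 100
    n_reps: int = 100
    pno_bins: int = 100
    n_samples: int = 1000
    seed: int = 0
    sdm_pca_scope: str = "extent"  # 'extent' or 'backgrounds'

    def __post_init__(self) -> None:
        for name in ("r", "n_reps", "pno_bins", "n_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.buffer_km <= 0:
            raise ValueError("buffer_km must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class PipelineResult:
    predictors: PredictorSet
    pca: env_space.PCATransform
    pc_grids: np.ndarray
    suitability: dict[str, np.ndarray]
    comparisons: list[overlap.PairwiseComparison]
    overlap_table: pd.DataFrame
    ancestral: anc.AncestralProfile | None
    dropped_records: int


def _clade_cell_scores(
    occ: OccurrenceSet, predictors: PredictorSet, pca: env_space.PCATransform
) -> tuple[np.ndarray, int]:
    """PC scores of the predictor values at each record's cell.

    Records on masked cells are dropped (count returned)."""
    geom = predictors.geometry
    row, col = geom.index_of(occ.lon, occ.lat)
    idx = [predictors.names.index(v) for v in pca.variable_names]
    values = predictors.arrays[idx][:, row, col].T
    ok = np.isfinite(values).all(axis=1)
    dropped = int((~ok).sum())
    return env_space.project(pca, values[ok]), dropped


def run_pipeline(
    config: PipelineConfig,
    stacks: dict[str, MonthlyStack] | None = None,
    occurrences: OccurrenceSet | None = None,
    trees: list[UltrametricTree] | None = None,
) -> PipelineResult:
    """Execute the full analysis; inputs may be passed in memory or read
    from the paths in `config`. Outputs land under `config.output_dir`."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        if stacks is None:
            if config.stacks_dir is None:
                raise ValueError("no stacks supplied (stacks_dir unset)")
            stacks = io.read_stacks(config.stacks_dir)
        if occurrences is None:
            if config.occurrences_csv is None:
                raise ValueError("no occurrences supplied (occurrences_csv unset)")
            occurrences = io.read_occurrences(config.occurrences_csv)
        if trees is None and config.tree_files:
            trees = [io.read_tree(p) for p in config.tree_files]
    except Exception as exc:
        raise RuntimeError(f"stage 'inputs' failed: {exc}") from exc

    geom = next(iter(stacks.values())).geometry
    log.info("pipeline seed=%d buffer_km=%s r=%d n_reps=%d pno_bins=%d n_samples=%d",
             config.seed, config.buffer_km, config.r, config.n_reps,
             config.pno_bins, config.n_samples)

    # ---- predictors ---------------------------------------------------------
    try:
        predictors = build_predictor_set(stacks)
        predictors.manifest().to_csv(out / "variables_manifest.csv", index=False)
        for name, source, bio in zip(predictors.names, predictors.sources, predictors.bio_codes):
            write_ascii_grid(out / f"predictor_{name}.asc", predictors[name], geom)
        log.info("stage biovars: 30 predictors derived")
    except Exception as exc:
        raise RuntimeError(f"stage 'biovars' failed: {exc}") from exc

    # ---- global PCA ---------------------------------------------------------
    try:
        valid = predictors.valid_mask
        if config.sdm_pca_scope == "backgrounds":
            pooled = np.zeros(geom.shape, dtype=bool)
            for clade in occurrences.clade_labels:
                pooled |= env_space.background_mask(
                    occurrences.subset(clade), geom, radius_km=config.buffer_km, valid=valid
                ).mask
            train_cells = pooled & valid
        else:
            train_cells = valid
        pca = env_space.fit_pca(
            predictors.table(train_cells), variable_names=predictors.names
        )
        pca.loadings_table().to_csv(out / "pca_loadings.csv", index=False)
        pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(len(pca.eigenvalues))],
                "eigenvalue": pca.eigenvalues,
                "variance_pct": 100.0 * pca.explained_variance_ratio,
            }
        ).to_csv(out / "pca_eigenvalues.csv", index=False)
        pc_grids = env_space.project_grid(pca, predictors)
        for k in range(pca.retained_count):
            write_ascii_grid(out / f"pc{k + 1}.asc", pc_grids[k], geom)
        log.info("stage pca: retained %d components (eigenvalue > 1)", pca.retained_count)
    except Exception as exc:
        raise RuntimeError(f"stage 'pca' failed: {exc}") from exc

    # ---- clade occurrence handling -----------------------------------------
    clades = occurrences.clade_labels
    occ_scores: dict[str, np.ndarray] = {}
    occ_by_clade: dict[str, OccurrenceSet] = {}
    dropped_total = 0
    for clade in clades:
        sub = occurrences.subset(clade)
        scores, dropped = _clade_cell_scores(sub, predictors, pca)
        dropped_total += dropped
        if dropped:
            log.warning("clade %s: dropped %d records on masked cells", clade, dropped)
        occ_scores[clade] = scores
        occ_by_clade[clade] = sub

    # ---- envelope SDMs ------------------------------------------------------
    suitability: dict[str, np.ndarray] = {}
    try:
        for clade in clades:
            model = envelope.fit_envelope(occ_scores[clade])
            surf = envelope.predict_suitability_grid(model, pc_grids)
            suitability[clade] = surf
            write_ascii_grid(out / f"suitability_{clade}.asc", surf, geom)
        log.info("stage sdm: fitted %d clade envelopes", len(clades))
    except Exception as exc:
        raise RuntimeError(f"stage 'sdm' failed: {exc}") from exc

    # ---- pairwise niche overlap --------------------------------------------
    try:
        rng = np.random.default_rng(stage_seed(config.seed, "overlap"))
        comparisons = []
        rows = []
        for c1, c2 in itertools.combinations(clades, 2):
            bg1 = env_space.background_mask(
                occ_by_clade[c1], geom, radius_km=config.buffer_km, valid=valid
            )
            bg2 = env_space.background_mask(
                occ_by_clade[c2], geom, radius_km=config.buffer_km, valid=valid
            )
            union = (bg1.mask | bg2.mask) & valid
            idx = [predictors.names.index(v) for v in pca.variable_names]
            pair_table = predictors.arrays[idx][:, union].T
            pair_pca = env_space.fit_pca(pair_table, variable_names=pca.variable_names)
            pair_pca.loadings_table().to_csv(
                out / f"pca_env_loadings_{c1}_{c2}.csv", index=False
            )

            def pair_scores(occ_set: OccurrenceSet) -> np.ndarray:
                row, col = geom.index_of(occ_set.lon, occ_set.lat)
                vals = predictors.arrays[idx][:, row, col].T
                vals = vals[np.isfinite(vals).all(axis=1)]
                return env_space.project(pair_pca, vals)

            bg1_scores = env_space.project(pair_pca, predictors.arrays[idx][:, bg1.mask & valid].T)
            bg2_scores = env_space.project(pair_pca, predictors.arrays[idx][:, bg2.mask & valid].T)
            comp = overlap.compare_clades(
                c1,
                c2,
                pair_scores(occ_by_clade[c1]),
                pair_scores(occ_by_clade[c2]),
                bg1_scores,
                bg2_scores,
                r=config.r,
                n_reps=config.n_reps,
                seed=rng,
            )
            comparisons.append(comp)
            rows.append(
                {
                    "pair": f"{c1}-{c2}",
                    "D": round(comp.d, 4),
                    "class": comp.overlap_class,
                    "equivalency_p": round(comp.equivalency.p_value, 4),
                    "similarity_p_2to1": round(comp.similarity_2_to_1.p_value, 4),
                    "similarity_p_1to2": round(comp.similarity_1_to_2.p_value, 4),
                }
            )
            log.info("overlap %s-%s: D=%.3f (%s) eq_p=%.3f",
                     c1, c2, comp.d, comp.overlap_class, comp.equivalency.p_value)
        overlap_table = pd.DataFrame(rows)
        overlap_table.to_csv(out / "overlap_table.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'overlap' failed: {exc}") from exc

    # ---- PNO + ancestral history -------------------------------------------
    ancestral_profile = None
    if trees:
        try:
            tips = trees[0].tip_labels
            missing = [t for t in tips if t not in clades]
            extra = [c for c in clades if c not in tips]
            if extra:
                log.warning("clades absent from the tree, excluded from history: %s", extra)
            if missing:
                raise ValueError(f"tree tips without occurrence data: {missing}")
            profiles: dict[str, dict[int, anc.PNOProfile]] = {}
            pno_rows = []
            for clade in tips:
                profiles[clade] = {}
                for k in range(pca.retained_count):
                    prof = anc.pno_profile(
                        suitability[clade],
                        pc_grids[k],
                        n_bins=config.pno_bins,
                        pc=k + 1,
                        clade=clade,
                    )
                    profiles[clade][k + 1] = prof
                    pno_rows.extend(
                        {"clade": clade, "pc": k + 1, "bin_center": c, "mass": m}
                        for c, m in zip(prof.bin_centers, prof.mass)
                    )
            pd.DataFrame(pno_rows).to_csv(out / "pno_profiles.csv", index=False)
            ancestral_profile = anc.ancestral_niche_history(
                trees,
                profiles,
                n_samples=config.n_samples,
                seed=np.random.default_rng(stage_seed(config.seed, "ancestral")),
            )
            ancestral_profile.table.to_csv(out / "node_tolerances.csv", index=False)
            log.info("stage ancestral: %d iterations over %d tree(s)",
                     config.n_samples, len(trees))
        except Exception as exc:
            raise RuntimeError(f"stage 'pno/ancestral' failed: {exc}") from exc

    return PipelineResult(
        predictors=predictors,
        pca=pca,
        pc_grids=pc_grids,
        suitability=suitability,
        comparisons=comparisons,
        overlap_table=overlap_table,
        ancestral=ancestral_profile,
        dropped_records=dropped_total,
    )
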