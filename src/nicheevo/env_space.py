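"""Environmental ordination: correlation PCA and background definition.

The 30 predictors mix units (surface temperature in degrees, reflectance
indices on [0, 1]), so dimensionality reduction uses the correlation
matrix: every variable is centred and scaled to unit sample variance
before the rotation. Components are retained by the Kaiser rule
(eigenvalue strictly > 1). The available background of a clade is the set
of grid cells within a great-circle buffer (default 100 km) of its
occurrence records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA

from .biovars import PredictorSet
from .grids import GridGeometry, haversine_km
from .synthetic import OccurrenceSet


@dataclass
class PCATransform:
    """Fitted correlation-matrix PCA.

    `loadings` has one row per component (all components, not only the
    retained ones); `variable_pc_corr` holds the Pearson correlation of
    each input variable with each retained component score.
    """

    variable_names: list[str]
    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray  # (n_components, n_vars), orthonormal rows
    eigenvalues: np.ndarray  # non-increasing
    retained_count: int
    variable_pc_corr: np.ndarray  # (n_vars, retained_count)

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    def loadings_table(self) -> pd.DataFrame:
        """Component loadings with variable-PC Pearson correlations in a
        parallel column, for the retained components."""
        data: dict[str, np.ndarray | list[str]] = {"variable": self.variable_names}
        for k in range(self.retained_count):
            data[f"PC{k + 1}_loading"] = self.loadings[k]
            data[f"PC{k + 1}_r"] = self.variable_pc_corr[:, k]
        return pd.DataFrame(data)


def fit_pca(
    table: np.ndarray,
    variable_names: list[str] | None = None,
    n_components: int | None = None,
) -> PCATransform:
    """Correlation-matrix PCA of a (n_cells, n_vars) predictor table.

    Variables with zero variance are dropped with a warning before the
    decomposition. When `n_components` is None, the Kaiser rule retains
    components with eigenvalue strictly greater than 1.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D (cells x variables) table")
    n, p = x.shape
    if n < 2:
        raise ValueError("need at least 2 valid cells to fit a PCA")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in the PCA training table")
    if variable_names is None:
        variable_names = [f"X{i + 1}" for i in range(p)]

    means = x.mean(axis=0)
    scales = x.std(axis=0, ddof=1)
    keep = scales > 0
    if not keep.all():
        dropped = [variable_names[i] for i in np.where(~keep)[0]]
        warnings.warn(f"dropping constant variables: {dropped}", stacklevel=2)
        x = x[:, keep]
        means, scales = means[keep], scales[keep]
        variable_names = [v for v, k in zip(variable_names, keep) if k]
        p = x.shape[1]
    if p == 0:
        raise ValueError("no non-constant variables left")

    z = (x - means) / scales
    pca = _SkPCA(n_components=min(n - 1, p), svd_solver="full")
    scores = pca.fit_transform(z)
    loadings = pca.components_
    eigenvalues = pca.explained_variance_

    # deterministic sign: the largest-|loading| entry of each component is positive
    for k in range(loadings.shape[0]):
        j = np.argmax(np.abs(loadings[k]))
        if loadings[k, j] < 0:
            loadings[k] *= -1
            scores[:, k] *= -1

    if n_components is None:
        retained = int(np.sum(eigenvalues > 1.0))
    else:
        retained = int(n_components)
    retained = max(retained, 1)
    retained = min(retained, loadings.shape[0])

    corr = np.empty((p, retained))
    for k in range(retained):
        s = scores[:, k]
        s_sd = s.std(ddof=1)
        if s_sd == 0:
            corr[:, k] = 0.0
        else:
            corr[:, k] = ((z - z.mean(axis=0)) * (s - s.mean())[:, None]).sum(axis=0) / (
                (n - 1) * s_sd
            )
    return PCATransform(
        variable_names=list(variable_names),
        means=means,
        scales=scales,
        loadings=loadings,
        eigenvalues=eigenvalues,
        retained_count=retained,
        variable_pc_corr=corr,
    )


def project(transform: PCATransform, values: np.ndarray) -> np.ndarray:
    """Project predictor vectors into the retained PC space.

    `values` is (n_vars,) or (n, n_vars) in the transform's variable
    order; returns (n, retained_count) scores.
    """
    v = np.atleast_2d(np.asarray(values, dtype=float))
    if v.shape[1] != len(transform.variable_names):
        raise ValueError(
            f"expected {len(transform.variable_names)} variables, got {v.shape[1]}"
        )
    z = (v - transform.means) / transform.scales
    return z @ transform.loadings[: transform.retained_count].T


def project_grid(transform: PCATransform, predictors: PredictorSet) -> np.ndarray:
    """Retained-PC score rasters, shape (retained, nrows, ncols); NaN where masked.

    Assumes the transform was fitted on the predictor set's variables in
    X1..X30 order (constant-dropped variables are matched by name).
    """
    idx = [predictors.names.index(v) for v in transform.variable_names]
    mask = predictors.valid_mask
    table = predictors.arrays[idx][:, mask].T
    scores = project(transform, table)
    out = np.full((transform.retained_count, *predictors.geometry.shape), np.nan)
    for k in range(transform.retained_count):
        out[k][mask] = scores[:, k]
    return out


@dataclass
class BackgroundMask:
    """Cells within the colonisable buffer of one clade's records."""

    mask: np.ndarray  # boolean grid
    radius_km: float
    geometry: GridGeometry

    def __or__(self, other: "BackgroundMask") -> "BackgroundMask":
        if other.geometry != self.geometry:
            raise ValueError("background masks on different grids")
        return BackgroundMask(self.mask | other.mask, max(self.radius_km, other.radius_km), self.geometry)


def background_mask(
    occurrences: OccurrenceSet,
    geometry: GridGeometry,
    radius_km: float = 100.0,
    valid: np.ndarray | None = None,
) -> BackgroundMask:
    """Cells whose center lies within `radius_km` of any record.

    Distance is the haversine great-circle distance on a spherical Earth.
    Cells flagged invalid in `valid` are never included. Records outside
    the grid extent raise an error listing the offending indices.
    """
    if len(occurrences) == 0:
        raise ValueError("background requires at least one record")
    inside = geometry.contains(occurrences.lon, occurrences.lat)
    if not np.all(inside):
        bad = np.argwhere(~inside).ravel().tolist()
        raise ValueError(f"records outside grid extent at indices {bad}")
    lon_mesh, lat_mesh = geometry.center_mesh()
    min_d = np.full(geometry.shape, np.inf)
    for lo, la in zip(occurrences.lon, occurrences.lat):
        d = haversine_km(lon_mesh, lat_mesh, lo, la)
        np.minimum(min_d, d, out=min_d)
    mask = min_d <= radius_km
    if valid is not None:
        mask &= valid
    return BackgroundMask(mask=mask, radius_km=radius_km, geometry=geometry)
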