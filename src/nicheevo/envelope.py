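"""Bioclim boxcar environmental envelopes on PC scores.

The envelope model stores, per retained component, the empirical
distribution of the training records and scores a query by its percentile
position: s = 1 - 2|F(x) - 0.5|, which peaks at 1 at the axis median and
declines linearly (in percentile units) to 0 at the training range limits;
anything outside the min-max box scores exactly 0. Axes are combined by
the minimum, so no variable is weighted above another and no interactions
enter — a deliberate, Grinnellian-niche reading of suitability. A classic
presence/absence box is available with `mode='binary'`.

Empirical CDF convention: F(x) = (#{v < x} + 0.5 * #{v = x}) / n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class EnvelopeModel:
    """Per-axis sorted training values; axis k = retained PC k+1."""

    training: list[np.ndarray]  # each sorted ascending

    def __post_init__(self) -> None:
        self.training = [np.sort(np.asarray(t, dtype=float)) for t in self.training]
        n = {len(t) for t in self.training}
        if len(n) != 1:
            raise ValueError("axes trained on different record counts")
        if n.pop() < 2:
            raise ValueError("envelope needs at least 2 training records")
        for k, t in enumerate(self.training):
            if t[0] == t[-1]:
                warnings.warn(
                    f"axis {k}: constant training values; predictions on this axis "
                    "degenerate to 0/1",
                    stacklevel=2,
                )

    @property
    def n_axes(self) -> int:
        return len(self.training)


def fit_envelope(training_scores: np.ndarray) -> EnvelopeModel:
    """Fit a boxcar envelope from (n_records, n_axes) PC scores."""
    scores = np.asarray(training_scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    if scores.shape[0] < 2:
        raise ValueError("envelope needs at least 2 training records")
    if not np.isfinite(scores).all():
        raise ValueError("non-finite training scores")
    return EnvelopeModel([scores[:, k] for k in range(scores.shape[1])])


def _axis_score(sorted_values: np.ndarray, x: np.ndarray) -> np.ndarray:
    n = len(sorted_values)
    less = np.searchsorted(sorted_values, x, side="left")
    leq = np.searchsorted(sorted_values, x, side="right")
    f = (less + 0.5 * (leq - less)) / n
    s = 1.0 - 2.0 * np.abs(f - 0.5)
    outside = (x < sorted_values[0]) | (x > sorted_values[-1])
    return np.where(outside, 0.0, s)


def predict_suitability(
    model: EnvelopeModel, scores: np.ndarray, mode: str = "percentile"
) -> np.ndarray:
    """Suitability in [0, 1] of query score vectors.

    `scores` is (n_axes,) or (n, n_axes). mode='percentile' gives the
    continuous percentile score (minimum across axes); mode='binary' gives
    1 inside the training min-max box and 0 outside. Non-finite queries
    yield NaN.
    """
    x = np.atleast_2d(np.asarray(scores, dtype=float))
    if x.shape[1] != model.n_axes:
        raise ValueError(f"expected {model.n_axes} axes, got {x.shape[1]}")
    finite = np.isfinite(x).all(axis=1)
    out = np.full(x.shape[0], np.nan)
    if mode == "percentile":
        per_axis = np.stack(
            [_axis_score(model.training[k], x[finite, k]) for k in range(model.n_axes)]
        )
        out[finite] = per_axis.min(axis=0)
    elif mode == "binary":
        inside = np.ones(finite.sum(), dtype=bool)
        for k in range(model.n_axes):
            t = model.training[k]
            inside &= (x[finite, k] >= t[0]) & (x[finite, k] <= t[-1])
        out[finite] = inside.astype(float)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def predict_suitability_grid(
    model: EnvelopeModel, pc_grids: np.ndarray, mode: str = "percentile"
) -> np.ndarray:
    """Suitability raster from PC-score rasters of shape (n_axes, nrows, ncols)."""
    pc_grids = np.asarray(pc_grids, dtype=float)
    if pc_grids.shape[0] != model.n_axes:
        raise ValueError(f"expected {model.n_axes} PC rasters, got {pc_grids.shape[0]}")
    flat = pc_grids.reshape(model.n_axes, -1).T
    return predict_suitability(model, flat, mode=mode).reshape(pc_grids.shape[1:])
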