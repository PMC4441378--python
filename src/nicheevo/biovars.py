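"""Bioclim-style temporal summaries of monthly environmental grids.

Each 12-month series is collapsed into the temperature-family bioclimatic
summaries: annual mean (BIO1), seasonality (BIO4, standard deviation of
the monthly values x 100), extreme months (BIO5/BIO6), annual range
(BIO7) and the warmest/coldest consecutive-quarter means (BIO10/BIO11,
with December-to-January wrap-around). A paired day/night series
additionally yields mean diurnal range (BIO2) and isothermality (BIO3).

Applied to the five monthly stacks this produces the 30 named predictors
X1-X30: seven summaries each for MIR, NDVI and EVI, and nine for the
day/night land-surface temperature pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import GridGeometry
from .synthetic import MonthlyStack

# summary order within each X-variable block
SINGLE_ORDER = ("BIO1", "BIO5", "BIO6", "BIO4", "BIO10", "BIO11", "BIO7")
DAYNIGHT_ORDER = ("BIO1", "BIO2", "BIO3", "BIO5", "BIO6", "BIO4", "BIO10", "BIO11", "BIO7")

BIO_DESCRIPTIONS = {
    "BIO1": "annual mean",
    "BIO2": "mean diurnal range",
    "BIO3": "isothermality (100*BIO2/BIO7)",
    "BIO4": "seasonality (SD of monthly values x 100)",
    "BIO5": "max of month with highest scores",
    "BIO6": "min of month with lowest scores",
    "BIO7": "annual range (BIO5-BIO6)",
    "BIO10": "mean of quarter with highest scores",
    "BIO11": "mean of quarter with lowest scores",
}


def _quarter_means(monthly: np.ndarray) -> np.ndarray:
    """Means of the 12 consecutive 3-month windows (Dec->Jan wrap).

    monthly has month as axis 0; returns shape (12, ...) with window i
    starting at month i. Ties between windows resolve to the earliest
    start month because argmax/argmin take the first maximum.
    """
    return np.stack(
        [(monthly[i] + monthly[(i + 1) % 12] + monthly[(i + 2) % 12]) / 3.0 for i in range(12)]
    )


def biovars_single(
    monthly: np.ndarray, seasonality_scale: float = 100.0, ddof: int = 1
) -> dict[str, np.ndarray]:
    """Seven bioclim summaries of one 12-month series (vectorised).

    `monthly` has the month as the leading axis (length 12); any trailing
    shape is carried through, and NaN (masked) cells propagate to every
    output. BIO4 defaults to the sample standard deviation x 100; set
    `seasonality_scale=1, ddof=0` for a raw population SD.
    """
    monthly = np.asarray(monthly, dtype=float)
    if monthly.shape[0] != 12:
        raise ValueError(f"expected 12 monthly values on axis 0, got {monthly.shape[0]}")
    quarters = _quarter_means(monthly)
    return {
        "BIO1": monthly.mean(axis=0),
        "BIO4": monthly.std(axis=0, ddof=ddof) * seasonality_scale,
        "BIO5": monthly.max(axis=0),
        "BIO6": monthly.min(axis=0),
        "BIO7": monthly.max(axis=0) - monthly.min(axis=0),
        "BIO10": quarters.max(axis=0),
        "BIO11": quarters.min(axis=0),
    }


def biovars_daynight(
    dlst: np.ndarray,
    ntlst: np.ndarray,
    seasonality_scale: float = 100.0,
    ddof: int = 1,
) -> dict[str, np.ndarray]:
    """Nine bioclim summaries of a day/night temperature pair.

    The day series acts as the daily maximum and the night series as the
    daily minimum: BIO2 is the mean month-wise day-night difference, BIO5
    the hottest day value, BIO6 the coldest night value, and BIO3 the
    isothermality 100*BIO2/BIO7 (defined as 0 where BIO7 = 0). BIO1/4/10/11
    summarise the month-wise day/night mean.
    """
    dlst = np.asarray(dlst, dtype=float)
    ntlst = np.asarray(ntlst, dtype=float)
    if dlst.shape[0] != 12 or ntlst.shape[0] != 12:
        raise ValueError("both series must have 12 monthly values on axis 0")
    if dlst.shape != ntlst.shape:
        raise ValueError("day and night series must have the same shape")
    with np.errstate(invalid="ignore"):
        if np.any(dlst < ntlst):
            warnings.warn("day values below night values at some cells/months", stacklevel=2)
    mean_monthly = (dlst + ntlst) / 2.0
    out = biovars_single(mean_monthly, seasonality_scale=seasonality_scale, ddof=ddof)
    bio2 = (dlst - ntlst).mean(axis=0)
    bio5 = dlst.max(axis=0)
    bio6 = ntlst.min(axis=0)
    bio7 = bio5 - bio6
    with np.errstate(divide="ignore", invalid="ignore"):
        bio3 = np.where(bio7 == 0, 0.0, 100.0 * bio2 / bio7)
    bio3 = np.where(np.isnan(bio7), np.nan, bio3)
    out.update({"BIO2": bio2, "BIO3": bio3, "BIO5": bio5, "BIO6": bio6, "BIO7": bio7})
    return out


@dataclass
class PredictorSet:
    """The 30 named predictor grids X1-X30 on a shared geometry."""

    names: list[str]  # X1..X30
    arrays: np.ndarray  # shape (n_vars, nrows, ncols)
    sources: list[str]  # MIR / LST / NDVI / EVI per variable
    bio_codes: list[str]  # BIO index per variable
    geometry: GridGeometry

    def __post_init__(self) -> None:
        n = len(self.names)
        if not (len(self.sources) == len(self.bio_codes) == self.arrays.shape[0] == n):
            raise ValueError("inconsistent predictor metadata lengths")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.arrays[self.names.index(name)]

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.arrays).all(axis=0)

    def table(self, cells: np.ndarray | None = None) -> np.ndarray:
        """(n_cells, n_vars) matrix of predictor values.

        `cells` is a boolean grid selecting cells; defaults to all jointly
        valid cells.
        """
        mask = self.valid_mask if cells is None else (cells & self.valid_mask)
        return self.arrays[:, mask].T

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.names,
                "source": self.sources,
                "transformation": [BIO_DESCRIPTIONS[b] for b in self.bio_codes],
                "bio": self.bio_codes,
            }
        )


def build_predictor_set(stacks: dict[str, MonthlyStack]) -> PredictorSet:
    """Derive the 30 predictors X1-X30 from the five monthly stacks.

    Block layout: MIR -> X1-X7, day/night LST -> X8-X16, NDVI -> X17-X23,
    EVI -> X24-X30; within each block the summaries follow SINGLE_ORDER /
    DAYNIGHT_ORDER, which puts MIR seasonality at X4, MIR annual range at
    X7 and LST seasonality at X13. A cell masked in any input stack is
    masked in all 30 outputs.
    """
    required = {"MIR", "DTLST", "NTLST", "NDVI", "EVI"}
    missing = required - set(stacks)
    if missing:
        raise ValueError(f"missing stacks: {sorted(missing)}")
    geom = stacks["MIR"].geometry
    for kind, stack in stacks.items():
        if stack.geometry != geom:
            raise ValueError(f"stack {kind} is not on the shared grid geometry")

    shared_valid = np.ones(geom.shape, dtype=bool)
    for stack in stacks.values():
        shared_valid &= stack.valid_mask

    names: list[str] = []
    arrays: list[np.ndarray] = []
    sources: list[str] = []
    bios: list[str] = []

    def add_block(source: str, values: dict[str, np.ndarray], order: tuple[str, ...]) -> None:
        for bio in order:
            names.append(f"X{len(names) + 1}")
            grid = np.where(shared_valid, values[bio], np.nan)
            arrays.append(grid)
            sources.append(source)
            bios.append(bio)

    add_block("MIR", biovars_single(stacks["MIR"].layers), SINGLE_ORDER)
    add_block("LST", biovars_daynight(stacks["DTLST"].layers, stacks["NTLST"].layers), DAYNIGHT_ORDER)
    add_block("NDVI", biovars_single(stacks["NDVI"].layers), SINGLE_ORDER)
    add_block("EVI", biovars_single(stacks["EVI"].layers), SINGLE_ORDER)

    return PredictorSet(
        names=names,
        arrays=np.stack(arrays),
        sources=sources,
        bio_codes=bios,
        geometry=geom,
    )
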