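"""Readers and writers for the pipeline's standard formats.

Occurrences: CSV with header lon,lat,clade. Monthly stacks: one ASCII grid
per month per variable, named {VAR}_{MM}.asc. Trees: Newick with branch
lengths in Ma.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import read_ascii_grid, write_ascii_grid
from .synthetic import VARIABLE_KINDS, MonthlyStack, OccurrenceSet
from .trees import UltrametricTree

log = logging.getLogger("nicheevo")


def read_occurrences(path: str | Path) -> OccurrenceSet:
    """Read lon,lat,clade records from CSV; malformed rows are reported
    with their line numbers and raise."""
    df = pd.read_csv(path)
    required = {"lon", "lat", "clade"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    bad = df.index[lon.isna() | lat.isna() | df["clade"].isna()]
    if len(bad):
        lines = [int(i) + 2 for i in bad]  # +2: header + 1-based
        raise ValueError(f"{path}: non-numeric coordinates or missing clade at lines {lines}")
    return OccurrenceSet(lon.to_numpy(), lat.to_numpy(), df["clade"].astype(str).to_numpy())


def write_occurrences(path: str | Path, occ: OccurrenceSet) -> None:
    pd.DataFrame({"lon": occ.lon, "lat": occ.lat, "clade": occ.clade}).to_csv(
        path, index=False
    )


def read_tree(path: str | Path, age_tolerance: float = 1e-6) -> UltrametricTree:
    """Read a Newick tree and validate ultrametricity within tolerance."""
    text = Path(path).read_text()
    return UltrametricTree.from_newick(text, age_tolerance=age_tolerance)


def write_tree(path: str | Path, tree: UltrametricTree) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def write_stacks(directory: str | Path, stacks: dict[str, MonthlyStack]) -> None:
    """Write each monthly layer as {VAR}_{MM}.asc."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for kind, stack in stacks.items():
        for m in range(12):
            write_ascii_grid(directory / f"{kind}_{m + 1:02d}.asc", stack.layers[m], stack.geometry)


def read_stacks(directory: str | Path) -> dict[str, MonthlyStack]:
    """Read the five {VAR}_{MM}.asc monthly stacks from a directory."""
    directory = Path(directory)
    stacks: dict[str, MonthlyStack] = {}
    for kind in VARIABLE_KINDS:
        layers = []
        geom = None
        for m in range(12):
            path = directory / f"{kind}_{m + 1:02d}.asc"
            if not path.exists():
                raise FileNotFoundError(f"missing monthly layer {path}")
            values, g = read_ascii_grid(path)
            if geom is None:
                geom = g
            elif g != geom:
                raise ValueError(f"{path}: geometry differs from {kind}_01.asc")
            layers.append(values)
        stacks[kind] = MonthlyStack(kind, np.stack(layers), geom)
    return stacks
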