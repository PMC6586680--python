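"""Presence-record cleaning, systematic thinning and pseudo-absence sampling.

Workflow for presence-only data: validate raw records against the study
grid and its land/data mask, remove pre-baseline records, thin to one
record per grid cell to damp sampling bias and spatial autocorrelation,
then draw background pseudo-absences uniformly without replacement from
the remaining valid cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridSpec, PredictorStack
from .io import OCCURRENCE_COLUMNS


@dataclass
class OccurrenceSet:
    """Validated presences plus (optionally) pseudo-absences for one species."""

    species: str
    presences: pd.DataFrame
    pseudo_absences: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["lon", "lat"]))
    provenance: list = field(default_factory=list)

    @property
    def n_presences(self) -> int:
        return len(self.presences)

    def labelled_points(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(lon, lat, label) arrays; label 1 = presence, 0 = pseudo-absence."""
        lon = np.concatenate([self.presences["lon"].to_numpy(float),
                              self.pseudo_absences["lon"].to_numpy(float)])
        lat = np.concatenate([self.presences["lat"].to_numpy(float),
                              self.pseudo_absences["lat"].to_numpy(float)])
        y = np.concatenate([np.ones(len(self.presences), dtype=int),
                            np.zeros(len(self.pseudo_absences), dtype=int)])
        return lon, lat, y


# rejection reasons, applied in this order
REASON_INCOMPLETE = "incomplete coordinates"
REASON_RANGE = "coordinate out of range"
REASON_EXTENT = "outside study extent"
REASON_MASK = "off-mask"
REASON_OLD = "pre-baseline year"


def clean_occurrences(records: pd.DataFrame, stack: PredictorStack,
                      min_year: int = 1960) -> tuple[OccurrenceSet, dict]:
    """Validate raw records against the grid, its mask and the baseline period.

    Removal rules, applied in order and logged per reason: incomplete
    coordinates; lon/lat outside [-180,180]/[-90,90]; outside the grid
    extent; on a masked (no-data/ocean) cell; year <= ``min_year - 1``.
    Records with a missing year are retained. Returns the cleaned set and
    a rejection-count dictionary whose entries plus ``retained`` sum to
    ``input``.
    """
    df = records.copy()
    for col in OCCURRENCE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    counts = {"input": len(df)}
    species = str(df["species"].dropna().iloc[0]) if df["species"].notna().any() else ""

    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    df["lon"], df["lat"] = lon, lat

    bad = lon.isna() | lat.isna()
    counts[REASON_INCOMPLETE] = int(bad.sum())
    df = df[~bad]

    bad = (df["lon"].abs() > 180) | (df["lat"].abs() > 90)
    counts[REASON_RANGE] = int(bad.sum())
    df = df[~bad]

    g = stack.grid
    inside = df.apply(lambda r: g.contains(r["lon"], r["lat"]), axis=1) \
        if len(df) else pd.Series([], dtype=bool)
    counts[REASON_EXTENT] = int((~inside).sum())
    df = df[inside] if len(df) else df

    if len(df):
        row, col = g.cell_index(df["lon"].to_numpy(), df["lat"].to_numpy())
        on_mask = stack.mask[row, col]
    else:
        on_mask = np.array([], dtype=bool)
    counts[REASON_MASK] = int((~on_mask).sum())
    df = df[on_mask]

    year = pd.to_numeric(df["year"], errors="coerce")
    bad = year.notna() & (year <= min_year - 1)
    counts[REASON_OLD] = int(bad.sum())
    df = df[~bad]

    counts["retained"] = len(df)
    occ = OccurrenceSet(
        species=species,
        presences=df.reset_index(drop=True),
        provenance=[{"stage": "clean", "min_year": min_year, "counts": counts}],
    )
    return occ, counts


def thin_systematic(occ: OccurrenceSet, cell_size: float, seed: int,
                    grid: GridSpec | None = None) -> OccurrenceSet:
    """Retain one presence per thinning cell, chosen uniformly at random.

    The thinning lattice is anchored at the study grid's north-west origin
    when ``grid`` is given, else at (-180, 90). Output count equals the
    number of distinct occupied cells; ties are broken by the seeded RNG,
    so the operation is reproducible and idempotent for a fixed lattice.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    ax, ay = (grid.x_min, grid.y_max) if grid is not None else (-180.0, 90.0)
    df = occ.presences
    if len(df) == 0:
        return OccurrenceSet(occ.species, df.copy(), occ.pseudo_absences.copy(),
                             occ.provenance + [{"stage": "thin", "kept": 0}])
    col = np.floor((df["lon"].to_numpy(float) - ax) / cell_size).astype(int)
    row = np.floor((ay - df["lat"].to_numpy(float)) / cell_size).astype(int)
    rng = np.random.default_rng(seed)
    keep_idx = []
    # iterate cells in sorted order so RNG consumption is input-order independent
    cells = pd.DataFrame({"row": row, "col": col, "i": np.arange(len(df))})
    for (_, _), grp in cells.sort_values(["row", "col", "i"]).groupby(["row", "col"], sort=True):
        members = grp["i"].to_numpy()
        keep_idx.append(members[rng.integers(0, len(members))])
    out = df.iloc[sorted(keep_idx)].reset_index(drop=True)
    return OccurrenceSet(
        species=occ.species,
        presences=out,
        pseudo_absences=occ.pseudo_absences.copy(),
        provenance=occ.provenance + [{
            "stage": "thin", "cell_size": cell_size, "seed": seed,
            "input": len(df), "kept": len(out)}],
    )


def sample_pseudo_absences(occ: OccurrenceSet, stack: PredictorStack, n: int = 1000,
                           exclude_presence_cells: bool = True,
                           seed: int = 0) -> OccurrenceSet:
    """Draw ``n`` pseudo-absence locations uniformly without replacement.

    Sampling is at cell granularity over the valid cells of ``stack``
    (minus presence cells when ``exclude_presence_cells``), with locations
    reported at cell centres.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    g = stack.grid
    rows, cols = stack.valid_rc()
    flat = rows * g.n_cols + cols
    if exclude_presence_cells and len(occ.presences):
        pr, pc = g.cell_index(occ.presences["lon"].to_numpy(),
                              occ.presences["lat"].to_numpy())
        presence_flat = np.unique(pr * g.n_cols + pc)
        flat = np.setdiff1d(flat, presence_flat, assume_unique=False)
    if len(flat) < n:
        raise ValueError(
            f"cannot sample {n} pseudo-absences: only {len(flat)} eligible cells")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(flat, size=n, replace=False)
    chosen.sort()
    lon, lat = g.cell_center(chosen // g.n_cols, chosen % g.n_cols)
    pa = pd.DataFrame({"lon": lon, "lat": lat})
    return OccurrenceSet(
        species=occ.species,
        presences=occ.presences.copy(),
        pseudo_absences=pa,
        provenance=occ.provenance + [{
            "stage": "pseudo_absences", "n": n, "seed": seed,
            "exclude_presence_cells": bool(exclude_presence_cells)}],
    )
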