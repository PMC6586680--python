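"""Change, replacement and portfolio analyses of binary suitability maps.

Baseline-vs-future comparison classifies every cell as remaining, lost
(vulnerable), gained or never suitable; summaries report area change as a
percentage of the baseline range, distributions over the altitudinal
gradient, whether a second crop can replace the first in its vulnerable
cells, and per-cell richness of a tree-species portfolio by main use
group (fruit, N-fixing, timber).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridSpec

# change categories
NEVER, REMAIN, LOSS, GAIN = 0, 1, 2, 3
INVALID = -1
CHANGE_CODES = {"never": NEVER, "remain": REMAIN, "loss": LOSS, "gain": GAIN}

# replacement categories
R_NONE, R_REPLACEABLE, R_BOTH, R_NO_ALTERNATIVE, R_A_ONLY = 0, 1, 2, 3, 4
REPLACEMENT_CODES = {
    "none": R_NONE, "replaceable": R_REPLACEABLE, "both_suitable": R_BOTH,
    "no_alternative": R_NO_ALTERNATIVE, "crop_a_only": R_A_ONLY,
}

# altitude bands reported alongside uniform binning (half-open, metres a.s.l.)
DEFAULT_BANDS = {"0-300 m": (0.0, 300.0), "400-700 m": (400.0, 700.0),
                 ">1800 m": (1800.0, np.inf)}

P_OTHER, P_HIGH, P_LOW = 0, 1, 2


@dataclass
class ChangeMap:
    """Per-cell change category; -1 marks masked cells."""

    categories: np.ndarray
    baseline_id: str = ""
    future_id: str = ""

    def count(self, category: int) -> int:
        return int(np.sum(self.categories == category))


def _check_same_shape(*arrays) -> None:
    shapes = {np.asarray(a).shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"rasters have mismatched grids: {sorted(shapes)}")


def classify_change(baseline: np.ndarray, future: np.ndarray,
                    baseline_id: str = "baseline", future_id: str = "future") -> ChangeMap:
    """remain = 1->1, loss = 1->0, gain = 0->1, never = 0->0."""
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(future, dtype=float)
    _check_same_shape(b, f)
    valid = ~np.isnan(b) & ~np.isnan(f)
    cat = np.full(b.shape, INVALID, dtype=np.int8)
    bp, fp = b > 0.5, f > 0.5
    cat[valid & bp & fp] = REMAIN
    cat[valid & bp & ~fp] = LOSS
    cat[valid & ~bp & fp] = GAIN
    cat[valid & ~bp & ~fp] = NEVER
    return ChangeMap(categories=cat, baseline_id=baseline_id, future_id=future_id)


def area_change_percent(change: ChangeMap, area_mode: str = "cells",
                        grid: GridSpec | None = None) -> dict:
    """Loss/gain/remain as percentages of the baseline suitable area.

    ``area_mode='cells'`` counts cells; ``'cos_lat_km2'`` weights each
    cell by the cosine of its row-centre latitude (proportional to true
    area on a lon/lat grid; requires ``grid``).
    """
    cat = change.categories
    if area_mode == "cells":
        w = np.ones(cat.shape)
    elif area_mode == "cos_lat_km2":
        if grid is None:
            raise ValueError("cos_lat_km2 weighting requires the grid")
        w = np.broadcast_to(
            np.cos(np.deg2rad(grid.y_centers()))[:, None], cat.shape)
    else:
        raise ValueError(f"unknown area_mode {area_mode!r}")
    a_remain = float(w[cat == REMAIN].sum())
    a_loss = float(w[cat == LOSS].sum())
    a_gain = float(w[cat == GAIN].sum())
    a_base = a_remain + a_loss
    if a_base == 0:
        raise ValueError("baseline presence is empty; percentages undefined")
    return {
        "loss_pct": 100.0 * a_loss / a_base,
        "gain_pct": 100.0 * a_gain / a_base,
        "remain_pct": 100.0 * a_remain / a_base,
    }


@dataclass
class AltitudinalProfile:
    """Change-category counts per uniform elevation bin and named band."""

    bin_width: float
    bins: pd.DataFrame       # columns: bin_lo, never, remain, loss, gain
    bands: pd.DataFrame      # per named band, same count columns


def _category_counts(cat: np.ndarray, sel: np.ndarray) -> dict:
    return {name: int(np.sum(cat[sel] == code)) for name, code in CHANGE_CODES.items()}


def altitudinal_profile(change: ChangeMap, elevation: np.ndarray,
                        bin_width: float = 100.0,
                        bands: dict | None = None) -> AltitudinalProfile:
    """Distribution of change categories over the elevation gradient.

    Uniform half-open bins [lo, lo + width) plus the named aggregate
    bands (defaults: 0-300, 400-700 and >1800 m a.s.l.).
    """
    cat = change.categories
    elev = np.asarray(elevation, dtype=float)
    _check_same_shape(cat, elev)
    bands = DEFAULT_BANDS if bands is None else bands
    ok = (cat != INVALID) & ~np.isnan(elev)
    rows = []
    if np.any(ok):
        lo0 = np.floor(elev[ok].min() / bin_width) * bin_width
        hi0 = elev[ok].max()
        edges = np.arange(lo0, hi0 + bin_width, bin_width)
        for lo in edges:
            sel = ok & (elev >= lo) & (elev < lo + bin_width)
            if not np.any(sel):
                continue
            rows.append({"bin_lo": float(lo), **_category_counts(cat, sel)})
    band_rows = []
    for name, (lo, hi) in bands.items():
        sel = ok & (elev >= lo) & (elev < hi)
        band_rows.append({"band": name, **_category_counts(cat, sel)})
    return AltitudinalProfile(
        bin_width=bin_width,
        bins=pd.DataFrame(rows, columns=["bin_lo", *CHANGE_CODES]),
        bands=pd.DataFrame(band_rows, columns=["band", *CHANGE_CODES]),
    )


@dataclass
class ReplacementMap:
    """Can crop B stand in where crop A becomes unsuitable?"""

    categories: np.ndarray
    replaceable_fraction: float
    band_fractions: pd.DataFrame


def replacement_analysis(change_a: ChangeMap, future_b: np.ndarray,
                         elevation: np.ndarray | None = None,
                         bands: dict | None = None) -> ReplacementMap:
    """Overlay crop A's change map with crop B's future suitability.

    replaceable = A-loss cells where B is suitable in the future;
    no_alternative = A-loss cells where it is not; both_suitable /
    crop_a_only partition A's future range by B's future suitability.
    The replaceable fraction (of A-loss cells) is reported overall and
    per altitude band when elevation is given.
    """
    cat_a = change_a.categories
    fb = np.asarray(future_b, dtype=float)
    _check_same_shape(cat_a, fb)
    valid = (cat_a != INVALID) & ~np.isnan(fb)
    b_pres = fb > 0.5
    a_loss = cat_a == LOSS
    a_future = (cat_a == REMAIN) | (cat_a == GAIN)
    out = np.full(cat_a.shape, INVALID, dtype=np.int8)
    out[valid] = R_NONE
    out[valid & a_loss & b_pres] = R_REPLACEABLE
    out[valid & a_loss & ~b_pres] = R_NO_ALTERNATIVE
    out[valid & a_future & b_pres] = R_BOTH
    out[valid & a_future & ~b_pres] = R_A_ONLY

    n_loss = int(np.sum(valid & a_loss))
    n_rep = int(np.sum(out == R_REPLACEABLE))
    overall = 100.0 * n_rep / n_loss if n_loss else float("nan")
    band_rows = []
    if elevation is not None:
        elev = np.asarray(elevation, dtype=float)
        _check_same_shape(cat_a, elev)
        bands = DEFAULT_BANDS if bands is None else bands
        for name, (lo, hi) in bands.items():
            sel = valid & (elev >= lo) & (elev < hi)
            nl = int(np.sum(sel & a_loss))
            nr = int(np.sum(sel & (out == R_REPLACEABLE)))
            band_rows.append({"band": name, "loss_cells": nl, "replaceable_cells": nr,
                              "replaceable_pct": 100.0 * nr / nl if nl else np.nan})
    return ReplacementMap(
        categories=out, replaceable_fraction=overall,
        band_fractions=pd.DataFrame(
            band_rows, columns=["band", "loss_cells", "replaceable_cells",
                                "replaceable_pct"]),
    )


@dataclass
class PortfolioMap:
    """Tree-portfolio richness over a crop's area."""

    total_richness: np.ndarray
    group_richness: dict
    classes: np.ndarray          # P_OTHER / P_HIGH / P_LOW, INVALID off crop area
    fractions: dict              # high_option_pct, low_option_pct of crop area


def portfolio_richness(per_species_future: dict, groups: dict, crop_area: np.ndarray,
                       rich_total: int = 30, rich_per_group: int = 10,
                       low_cutoff: int = 3) -> PortfolioMap:
    """Species richness and option classes over the crop area.

    A cell is high-option when more than ``rich_total`` species are
    suitable AND every use group supplies at least ``rich_per_group``;
    low-option when at most ``low_cutoff`` species are suitable.
    Fractions are percentages of crop-area cells.
    """
    if not per_species_future:
        raise ValueError("per_species_future is empty")
    missing = [s for s in per_species_future if s not in groups]
    if missing:
        raise ValueError(f"species missing group assignment: {missing}")
    crop = np.asarray(crop_area, dtype=float)
    shape = crop.shape
    group_names = sorted(set(groups[s] for s in per_species_future))
    total = np.zeros(shape)
    by_group = {gname: np.zeros(shape) for gname in group_names}
    for sp, fmap in per_species_future.items():
        fm = np.asarray(fmap, dtype=float)
        _check_same_shape(crop, fm)
        pres = (fm > 0.5).astype(float)
        total += pres
        by_group[groups[sp]] += pres
    on_crop = (crop > 0.5) & ~np.isnan(crop)
    high = on_crop & (total > rich_total)
    for gname in group_names:
        high &= by_group[gname] >= rich_per_group
    low = on_crop & (total <= low_cutoff)
    classes = np.full(shape, INVALID, dtype=np.int8)
    classes[on_crop] = P_OTHER
    classes[high] = P_HIGH
    classes[low] = P_LOW
    n_crop = int(on_crop.sum())
    if n_crop == 0:
        raise ValueError("crop area is empty")
    return PortfolioMap(
        total_richness=np.where(on_crop, total, np.nan),
        group_richness={g: np.where(on_crop, a, np.nan) for g, a in by_group.items()},
        classes=classes,
        fractions={
            "high_option_pct": 100.0 * int(high.sum()) / n_crop,
            "low_option_pct": 100.0 * int(low.sum()) / n_crop,
        },
    )


def species_area_change_table(per_species_change: dict, groups: dict,
                              change_cutoff_pct: float = 15.0):
    """Per-species baseline/future areas and % change, with group tallies.

    Returns ``(table, group_counts)``: the table has one row per species
    (sorted by group then |%change| descending; species with an empty
    baseline get NaN %change and are excluded from tallies), and
    ``group_counts`` counts species losing or gaining more than
    ``change_cutoff_pct`` per use group.
    """
    if not per_species_change:
        raise ValueError("per_species_change is empty")
    rows = []
    for sp, cm in per_species_change.items():
        a_base = cm.count(REMAIN) + cm.count(LOSS)
        a_fut = cm.count(REMAIN) + cm.count(GAIN)
        pct = 100.0 * (a_fut - a_base) / a_base if a_base else np.nan
        rows.append({"species": sp, "group": groups.get(sp, ""),
                     "baseline_cells": a_base, "future_cells": a_fut,
                     "pct_change": pct})
    table = pd.DataFrame(rows)
    table["abs_change"] = table["pct_change"].abs()
    table = (table.sort_values(["group", "abs_change"], ascending=[True, False])
             .drop(columns="abs_change").reset_index(drop=True))
    ok = table["pct_change"].notna()
    tallies = []
    for g, sub in table[ok].groupby("group"):
        tallies.append({
            "group": g,
            "n_species": len(sub),
            "n_losing_gt_cutoff": int((sub["pct_change"] < -change_cutoff_pct).sum()),
            "n_gaining_gt_cutoff": int((sub["pct_change"] > change_cutoff_pct).sum()),
        })
    return table, pd.DataFrame(tallies, columns=["group", "n_species",
                                                 "n_losing_gt_cutoff",
                                                 "n_gaining_gt_cutoff"])
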