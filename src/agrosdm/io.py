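"""Plain-text raster and table IO.

Rasters are stored as ESRI ASCII grids (``.asc``) — a text format readable
by GDAL/QGIS — one file per layer, with the validity mask as an extra
``mask.asc`` layer of 0/1. Occurrence tables are CSV with the columns
``species, lon, lat, year, source``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import NODATA, GridSpec, PredictorStack

OCCURRENCE_COLUMNS = ["species", "lon", "lat", "year", "source"]


def write_ascii_grid(path, array: np.ndarray, grid: GridSpec, nodata: float = NODATA) -> None:
    array = np.asarray(array, dtype=float)
    if array.shape != grid.shape:
        raise ValueError("array shape does not match grid")
    out = np.where(np.isnan(array), nodata, array)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.x_min!r}\n"
        f"yllcorner {grid.y_min!r}\n"
        f"cellsize {grid.resolution!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path) -> tuple[np.ndarray, GridSpec]:
    meta: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        data = np.loadtxt(fh)
    n_rows, n_cols = int(meta["nrows"]), int(meta["ncols"])
    data = data.reshape(n_rows, n_cols)
    nodata = meta.get("nodata_value", NODATA)
    data[data == nodata] = np.nan
    grid = GridSpec(
        n_rows=n_rows, n_cols=n_cols,
        x_min=meta["xllcorner"], y_min=meta["yllcorner"],
        x_max=meta["xllcorner"] + n_cols * meta["cellsize"],
        y_max=meta["yllcorner"] + n_rows * meta["cellsize"],
        resolution=meta["cellsize"],
    )
    return data, grid


def write_stack(directory, stack: PredictorStack) -> list[Path]:
    """One .asc per layer plus the 0/1 mask and a layer-order manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, arr in stack.layers.items():
        p = directory / f"{name}.asc"
        write_ascii_grid(p, arr, stack.grid)
        written.append(p)
    p = directory / "mask.asc"
    write_ascii_grid(p, stack.mask.astype(float), stack.grid)
    written.append(p)
    order = directory / "layers.json"
    order.write_text(json.dumps({"layers": stack.layer_names}, indent=1))
    written.append(order)
    return written


def read_stack(directory) -> PredictorStack:
    directory = Path(directory)
    names = json.loads((directory / "layers.json").read_text())["layers"]
    mask_arr, grid = read_ascii_grid(directory / "mask.asc")
    mask = mask_arr > 0.5
    layers = {}
    for name in names:
        arr, g = read_ascii_grid(directory / f"{name}.asc")
        if g != grid:
            raise ValueError(f"layer {name} has a different grid")
        layers[name] = arr
    return PredictorStack(grid=grid, layers=layers, mask=mask)


def write_occurrences(path, records: pd.DataFrame) -> None:
    records.loc[:, OCCURRENCE_COLUMNS].to_csv(path, index=False)


def read_occurrences(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in OCCURRENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence table missing column(s): {missing}")
    return df


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
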