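"""Georeferenced lattice and predictor-stack containers.

A :class:`GridSpec` describes a regular lon/lat lattice with square cells;
rows are ordered north to south, as in common raster formats. A
:class:`PredictorStack` bundles named co-registered layers (bioclimatic
predictors, elevation) sharing one validity mask; invalid cells carry NaN
so no computation can silently read them as data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NODATA = -9999.0

#: layer names treated as temperature-like (WorldClim convention: bio01-bio11
#: are temperature variables, bio12-bio19 precipitation).
_TEMP_BIO = {f"bio{i:02d}" for i in range(1, 12)}


def is_temperature_like(name: str) -> bool:
    """Whether a layer name denotes a temperature-type variable."""
    low = name.lower()
    return low in _TEMP_BIO or "temp" in low or low.startswith("tmean")


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid with square cells, rows north -> south.

    Cell membership uses half-open intervals ``[edge, edge + resolution)``
    on both axes, so a point exactly on the eastern/northern boundary of
    the grid falls outside it.
    """

    n_rows: int
    n_cols: int
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    resolution: float

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if not math.isclose((self.x_max - self.x_min) / self.resolution, self.n_cols,
                            rel_tol=0, abs_tol=1e-6):
            raise ValueError("x extent inconsistent with n_cols * resolution")
        if not math.isclose((self.y_max - self.y_min) / self.resolution, self.n_rows,
                            rel_tol=0, abs_tol=1e-6):
            raise ValueError("y extent inconsistent with n_rows * resolution")

    @classmethod
    def from_origin(cls, n_rows: int, n_cols: int, x_min: float, y_max: float,
                    resolution: float) -> "GridSpec":
        """Build a grid from its north-west corner and cell counts."""
        return cls(
            n_rows=n_rows, n_cols=n_cols,
            x_min=x_min, y_min=y_max - n_rows * resolution,
            x_max=x_min + n_cols * resolution, y_max=y_max,
            resolution=resolution,
        )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def x_centers(self) -> np.ndarray:
        return self.x_min + (np.arange(self.n_cols) + 0.5) * self.resolution

    def y_centers(self) -> np.ndarray:
        """Latitude of row centres, in row order (north -> south)."""
        return self.y_max - (np.arange(self.n_rows) + 0.5) * self.resolution

    def contains(self, lon: float, lat: float) -> bool:
        return (self.x_min <= lon < self.x_max) and (self.y_min <= lat < self.y_max)

    def cell_index(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised (row, col) of the cell containing each point.

        Points outside the grid raise ``ValueError``; use :meth:`contains`
        to pre-filter.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.x_min) / self.resolution).astype(int)
        row_s = np.floor((lat - self.y_min) / self.resolution).astype(int)
        row = self.n_rows - 1 - row_s
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        if np.any(bad):
            raise ValueError("point(s) outside grid extent")
        return row, col

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.x_min + (col + 0.5) * self.resolution
        lat = self.y_max - (row + 0.5) * self.resolution
        return lon, lat


@dataclass
class PredictorStack:
    """Named raster layers on one grid, sharing one validity mask.

    ``mask`` is True on valid cells; every layer holds NaN wherever the
    mask is False (the nodata sentinel inside the container is NaN so
    arithmetic on invalid cells can never masquerade as data).
    """

    grid: GridSpec
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.ones(self.grid.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        fixed = {}
        for name, arr in self.layers.items():
            fixed[name] = self._conform(arr)
        self.layers = fixed

    def _conform(self, arr: np.ndarray) -> np.ndarray:
        arr = np.array(arr, dtype=float)
        if arr.shape != self.grid.shape:
            raise ValueError("layer shape does not match grid")
        arr[~self.mask] = np.nan
        return arr

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    def add_layer(self, name: str, arr: np.ndarray) -> None:
        if name in self.layers:
            raise ValueError(f"duplicate layer name {name!r}")
        self.layers[name] = self._conform(arr)

    def require_layers(self, names) -> None:
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"stack is missing layer(s): {missing}")

    def valid_rc(self) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of valid cells, row-major order."""
        return np.nonzero(self.mask)

    def values_at(self, row, col, names=None) -> np.ndarray:
        """Predictor matrix (n points x n layers) at given cells."""
        names = list(names) if names is not None else self.layer_names
        self.require_layers(names)
        return np.column_stack([self.layers[n][row, col] for n in names])

    def table(self, names=None) -> pd.DataFrame:
        """Valid-cell values as a DataFrame (one row per valid cell)."""
        names = list(names) if names is not None else self.layer_names
        self.require_layers(names)
        r, c = self.valid_rc()
        return pd.DataFrame({n: self.layers[n][r, c] for n in names})

    def copy(self) -> "PredictorStack":
        return PredictorStack(
            grid=self.grid,
            layers={n: a.copy() for n, a in self.layers.items()},
            mask=self.mask.copy(),
        )
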