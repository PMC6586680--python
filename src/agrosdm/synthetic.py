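"""Synthetic climate landscapes, virtual species and pseudo-GCM futures.

Every downstream stage of the pipeline can be validated against ground
truth by running it on landscapes produced here: spatially autocorrelated
predictor surfaces with an elevation gradient, virtual species whose
suitability is a known product of Gaussian responses, presence samples
drawn from that suitability (optionally with sampling bias), and ensembles
of pseudo-GCM future stacks built as per-GCM perturbations around a
scenario mean shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import GridSpec, PredictorStack, is_temperature_like
from .occurrences import OccurrenceSet

#: lapse applied to temperature-like layers per unit of standardised
#: elevation; > 1 guarantees a negative elevation-temperature correlation
#: because the uncoupled field has unit variance (|cov| <= 1 < lapse).
ELEVATION_LAPSE = 1.5


@dataclass(frozen=True)
class VirtualSpecies:
    """A species with a known climatic niche.

    The niche is a per-predictor Gaussian response: suitability is the
    product over niche layers of exp(-((v - mu) / sigma)^2 / 2), so it
    equals 1 where every predictor sits at its niche centre and decays
    with standardised distance from it.
    """

    name: str
    niche: dict  # layer name -> (mu, sigma)
    prevalence_target: float = 0.15

    def __post_init__(self) -> None:
        for layer, (mu, sigma) in self.niche.items():
            if sigma <= 0:
                raise ValueError(f"niche sigma must be positive (layer {layer!r})")
        if not (0 < self.prevalence_target <= 1):
            raise ValueError("prevalence_target must be in (0, 1]")


@dataclass(frozen=True)
class ScenarioSpec:
    """A future-climate scenario realised as ``gcm_count`` pseudo-GCMs.

    Each pseudo-GCM applies ``mean_shift`` plus a per-GCM, per-layer
    spatially constant deviation with standard deviation ``gcm_spread``;
    the GCM-mean applied delta converges to ``mean_shift``.
    """

    name: str
    mean_shift: dict = field(default_factory=dict)   # layer -> delta
    gcm_count: int = 17
    gcm_spread: dict = field(default_factory=dict)   # layer -> sd of deviations
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gcm_count < 1:
            raise ValueError("gcm_count must be >= 1")
        for layer, sd in self.gcm_spread.items():
            if sd < 0:
                raise ValueError(f"gcm_spread must be >= 0 (layer {layer!r})")


def _smooth_field(rng: np.random.Generator, shape, window: int = 5) -> np.ndarray:
    """Unit-variance smoothed white noise (moving average of fixed window)."""
    noise = rng.standard_normal(shape)
    smooth = ndimage.uniform_filter(noise, size=window, mode="nearest")
    return (smooth - smooth.mean()) / smooth.std()


def _gradient(rng: np.random.Generator, shape) -> np.ndarray:
    """Unit-variance linear ramp with a random orientation."""
    n_rows, n_cols = shape
    yy, xx = np.meshgrid(np.linspace(-1, 1, n_rows), np.linspace(-1, 1, n_cols),
                         indexing="ij")
    theta = rng.uniform(0, 2 * np.pi)
    ramp = np.cos(theta) * xx + np.sin(theta) * yy
    return (ramp - ramp.mean()) / ramp.std()


def generate_predictor_stack(spec: GridSpec, layer_names, seed: int,
                             elevation_coupling: bool = True,
                             smoothing_window: int = 5,
                             masked_fraction: float = 0.05,
                             max_elevation: float = 3000.0) -> PredictorStack:
    """Generate a deterministic synthetic predictor stack plus elevation.

    Each layer is a large-scale linear gradient plus spatially
    autocorrelated noise, standardised to mean 0 / sd 1. An ``elevation``
    layer (0..``max_elevation`` m) is always produced; the lowest
    ``masked_fraction`` of the raw elevation field is masked out,
    emulating ocean/no-data cells. With ``elevation_coupling``,
    temperature-like layers decrease linearly with elevation.
    """
    layer_names = list(layer_names)
    if not layer_names:
        raise ValueError("layer_names must be non-empty")
    rng = np.random.default_rng(seed)
    shape = spec.shape

    elev_raw = 0.8 * _gradient(rng, shape) + _smooth_field(rng, shape, smoothing_window)
    sea_level = np.quantile(elev_raw, masked_fraction) if masked_fraction > 0 else -np.inf
    mask = elev_raw > sea_level
    elev = np.full(shape, np.nan)
    span = elev_raw.max() - sea_level
    elev[mask] = (elev_raw[mask] - sea_level) / span * max_elevation
    elev_std = (elev_raw - elev_raw.mean()) / elev_raw.std()

    layers = {}
    for name in layer_names:
        base = _gradient(rng, shape) + _smooth_field(rng, shape, smoothing_window)
        base = (base - base.mean()) / base.std()
        if elevation_coupling and is_temperature_like(name):
            base = base - ELEVATION_LAPSE * elev_std
        layers[name] = base
    layers["elevation"] = elev
    return PredictorStack(grid=spec, layers=layers, mask=mask)


def true_suitability(species: VirtualSpecies, stack: PredictorStack) -> np.ndarray:
    """Ground-truth suitability in [0, 1]; NaN on masked cells."""
    stack.require_layers(species.niche)
    s = np.ones(stack.grid.shape)
    for layer, (mu, sigma) in species.niche.items():
        z = (stack.layers[layer] - mu) / sigma
        s = s * np.exp(-0.5 * z * z)
    s[~stack.mask] = np.nan
    return s


def make_virtual_species(stack: PredictorStack, layer_names, seed: int,
                         prevalence_target: float = 0.15,
                         name: str = "virtual") -> VirtualSpecies:
    """Construct a species whose niche centre lies on the landscape.

    The centre is the predictor vector of a random valid cell; niche
    widths are a common multiple of each layer's standard deviation,
    bisected so that roughly ``prevalence_target`` of valid cells have
    suitability >= 0.5.
    """
    layer_names = list(layer_names)
    stack.require_layers(layer_names)
    rng = np.random.default_rng(seed)
    r, c = stack.valid_rc()
    i = rng.integers(0, len(r))
    mu = {n: float(stack.layers[n][r[i], c[i]]) for n in layer_names}
    sd = {n: float(np.nanstd(stack.layers[n])) for n in layer_names}

    def prevalence(scale: float) -> float:
        sp = VirtualSpecies(name, {n: (mu[n], scale * sd[n]) for n in layer_names},
                            prevalence_target)
        s = true_suitability(sp, stack)
        return float(np.nanmean(s >= 0.5))

    lo, hi = 0.05, 30.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if prevalence(mid) < prevalence_target:
            lo = mid
        else:
            hi = mid
    scale = 0.5 * (lo + hi)
    return VirtualSpecies(name, {n: (mu[n], scale * sd[n]) for n in layer_names},
                          prevalence_target)


def sample_occurrences(species: VirtualSpecies, stack: PredictorStack, n: int,
                       bias: np.ndarray | None = None, seed: int = 0,
                       year: int = 2001) -> OccurrenceSet:
    """Draw ``n`` presence records with probability proportional to s * bias.

    Sampling is with replacement across valid cells (duplicates allowed;
    thinning is a downstream concern); records are reported at cell
    centres with a constant year and source tag.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    s = true_suitability(species, stack)
    r, c = stack.valid_rc()
    w = s[r, c]
    if bias is not None:
        bias = np.asarray(bias, dtype=float)
        if bias.shape != stack.grid.shape:
            raise ValueError("bias raster shape does not match grid")
        w = w * bias[r, c]
    total = np.nansum(w)
    if not np.isfinite(total) or total <= 0:
        raise ValueError("all sampling weights are zero")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(r), size=n, replace=True, p=w / total)
    lon, lat = stack.grid.cell_center(r[idx], c[idx])
    df = pd.DataFrame({
        "species": species.name, "lon": lon, "lat": lat,
        "year": year, "source": "synthetic",
    })
    return OccurrenceSet(species=species.name, presences=df,
                         provenance=[{"stage": "simulate", "n": n, "seed": seed}])


def generate_future_stacks(baseline: PredictorStack,
                           scenario: ScenarioSpec) -> list[PredictorStack]:
    """One perturbed stack per pseudo-GCM.

    Stack g applies ``mean_shift + eps_g`` per layer, where ``eps_g`` is a
    spatially constant deviation drawn from N(0, gcm_spread). Layers not
    named in the scenario (e.g. elevation) are copied unchanged.
    """
    names = set(baseline.layer_names)
    unknown = [k for k in set(scenario.mean_shift) | set(scenario.gcm_spread)
               if k not in names]
    if unknown:
        raise KeyError(f"scenario references unknown layer(s): {sorted(unknown)}")
    rng = np.random.default_rng(scenario.seed)
    stacks = []
    spread_layers = sorted(scenario.gcm_spread)
    for _ in range(scenario.gcm_count):
        eps = {k: rng.normal(0.0, scenario.gcm_spread[k]) for k in spread_layers}
        layers = {}
        for name, arr in baseline.layers.items():
            delta = scenario.mean_shift.get(name, 0.0) + eps.get(name, 0.0)
            layers[name] = arr + delta
        stacks.append(PredictorStack(grid=baseline.grid, layers=layers,
                                     mask=baseline.mask.copy()))
    return stacks
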