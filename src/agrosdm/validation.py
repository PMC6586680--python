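"""Ground-truth validation studies on synthetic landscapes.

Because the workflow is meant for real occurrence and climate archives it
cannot be checked end to end against its original inputs at desk scale;
instead these studies measure the properties that matter on virtual
species: can the consensus recover a known niche (held-out AUC and
correlation with true suitability), and does a warming scenario on an
elevation-coupled landscape push the projected range upslope and produce
losses that grow with the size of the shift.
"""

from __future__ import annotations

import numpy as np

from .ensemble import binarize, compute_auc, fit_ensemble, predict_consensus
from .grid import GridSpec
from .occurrences import sample_pseudo_absences
from .projection import project_and_integrate
from .synthetic import (ScenarioSpec, generate_future_stacks,
                        generate_predictor_stack, make_virtual_species,
                        sample_occurrences, true_suitability)

RECOVERY_LAYERS = ["bio02", "bio08", "bio09", "bio13", "bio14"]


def parameter_recovery_trial(seed: int, n_rows: int = 100, n_cols: int = 100,
                             n_presence: int = 300, n_pseudo_absence: int = 1000,
                             k: int = 4) -> dict:
    """Fit the consensus on one virtual species and score it against truth.

    The held-out AUC is the consensus's discrimination of the species'
    true range: fresh cells drawn from inside the range (true suitability
    >= 0.5) are scored against fresh cells drawn from outside it, none of
    them seen in training. Scoring against the true binary range (rather
    than against raw background, where truly suitable cells would be
    counted as absences) is the standard virtual-species evaluation; it
    makes a perfect model score near 1. The cellwise Pearson correlation
    with true suitability is reported alongside.
    """
    grid = GridSpec.from_origin(n_rows, n_cols, -100.0, 20.0, 0.05)
    stack = generate_predictor_stack(grid, RECOVERY_LAYERS, seed=seed)
    sp = make_virtual_species(stack, ["bio08", "bio13", "bio14"], seed=seed + 1,
                              prevalence_target=0.15)
    occ = sample_occurrences(sp, stack, n=n_presence, seed=seed + 2)
    occ = sample_pseudo_absences(occ, stack, n=n_pseudo_absence, seed=seed + 3)
    calib = fit_ensemble(occ, stack, RECOVERY_LAYERS, k=k, seed=seed + 4)
    suit = predict_consensus(calib, stack)

    truth = true_suitability(sp, stack)
    rng = np.random.default_rng(seed + 5)
    train_lon, train_lat, _ = occ.labelled_points()
    tr, tc = grid.cell_index(train_lon, train_lat)
    seen = np.zeros(grid.shape, dtype=bool)
    seen[tr, tc] = True
    inside = np.flatnonzero((truth >= 0.5) & ~seen & stack.mask)
    outside = np.flatnonzero((truth < 0.5) & ~seen & stack.mask)
    pres = rng.choice(inside, size=min(150, len(inside)), replace=False)
    absc = rng.choice(outside, size=min(500, len(outside)), replace=False)
    flat_suit = suit.ravel()
    auc = compute_auc(flat_suit[pres], flat_suit[absc])

    ok = stack.mask
    pearson = float(np.corrcoef(suit[ok], truth[ok])[0, 1])
    return {"holdout_auc": float(auc), "truth_pearson_r": pearson,
            "n_cells": int(ok.sum())}


def climate_response_trial(seed: int, small_shift: float = 0.5,
                           large_shift: float = 1.0, n_rows: int = 50,
                           n_cols: int = 50, gcm_count: int = 5) -> dict:
    """Warming response of one virtual species on an elevation-coupled landscape.

    Two pseudo-scenarios shift the temperature-like predictors by
    ``small_shift`` and ``large_shift`` (in within-landscape SD units);
    both are projected through the fitted consensus and integrated over
    ``gcm_count`` pseudo-GCMs. Reports mean elevation of baseline and
    future presence plus the loss percentage under each shift.
    """
    grid = GridSpec.from_origin(n_rows, n_cols, -100.0, 20.0, 0.05)
    layers = ["bio02", "bio08", "bio13"]
    stack = generate_predictor_stack(grid, layers, seed=seed, elevation_coupling=True)
    sp = make_virtual_species(stack, ["bio08", "bio13"], seed=seed + 1,
                              prevalence_target=0.15)
    occ = sample_occurrences(sp, stack, n=200, seed=seed + 2)
    occ = sample_pseudo_absences(occ, stack, n=500, seed=seed + 3)
    calib = fit_ensemble(occ, stack, layers, seed=seed + 4)
    baseline = binarize(predict_consensus(calib, stack), calib.threshold)

    elev = stack.layers["elevation"]
    out = {"baseline_mean_elevation": _mean_elev(baseline, elev)}
    for label, shift in (("small", small_shift), ("large", large_shift)):
        sc = ScenarioSpec(f"warm_{label}",
                          mean_shift={"bio02": 0.6 * shift, "bio08": shift},
                          gcm_count=gcm_count, gcm_spread={"bio08": 0.1},
                          seed=seed + 10)
        pset = project_and_integrate(calib, generate_future_stacks(stack, sc),
                                     sc.name)
        from .change import area_change_percent, classify_change
        pct = area_change_percent(classify_change(baseline, pset.integrated))
        out[f"loss_pct_{label}"] = pct["loss_pct"]
        if label == "small":
            out["future_mean_elevation"] = _mean_elev(pset.integrated, elev)
    return out


def _mean_elev(binary: np.ndarray, elevation: np.ndarray) -> float:
    sel = binary == 1.0
    if not np.any(sel):
        return float("nan")
    return float(np.nanmean(elevation[sel]))
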