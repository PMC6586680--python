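"""Fit the AUC-weighted consensus to a virtual species and score it against truth.

Builds a synthetic climate landscape, defines a species with a known
Gaussian niche, samples presence-only records and pseudo-absences, fits
the six-learner consensus with 4-fold cross-validation, and compares the
predicted suitability surface with the known truth.
"""

import numpy as np

from agrosdm import (GridSpec, fit_ensemble, generate_predictor_stack,
                     make_virtual_species, predict_consensus, sample_occurrences,
                     sample_pseudo_absences, true_suitability)

grid = GridSpec.from_origin(60, 60, -100.0, 20.0, 0.05)
layers = ["bio02", "bio08", "bio13", "bio14"]
stack = generate_predictor_stack(grid, layers, seed=1)
species = make_virtual_species(stack, ["bio08", "bio13"], seed=2,
                               prevalence_target=0.15, name="demo_tree")

occ = sample_occurrences(species, stack, n=250, seed=3)
occ = sample_pseudo_absences(occ, stack, n=1000, seed=4)
calib = fit_ensemble(occ, stack, layers, k=4, weight_cutoff=0.05, seed=5)

print("per-learner mean cross-validated AUC:")
for name, auc in calib.mean_auc.sort_values(ascending=False).items():
    flag = "selected" if name in calib.weights.selected else "dropped"
    print(f"  {name:18s} {auc:0.3f}  ({flag}, final weight "
          f"{calib.weights.final.get(name, 0):0.3f})")
print(f"maxSS presence threshold: {calib.threshold:0.3f}")

suit = predict_consensus(calib, stack)
truth = true_suitability(species, stack)
r = np.corrcoef(suit[stack.mask], truth[stack.mask])[0, 1]
print(f"cellwise Pearson r between consensus and true suitability: {r:0.3f}")
print("(r near 1 means the ensemble recovered the species' known niche;")
print(" weights near 1/6 mean every learner discriminates comparably well)")
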