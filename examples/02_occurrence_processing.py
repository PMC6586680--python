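"""Clean, thin and augment a raw presence table.

Starts from records with planted defects (missing coordinates, a point in
the ocean mask, pre-1960 dates), validates them against the study grid,
thins to one record per cell, and draws 1,000 pseudo-absences.
"""

import numpy as np
import pandas as pd

from agrosdm import (GridSpec, clean_occurrences, generate_predictor_stack,
                     sample_pseudo_absences, thin_systematic)

grid = GridSpec.from_origin(50, 50, -100.0, 20.0, 0.05)
stack = generate_predictor_stack(grid, ["bio08", "bio13"], seed=10)

rng = np.random.default_rng(11)
good = pd.DataFrame({
    "species": "demo", "lon": rng.uniform(-100, -97.6, 300),
    "lat": rng.uniform(17.6, 19.999, 300), "year": 2005, "source": "survey"})
bad = pd.DataFrame([
    {"species": "demo", "lon": np.nan, "lat": 18.0, "year": 2005, "source": "s"},
    {"species": "demo", "lon": -98.0, "lat": 18.5, "year": 1950, "source": "s"},
    {"species": "demo", "lon": -80.0, "lat": 18.0, "year": 2005, "source": "s"},
])
records = pd.concat([good, bad], ignore_index=True)

occ, counts = clean_occurrences(records, stack, min_year=1960)
print("cleaning report (records per rejection rule):")
for rule, n in counts.items():
    print(f"  {rule:25s} {n}")

thinned = thin_systematic(occ, cell_size=grid.resolution, seed=12, grid=grid)
print(f"thinning: {occ.n_presences} -> {thinned.n_presences} records "
      "(one per occupied grid cell; damps sampling bias and autocorrelation)")

final = sample_pseudo_absences(thinned, stack, n=1000, seed=13)
print(f"pseudo-absences drawn without replacement: {len(final.pseudo_absences)}")
print("(these background cells stand in for true absences when fitting)")
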