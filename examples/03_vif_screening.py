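"""Stepwise VIF screening of a predictor stack with planted collinearity.

Adds a layer built as a linear blend of two others and shows the screen
removing layers one at a time until every retained predictor has
VIF <= 10.
"""

import numpy as np

from agrosdm import (GridSpec, compute_vif, generate_predictor_stack,
                     select_predictors_vif)

grid = GridSpec.from_origin(40, 40, -100.0, 20.0, 0.05)
stack = generate_predictor_stack(grid, ["bio02", "bio08", "bio13", "bio14"], seed=20)
blend = (0.7 * np.nan_to_num(stack.layers["bio02"])
         + 0.3 * np.nan_to_num(stack.layers["bio08"])
         + 0.05 * np.random.default_rng(21).standard_normal(grid.shape))
stack.add_layer("bio07", blend)

report = select_predictors_vif(stack, threshold=10.0, seed=22)
for i, it in enumerate(report.iterations):
    vifs = ", ".join(f"{k}={v:0.1f}" for k, v in it["vif"].items())
    action = f"remove {it['removed']}" if it["removed"] else "stop (all <= 10)"
    print(f"iteration {i}: {vifs} -> {action}")
print(f"retained predictors: {report.retained}")

audit = compute_vif(stack.table(report.retained))
print("audit VIFs on the retained set:",
      {k: round(v, 2) for k, v in audit.items()})
print("(VIF_j = 1/(1-R^2) of predictor j regressed on the others; values")
print(" above 10 flag collinearity that would destabilise the learners)")
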