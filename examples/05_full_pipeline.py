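"""Run the full demo pipeline (3 species, 2 scenarios x 5 pseudo-GCMs).

Equivalent to the CLI
``agrosdm run-all --config <config.yaml> --run-dir <dir>``; all artifacts
are plain text (ASCII rasters, CSV tables, JSON manifests).
"""

import tempfile
from pathlib import Path

import pandas as pd

from agrosdm import PipelineRun, demo_config

with tempfile.TemporaryDirectory() as tmp:
    run = PipelineRun(demo_config(seed=42), tmp)
    run.run_all()
    analysis = Path(tmp) / "analysis"
    print("suitability change (% of each species' baseline range):")
    print(pd.read_csv(analysis / "area_change.csv").to_string(index=False))
    print("\ncrop replacement (can the cocoa-like crop cover the coffee-like"
          " crop's vulnerable cells?):")
    print(pd.read_csv(analysis / "replacement.csv").to_string(index=False))
    print("\nagroforestry portfolio over the coffee-like crop's area:")
    print(pd.read_csv(analysis / "portfolio.csv").to_string(index=False))
    print("\n(loss% grows with the stronger scenario; replacement and portfolio")
    print(" percentages are fractions of the first crop's area)")
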