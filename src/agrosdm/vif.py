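"""Stepwise variance-inflation-factor predictor screening.

VIF_j = 1/(1 - R^2_j), with R^2_j from an intercept-included least-squares
regression of predictor j on all the others. Predictors are dropped one at
a time — always the one with the highest VIF, while that VIF exceeds the
threshold (default 10) — so the retained set is mutually low-collinearity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import PredictorStack

_PERFECT_FIT_TOL = 1e-12


def compute_vif(values: pd.DataFrame) -> pd.Series:
    """VIF per variable for a cells-x-variables table.

    Rows containing any missing value are excluded. Perfect collinearity
    is reported as +inf; a constant (zero-variance) variable is an error
    since its VIF is undefined.
    """
    df = pd.DataFrame(values).dropna()
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 variables")
    n, p = df.shape
    if n <= p:
        raise ValueError(f"need more rows ({n}) than variables ({p})")
    X = df.to_numpy(dtype=float)
    for j, c in enumerate(cols):
        if np.var(X[:, j]) == 0:
            raise ValueError(f"variable {c!r} is constant; VIF undefined")
    out = {}
    ones = np.ones((n, 1))
    for j, c in enumerate(cols):
        yj = X[:, j]
        Z = np.hstack([ones, np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(Z, yj, rcond=None)
        resid = yj - Z @ beta
        sst = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / sst
        out[c] = np.inf if (1.0 - r2) < _PERFECT_FIT_TOL else 1.0 / (1.0 - r2)
    return pd.Series(out)


@dataclass
class VifReport:
    """Trace of the stepwise screening: per-iteration VIFs and removals."""

    iterations: list = field(default_factory=list)  # {"vif": {...}, "removed": str|None}
    retained: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        def enc(v):
            return "inf" if np.isinf(v) else float(v)
        payload = {
            "iterations": [{"vif": {k: enc(v) for k, v in it["vif"].items()},
                            "removed": it["removed"]} for it in self.iterations],
            "retained": list(self.retained),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def select_predictors_vif(stack: PredictorStack, threshold: float = 10.0,
                          sample: int | None = 10000, seed: int = 0,
                          layer_names=None) -> VifReport:
    """Iteratively remove the highest-VIF layer while it exceeds threshold.

    VIF is computed on a seeded random subsample of at most ``sample``
    valid cells (``sample=None`` uses the full grid). Ties on the maximum
    VIF break by lexicographic layer name. By default all layers except
    ``elevation`` are screened.
    """
    if threshold <= 1:
        raise ValueError("threshold must be > 1")
    if layer_names is None:
        layer_names = [n for n in stack.layer_names if n != "elevation"]
    table = stack.table(layer_names)
    if sample is not None and len(table) > sample:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(table), size=sample, replace=False)
        table = table.iloc[np.sort(idx)]
    current = sorted(layer_names)
    report = VifReport()
    while len(current) >= 2:
        vifs = compute_vif(table[current])
        vifs = vifs.reindex(sorted(vifs.index))     # lexicographic tie-break
        worst = vifs.idxmax()
        if vifs[worst] > threshold:
            report.iterations.append({"vif": vifs.to_dict(), "removed": worst})
            current = [c for c in current if c != worst]
        else:
            report.iterations.append({"vif": vifs.to_dict(), "removed": None})
            break
    report.retained = current
    return report
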