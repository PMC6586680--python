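"""AUC-weighted consensus suitability modelling.

Calibration follows the weighted-average consensus approach: each learner
is scored by stratified k-fold cross-validated AUC (default k=4), AUCs are
normalised into weights, learners contributing more than a weight cutoff
(default 0.05, i.e. at least 5% of consensus predictivity) are retained
with weights renormalised to one, refit on all data, and the consensus
probability surface is binarised at the threshold maximising
sensitivity + specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .grid import PredictorStack
from .learners import Learner, default_learners, predict_presence_probability
from .occurrences import OccurrenceSet


def assign_folds(labels, k: int = 4, seed: int = 0) -> np.ndarray:
    """Stratified balanced random fold assignment.

    Within each class, rows are permuted and dealt round-robin across the
    k folds, so per-class fold sizes differ by at most one and every fold
    holds at least one row of each class (requires >= k rows per class).
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds = np.empty(len(labels), dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise ValueError(f"class {cls!r} has {len(idx)} rows, fewer than k={k}")
        perm = rng.permutation(idx)
        folds[perm] = np.arange(len(perm)) % k
    return folds


def compute_auc(presence_scores, absence_scores) -> float:
    """Area under the ROC curve via the rank-sum identity.

    Equals the fraction of (presence, absence) score pairs where the
    presence scores higher, counting ties as one half.
    """
    p = np.asarray(presence_scores, dtype=float)
    a = np.asarray(absence_scores, dtype=float)
    if p.size == 0 or a.size == 0:
        raise ValueError("presence and absence score lists must be non-empty")
    ranks = rankdata(np.concatenate([p, a]))
    n1, n0 = p.size, a.size
    return float((ranks[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def crossvalidate_learners(learners, X, y, folds, seed: int = 0):
    """Per-learner per-fold cross-validated AUC.

    Returns ``(auc_table, mean_auc, failures)``. A learner that raises or
    produces non-finite scores on any fold has its mean AUC set to 0.5
    (no discrimination) and the failure logged, rather than aborting the
    species.
    """
    learners = list(learners)
    if len(learners) < 2:
        raise ValueError("need at least 2 learners")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    folds = np.asarray(folds)
    k = int(folds.max()) + 1
    auc = pd.DataFrame(np.nan, index=[l.name for l in learners], columns=range(k))
    failures = []
    for li, learner in enumerate(learners):
        failed = False
        for f in range(k):
            test = folds == f
            try:
                est = learner.build(seed + li)
                est.fit(X[~test], y[~test])
                scores = predict_presence_probability(est, X[test])
                if not np.all(np.isfinite(scores)):
                    raise ValueError("non-finite scores")
                auc.loc[learner.name, f] = compute_auc(
                    scores[y[test] == 1], scores[y[test] == 0])
            except Exception as exc:  # noqa: BLE001 - failure policy by contract
                failures.append({"learner": learner.name, "fold": f, "error": str(exc)})
                failed = True
                break
        if failed:
            auc.loc[learner.name] = np.nan
    mean_auc = auc.mean(axis=1)
    mean_auc[mean_auc.isna()] = 0.5
    return auc, mean_auc, failures


@dataclass(frozen=True)
class WeightReport:
    """Raw AUC weights, the selected learner set and renormalised weights."""

    raw: dict
    selected: tuple
    final: dict


def compute_weights(mean_aucs, weight_cutoff: float = 0.05) -> WeightReport:
    """Normalise AUCs into weights and drop weak contributors.

    raw_i = AUC_i / sum(AUC); learners with raw weight strictly above
    ``weight_cutoff`` are selected and their weights renormalised to sum
    to one.
    """
    items = dict(mean_aucs)
    vals = np.array(list(items.values()), dtype=float)
    if np.any(vals < 0):
        raise ValueError("AUCs must be >= 0")
    total = vals.sum()
    if total <= 0:
        raise ValueError("at least one AUC must be positive")
    raw = {k: v / total for k, v in items.items()}
    selected = tuple(k for k, w in raw.items() if w > weight_cutoff)
    if not selected:
        raise ValueError("no learner exceeds the weight cutoff; cannot build consensus")
    sel_total = sum(raw[k] for k in selected)
    final = {k: raw[k] / sel_total for k in selected}
    return WeightReport(raw=raw, selected=selected, final=final)


def find_threshold_maxss(presence_scores, absence_scores) -> float:
    """Smallest threshold maximising sensitivity + specificity.

    Candidates are the unique observed scores; a point is classified
    presence iff its score >= threshold. The comparison is done in exact
    integer counts so ties resolve deterministically to the smallest
    maximiser (which maximises mapped presence area).
    """
    p = np.sort(np.asarray(presence_scores, dtype=float))
    a = np.sort(np.asarray(absence_scores, dtype=float))
    if p.size == 0 or a.size == 0:
        raise ValueError("presence and absence score lists must be non-empty")
    cand = np.unique(np.concatenate([p, a]))
    n1, n0 = p.size, a.size
    tp = n1 - np.searchsorted(p, cand, side="left")   # presences >= t
    tn = np.searchsorted(a, cand, side="left")        # absences < t
    # sens + spec = tp/n1 + tn/n0; compare as integers tp*n0 + tn*n1
    score = tp * n0 + tn * n1
    best = np.flatnonzero(score == score.max())[0]
    return float(cand[best])


def binarize(suitability: np.ndarray, threshold: float) -> np.ndarray:
    """Presence (1.0) iff suitability >= threshold; NaN mask preserved."""
    s = np.asarray(suitability, dtype=float)
    out = np.where(np.isnan(s), np.nan, (s >= threshold).astype(float))
    return out


@dataclass
class EnsembleCalibration:
    """Everything needed to project the consensus model.

    Holds the CV AUC table, raw/final weights with selection flags, the
    fitted final learners (refit on all rows) and the maxSS presence
    threshold derived from the training consensus scores.
    """

    predictor_names: list
    auc_table: pd.DataFrame
    mean_auc: pd.Series
    weights: WeightReport
    threshold: float
    models: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)
    seed: int = 0

    def predict_rows(self, X: np.ndarray) -> np.ndarray:
        """Consensus probability for a predictor matrix."""
        X = np.asarray(X, dtype=float)
        out = np.zeros(len(X))
        for name in self.weights.selected:
            out += self.weights.final[name] * predict_presence_probability(
                self.models[name], X)
        return out

    def summary(self) -> dict:
        """JSON-serialisable calibration summary."""
        return {
            "predictors": list(self.predictor_names),
            "auc_per_fold": {n: [None if pd.isna(v) else float(v)
                                 for v in self.auc_table.loc[n]]
                             for n in self.auc_table.index},
            "mean_auc": {k: float(v) for k, v in self.mean_auc.items()},
            "raw_weights": {k: float(v) for k, v in self.weights.raw.items()},
            "selected": list(self.weights.selected),
            "final_weights": {k: float(v) for k, v in self.weights.final.items()},
            "threshold": float(self.threshold),
            "failures": self.failures,
            "seed": self.seed,
        }


def fit_ensemble(occ: OccurrenceSet, stack: PredictorStack, predictor_names,
                 learners=None, k: int = 4, weight_cutoff: float = 0.05,
                 seed: int = 0) -> EnsembleCalibration:
    """Calibrate the consensus model for one species.

    Cross-validates every learner with stratified k-fold AUC, computes
    AUC weights with the selection cutoff, refits the selected learners
    on all rows, and sets the presence threshold by maximum
    sensitivity + specificity on the training consensus scores.
    """
    learners = list(learners) if learners is not None else default_learners()
    predictor_names = list(predictor_names)
    stack.require_layers(predictor_names)
    lon, lat, y = occ.labelled_points()
    row, col = stack.grid.cell_index(lon, lat)
    X = stack.values_at(row, col, predictor_names)
    keep = np.all(np.isfinite(X), axis=1)
    X, y = X[keep], y[keep]

    folds = assign_folds(y, k=k, seed=seed)
    auc_table, mean_auc, failures = crossvalidate_learners(learners, X, y, folds, seed=seed)
    weights = compute_weights(mean_auc.to_dict(), weight_cutoff=weight_cutoff)

    models = {}
    by_name = {l.name: l for l in learners}
    for li, name in enumerate(weights.selected):
        est = by_name[name].build(seed + 1000 + li)
        est.fit(X, y)
        models[name] = est

    calib = EnsembleCalibration(
        predictor_names=predictor_names, auc_table=auc_table, mean_auc=mean_auc,
        weights=weights, threshold=0.5, models=models, failures=failures, seed=seed)
    scores = calib.predict_rows(X)
    calib.threshold = find_threshold_maxss(scores[y == 1], scores[y == 0])
    return calib


def predict_consensus(calib: EnsembleCalibration, stack: PredictorStack) -> np.ndarray:
    """Consensus suitability raster in [0, 1]; masked cells stay NaN."""
    stack.require_layers(calib.predictor_names)
    r, c = stack.valid_rc()
    X = stack.values_at(r, c, calib.predictor_names)
    out = np.full(stack.grid.shape, np.nan)
    out[r, c] = calib.predict_rows(X)
    return out
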