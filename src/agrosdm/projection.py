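"""Multi-GCM projection and agreement voting.

The calibrated consensus is projected onto each GCM's future stack and
binarised with the baseline threshold; the resulting binary maps are then
integrated by a likelihood-scale vote: a cell keeps predicted presence
(or absence) only when at least an agreement fraction of GCMs (default
66%) concur. Cells reaching neither consensus are flagged uncertain and
treated as not suitable downstream, so ambiguity is conservative but not
destroyed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ensemble import EnsembleCalibration, binarize, predict_consensus


def vote_threshold(g: int, agreement: float) -> int:
    """Minimum concurring votes out of g: ceil(agreement * g).

    With 17 GCMs and 66% agreement this is 12. A tiny slack guards
    against float artefacts inflating an exact product (e.g. 0.66*50).
    """
    return math.ceil(agreement * g - 1e-9)


def project_scenario(calib: EnsembleCalibration, gcm_stacks, threshold: float) -> list[np.ndarray]:
    """One binary presence raster per GCM stack, using the baseline threshold."""
    maps = []
    for stack in gcm_stacks:
        suit = predict_consensus(calib, stack)
        maps.append(binarize(suit, threshold))
    return maps


def integrate_gcm_votes(binary_maps, agreement: float = 0.66) -> tuple[np.ndarray, np.ndarray]:
    """Integrate per-GCM binary maps by the >= agreement voting rule.

    A cell is presence when presence votes reach ``vote_threshold``,
    absence when absence votes do; cells meeting neither are flagged in
    the returned uncertainty raster and set to absence in the integrated
    raster. Returns ``(integrated, uncertain)``.
    """
    maps = [np.asarray(m, dtype=float) for m in binary_maps]
    g = len(maps)
    if g < 1:
        raise ValueError("need at least one binary map")
    if not (0.5 < agreement <= 1.0):
        raise ValueError("agreement must be in (0.5, 1]")
    shape = maps[0].shape
    for m in maps[1:]:
        if m.shape != shape:
            raise ValueError("binary maps have mismatched grids")
    votes = np.sum(maps, axis=0)   # NaN propagates through masked cells
    need = vote_threshold(g, agreement)
    presence = votes >= need
    absence = (g - votes) >= need
    uncertain = ~presence & ~absence & ~np.isnan(votes)
    integrated = np.where(np.isnan(votes), np.nan, presence.astype(float))
    return integrated, uncertain


@dataclass
class ProjectionSet:
    """Per-GCM binary maps for one scenario plus the integrated result."""

    scenario: str
    gcm_maps: list
    integrated: np.ndarray
    uncertain: np.ndarray


def project_and_integrate(calib: EnsembleCalibration, gcm_stacks, scenario: str,
                          agreement: float = 0.66) -> ProjectionSet:
    """Convenience wrapper: project every GCM then integrate the votes."""
    maps = project_scenario(calib, gcm_stacks, calib.threshold)
    integrated, uncertain = integrate_gcm_votes(maps, agreement=agreement)
    return ProjectionSet(scenario=scenario, gcm_maps=maps,
                         integrated=integrated, uncertain=uncertain)
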