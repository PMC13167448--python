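"""Boyce-weighted ensembles and suitability binarization.

Models that cleared the retention bar (cross-validated Boyce index strictly
greater than 0.6) are averaged with weights proportional to their Boyce
scores.  The continuous ensemble is then cut into suitable / non-suitable
cells at the species' Boyce-maximization threshold: the lowest suitability
window midpoint above which presences are observed at least as often as the
available environment would predict (the stable P/E >= 1 crossing of the
Boyce curve).  The current-conditions threshold is reused unchanged for all
future projections of that species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sdm import BoyceCurve, FittedSDM, boyce_curve
from .world import Landscape

RETENTION_THRESHOLD = 0.6


class UnmodellableSpeciesError(RuntimeError):
    """No model family cleared the retention bar for this species."""


class NoThresholdError(RuntimeError):
    """The P/E curve never stabilizes at >= 1: no binarization threshold."""


@dataclass
class EnsembleModel:
    """Retained models with Boyce-proportional weights for one predictor set."""

    species_id: str
    predictor_set: str
    members: list[FittedSDM]
    weights: np.ndarray
    retention_threshold: float = RETENTION_THRESHOLD
    binarization_threshold: float | None = None
    projections: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def predictor_names(self) -> tuple[str, ...]:
        return self.members[0].predictor_names


def build_ensemble(
    models: list[FittedSDM],
    species_id: str = "",
    predictor_set: str = "",
    retention_threshold: float = RETENTION_THRESHOLD,
) -> EnsembleModel:
    """Retain models with cv_boyce strictly above the threshold and weight them.

    Weights are cv_boyce_k / sum(cv_boyce) over retained members.  With no
    retained member the species is unmodellable for this predictor set and
    :class:`UnmodellableSpeciesError` is raised (callers log and skip).
    """
    if not models:
        raise ValueError("need at least one candidate model")
    retained = [m for m in models if np.isfinite(m.cv_boyce) and m.cv_boyce > retention_threshold]
    if not retained:
        raise UnmodellableSpeciesError(
            f"species {species_id or '<unknown>'}: no model exceeded "
            f"Boyce {retention_threshold} for predictor set {predictor_set or '<unset>'}"
        )
    scores = np.array([m.cv_boyce for m in retained], dtype=float)
    return EnsembleModel(
        species_id=species_id,
        predictor_set=predictor_set,
        members=retained,
        weights=scores / scores.sum(),
        retention_threshold=retention_threshold,
    )


def predict_ensemble(
    ensemble: EnsembleModel,
    landscape: Landscape,
    register: bool = True,
) -> np.ndarray:
    """Cellwise Boyce-weighted mean suitability over the landscape's land cells.

    Returns a full raster (NaN at sea); the result is registered on the
    ensemble under the landscape's scenario tag.
    """
    names = list(ensemble.predictor_names)
    missing = [n for n in names if n not in landscape.layers]
    if missing:
        raise KeyError(f"landscape lacks predictor layer(s) {missing}")
    env = landscape.land_table(names)
    preds = np.stack([m.predict(env) for m in ensemble.members])
    combined = ensemble.weights @ preds
    raster = np.full(landscape.shape, np.nan)
    raster[landscape.land_mask] = np.clip(combined, 0.0, 1.0)
    if register:
        ensemble.projections[landscape.scenario] = raster
    return raster


def boyce_max_threshold(
    suitability_at_presences: np.ndarray,
    suitability_at_background: np.ndarray,
    mode: str = "crossing",
    window_width: float = 0.1,
    n_windows: int = 101,
) -> tuple[float, BoyceCurve]:
    """Binarization threshold from the ensemble's current Boyce curve.

    mode="crossing" (default): the lowest retained midpoint m such that
    F = P/E >= 1 at m and at every retained midpoint above m.  If F >= 1
    everywhere the threshold is the lowest midpoint; if the curve never ends
    at F >= 1, :class:`NoThresholdError` is raised and the species is flagged.

    mode="first_crossing": the lowest retained midpoint with F >= 1, without
    requiring stability above it.
    """
    curve = boyce_curve(
        suitability_at_presences, suitability_at_background, window_width, n_windows
    )
    F = curve.ratios
    ok = F >= 1.0
    if mode == "crossing":
        # longest suffix of retained windows with F >= 1
        if not ok[-1]:
            raise NoThresholdError("P/E ratio below 1 in the top suitability window")
        below = np.flatnonzero(~ok)
        start = 0 if below.size == 0 else below[-1] + 1
        return float(curve.midpoints[start]), curve
    if mode == "first_crossing":
        idx = np.flatnonzero(ok)
        if idx.size == 0:
            raise NoThresholdError("P/E ratio never reaches 1")
        return float(curve.midpoints[idx[0]]), curve
    raise ValueError(f"unknown threshold mode {mode!r}")


def binarize(suitability: np.ndarray, threshold: float, land_mask: np.ndarray | None = None) -> np.ndarray:
    """Binary suitable/non-suitable map: 1 iff suitability >= threshold."""
    binary = (np.nan_to_num(suitability, nan=-np.inf) >= threshold).astype(np.uint8)
    if land_mask is not None:
        binary = np.where(land_mask, binary, 0).astype(np.uint8)
    return binary
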