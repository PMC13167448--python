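"""Pseudo-absence design: surface range envelope + target-group sampling.

With presence-only data, the models need background ("pseudo-absence")
points.  For each species we draw exactly as many pseudo-absences as there
are presences, from land cells *outside* a per-variable quantile envelope of
the presence climate (so PAs are climatically distinct from presences), with
selection probability proportional to the sampling-effort field.  The
effort weighting is the target-group bias correction: background points
inherit the same observation bias as the presences, so the bias cancels in
the fitted presence/background contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import derive_seed
from .world import Landscape, SamplingEffort


class InsufficientEligibleCellsError(RuntimeError):
    """Raised when fewer eligible cells exist than pseudo-absences requested."""


@dataclass(frozen=True)
class SREnvelope:
    """Per-variable quantile box in climatic space.

    A cell is *inside* iff every variable lies within [lower, upper]
    inclusive.  Bounds are the empirical q and 1-q quantiles (linear
    interpolation) of the presence values.
    """

    lower: dict[str, float]
    upper: dict[str, float]
    q: float

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.lower)

    def inside(self, env: pd.DataFrame) -> np.ndarray:
        ok = np.ones(len(env), dtype=bool)
        for v in self.variables:
            x = env[v].to_numpy(dtype=float)
            ok &= (x >= self.lower[v]) & (x <= self.upper[v])
        return ok


@dataclass
class PseudoAbsenceSet:
    """Sampled background records mirroring the occurrence schema."""

    species_id: str
    data: pd.DataFrame
    seed: int


def fit_sre(presence_env: pd.DataFrame, q: float = 0.025) -> SREnvelope:
    """Fit the surface range envelope from presence environment values."""
    if len(presence_env) < 2:
        raise ValueError("need at least two presence records to fit an envelope")
    if not 0 <= q < 0.5:
        raise ValueError(f"envelope quantile must satisfy 0 <= q < 0.5, got {q}")
    lower, upper = {}, {}
    for v in presence_env.columns:
        x = presence_env[v].to_numpy(dtype=float)
        lower[v] = float(np.quantile(x, q))
        upper[v] = float(np.quantile(x, 1 - q))
    return SREnvelope(lower=lower, upper=upper, q=q)


def sample_pa(
    envelope: SREnvelope,
    landscape: Landscape,
    effort: SamplingEffort,
    n: int,
    seed: int,
    species_id: str = "",
    exclude_cells: np.ndarray | None = None,
) -> PseudoAbsenceSet:
    """Draw ``n`` pseudo-absences outside the envelope, weighted by effort.

    Sampling is without replacement over {land cells outside the envelope},
    minus any ``exclude_cells`` (presence cells are never eligible, even when
    they fall outside the envelope).
    """
    if n < 1:
        raise ValueError("need n >= 1 pseudo-absences")
    cells = landscape.land_cells()
    env = landscape.env_at(cells[:, 0], cells[:, 1])
    eligible = ~envelope.inside(env[list(envelope.variables)])
    if exclude_cells is not None and len(exclude_cells):
        occupied = set(map(tuple, np.asarray(exclude_cells)))
        eligible &= np.fromiter(
            (tuple(c) not in occupied for c in cells), dtype=bool, count=len(cells)
        )
    idx_pool = np.flatnonzero(eligible)
    if len(idx_pool) < n:
        raise InsufficientEligibleCellsError(
            f"only {len(idx_pool)} land cells outside the envelope for {n} "
            "pseudo-absences; reduce the envelope quantile q"
        )
    w = effort.values[cells[idx_pool, 0], cells[idx_pool, 1]].astype(float)
    w = w / w.sum()
    rng = np.random.default_rng(derive_seed(seed, "pseudoabsence", species_id))
    chosen = rng.choice(idx_pool, size=n, replace=False, p=w)
    rows, cols = cells[chosen, 0], cells[chosen, 1]
    data = landscape.env_at(rows, cols)
    data.insert(0, "col", cols)
    data.insert(0, "row", rows)
    return PseudoAbsenceSet(species_id=species_id, data=data, seed=seed)
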