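"""Occurrence-record preparation: spatial dedup, environmental thinning,
and the minimum-record rule.

Presence-only records arrive with heavy spatial and environmental sampling
bias; the three filters here reduce pseudoreplication (one record per grid
cell), balance representation across environmental space (one record per
occupied bin of a coarse multidimensional environmental grid) and drop
species left with too few records to model.  The pipeline order is fixed:
dedup -> environmental filter -> minimum-record rule.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._util import derive_seed

STAGES = ("raw", "deduped", "env_filtered")


@dataclass
class OccurrenceSet:
    """Per-species presence records with cell indices and environment values.

    ``data`` holds one record per row: ``row``, ``col`` plus one column per
    environmental layer; ``stage`` tracks progress through the filter chain.
    """

    species_id: str
    data: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    def __len__(self) -> int:
        return len(self.data)

    def cells(self) -> np.ndarray:
        return self.data[["row", "col"]].to_numpy()


def dedupe_spatial(occ: OccurrenceSet) -> OccurrenceSet:
    """Keep one record per occupied grid cell (first in input order).

    Idempotent: running it on an already-deduplicated set is a no-op.
    """
    if occ.stage not in ("raw", "deduped"):
        raise ValueError(f"dedupe_spatial expects stage 'raw' or 'deduped', got {occ.stage!r}")
    data = occ.data.drop_duplicates(subset=["row", "col"], keep="first").reset_index(drop=True)
    return replace(occ, data=data, stage="deduped")


def env_filter(
    occ: OccurrenceSet,
    layers: tuple[str, ...] | list[str],
    n_bins: int = 6,
    seed: int = 0,
) -> OccurrenceSet:
    """Thin records to one per occupied bin of the environmental grid.

    Each climatic variable of the active predictor set is cut into ``n_bins``
    equal-width bins spanning that species' own occurrence range; one record
    is retained uniformly at random per occupied multidimensional bin.  The
    top edge is right-closed (the maximum joins the top bin); a variable that
    is constant across records contributes a single bin.
    """
    if occ.stage != "deduped":
        raise ValueError(f"env_filter expects stage 'deduped', got {occ.stage!r}")
    if len(occ.data) == 0:
        return replace(occ, stage="env_filtered")

    bin_idx = np.zeros((len(occ.data), len(layers)), dtype=np.int64)
    for j, name in enumerate(layers):
        x = occ.data[name].to_numpy(dtype=float)
        lo, hi = x.min(), x.max()
        if hi == lo:
            continue  # constant variable: single bin
        width = (hi - lo) / n_bins
        bin_idx[:, j] = np.minimum(((x - lo) / width).astype(np.int64), n_bins - 1)

    rng = np.random.default_rng(derive_seed(seed, "env_filter", occ.species_id))
    key = pd.Series(map(tuple, bin_idx), index=occ.data.index)
    keep = []
    for _, grp in occ.data.groupby(key, sort=True):
        keep.append(grp.index[rng.integers(len(grp))])
    data = occ.data.loc[sorted(keep)].reset_index(drop=True)
    return replace(occ, data=data, stage="env_filtered")


def min_records_filter(occ: OccurrenceSet, threshold: int = 30) -> bool:
    """Accept a species only if it retains at least ``threshold`` records."""
    if occ.stage != "env_filtered":
        raise ValueError(f"min_records_filter expects stage 'env_filtered', got {occ.stage!r}")
    return len(occ.data) >= threshold


def prepare_species(
    occ: OccurrenceSet,
    climatic_layers: tuple[str, ...] | list[str],
    n_bins: int = 6,
    min_records: int = 30,
    seed: int = 0,
) -> tuple[OccurrenceSet, bool, dict]:
    """Run the full filter chain; returns (filtered set, accepted, report)."""
    deduped = dedupe_spatial(occ)
    filtered = env_filter(deduped, climatic_layers, n_bins=n_bins, seed=seed)
    accepted = min_records_filter(filtered, threshold=min_records)
    report = {
        "species_id": occ.species_id,
        "raw_n": len(occ),
        "deduped_n": len(deduped),
        "filtered_n": len(filtered),
        "accepted": accepted,
    }
    return filtered, accepted, report
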