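"""Richness stacking and derived invasion-risk analytics.

Single-species binary maps are summed into potential richness per grid cell;
from the stack come invasion hotspots (cells suitable for more than a set
fraction of the modelled pool), absolute/proportional change maps, per-cell
species turnover (Jaccard dissimilarity between current and future suitable
sets), a coefficient-of-variation uncertainty surface across ensemble
members, and the dispersal-limited sensitivity that keeps only continents
where a species is already naturalized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class HotspotResult:
    """Hotspot mask at one pool fraction.

    ``cutoff`` is floor(fraction x pool size); a cell is a hotspot iff its
    richness strictly exceeds the cutoff.  Future maps reuse the cutoff
    established under current conditions.
    """

    pool_size: int
    fraction: float
    cutoff: int
    mask: np.ndarray
    land_fraction: float


def hotspot_cutoff(pool_size: int, fraction: float = 0.10) -> int:
    if pool_size <= 0:
        raise ValueError("modelled pool size must be positive")
    if not 0 < fraction < 1:
        raise ValueError("hotspot fraction must lie in (0, 1)")
    return math.floor(fraction * pool_size)


def stack_richness(binary_maps) -> np.ndarray:
    """Cellwise integer sum of single-species binary maps."""
    maps = list(binary_maps)
    if not maps:
        raise ValueError("need at least one binary map")
    shape = maps[0].shape
    for m in maps:
        if m.shape != shape:
            raise ValueError(f"grid mismatch: {m.shape} vs {shape}")
    return np.sum(np.stack(maps).astype(np.int64), axis=0)


def hotspot_map(
    richness: np.ndarray,
    pool_size: int,
    land_mask: np.ndarray,
    fraction: float = 0.10,
    cutoff: int | None = None,
) -> HotspotResult:
    """Hotspots: land cells with richness > cutoff (strict).

    Pass ``cutoff`` explicitly to evaluate a future stack against the cutoff
    fixed under current conditions.
    """
    c = hotspot_cutoff(pool_size, fraction) if cutoff is None else int(cutoff)
    mask = (richness > c) & land_mask
    n_land = int(land_mask.sum())
    return HotspotResult(
        pool_size=pool_size,
        fraction=fraction,
        cutoff=c,
        mask=mask,
        land_fraction=float(mask.sum() / n_land) if n_land else float("nan"),
    )


def change_maps(current: np.ndarray, future: np.ndarray, land_mask: np.ndarray):
    """Absolute and proportional richness change (proportional NaN where current=0)."""
    if current.shape != future.shape:
        raise ValueError("grid mismatch between current and future richness")
    absolute = np.where(land_mask, future.astype(float) - current.astype(float), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        proportional = absolute / current.astype(float)
    proportional = np.where(land_mask & (current > 0), proportional, np.nan)
    return absolute, proportional


def turnover(current_stack: np.ndarray, future_stack: np.ndarray) -> np.ndarray:
    """Per-cell Jaccard dissimilarity between current and future suitable sets.

    Inputs are (n_species, nrows, ncols) boolean/0-1 stacks over the same
    pool.  0 = identical suitable-species list, 1 = no species in common;
    cells with both sets empty score 0.
    """
    cur = np.asarray(current_stack, dtype=bool)
    fut = np.asarray(future_stack, dtype=bool)
    if cur.shape != fut.shape:
        raise ValueError("stacks must share species pool and grid")
    inter = np.sum(cur & fut, axis=0).astype(float)
    union = np.sum(cur | fut, axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = 1.0 - inter / union
    return np.where(union > 0, t, 0.0)


def cv_map(member_richness) -> np.ndarray:
    """Coefficient of variation (sd/mean, n-1 denominator) across members.

    NaN where the member mean is zero (CV undefined).
    """
    members = np.stack(list(member_richness)).astype(float)
    if members.shape[0] < 2:
        raise ValueError("need at least two ensemble members for a CV map")
    mean = members.mean(axis=0)
    sd = members.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    return np.where(mean > 0, cv, np.nan)


def continental_filter(
    binary_map: np.ndarray,
    naturalized_continents: frozenset[int] | set[int],
    continents: np.ndarray,
) -> np.ndarray:
    """Zero suitability outside continents where the species is naturalized."""
    if not naturalized_continents:
        raise ValueError("naturalized-continent set is empty")
    allowed = np.isin(continents, sorted(naturalized_continents))
    return np.where(allowed, binary_map, 0).astype(binary_map.dtype)


def hotspot_persistence(current: HotspotResult, future: HotspotResult) -> float:
    """Percentage of current hotspot cells that remain hotspots in the future."""
    if current.mask.shape != future.mask.shape:
        raise ValueError("hotspot grids do not match")
    if current.cutoff != future.cutoff:
        raise ValueError("persistence requires a shared richness cutoff")
    n_cur = int(current.mask.sum())
    if n_cur == 0:
        raise ValueError("no current hotspot cells; persistence undefined")
    return 100.0 * float((current.mask & future.mask).sum()) / n_cur
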