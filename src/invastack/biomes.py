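"""Biome-space analytics: Whittaker assignment, weighted kernel density,
centroids and per-biome richness means.

Every land cell is placed in (mean annual temperature deg C, annual
precipitation cm) space and assigned to one of nine Whittaker biomes using
the packaged polygon fixture; richness-weighted kernel density in that space
yields a centroid and a 95% contour whose shift between scenarios summarizes
how invasion risk moves through climate space.  Assignment always uses the
current climate — biome locations are held fixed under future scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.stats import gaussian_kde
from shapely.geometry import Polygon
from skimage import measure

from .whittaker_synthetic import BIOME_NAMES, BIOME_POLYGONS
from .world import Landscape


def biome_polygons() -> dict[int, Polygon]:
    """The packaged biome polygons as shapely geometries, keyed by biome id."""
    polys = {}
    for bid, (_, verts) in BIOME_POLYGONS.items():
        poly = Polygon(verts)
        if not poly.is_valid or poly.area == 0:
            raise ValueError(f"degenerate biome polygon for id {bid}")
        polys[bid] = poly
    return polys


def assign_biome(
    temp_c: np.ndarray,
    precip_cm: np.ndarray,
    polygons: dict[int, Polygon] | None = None,
) -> np.ndarray:
    """Assign each (T, P) point to a biome id.

    Point-in-polygon (boundary inclusive) in ascending biome-id order, so a
    point on a shared edge takes the lowest id.  Points outside every polygon
    go to the nearest polygon by Euclidean distance in standardized (T, P)
    space (each axis divided by its sd over the input points).
    """
    if polygons is None:
        polygons = biome_polygons()
    T = np.asarray(temp_c, dtype=float).ravel()
    P = np.asarray(precip_cm, dtype=float).ravel()
    pts = shapely.points(T, P)
    labels = np.zeros(T.size, dtype=np.int32)
    for bid in sorted(polygons):
        unset = labels == 0
        if not unset.any():
            break
        inside = shapely.covers(polygons[bid], pts[unset])
        idx = np.flatnonzero(unset)[inside]
        labels[idx] = bid
    unset = labels == 0
    if unset.any():
        t_sd = T.std() or 1.0
        p_sd = P.std() or 1.0
        pts_std = shapely.points(T[unset] / t_sd, P[unset] / p_sd)
        dists = np.stack([
            shapely.distance(
                shapely.transform(polygons[bid], lambda c: c / np.array([t_sd, p_sd])),
                pts_std,
            )
            for bid in sorted(polygons)
        ])
        nearest = np.argmin(dists, axis=0)  # argmin ties -> lowest biome id
        labels[unset] = np.array(sorted(polygons))[nearest]
    return labels.reshape(np.asarray(temp_c).shape)


def assign_biome_landscape(landscape: Landscape, polygons=None) -> np.ndarray:
    """Biome raster for a landscape (0 at sea); precipitation converted mm->cm."""
    land = landscape.land_mask
    labels = np.zeros(landscape.shape, dtype=np.int32)
    labels[land] = assign_biome(
        landscape.layers["temp_mean"][land],
        landscape.layers["precip_annual"][land] / 10.0,
        polygons,
    )
    return labels


@dataclass
class DensitySummary:
    """Weighted kernel-density summary of richness in biome space."""

    centroid: tuple[float, float]
    level: float
    contours: list[np.ndarray]
    mass_inside: float


def richness_density(
    points: np.ndarray,
    weights: np.ndarray,
    grid_n: int = 256,
    mass: float = 0.95,
) -> DensitySummary:
    """Richness-weighted centroid and 95% kernel contour in (T, P) space.

    The centroid is the weighted mean of the points.  A 2-D Gaussian KDE with
    the normal-reference (Scott) bandwidth on the weighted points is
    evaluated on a ``grid_n`` x ``grid_n`` grid; the contour level is the
    highest density value whose superlevel set holds at least ``mass`` of the
    kernel mass on the grid (numerical quadrature), and the returned
    polylines trace that level set in data coordinates.
    """
    pts = np.asarray(points, dtype=float)
    w = np.asarray(weights, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if len(pts) < 10:
        raise ValueError("need at least 10 weighted points")
    if (w < 0).any() or w.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")

    centroid = tuple(np.average(pts, axis=0, weights=w))

    try:
        kde = gaussian_kde(pts.T, weights=w)
    except (np.linalg.LinAlgError, ValueError):
        # weight effectively on a single point: centroid is defined, the
        # kernel is degenerate — report no contour
        return DensitySummary(centroid=centroid, level=float("nan"),
                              contours=[], mass_inside=float("nan"))
    pad = 3.0 * np.sqrt(np.diag(kde.covariance))
    lo = pts.min(axis=0) - pad
    hi = pts.max(axis=0) + pad
    xs = np.linspace(lo[0], hi[0], grid_n)
    ys = np.linspace(lo[1], hi[1], grid_n)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    dens = kde(np.vstack([gx.ravel(), gy.ravel()])).reshape(grid_n, grid_n)

    cell_area = (xs[1] - xs[0]) * (ys[1] - ys[0])
    flat = np.sort(dens.ravel())[::-1]
    cum = np.cumsum(flat) * cell_area
    total = cum[-1]
    k = int(np.searchsorted(cum, mass * total))
    level = float(flat[min(k, flat.size - 1)])
    mass_inside = float((dens[dens >= level].sum() * cell_area) / total)

    contours = []
    for seg in measure.find_contours(dens, level):
        xy = np.column_stack([
            np.interp(seg[:, 0], np.arange(grid_n), xs),
            np.interp(seg[:, 1], np.arange(grid_n), ys),
        ])
        contours.append(xy)
    return DensitySummary(centroid=centroid, level=level, contours=contours, mass_inside=mass_inside)


def biome_means(richness: np.ndarray, assignment: np.ndarray, land_mask: np.ndarray) -> pd.DataFrame:
    """Mean richness per biome plus a global row; empty biomes are absent."""
    r = richness[land_mask].astype(float)
    a = assignment[land_mask]
    rows = []
    for bid in sorted(np.unique(a)):
        rows.append({
            "biome_id": int(bid),
            "biome": BIOME_NAMES.get(int(bid), "unknown"),
            "n_cells": int((a == bid).sum()),
            "mean_richness": float(r[a == bid].mean()),
        })
    rows.append({
        "biome_id": 0,
        "biome": "global",
        "n_cells": int(land_mask.sum()),
        "mean_richness": float(r.mean()),
    })
    return pd.DataFrame(rows)
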