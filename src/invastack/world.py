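"""Synthetic landscapes, future scenarios, sampling effort and virtual species.

The generator builds a small gridded world whose layers mimic the structure of
the predictor stack used for global plant-invasion modelling: bioclim-like
temperature and precipitation summaries, a natural land-use fraction and soil
pH, for a current baseline and two future scenarios (mild / severe), each in
two "climate-model analogue" realizations.  Species are virtual: their niche
is a product of independent Gaussian responses, so the true suitability
surface is known in closed form and downstream models can be scored against
it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ._util import derive_seed, smooth_field

LAYER_NAMES = (
    "temp_mean",
    "temp_range",
    "temp_seasonality",
    "temp_warmq",
    "precip_annual",
    "precip_seasonality",
    "precip_warmq",
    "landuse_natural_fraction",
    "soil_ph",
)

#: The two alternative predictor sets used in parallel throughout the
#: pipeline.  Layers may correlate freely *across* sets (e.g. warmest-quarter
#: temperature tracks annual mean temperature, as bio10 tracks bio1); the
#: collinearity screen applies within each set only.
PREDICTOR_SETS: dict[str, tuple[str, ...]] = {
    "set1": (
        "temp_mean",
        "temp_range",
        "precip_annual",
        "precip_seasonality",
        "landuse_natural_fraction",
        "soil_ph",
    ),
    "set2": (
        "temp_seasonality",
        "temp_warmq",
        "precip_seasonality",
        "precip_warmq",
        "landuse_natural_fraction",
        "soil_ph",
    ),
}

#: Climatic members of each predictor set (land use and soil pH excluded);
#: these drive environmental filtering and the surface range envelope.
CLIMATIC_SETS: dict[str, tuple[str, ...]] = {
    name: tuple(v for v in layers if v not in ("landuse_natural_fraction", "soil_ph"))
    for name, layers in PREDICTOR_SETS.items()
}

SCENARIOS = ("current", "mild_r1", "mild_r2", "severe_r1", "severe_r2")
FUTURE_SCENARIOS = SCENARIOS[1:]


@dataclass(frozen=True)
class ScenarioParams:
    """Additive/multiplicative changes defining the two future scenarios.

    Temperature shifts are in degrees C, precipitation change is a multiplier,
    land-use change is an additive change of the natural fraction.  The mild
    scenario is a sustainability pathway (slight warming, recovering natural
    vegetation); the severe one is a fossil-fuelled pathway (strong warming,
    drying, natural-vegetation loss).  ``noise_amplitude_*`` scales the smooth
    realization noise that stands in for the spread between climate models.
    """

    delta_temp_mild: float = 2.0
    delta_temp_severe: float = 4.5
    precip_factor_mild: float = 1.05
    precip_factor_severe: float = 0.90
    landuse_delta_mild: float = 0.05
    landuse_delta_severe: float = -0.10
    noise_amplitude_temp: float = 0.6
    noise_amplitude_precip: float = 0.05
    noise_amplitude_landuse: float = 0.02

    def __post_init__(self) -> None:
        if not self.delta_temp_mild < self.delta_temp_severe:
            raise ValueError(
                "mild temperature shift must be smaller than the severe one "
                f"(got {self.delta_temp_mild} >= {self.delta_temp_severe})"
            )
        if self.noise_amplitude_temp >= self.delta_temp_mild:
            raise ValueError("realization noise must not swamp the mild warming signal")


@dataclass
class Landscape:
    """A multi-layer gridded environment for one scenario tag.

    Grid indexing is 0-based (row, col), row-major, unit cell size, no CRS.
    ``continents`` holds small positive integers on land and 0 at sea.
    """

    scenario: str
    layers: dict[str, np.ndarray]
    land_mask: np.ndarray
    continents: np.ndarray
    seed: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.land_mask.shape

    @property
    def n_land(self) -> int:
        return int(self.land_mask.sum())

    def land_cells(self) -> np.ndarray:
        """(n_land, 2) array of (row, col) land-cell indices, row-major order."""
        return np.argwhere(self.land_mask)

    def land_table(self, names: tuple[str, ...] | list[str] = LAYER_NAMES) -> pd.DataFrame:
        """Layer values over land cells, one row per land cell (row-major)."""
        return pd.DataFrame({n: self.layers[n][self.land_mask] for n in names})

    def env_at(self, rows, cols, names: tuple[str, ...] | list[str] = LAYER_NAMES) -> pd.DataFrame:
        return pd.DataFrame({n: self.layers[n][rows, cols] for n in names})

    def land_env(self, names: tuple[str, ...] | list[str] = LAYER_NAMES) -> pd.DataFrame:
        """Like :meth:`land_table` but with leading row/col coordinate columns."""
        cells = self.land_cells()
        df = self.env_at(cells[:, 0], cells[:, 1], names)
        df.insert(0, "col", cells[:, 1])
        df.insert(0, "row", cells[:, 0])
        return df


@dataclass
class SamplingEffort:
    """Normalized sampling-intensity field (sums to 1 over land, 0 at sea)."""

    values: np.ndarray
    seed: int

    def land_values(self, land_mask: np.ndarray) -> np.ndarray:
        return self.values[land_mask]


@dataclass
class VirtualSpecies:
    """A simulated species with a known Gaussian-product niche.

    ``suitability`` is the true suitability surface S*, rescaled so its
    maximum over land is 1; ``niche`` maps layer name -> (mu, sigma).
    """

    species_id: str
    niche: dict[str, tuple[float, float]]
    suitability: np.ndarray
    naturalized_continents: frozenset[int]
    lam: float

    def __post_init__(self) -> None:
        if not self.naturalized_continents:
            raise ValueError("naturalized-continent set must be non-empty")
        for v, (_, sigma) in self.niche.items():
            if sigma <= 0:
                raise ValueError(f"niche breadth for {v!r} must be positive")


@dataclass(frozen=True)
class NicheConfig:
    """How virtual-species niches are drawn.

    Optima are sampled uniformly between the given quantiles of each layer
    over land; breadths are uniform multiples of the layer's land sd.  The
    expected raw record count ``lam`` feeds a Poisson draw per species.
    """

    layers: tuple[str, ...] = ("temp_mean", "precip_annual")
    mu_quantiles: tuple[float, float] = (0.15, 0.85)
    # breadths of 0.35-0.9 environmental sd yield suitable-area prevalences
    # around 0.01-0.3 of land (median ~0.15), the conventional range for
    # virtual-species benchmarks
    sigma_sd_range: tuple[float, float] = (0.35, 0.9)
    lam: float = 500.0


def _pearson_max(layers: dict[str, np.ndarray], names: tuple[str, ...], mask: np.ndarray) -> float:
    mat = np.vstack([layers[n][mask] for n in names])
    r = np.corrcoef(mat)
    np.fill_diagonal(r, 0.0)
    return float(np.nanmax(np.abs(r)))


def _make_land(rng: np.random.Generator, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Land mask + continent labels from a thresholded smooth blob field.

    Components smaller than ``min_cells`` are dropped from land so that every
    continent is big enough to host occurrences; at least two continents are
    required (caller retries with fresh noise otherwise).
    """
    min_cells = 20
    blob = smooth_field(rng, shape, sigma=min(shape) / 8)
    land = blob > np.quantile(blob, 0.30)
    labels, n = ndimage.label(land)
    sizes = np.bincount(labels.ravel())
    keep = np.flatnonzero(sizes >= min_cells)
    keep = keep[keep != 0]
    land = np.isin(labels, keep)
    labels = np.where(land, labels, 0)
    # relabel 1..K in size order for stable small ids
    relabel = np.zeros(sizes.size, dtype=np.int32)
    order = sorted(keep, key=lambda k: -sizes[k])
    for new, old in enumerate(order, start=1):
        relabel[old] = new
    return land, relabel[labels]


def _base_layers(rng: np.random.Generator, shape: tuple[int, int]) -> dict[str, np.ndarray]:
    nr, nc = shape
    sig = min(shape) / 10
    lat = np.linspace(-10.0, 28.0, nr)[:, None] * np.ones((1, nc))

    z_t = smooth_field(rng, shape, sig)
    z_tr = smooth_field(rng, shape, sig)
    z_p = smooth_field(rng, shape, sig)
    z_ps = smooth_field(rng, shape, sig)
    z_lu = smooth_field(rng, shape, sig)
    z_ph = smooth_field(rng, shape, sig)
    z_aux = smooth_field(rng, shape, sig)

    temp_mean = lat + 3.0 * z_t
    temp_range = np.clip(14.0 + 5.0 * z_tr, 2.0, None)
    precip_annual = np.clip(800.0 * np.exp(0.8 * z_p), 10.0, 4500.0)

    layers = {
        "temp_mean": temp_mean,
        "temp_range": temp_range,
        # bio4-like: tracks the annual range plus its own noise (cross-set
        # correlation is intended; the two never share a predictor set)
        "temp_seasonality": np.clip(5.0 + 1.5 * (temp_range - 14.0) / 5.0 + 0.8 * z_aux, 0.5, None),
        "temp_warmq": temp_mean + 9.0 + 1.2 * smooth_field(rng, shape, sig),
        "precip_annual": precip_annual,
        "precip_seasonality": np.clip(45.0 + 22.0 * z_ps, 1.0, None),
        "precip_warmq": np.clip(precip_annual * (0.35 + 0.10 * smooth_field(rng, shape, sig)), 1.0, None),
        "landuse_natural_fraction": np.clip(0.5 + 0.25 * z_lu, 0.0, 1.0),
        "soil_ph": np.clip(6.3 + 0.8 * z_ph, 3.5, 9.0),
    }
    return layers


def _future_layers(
    current: dict[str, np.ndarray],
    rng: np.random.Generator,
    delta_temp: float,
    precip_factor: float,
    landuse_delta: float,
    params: ScenarioParams,
) -> dict[str, np.ndarray]:
    shape = current["temp_mean"].shape
    sig = min(shape) / 10
    a_t, a_p, a_lu = (
        params.noise_amplitude_temp,
        params.noise_amplitude_precip,
        params.noise_amplitude_landuse,
    )
    noise_t = a_t * smooth_field(rng, shape, sig)
    noise_p = 1.0 + a_p * smooth_field(rng, shape, sig)
    noise_lu = a_lu * smooth_field(rng, shape, sig)

    out = {}
    out["temp_mean"] = current["temp_mean"] + delta_temp + noise_t
    out["temp_warmq"] = current["temp_warmq"] + delta_temp + noise_t
    out["temp_range"] = current["temp_range"] + 0.3 * delta_temp + 0.5 * noise_t
    out["temp_seasonality"] = np.clip(
        current["temp_seasonality"] + 0.1 * delta_temp + 0.2 * noise_t, 0.5, None
    )
    out["precip_annual"] = np.clip(current["precip_annual"] * precip_factor * noise_p, 1.0, None)
    out["precip_warmq"] = np.clip(current["precip_warmq"] * precip_factor * noise_p, 1.0, None)
    out["precip_seasonality"] = np.clip(current["precip_seasonality"] * noise_p, 1.0, None)
    out["landuse_natural_fraction"] = np.clip(
        current["landuse_natural_fraction"] + landuse_delta + noise_lu, 0.0, 1.0
    )
    out["soil_ph"] = current["soil_ph"].copy()  # held constant into the future
    return out


def make_world(
    seed: int,
    shape: tuple[int, int] = (100, 100),
    params: ScenarioParams | None = None,
    max_abs_r: float = 0.70,
) -> dict[str, Landscape]:
    """Generate the five-scenario landscape family for one world seed.

    Returns one :class:`Landscape` per scenario tag; all share the land mask,
    continent labels and soil pH.  Noise is regenerated (bounded retries)
    until no within-predictor-set layer pair exceeds ``max_abs_r`` Pearson
    correlation over land, in any scenario.
    """
    if params is None:
        params = ScenarioParams()
    nr, nc = shape
    if nr < 20 or nc < 20:
        raise ValueError(f"grid must be at least 20x20, got {shape}")

    for attempt in range(50):
        rng = np.random.default_rng(derive_seed(seed, "world", attempt))
        land, continents = _make_land(rng, shape)
        if continents.max(initial=0) < 2 or land.sum() < 0.2 * nr * nc:
            continue
        current = _base_layers(rng, shape)

        scen_specs = {
            "mild": (params.delta_temp_mild, params.precip_factor_mild, params.landuse_delta_mild),
            "severe": (params.delta_temp_severe, params.precip_factor_severe, params.landuse_delta_severe),
        }
        all_layers = {"current": current}
        for scen, (dt, pf, lud) in scen_specs.items():
            for real in (1, 2):
                rng_f = np.random.default_rng(derive_seed(seed, "future", attempt, scen, real))
                all_layers[f"{scen}_r{real}"] = _future_layers(current, rng_f, dt, pf, lud, params)

        worst = max(
            _pearson_max(lyr, names, land)
            for lyr in all_layers.values()
            for names in PREDICTOR_SETS.values()
        )
        if worst <= max_abs_r:
            return {
                tag: Landscape(
                    scenario=tag,
                    layers=all_layers[tag],
                    land_mask=land,
                    continents=continents,
                    seed=seed,
                )
                for tag in SCENARIOS
            }
    raise RuntimeError("could not generate a world meeting the collinearity constraint")


def make_effort(
    seed: int,
    landscape: Landscape,
    hotspot_centres: list[tuple[int, int]] | None = None,
    sigma: float | None = None,
    n_centres: int = 3,
) -> SamplingEffort:
    """Smooth, strictly positive sampling-effort field normalized over land.

    The field is a sum of Gaussian bumps around survey "hotspot" centres
    (think: well-sampled regions near herbaria and roads).  If no centres are
    given, ``n_centres`` are drawn uniformly from land cells.
    """
    land = landscape.land_mask
    if not land.any():
        raise ValueError("landscape has no land cells")
    rng = np.random.default_rng(derive_seed(seed, "effort"))
    if hotspot_centres is None:
        cells = landscape.land_cells()
        idx = rng.choice(len(cells), size=min(n_centres, len(cells)), replace=False)
        hotspot_centres = [tuple(c) for c in cells[idx]]
    if not any(land[r, c] for r, c in hotspot_centres):
        raise ValueError("at least one effort centre must lie on land")
    if sigma is None:
        # decay scale of one-third of the domain: effort spans a few orders of
        # magnitude across land but never starves whole regions of records,
        # matching the land-wide but heavy-tailed character of real
        # sampling-intensity indices
        sigma = max(landscape.shape) / 3

    rr, cc = np.mgrid[0 : land.shape[0], 0 : land.shape[1]]
    field = np.zeros(land.shape)
    for r0, c0 in hotspot_centres:
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        field += np.exp(-d2 / (2 * sigma**2))
    field = np.where(land, field, 0.0)
    field /= field[land].sum()
    return SamplingEffort(values=field, seed=seed)


def make_species(
    seed: int,
    landscape: Landscape,
    n_species: int,
    niche_config: NicheConfig | None = None,
) -> list[VirtualSpecies]:
    """Draw ``n_species`` virtual species with Gaussian-product niches.

    True suitability: S*(cell) = prod_v exp(-(x_v - mu_v)^2 / (2 sigma_v^2)),
    rescaled to max 1 over land.  Each species is naturalized on a random
    non-empty subset of continents.
    """
    cfg = niche_config or NicheConfig()
    for v in cfg.layers:
        if v not in landscape.layers:
            raise KeyError(f"niche variable {v!r} is not a landscape layer")
    if len(cfg.layers) < 2:
        raise ValueError("niche must use at least two layers")

    land = landscape.land_mask
    labels = sorted(set(landscape.continents[land].tolist()))
    out = []
    for i in range(n_species):
        rng = np.random.default_rng(derive_seed(seed, "species", i))
        niche = {}
        log_s = np.zeros(landscape.shape)
        for v in cfg.layers:
            vals = landscape.layers[v][land]
            lo, hi = np.quantile(vals, cfg.mu_quantiles)
            mu = float(rng.uniform(lo, hi))
            sigma = float(rng.uniform(*cfg.sigma_sd_range) * vals.std())
            sigma = max(sigma, 1e-9)
            niche[v] = (mu, sigma)
            log_s -= (landscape.layers[v] - mu) ** 2 / (2 * sigma**2)
        suit = np.exp(log_s - log_s[land].max())
        suit = np.where(land, suit, 0.0)
        k = int(rng.integers(1, len(labels) + 1))
        nat = frozenset(rng.choice(labels, size=k, replace=False).tolist())
        out.append(
            VirtualSpecies(
                species_id=f"vs{i:03d}",
                niche=niche,
                suitability=suit,
                naturalized_continents=nat,
                lam=cfg.lam,
            )
        )
    return out


def sample_occurrences(
    seed: int,
    species: VirtualSpecies,
    landscape: Landscape,
    effort: SamplingEffort,
):
    """Draw presence-only records: Poisson count, cells ~ S* x effort.

    Records are drawn with replacement (within-cell duplicates are part of
    the raw-data model) and carry the cell's full environment vector.
    """
    from .occurrences import OccurrenceSet  # local import avoids a cycle

    if species.lam <= 0:
        raise ValueError("expected record count lambda must be positive")
    land = landscape.land_mask
    w = (species.suitability * effort.values)[land]
    total = w.sum()
    if total == 0:
        raise ValueError("suitability x effort is identically zero on land")
    rng = np.random.default_rng(derive_seed(seed, "occurrences", species.species_id))
    n_raw = int(rng.poisson(species.lam))
    cells = landscape.land_cells()
    idx = rng.choice(len(cells), size=n_raw, replace=True, p=w / total)
    rows, cols = cells[idx, 0], cells[idx, 1]
    data = landscape.env_at(rows, cols)
    data.insert(0, "col", cols)
    data.insert(0, "row", rows)
    return OccurrenceSet(species_id=species.species_id, data=data, stage="raw")


def write_landscapes(landscapes: dict[str, Landscape], outdir) -> list[str]:
    """Write each scenario as a multi-band TIFF (band order = LAYER_NAMES)."""
    import json
    from pathlib import Path

    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for tag, ls in landscapes.items():
        stack = np.stack([ls.layers[n] for n in LAYER_NAMES]).astype(np.float32)
        path = outdir / f"landscape_{tag}.tif"
        meta = {"bands": list(LAYER_NAMES), "scenario": tag, "seed": ls.seed}
        tifffile.imwrite(path, stack, description=json.dumps(meta))
        written.append(str(path))
    return written
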