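"""End-to-end orchestration: simulate -> filter -> fit -> ensemble -> stack.

`run_pipeline` executes the whole analysis for one configured synthetic
world: landscape + scenario generation, virtual species and biased
occurrence sampling, record filtering, pseudo-absence design, model fitting
with spatial-block CV, Boyce-weighted ensembling and binarization, richness
stacking with hotspot / turnover / uncertainty analytics, biome-space
summaries, and the continent-restricted dispersal sensitivity.  Every
stochastic stage derives its seed from the master seed plus the stage name
and species id, so a run is a pure function of its config.  Per-species
failures (too few records, no retained model, no threshold) are logged in
the manifest and never abort the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ensemble as ens
from . import stacking
from ._util import derive_seed
from .biomes import assign_biome_landscape, biome_means, richness_density
from .occurrences import prepare_species
from .pseudoabsence import InsufficientEligibleCellsError, fit_sre, sample_pa
from .sdm import ALGORITHMS, BlockPartitionError, cross_validate, fit, make_blocks
from .world import (
    CLIMATIC_SETS,
    FUTURE_SCENARIOS,
    PREDICTOR_SETS,
    NicheConfig,
    ScenarioParams,
    make_effort,
    make_species,
    make_world,
    sample_occurrences,
    write_landscapes,
)

logger = logging.getLogger("invastack")

FUTURE_PAIRS = {"mild": ("mild_r1", "mild_r2"), "severe": ("severe_r1", "severe_r2")}


@dataclass
class RunConfig:
    """Full configuration of a pipeline run; round-trips through YAML."""

    seed: int = 1
    shape: tuple[int, int] = (100, 100)
    n_species: int = 30
    scenario_params: dict = field(default_factory=dict)
    niche_layers: tuple[str, ...] = ("temp_mean", "precip_annual")
    niche_mu_quantiles: tuple[float, float] = (0.15, 0.85)
    niche_sigma_sd_range: tuple[float, float] = (0.35, 0.9)
    lam: float = 500.0
    n_effort_centres: int = 3
    effort_centres: list | None = None
    n_bins: int = 6
    min_records: int = 30
    sre_q: float = 0.025
    boyce_window_width: float = 0.1
    boyce_n_windows: int = 101
    retention_threshold: float = 0.6
    threshold_mode: str = "crossing"
    hotspot_fractions: tuple[float, ...] = (0.05, 0.10, 0.15)
    predictor_sets: tuple[str, ...] = ("set1", "set2")
    write_species_rasters: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        for k in ("shape", "niche_layers", "niche_mu_quantiles",
                  "niche_sigma_sd_range", "hotspot_fractions", "predictor_sets"):
            if k in kwargs and kwargs[k] is not None:
                kwargs[k] = tuple(kwargs[k])
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def niche_config(self) -> NicheConfig:
        return NicheConfig(
            layers=self.niche_layers,
            mu_quantiles=self.niche_mu_quantiles,
            sigma_sd_range=self.niche_sigma_sd_range,
            lam=self.lam,
        )


@dataclass
class SpeciesModelResult:
    """Per species x predictor set modelling outcome."""

    species_id: str
    predictor_set: str
    status: str  # modelled | too_few_records | no_pseudoabsences |
    #              blocks_failed | unmodellable | no_threshold
    n_presences: int = 0
    ensemble: ens.EnsembleModel | None = None
    binary: dict[str, np.ndarray] = field(default_factory=dict)
    model_rows: list[dict] = field(default_factory=list)


def model_species(
    occ_raw,
    species,
    landscapes: dict,
    effort,
    set_id: str,
    config: RunConfig,
    background_env: pd.DataFrame,
) -> SpeciesModelResult:
    """Filter, sample PAs, fit/CV all algorithms, ensemble and binarize one
    species under one predictor set, projecting all five scenario tags."""
    current = landscapes["current"]
    sid = species.species_id
    res = SpeciesModelResult(species_id=sid, predictor_set=set_id, status="modelled")

    filtered, accepted, _ = prepare_species(
        occ_raw, CLIMATIC_SETS[set_id], n_bins=config.n_bins,
        min_records=config.min_records, seed=config.seed,
    )
    res.n_presences = len(filtered)
    if not accepted:
        res.status = "too_few_records"
        return res

    pres = filtered.data
    envelope = fit_sre(pres[list(CLIMATIC_SETS[set_id])], q=config.sre_q)
    try:
        pa = sample_pa(
            envelope, current, effort, n=len(pres), seed=config.seed,
            species_id=sid, exclude_cells=filtered.cells(),
        )
    except InsufficientEligibleCellsError as exc:
        logger.warning("%s/%s: %s", sid, set_id, exc)
        res.status = "no_pseudoabsences"
        return res
    assert len(pa.data) == len(pres), "pseudo-absence count must equal presences"

    coords = np.vstack([pres[["row", "col"]].to_numpy(), pa.data[["row", "col"]].to_numpy()])
    try:
        blocks = make_blocks(coords)
    except BlockPartitionError as exc:
        logger.warning("%s/%s: %s", sid, set_id, exc)
        res.status = "blocks_failed"
        return res

    names = PREDICTOR_SETS[set_id]
    models = []
    for alg in ALGORITHMS:
        alg_seed = derive_seed(config.seed, "fit", sid, set_id, alg)
        cv, folds = cross_validate(
            alg, pres, pa.data, names, background_env, seed=alg_seed, blocks=blocks,
            window_width=config.boyce_window_width, n_windows=config.boyce_n_windows,
        )
        try:
            model = fit(alg, pres, pa.data, names, seed=alg_seed, predictor_set_id=set_id)
        except Exception as exc:  # algorithm isolation: log and move on
            logger.warning("%s/%s: %s refit failed (%s)", sid, set_id, alg, exc)
            cv, folds = float("nan"), folds
            res.model_rows.append({
                "species_id": sid, "predictor_set": set_id, "algorithm": alg,
                "cv_boyce": float("nan"), "retained": False,
            })
            continue
        model.cv_boyce = cv
        model.fold_boyce = folds
        models.append(model)
        res.model_rows.append({
            "species_id": sid, "predictor_set": set_id, "algorithm": alg,
            "cv_boyce": cv,
            **{f"fold_{i}": f for i, f in enumerate(folds)},
            "retained": bool(np.isfinite(cv) and cv > config.retention_threshold),
        })

    try:
        ensemble = ens.build_ensemble(
            models, species_id=sid, predictor_set=set_id,
            retention_threshold=config.retention_threshold,
        )
    except ens.UnmodellableSpeciesError as exc:
        logger.warning("%s", exc)
        res.status = "unmodellable"
        return res

    suit_current = ens.predict_ensemble(ensemble, current)
    pres_rc = pres[["row", "col"]].to_numpy()
    try:
        t_star, _ = ens.boyce_max_threshold(
            suit_current[pres_rc[:, 0], pres_rc[:, 1]],
            suit_current[current.land_mask],
            mode=config.threshold_mode,
            window_width=config.boyce_window_width,
            n_windows=config.boyce_n_windows,
        )
    except ens.NoThresholdError as exc:
        logger.warning("%s/%s: %s", sid, set_id, exc)
        res.status = "no_threshold"
        return res
    ensemble.binarization_threshold = t_star

    res.binary["current"] = ens.binarize(suit_current, t_star, current.land_mask)
    for tag in FUTURE_SCENARIOS:
        suit = ens.predict_ensemble(ensemble, landscapes[tag])
        res.binary[tag] = ens.binarize(suit, t_star, current.land_mask)
    res.ensemble = ensemble
    return res


def _median_iqr(values: np.ndarray) -> dict:
    q25, med, q75 = np.percentile(values, [25, 50, 75])
    return {"median": float(med), "iqr_low": float(q25), "iqr_high": float(q75)}


def _stack_members(results, set_ids, tag_for_set) -> dict[str, np.ndarray]:
    """Member richness rasters keyed by member name."""
    members = {}
    for set_id in set_ids:
        tag, name = tag_for_set(set_id)
        maps = [r.binary[tag] for r in results
                if r.predictor_set == set_id and r.status == "modelled"]
        if maps:
            members[name] = stacking.stack_richness(maps)
    return members


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full analysis; writes artifacts and returns the manifest."""
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    params = ScenarioParams(**config.scenario_params)
    landscapes = make_world(config.seed, tuple(config.shape), params)
    current = landscapes["current"]
    land = current.land_mask
    effort = make_effort(
        derive_seed(config.seed, "effort-stage"), current,
        hotspot_centres=config.effort_centres, n_centres=config.n_effort_centres,
    )
    species = make_species(config.seed, current, config.n_species, config.niche_config())
    logger.info("world %s: %d land cells, %d continents, %d species",
                config.shape, current.n_land, int(current.continents.max()), len(species))

    backgrounds = {
        set_id: current.land_env(PREDICTOR_SETS[set_id]) for set_id in config.predictor_sets
    }

    results: list[SpeciesModelResult] = []
    occ_reports = []
    for sp in species:
        occ_raw = sample_occurrences(config.seed, sp, current, effort)
        for set_id in config.predictor_sets:
            t_sp = time.time()
            res = model_species(occ_raw, sp, landscapes, effort, set_id, config,
                                backgrounds[set_id])
            results.append(res)
            occ_reports.append({
                "species_id": sp.species_id, "predictor_set": set_id,
                "raw_n": len(occ_raw), "filtered_n": res.n_presences,
                "status": res.status,
            })
            logger.info("%s/%s: %s (%.1fs)", sp.species_id, set_id, res.status,
                        time.time() - t_sp)

    modelled = [r for r in results if r.status == "modelled"]
    modelled_species = sorted({r.species_id for r in modelled})
    pool_size = len(modelled_species)
    if pool_size == 0:
        raise RuntimeError("no species could be modelled; enlarge the world or pool")

    # --- stacking: members, consensus, hotspots, turnover, CV -------------
    member_richness: dict[str, dict[str, np.ndarray]] = {}
    member_richness["current"] = _stack_members(
        modelled, config.predictor_sets, lambda s: ("current", f"{s}"))
    for scen, tags in FUTURE_PAIRS.items():
        members = {}
        for set_id, tag in product(config.predictor_sets, tags):
            got = _stack_members(modelled, [set_id], lambda s, t=tag: (t, f"{s}_{t}"))
            members.update(got)
        member_richness[scen] = members

    consensus = {
        scen: np.mean(np.stack(list(m.values())), axis=0)
        for scen, m in member_richness.items()
    }

    cutoffs = {f: stacking.hotspot_cutoff(pool_size, f) for f in config.hotspot_fractions}
    hotspots = {
        scen: {f: stacking.hotspot_map(consensus[scen], pool_size, land,
                                       fraction=f, cutoff=cutoffs[f])
               for f in config.hotspot_fractions}
        for scen in consensus
    }
    main_f = 0.10 if 0.10 in cutoffs else config.hotspot_fractions[0]
    persistence = {
        scen: stacking.hotspot_persistence(hotspots["current"][main_f], hotspots[scen][main_f])
        for scen in FUTURE_PAIRS
    }

    cv_maps = {scen: stacking.cv_map(list(member_richness[scen].values()))
               for scen in FUTURE_PAIRS}

    # turnover per (set, realization) member, then averaged
    turnover_maps = {}
    by_set_current = {
        set_id: np.stack([r.binary["current"] for r in modelled if r.predictor_set == set_id])
        for set_id in config.predictor_sets
        if any(r.predictor_set == set_id for r in modelled)
    }
    for scen, tags in FUTURE_PAIRS.items():
        layers = []
        for set_id, cur_stack in by_set_current.items():
            for tag in tags:
                fut_stack = np.stack([
                    r.binary[tag] for r in modelled if r.predictor_set == set_id
                ])
                layers.append(stacking.turnover(cur_stack, fut_stack))
        turnover_maps[scen] = np.mean(np.stack(layers), axis=0)

    change = {
        scen: stacking.change_maps(consensus["current"], consensus[scen], land)
        for scen in FUTURE_PAIRS
    }

    # --- continental dispersal filter sensitivity -------------------------
    sp_by_id = {sp.species_id: sp for sp in species}
    filt_consensus = {}
    for scen in consensus:
        members = []
        scen_tags = ("current",) if scen == "current" else FUTURE_PAIRS[scen]
        for set_id in config.predictor_sets:
            for tag in scen_tags:
                maps = [
                    stacking.continental_filter(
                        r.binary[tag], sp_by_id[r.species_id].naturalized_continents,
                        current.continents)
                    for r in modelled if r.predictor_set == set_id
                ]
                if maps:
                    members.append(stacking.stack_richness(maps))
        filt_consensus[scen] = np.mean(np.stack(members), axis=0)
    filt_hotspots = {
        scen: stacking.hotspot_map(filt_consensus[scen], pool_size, land,
                                   fraction=main_f, cutoff=cutoffs[main_f])
        for scen in filt_consensus
    }

    # --- biome space ------------------------------------------------------
    biome_raster = assign_biome_landscape(current)
    tp_points = np.column_stack([
        current.layers["temp_mean"][land],
        current.layers["precip_annual"][land] / 10.0,
    ])
    centroids = {}
    biome_tables = {}
    for scen in consensus:
        w = consensus[scen][land]
        dens = richness_density(tp_points, w)
        centroids[scen] = {
            "temp_c": dens.centroid[0], "precip_cm": dens.centroid[1],
            "contour_level": dens.level, "mass_inside": dens.mass_inside,
        }
        biome_tables[scen] = biome_means(consensus[scen], biome_raster, land)

    # --- artifacts --------------------------------------------------------
    files = []
    files += write_landscapes(landscapes, outdir / "landscapes")
    files.append(_write_csv(pd.DataFrame(occ_reports), outdir / "species_filter_report.csv"))
    model_df = pd.DataFrame([row for r in results for row in r.model_rows])
    files.append(_write_csv(model_df, outdir / "model_report.csv"))
    ens_rows = [{
        "species_id": r.species_id, "predictor_set": r.predictor_set,
        "n_members": len(r.ensemble.members),
        "weights": ";".join(f"{w:.6f}" for w in r.ensemble.weights),
        "threshold": r.ensemble.binarization_threshold,
    } for r in modelled]
    files.append(_write_csv(pd.DataFrame(ens_rows), outdir / "ensemble_report.csv"))

    raster_dir = outdir / "rasters"
    for scen, cons in consensus.items():
        files.append(_write_tif(np.round(cons), raster_dir / f"richness_{scen}.tif"))
        files.append(_write_tif(filt_consensus[scen],
                                raster_dir / f"richness_filtered_{scen}.tif"))
        for f, hs in hotspots[scen].items():
            files.append(_write_tif(hs.mask.astype(np.uint8),
                                    raster_dir / f"hotspot_{scen}_f{int(f * 100):02d}.tif"))
    for scen in FUTURE_PAIRS:
        files.append(_write_tif(turnover_maps[scen], raster_dir / f"turnover_{scen}.tif"))
        files.append(_write_tif(cv_maps[scen], raster_dir / f"cv_{scen}.tif"))
        ab, prop = change[scen]
        files.append(_write_tif(ab, raster_dir / f"change_abs_{scen}.tif"))
        files.append(_write_tif(prop, raster_dir / f"change_prop_{scen}.tif"))
    files.append(_write_tif(biome_raster, raster_dir / "biomes.tif"))
    for scen, table in biome_tables.items():
        files.append(_write_csv(table, outdir / f"biome_means_{scen}.csv"))

    if config.write_species_rasters:
        for r in modelled:
            for tag, b in r.binary.items():
                files.append(_write_tif(
                    b, raster_dir / "species" / f"{r.species_id}_{r.predictor_set}_{tag}.tif"))

    retained_boyce = model_df.loc[model_df["retained"], "cv_boyce"]
    summary = {
        "pool_size": pool_size,
        "n_species_simulated": config.n_species,
        "species_status_counts": pd.DataFrame(occ_reports)["status"].value_counts().to_dict(),
        "median_cv_boyce_retained": float(retained_boyce.median()) if len(retained_boyce) else None,
        "richness": {scen: _median_iqr(cons[land]) for scen, cons in consensus.items()},
        "hotspot_land_fraction": {
            scen: {f"{f:.2f}": hs[f].land_fraction for f in config.hotspot_fractions}
            for scen, hs in hotspots.items()
        },
        "hotspot_cutoffs": {f"{f:.2f}": c for f, c in cutoffs.items()},
        "hotspot_persistence_pct": persistence,
        "mean_turnover": {scen: float(np.nanmean(t[land]))
                          for scen, t in turnover_maps.items()},
        "centroids": centroids,
        "filtered_hotspot_land_fraction": {
            scen: hs.land_fraction for scen, hs in filt_hotspots.items()
        },
    }
    spath = outdir / "summary.json"
    spath.write_text(json.dumps(summary, indent=2, sort_keys=True))
    files.append(str(spath))

    cpath = outdir / "config.yaml"
    config.to_yaml(cpath)
    files.append(str(cpath))

    manifest = {
        "config": config.to_dict(),
        "pool_size": pool_size,
        "runtime_s": round(time.time() - t0, 1),
        "artifacts": {
            str(Path(f).relative_to(outdir)): _sha256(f) for f in files
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def report(outdir) -> dict:
    """Recompute the headline summary from a completed run's artifacts.

    Reads the manifest, recomputes richness medians/IQRs from the written
    richness rasters and merges the stored summary; regeneration is
    idempotent.
    """
    import tifffile

    outdir = Path(outdir)
    man_path = outdir / "manifest.json"
    if not man_path.exists():
        raise FileNotFoundError(f"no manifest at {man_path}")
    manifest = json.loads(man_path.read_text())
    if not manifest.get("artifacts"):
        raise ValueError("manifest lists no artifacts; run the pipeline first")
    summary = json.loads((outdir / "summary.json").read_text())

    recomputed = {}
    for name in manifest["artifacts"]:
        if name.startswith("rasters/richness_") and "filtered" not in name:
            scen = Path(name).stem.replace("richness_", "")
            r = tifffile.imread(outdir / name)
            vals = r[np.isfinite(r)]
            recomputed[scen] = _median_iqr(vals)
    out = {"summary": summary, "richness_recomputed": recomputed}
    (outdir / "report.json").write_text(json.dumps(out, indent=2, sort_keys=True))
    return out


def _write_csv(df: pd.DataFrame, path) -> str:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return str(path)


def _write_tif(arr: np.ndarray, path) -> str:
    import tifffile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = arr.astype(np.float32) if arr.dtype.kind == "f" else arr
    tifffile.imwrite(path, data)
    return str(path)


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
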