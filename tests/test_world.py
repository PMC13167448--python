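"""Synthetic world generator: determinism, scenario structure, species law."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.stats import chisquare

from invastack import world as w
from invastack.world import (
    LAYER_NAMES,
    PREDICTOR_SETS,
    SCENARIOS,
    NicheConfig,
    ScenarioParams,
)


class TestMakeWorld:
    def test_seeded_determinism_bit_identical(self, small_world):
        again = w.make_world(seed=7, shape=(60, 60))
        for tag in SCENARIOS:
            for name in LAYER_NAMES:
                np.testing.assert_array_equal(
                    small_world[tag].layers[name], again[tag].layers[name]
                )
        np.testing.assert_array_equal(small_world["current"].land_mask,
                                      again["current"].land_mask)

    def test_soil_ph_constant_across_scenarios(self, small_world):
        ref = small_world["current"].layers["soil_ph"]
        for tag in SCENARIOS[1:]:
            np.testing.assert_array_equal(small_world[tag].layers["soil_ph"], ref)

    def test_collinearity_bound_by_direct_correlation(self, small_world):
        # brute-force Pearson oracle over land, every scenario, both sets
        for tag in SCENARIOS:
            ls = small_world[tag]
            land = ls.land_mask
            for names in PREDICTOR_SETS.values():
                mat = np.vstack([ls.layers[n][land] for n in names])
                r = np.corrcoef(mat)
                np.fill_diagonal(r, 0)
                assert np.abs(r).max() <= 0.70 + 1e-12

    def test_layer_invariants(self, small_world):
        for tag in SCENARIOS:
            ls = small_world[tag]
            land = ls.land_mask
            lu = ls.layers["landuse_natural_fraction"]
            assert lu.min() >= 0 and lu.max() <= 1
            for name in LAYER_NAMES:
                assert np.isfinite(ls.layers[name][land]).all()

    def test_continents_partition_land(self, current):
        labels = current.continents
        assert (labels[current.land_mask] > 0).all()
        assert (labels[~current.land_mask] == 0).all()
        n_components = ndimage.label(current.land_mask)[1]
        assert labels.max() >= 2
        assert labels.max() == n_components

    def test_scenario_temperature_ordering(self, small_world):
        params = ScenarioParams()
        land = small_world["current"].land_mask
        cur = small_world["current"].layers["temp_mean"][land]
        tol = 2 * params.noise_amplitude_temp
        for r in (1, 2):
            mild = small_world[f"mild_r{r}"].layers["temp_mean"][land] - cur
            severe = small_world[f"severe_r{r}"].layers["temp_mean"][land] - cur
            assert (mild > 0 - tol).all() and mild.mean() > 0
            assert (severe > mild - tol).all() and severe.mean() > mild.mean()

    def test_shape_and_param_validation(self):
        with pytest.raises(ValueError, match="20x20"):
            w.make_world(seed=1, shape=(10, 30))
        with pytest.raises(ValueError, match="smaller"):
            ScenarioParams(delta_temp_mild=5.0, delta_temp_severe=4.0)


class TestMakeEffort:
    def test_normalized_and_positive_on_land(self, current, effort):
        vals = effort.values[current.land_mask]
        assert vals.sum() == pytest.approx(1.0, abs=1e-9)
        assert (vals > 0).all()
        assert (effort.values[~current.land_mask] == 0).all()

    def test_single_centre_peaks_at_centre(self, current):
        r0, c0 = map(int, current.land_cells()[10])
        eff = w.make_effort(seed=1, landscape=current, hotspot_centres=[(r0, c0)])
        peak = np.unravel_index(np.argmax(eff.values), eff.values.shape)
        assert peak == (r0, c0)

    def test_duplicate_centres_give_proportional_field(self, current):
        # field algebra: doubling every bump rescales away under normalization
        r0, c0 = map(int, current.land_cells()[10])
        one = w.make_effort(seed=1, landscape=current, hotspot_centres=[(r0, c0)])
        two = w.make_effort(seed=1, landscape=current, hotspot_centres=[(r0, c0), (r0, c0)])
        np.testing.assert_allclose(one.values, two.values, atol=1e-12)

    def test_centre_off_land_rejected(self, current):
        sea = np.argwhere(~current.land_mask)[0]
        with pytest.raises(ValueError, match="land"):
            w.make_effort(seed=1, landscape=current, hotspot_centres=[tuple(sea)])


class TestMakeSpecies:
    def test_flat_niche_limit(self, current):
        cfg = NicheConfig(sigma_sd_range=(200.0, 300.0))
        sp = w.make_species(seed=3, landscape=current, n_species=1, niche_config=cfg)[0]
        assert sp.suitability[current.land_mask].min() > 0.99

    def test_suitability_closed_form(self, current, species_pool):
        # recompute S* at arbitrary cells from mu, sigma and the layers
        sp = species_pool[0]
        land_cells = current.land_cells()
        log_s = np.zeros(current.shape)
        for v, (mu, sigma) in sp.niche.items():
            log_s -= (current.layers[v] - mu) ** 2 / (2 * sigma**2)
        expected = np.exp(log_s - log_s[current.land_mask].max())
        for r, c in land_cells[::97]:
            assert sp.suitability[r, c] == pytest.approx(expected[r, c], abs=1e-12)
        assert sp.suitability[current.land_mask].max() == pytest.approx(1.0)

    def test_ids_unique_and_continents_nonempty(self, species_pool):
        ids = [sp.species_id for sp in species_pool]
        assert len(set(ids)) == len(ids)
        for sp in species_pool:
            assert sp.naturalized_continents

    def test_unknown_niche_layer_rejected(self, current):
        cfg = NicheConfig(layers=("temp_mean", "nonexistent"))
        with pytest.raises(KeyError, match="nonexistent"):
            w.make_species(seed=1, landscape=current, n_species=1, niche_config=cfg)


class TestSampleOccurrences:
    def test_seeded_determinism(self, current, effort, species_pool):
        a = w.sample_occurrences(5, species_pool[0], current, effort)
        b = w.sample_occurrences(5, species_pool[0], current, effort)
        assert a.data.equals(b.data)

    def test_indicator_suitability_pins_all_records(self, current, effort, species_pool):
        import dataclasses

        r0, c0 = map(int, current.land_cells()[42])
        onehot = np.zeros(current.shape)
        onehot[r0, c0] = 1.0
        sp = dataclasses.replace(species_pool[0], suitability=onehot, lam=50.0)
        occ = w.sample_occurrences(2, sp, current, effort)
        assert (occ.data["row"] == r0).all() and (occ.data["col"] == c0).all()

    def test_two_cell_sampling_ratio(self, current, effort, species_pool):
        # weights 3:1 across two cells -> record ratio within 3 s.e.
        import dataclasses

        cells = current.land_cells()
        (r1, c1), (r2, c2) = cells[5], cells[-5]
        suit = np.zeros(current.shape)
        e1, e2 = effort.values[r1, c1], effort.values[r2, c2]
        suit[r1, c1] = 3.0 / e1
        suit[r2, c2] = 1.0 / e2
        sp = dataclasses.replace(species_pool[0], suitability=suit, lam=4000.0)
        occ = w.sample_occurrences(9, sp, current, effort)
        n1 = ((occ.data["row"] == r1) & (occ.data["col"] == c1)).sum()
        n = len(occ)
        se = np.sqrt(0.75 * 0.25 / n)
        assert abs(n1 / n - 0.75) < 3 * se

    def test_occurrence_law_chi_square(self, current, effort, species_pool):
        # empirical cell frequencies at N=1e5 match S* x effort (normalized)
        import dataclasses

        sp = dataclasses.replace(species_pool[1], lam=1e5)
        occ = w.sample_occurrences(13, sp, current, effort)
        land = current.land_cells()
        p = (sp.suitability * effort.values)[land[:, 0], land[:, 1]]
        p = p / p.sum()
        idx = {tuple(c): i for i, c in enumerate(land)}
        counts = np.zeros(len(land))
        for r, c in occ.data[["row", "col"]].to_numpy():
            counts[idx[(r, c)]] += 1
        n = counts.sum()
        # pool cells with small expectation for a valid chi-square
        order = np.argsort(p)[::-1]
        exp_sorted, obs_sorted = p[order] * n, counts[order]
        big = exp_sorted >= 5
        exp_b = np.append(exp_sorted[big], exp_sorted[~big].sum())
        obs_b = np.append(obs_sorted[big], obs_sorted[~big].sum())
        stat, pval = chisquare(obs_b, exp_b * (obs_b.sum() / exp_b.sum()))
        assert pval > 0.001

    def test_zero_weight_rejected(self, current, effort, species_pool):
        import dataclasses

        sp = dataclasses.replace(species_pool[0], suitability=np.zeros(current.shape))
        with pytest.raises(ValueError, match="zero"):
            w.sample_occurrences(1, sp, current, effort)
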