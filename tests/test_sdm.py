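"""SDM engine: collinearity screen, spatial blocks, Boyce index, model fits."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from invastack import world as w
from invastack.sdm import (
    ALGORITHMS,
    BlockPartitionError,
    BoyceUndefinedError,
    boyce_index,
    collinearity_screen,
    cross_validate,
    fit,
    make_blocks,
)
from invastack.world import CLIMATIC_SETS, PREDICTOR_SETS


class TestCollinearityScreen:
    def test_self_correlation_fails(self, current):
        layers = {"a": current.layers["temp_mean"], "b": current.layers["temp_mean"]}
        passed, report = collinearity_screen(layers, current.land_mask)
        assert not passed and report.loc[0, "fail"]
        assert report.loc[0, "r"] == pytest.approx(1.0)

    def test_independent_noise_passes(self, current, rng):
        layers = {k: rng.normal(size=current.shape) for k in "abc"}
        passed, _ = collinearity_screen(layers, current.land_mask)
        assert passed

    def test_exact_threshold_passes_strict_exceedance_fails(self, current):
        # construct a pair with empirical |r| = 0.70 exactly (Gram-Schmidt)
        land = current.land_mask
        n = int(land.sum())
        rng = np.random.default_rng(0)
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        x = (x - x.mean()) / x.std()
        z = z - z.mean()
        z -= (z @ x) / (x @ x) * x
        z /= z.std()
        la = np.zeros(current.shape)
        lb = np.zeros(current.shape)
        la[land] = x
        for rho, expect_pass in [(0.70, True), (0.71, False)]:
            lb[land] = rho * x + np.sqrt(1 - rho**2) * z
            passed, report = collinearity_screen({"a": la, "b": lb}, land)
            assert report.loc[0, "r"] == pytest.approx(rho, abs=1e-9)
            assert passed is expect_pass

    def test_constant_layer_flagged(self, current):
        layers = {"a": current.layers["temp_mean"], "b": np.ones(current.shape)}
        passed, report = collinearity_screen(layers, current.land_mask)
        assert not passed
        assert "constant" in report.loc[0, "reason"]


class TestMakeBlocks:
    def test_counts_match_quadrant_oracle(self, rng):
        pts = rng.uniform(0, 100, size=(1000, 2))
        part = make_blocks(pts)
        mr, mc = np.median(pts[:, 0]), np.median(pts[:, 1])
        oracle = 2 * (pts[:, 0] > mr) + (pts[:, 1] > mc)
        np.testing.assert_array_equal(part.labels, oracle.astype(int))
        counts = np.bincount(part.labels, minlength=4)
        assert counts.sum() == 1000 and (counts > 0).all()

    def test_every_point_in_exactly_one_block(self, rng):
        pts = rng.integers(0, 50, size=(200, 2))
        part = make_blocks(pts)
        assert part.labels.shape == (200,)
        assert set(np.unique(part.labels)) <= {0, 1, 2, 3}

    def test_four_corners_one_per_block(self):
        pts = np.array([[0, 0], [0, 10], [10, 0], [10, 10]])
        part = make_blocks(pts)
        assert sorted(part.labels) == [0, 1, 2, 3]

    def test_degenerate_points_rejected(self):
        with pytest.raises(BlockPartitionError):
            make_blocks(np.array([[1, 1]] * 10))


def _rank(a):
    # hand-coded midrank for the Spearman oracle
    a = np.asarray(a, dtype=float)
    order = np.argsort(a, kind="mergesort")
    ranks = np.empty(len(a))
    sa = a[order]
    i = 0
    while i < len(a):
        j = i
        while j + 1 < len(a) and sa[j + 1] == sa[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def _spearman_oracle(x, y):
    rx, ry = _rank(x), _rank(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


class TestBoyceIndex:
    def test_perfect_ranking_near_one(self):
        rng = np.random.default_rng(1)
        back = np.linspace(0, 1, 1000)
        p = back**3 / (back**3).sum()
        pres = rng.choice(back, 200, p=p)
        b, curve = boyce_index(pres, back)
        assert b > 0.9
        assert (curve.expected_freq > 0).all()
        assert (curve.ratios >= 0).all()

    def test_random_presences_near_zero(self):
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            back = rng.uniform(0, 1, 1000)
            pres = rng.choice(back, 100)
            vals.append(boyce_index(pres, back)[0])
        assert abs(np.mean(vals)) < 0.15

    def test_reflection_flips_sign(self):
        # x -> 1-x reverses the suitability ranking, so the index negates
        rng = np.random.default_rng(3)
        back = rng.uniform(0, 1, 1000)
        pres = rng.choice(back, 100)
        b_fwd, _ = boyce_index(pres, back)
        b_rev, _ = boyce_index(1 - pres, 1 - back)
        assert b_rev == pytest.approx(-b_fwd, abs=1e-9)

    def test_matches_hand_coded_spearman_on_curve(self):
        rng = np.random.default_rng(5)
        back = rng.uniform(0, 1, 500)
        pres = rng.choice(back, 80)
        b, curve = boyce_index(pres, back)
        assert b == pytest.approx(_spearman_oracle(curve.ratios, curve.midpoints), abs=1e-12)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(BoyceUndefinedError, match="identical"):
            boyce_index(np.full(5, 0.5), np.full(20, 0.5))
        with pytest.raises(ValueError, match="background"):
            boyce_index(np.array([0.5]), np.array([0.1, 0.9]))
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            boyce_index(np.array([1.5]), np.linspace(0, 1, 20))


@pytest.fixture(scope="module")
def calib(current, effort, species_pool):
    from invastack.occurrences import prepare_species
    from invastack.pseudoabsence import fit_sre, sample_pa

    occ = w.sample_occurrences(3, species_pool[0], current, effort)
    filt, accepted, _ = prepare_species(occ, CLIMATIC_SETS["set1"], seed=3)
    assert accepted
    pres = filt.data
    envlp = fit_sre(pres[list(CLIMATIC_SETS["set1"])])
    pa = sample_pa(envlp, current, effort, len(pres), seed=3, species_id="sp",
                   exclude_cells=filt.cells())
    return pres, pa.data


class TestFit:
    @pytest.mark.parametrize("alg", ALGORITHMS)
    def test_predictions_bounded_and_deterministic(self, alg, calib, current):
        pres, pa = calib
        names = PREDICTOR_SETS["set1"]
        m1 = fit(alg, pres, pa, names, seed=11)
        m2 = fit(alg, pres, pa, names, seed=11)
        env = current.land_table(names)
        p1, p2 = m1.predict(env), m2.predict(env)
        np.testing.assert_array_equal(p1, p2)
        assert p1.min() >= 0 and p1.max() <= 1

    def test_constant_predictor_named_in_error(self, calib):
        pres, pa = calib
        pres = pres.copy()
        pa = pa.copy()
        pres["soil_ph"] = 5.0
        pa["soil_ph"] = 5.0
        with pytest.raises(ValueError, match="soil_ph"):
            fit("linear-logistic", pres, pa, PREDICTOR_SETS["set1"], seed=1)

    def test_unbalanced_calibration_rejected(self, calib):
        pres, pa = calib
        with pytest.raises(ValueError, match="equal"):
            fit("linear-logistic", pres, pa.iloc[:-2], PREDICTOR_SETS["set1"], seed=1)

    def test_recovers_single_variable_truth(self, current, effort, species_pool):
        # a species driven by temp_mean alone: fitted suitability must
        # rank-correlate strongly with the true response
        from scipy.stats import spearmanr

        from invastack.occurrences import prepare_species
        from invastack.pseudoabsence import fit_sre, sample_pa

        land = current.land_mask
        t = current.layers["temp_mean"]
        mu = float(np.quantile(t[land], 0.4))
        sigma = 0.6 * t[land].std()
        suit = np.where(land, np.exp(-((t - mu) ** 2) / (2 * sigma**2)), 0.0)
        suit /= suit[land].max()
        sp = dataclasses.replace(species_pool[0], niche={"temp_mean": (mu, sigma)},
                                 suitability=suit, lam=800.0)
        occ = w.sample_occurrences(21, sp, current, effort)
        filt, accepted, _ = prepare_species(occ, CLIMATIC_SETS["set1"], seed=21)
        assert accepted
        envlp = fit_sre(filt.data[list(CLIMATIC_SETS["set1"])])
        pa = sample_pa(envlp, current, effort, len(filt.data), seed=21,
                       species_id="x", exclude_cells=filt.cells())
        # with the informative predictor the response is recovered nearly
        # perfectly; adding the uninformative predictors erodes the rank
        # correlation only in the near-zero-suitability tail
        solo = fit("linear-logistic", filt.data, pa.data, ["temp_mean"], seed=1)
        pred_solo = solo.predict(current.land_table(["temp_mean"]))
        assert spearmanr(pred_solo, suit[land]).statistic > 0.95
        full = fit("linear-logistic", filt.data, pa.data, PREDICTOR_SETS["set1"], seed=1)
        pred_full = full.predict(current.land_table(PREDICTOR_SETS["set1"]))
        assert spearmanr(pred_full, suit[land]).statistic > 0.5


class TestCrossValidate:
    def test_four_folds_reported(self, calib, current):
        pres, pa = calib
        cv, folds = cross_validate("linear-logistic", pres, pa, PREDICTOR_SETS["set1"],
                                   current.land_env(PREDICTOR_SETS["set1"]), seed=2)
        assert len(folds) == 4
        defined = [f for f in folds if np.isfinite(f)]
        assert cv == pytest.approx(np.mean(defined))
        assert all(-1 <= f <= 1 for f in defined)

    def test_shuffled_labels_score_near_zero(self, calib, current, rng):
        # permutation null: presences and PAs swapped at random
        pres, pa = calib
        pooled = pd.concat([pres, pa], ignore_index=True).sample(
            frac=1, random_state=7).reset_index(drop=True)
        fake_pres = pooled.iloc[: len(pres)]
        fake_pa = pooled.iloc[len(pres):]
        cv, _ = cross_validate("linear-logistic", fake_pres, fake_pa,
                               PREDICTOR_SETS["set1"],
                               current.land_env(PREDICTOR_SETS["set1"]), seed=2)
        assert abs(cv) < 0.35
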