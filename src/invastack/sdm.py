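"""SDM engine: model families, spatial-block CV and the continuous Boyce index.

Four model families are fitted to the presence / pseudo-absence contrast at
their library defaults: a linear logistic regression, a smooth-additive
logistic model (penalized B-splines), bagged trees (random forest) and
boosted trees (gradient boosting).  Performance is measured with the
continuous Boyce index under 4-fold spatial block cross-validation, the
appropriate presence-only evaluation: it asks whether cells predicted more
suitable contain observed presences more often than the available
environment would suggest, and is invariant to monotone rescaling of the
prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as dataclass_replace

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler

ALGORITHMS = ("linear-logistic", "additive-smooth", "bagged-trees", "boosted-trees")


class BoyceUndefinedError(ValueError):
    """The Boyce index cannot be computed (degenerate predictions/windows)."""


class BlockPartitionError(ValueError):
    """A spatial block came out empty; more (or better-spread) data needed."""


# ---------------------------------------------------------------------------
# collinearity screen

def collinearity_screen(
    layers: dict[str, np.ndarray],
    land_mask: np.ndarray,
    names: tuple[str, ...] | list[str] | None = None,
    max_abs_r: float = 0.70,
) -> tuple[bool, pd.DataFrame]:
    """Pairwise Pearson screen over land cells.

    A pair fails only on strict exceedance (|r| > max_abs_r); a constant
    layer has undefined correlations and fails with its own reason.
    """
    names = list(names if names is not None else layers)
    if len(names) < 2:
        raise ValueError("need at least two layers to screen")
    rows = []
    passed = True
    vals = {n: layers[n][land_mask].astype(float) for n in names}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if vals[a].std() == 0 or vals[b].std() == 0:
                rows.append({"var_a": a, "var_b": b, "r": np.nan,
                             "fail": True, "reason": "constant layer"})
                passed = False
                continue
            r = float(np.corrcoef(vals[a], vals[b])[0, 1])
            # strict exceedance, with a float guard so |r| == threshold passes
            fail = abs(r) - max_abs_r > 1e-12
            passed &= not fail
            rows.append({"var_a": a, "var_b": b, "r": r, "fail": fail,
                         "reason": "exceeds threshold" if fail else ""})
    return passed, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# spatial blocks

@dataclass(frozen=True)
class BlockPartition:
    """2x2 quadrant partition of space, split at calibration-point medians.

    ``labels`` assigns each calibration point to its block; :meth:`assign`
    maps any other coordinates (e.g. background cells) into the same blocks,
    so held-out evaluation can compare presences with the available
    environment *of the same block*.
    """

    labels: np.ndarray
    median_row: float
    median_col: float

    def assign(self, coords: np.ndarray) -> np.ndarray:
        pts = np.asarray(coords)
        return (
            2 * (pts[:, 0] > self.median_row).astype(int)
            + (pts[:, 1] > self.median_col).astype(int)
        )


def make_blocks(points: np.ndarray) -> BlockPartition:
    """Partition calibration points into 2x2 spatial quadrants.

    The split is at the median row and median column of the points; a point
    exactly on a median goes to the lower-index (<=) side.  Block ids are
    0..3 = 2*(row > median_row) + (col > median_col).
    """
    pts = np.asarray(points)
    if len(pts) < 4:
        raise BlockPartitionError("need at least 4 calibration points")
    part = BlockPartition(
        labels=np.empty(0, dtype=int),
        median_row=float(np.median(pts[:, 0])),
        median_col=float(np.median(pts[:, 1])),
    )
    labels = part.assign(pts)
    counts = np.bincount(labels, minlength=4)
    if (counts == 0).any():
        raise BlockPartitionError(
            f"empty spatial block(s) {np.flatnonzero(counts == 0).tolist()}; "
            "calibration points are too clustered — more data needed"
        )
    return dataclass_replace(part, labels=labels)


# ---------------------------------------------------------------------------
# continuous Boyce index

@dataclass
class BoyceCurve:
    """Predicted-to-expected ratio curve underlying the Boyce index.

    ``midpoints`` are suitability-window centres; P is the share of presence
    predictions in each window, E the share of background predictions, and
    F = P/E.  Windows overlap, so the P's need not sum to 1; windows with
    E = 0 are dropped before the rank correlation.
    """

    midpoints: np.ndarray
    presence_freq: np.ndarray
    expected_freq: np.ndarray

    @property
    def ratios(self) -> np.ndarray:
        return self.presence_freq / self.expected_freq


def boyce_curve(
    pred_at_presences: np.ndarray,
    pred_at_background: np.ndarray,
    window_width: float = 0.1,
    n_windows: int = 101,
) -> BoyceCurve:
    """P/E ratio curve over suitability windows tiling [0, 1].

    Both endpoints of each window are inclusive; windows without background
    mass are dropped.  Raises :class:`BoyceUndefinedError` for identical
    predictions or fewer than 3 retained windows.
    """
    p = np.asarray(pred_at_presences, dtype=float)
    b = np.asarray(pred_at_background, dtype=float)
    if p.size < 1 or b.size < 10:
        raise ValueError("need >=1 presence and >=10 background predictions")
    allv = np.concatenate([p, b])
    if allv.min() < 0 or allv.max() > 1:
        raise ValueError("predictions must lie in [0, 1]")
    if np.ptp(allv) == 0:
        raise BoyceUndefinedError("all predictions are identical; index undefined")

    half = window_width / 2
    mids = np.linspace(half, 1 - half, n_windows)
    lo, hi = mids - half, mids + half
    ps = np.sort(p)
    bs = np.sort(b)
    # inclusive window counts via sorted-array bisection
    pcount = np.searchsorted(ps, hi, side="right") - np.searchsorted(ps, lo, side="left")
    bcount = np.searchsorted(bs, hi, side="right") - np.searchsorted(bs, lo, side="left")
    P = pcount / p.size
    E = bcount / b.size
    keep = E > 0
    if keep.sum() < 3:
        raise BoyceUndefinedError("fewer than 3 windows contain background mass")
    return BoyceCurve(midpoints=mids[keep], presence_freq=P[keep], expected_freq=E[keep])


def boyce_index(
    pred_at_presences: np.ndarray,
    pred_at_background: np.ndarray,
    window_width: float = 0.1,
    n_windows: int = 101,
) -> tuple[float, BoyceCurve]:
    """Continuous Boyce index: Spearman correlation of F = P/E with suitability.

    Returns the index in [-1, 1] plus the retained curve.  Degenerate inputs
    (identical predictions, fewer than 3 windows with background mass, or a
    flat F curve) raise :class:`BoyceUndefinedError`.
    """
    curve = boyce_curve(pred_at_presences, pred_at_background, window_width, n_windows)
    F = curve.ratios
    if np.ptp(F) == 0:
        raise BoyceUndefinedError("P/E ratio curve is flat; rank correlation undefined")
    rho = spearmanr(F, curve.midpoints).statistic
    return float(rho), curve


# ---------------------------------------------------------------------------
# model families

class _GamModel:
    """Binomial GAM with B-spline smooths (statsmodels), sklearn-ish predict.

    Smoothness is selected on a small penalty-weight grid by held-out
    log-loss (an internal seeded 80/20 split), standing in for the automatic
    smoothness selection GAM libraries apply by default; the winning penalty
    is refitted on all data.
    """

    ALPHA_GRID = (1.0, 10.0, 100.0, 1000.0)

    def __init__(self, df: int = 6, degree: int = 3, seed: int = 0):
        self.df = df
        self.degree = degree
        self.seed = seed

    def _fit_one(self, X, y, alpha):
        import statsmodels.api as sm
        from statsmodels.gam.api import BSplines, GLMGam

        p = X.shape[1]
        bs = BSplines(X, df=[self.df] * p, degree=[self.degree] * p)
        model = GLMGam(y, exog=np.ones((len(X), 1)), smoother=bs,
                       family=sm.families.Binomial(), alpha=[alpha] * p)
        return model.fit()

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self._lo = X.min(axis=0)
        self._hi = X.max(axis=0)
        rng = np.random.default_rng(self.seed)
        idx = rng.permutation(len(X))
        n_val = max(1, len(X) // 5)
        val, tr = idx[:n_val], idx[n_val:]

        best_alpha, best_loss = None, np.inf
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for alpha in self.ALPHA_GRID:
                try:
                    res = self._fit_one(X[tr], y[tr], alpha)
                    pred = np.clip(
                        np.asarray(res.predict(np.ones((n_val, 1)),
                                               exog_smooth=np.clip(X[val], self._lo, self._hi))),
                        1e-9, 1 - 1e-9,
                    )
                    loss = -np.mean(y[val] * np.log(pred) + (1 - y[val]) * np.log(1 - pred))
                except Exception:
                    continue
                if loss < best_loss:
                    best_alpha, best_loss = alpha, loss
            if best_alpha is None:
                best_alpha = self.ALPHA_GRID[-1]
            self.alpha_ = best_alpha
            self._res = self._fit_one(X, y, best_alpha)
            self._bs = self._res.model.smoother
        return self

    def predict_proba_pos(self, X: np.ndarray) -> np.ndarray:
        # clip to the training hull: B-spline bases are undefined beyond it
        X = np.clip(np.asarray(X, dtype=float), self._lo, self._hi)
        return np.asarray(self._res.predict(np.ones((len(X), 1)), exog_smooth=X))


def _build_estimator(algorithm_id: str, seed: int):
    if algorithm_id == "linear-logistic":
        # quadratic terms are the standard SDM-GLM default: a purely linear
        # predictor cannot represent a unimodal (mid-range optimum) response
        return make_pipeline(
            PolynomialFeatures(degree=2, include_bias=False),
            StandardScaler(),
            LogisticRegression(max_iter=1000),
        )
    if algorithm_id == "additive-smooth":
        return _GamModel(seed=seed)
    if algorithm_id == "bagged-trees":
        return RandomForestClassifier(random_state=seed)
    if algorithm_id == "boosted-trees":
        return GradientBoostingClassifier(random_state=seed)
    raise ValueError(f"unknown algorithm {algorithm_id!r}; choose from {ALGORITHMS}")


@dataclass
class FittedSDM:
    """A trained model family with its CV score attached.

    ``cv_boyce`` is the mean continuous Boyce index over the spatial CV
    folds (NaN if every fold was undefined -> the model is rejected).
    """

    algorithm: str
    predictor_names: tuple[str, ...]
    predictor_set: str
    estimator: object
    seed: int
    cv_boyce: float = np.nan
    fold_boyce: list = field(default_factory=list)

    def predict(self, env: pd.DataFrame | np.ndarray) -> np.ndarray:
        if isinstance(env, pd.DataFrame):
            X = env[list(self.predictor_names)].to_numpy(dtype=float)
        else:
            X = np.asarray(env, dtype=float)
        if isinstance(self.estimator, _GamModel):
            out = self.estimator.predict_proba_pos(X)
        else:
            out = self.estimator.predict_proba(X)[:, 1]
        return np.clip(out, 0.0, 1.0)


def _design(presence_env: pd.DataFrame, pa_env: pd.DataFrame, names: list[str]):
    X = np.vstack([
        presence_env[names].to_numpy(dtype=float),
        pa_env[names].to_numpy(dtype=float),
    ])
    y = np.concatenate([np.ones(len(presence_env)), np.zeros(len(pa_env))])
    for j, n in enumerate(names):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"predictor {n!r} is constant over the calibration data")
    return X, y


def fit(
    algorithm_id: str,
    presences: pd.DataFrame,
    pas: pd.DataFrame,
    predictor_set: tuple[str, ...] | list[str],
    seed: int,
    predictor_set_id: str = "",
    enforce_balance: bool = True,
) -> FittedSDM:
    """Fit one model family on the full calibration data (1=presence, 0=PA)."""
    names = list(predictor_set)
    if enforce_balance:
        if len(presences) < 30:
            raise ValueError("need at least 30 presence records to fit")
        if len(pas) != len(presences):
            raise ValueError("pseudo-absence count must equal presence count")
    X, y = _design(presences, pas, names)
    est = _build_estimator(algorithm_id, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
    return FittedSDM(
        algorithm=algorithm_id,
        predictor_names=tuple(names),
        predictor_set=predictor_set_id,
        estimator=est,
        seed=seed,
    )


def cross_validate(
    algorithm_id: str,
    presences: pd.DataFrame,
    pas: pd.DataFrame,
    predictor_set: tuple[str, ...] | list[str],
    background: pd.DataFrame,
    seed: int,
    blocks: BlockPartition | None = None,
    window_width: float = 0.1,
    n_windows: int = 101,
) -> tuple[float, list[float]]:
    """4-fold spatial block CV; returns (cv_boyce, per-fold Boyce values).

    Each block is held out once; the model is trained on the other three and
    scored by the Boyce index of its predictions at the held-out presences
    against the background cells *of the held-out block* (``background`` must
    carry row/col coordinates plus the predictor columns).  Comparing against
    the block's own available environment is essential: a block need not
    contain the full suitability range, and a full-landscape expectation
    would make even a perfect model look hump-shaped.  Folds with no
    held-out presences or an undefined index are dropped (NaN in the fold
    list); cv_boyce is NaN if every fold is undefined, rejecting the model.
    """
    names = list(predictor_set)
    coords = np.vstack([presences[["row", "col"]].to_numpy(), pas[["row", "col"]].to_numpy()])
    if blocks is None:
        blocks = make_blocks(coords)
    labels = blocks.labels
    back_blocks = blocks.assign(background[["row", "col"]].to_numpy())
    is_pres = np.concatenate([np.ones(len(presences), bool), np.zeros(len(pas), bool)])
    env_all = pd.concat([presences, pas], ignore_index=True)

    fold_scores: list[float] = []
    for k in range(4):
        train = labels != k
        test_pres = is_pres & (labels == k)
        if test_pres.sum() == 0:
            warnings.warn(f"fold {k}: no held-out presences; fold dropped")
            fold_scores.append(np.nan)
            continue
        tr_pres = env_all[train & is_pres]
        tr_pa = env_all[train & ~is_pres]
        if len(tr_pres) == 0 or len(tr_pa) == 0:
            warnings.warn(f"fold {k}: one-class training data; fold dropped")
            fold_scores.append(np.nan)
            continue
        try:
            model = fit(algorithm_id, tr_pres, tr_pa, names, seed=seed,
                        predictor_set_id="cv", enforce_balance=False)
            pred_pres = model.predict(env_all[test_pres])
            pred_back = model.predict(background[back_blocks == k])
            score, _ = boyce_index(pred_pres, pred_back, window_width, n_windows)
        except Exception as exc:  # fold isolation: a failed fold never aborts CV
            warnings.warn(f"fold {k}: dropped ({type(exc).__name__}: {exc})")
            fold_scores.append(np.nan)
            continue
        fold_scores.append(score)
    arr = np.asarray(fold_scores, dtype=float)
    cv = float(np.nanmean(arr)) if np.isfinite(arr).any() else float("nan")
    return cv, fold_scores
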