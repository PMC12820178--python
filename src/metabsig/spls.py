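"""Single-component sparse partial least squares (sPLS) BMI scoring.

The direction vector is the soft-thresholded vector of metabolite-BMI
correlations (the classical one-component PLS direction with an L1-style
threshold): with ``c_j = corr(Z_j, y)`` and sparsity ``eta`` in [0, 1],

    w_j = sign(c_j) * max(0, |c_j| - eta * max_k |c_k|),   w <- w / ||w||.

The metabolite score is ``s = Z w``; a final univariate regression of y on s
supplies the score->BMI slope used for prediction.  ``eta = 0`` recovers
exact one-component PLS; larger ``eta`` zeroes progressively more
metabolites, with ``eta = 1`` thresholding everything away (invalid).

Sparsity is tuned on a grid (default 0, 0.1, ..., 1) by repeated k-fold
cross-validation, selecting the grid value with the lowest RMSECV (root mean
squared error of held-out predictions, reported in response-SD units);
within each fold the metabolite matrix and response are standardised on the
training rows only, so the held-out error is leakage-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold, StratifiedKFold

from ._utils import as_frame, rng_from

__all__ = [
    "SparsePLS",
    "SparsePLSCV",
    "TuningResult",
    "fit_spls_one_component",
    "tune_sparsity",
    "predict_score",
    "transfer_fit",
]

DEFAULT_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))


def _soft_threshold_direction(c: np.ndarray, eta: float) -> np.ndarray:
    thr = eta * np.max(np.abs(c))
    w = np.sign(c) * np.clip(np.abs(c) - thr, 0.0, None)
    peak = np.max(np.abs(w))
    if peak == 0:
        return w
    w = w / peak  # pre-scale so the norm cannot under/overflow
    return w / np.linalg.norm(w)


def _standardize_cols(V: np.ndarray):
    mu = V.mean(axis=0)
    sd = V.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)  # constant columns contribute nothing
    return (V - mu) / sd, mu, sd


class SparsePLS(RegressorMixin, BaseEstimator):
    """One-component sparse PLS regressor of a response on metabolites.

    Parameters
    ----------
    eta : float in [0, 1)
        Sparsity level; fraction of the largest absolute correlation used as
        the soft threshold. 0 keeps every metabolite.

    Attributes
    ----------
    weights_ : pd.Series
        Unit-norm sparse direction over the training columns, oriented so the
        training score correlates positively with the response.
    slope_ : float
        Regression slope of the standardised response on the training score.
    x_mean_, x_scale_, y_mean_, y_scale_ : training standardisation.
    """

    def __init__(self, eta: float = 0.0):
        self.eta = eta

    def fit(self, X, y):
        if not (0.0 <= self.eta <= 1.0):
            raise ValueError(f"eta must lie in [0, 1]; got {self.eta}")
        X = as_frame(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != len(X):
            raise ValueError("X and y have different lengths")
        Z, self.x_mean_, self.x_scale_ = _standardize_cols(X.to_numpy(dtype=float))
        ysd = y.std(ddof=1)
        if ysd <= 0:
            raise ValueError("response is constant; cannot fit")
        self.y_mean_, self.y_scale_ = float(y.mean()), float(ysd)
        yz = (y - self.y_mean_) / self.y_scale_

        c = Z.T @ yz / (len(y) - 1)  # metabolite-response correlations
        w = _soft_threshold_direction(c, self.eta)
        if not np.any(w):
            raise ValueError(
                f"eta={self.eta} soft-thresholds every weight to zero "
                "(threshold equals the largest |correlation|); use a smaller eta"
            )
        s = Z @ w
        denom = float(s @ s)
        slope = float(s @ yz) / denom
        if slope < 0:  # orient so higher score = higher predicted response
            w, slope = -w, -slope
        self.columns_ = list(X.columns)
        self.weights_ = pd.Series(w, index=self.columns_, name="weight")
        self.slope_ = slope
        self.n_features_in_ = X.shape[1]
        return self

    # -- projection -----------------------------------------------------
    def _check_columns(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.columns_ if c not in X.columns]
        extra = [c for c in X.columns if c not in self.columns_]
        if missing or extra:
            raise ValueError(
                f"column mismatch with the fitted model: missing={missing[:5]}"
                f"{'...' if len(missing) > 5 else ''}, extra={extra[:5]}"
                f"{'...' if len(extra) > 5 else ''}"
            )
        return X[self.columns_]

    def transform(self, X) -> np.ndarray:
        """Raw (un-normalised) latent score using the training standardisation."""
        X = self._check_columns(as_frame(X, columns=self.columns_))
        Z = (X.to_numpy(dtype=float) - self.x_mean_) / self.x_scale_
        return Z @ self.weights_.to_numpy()

    def predict(self, X) -> np.ndarray:
        return self.y_mean_ + self.y_scale_ * self.slope_ * self.transform(X)

    @property
    def selected_ids(self) -> list:
        return list(self.weights_.index[self.weights_ != 0])


@dataclass(frozen=True)
class TuningResult:
    """Cross-validation summary across the sparsity grid."""

    grid: tuple
    rmsecv: pd.Series          # per eta, response-SD units
    r2cv: pd.Series            # per eta
    rmsecv_sd: pd.Series       # SD across repeats
    selected_eta: float
    folds: int
    repeats: int
    seed: int


def _cv_splitter(y, folds, rng, stratify):
    seed = int(rng.integers(0, 2**31 - 1))
    if stratify:
        tert = pd.qcut(pd.Series(y).rank(method="first"), 3, labels=False)
        return StratifiedKFold(folds, shuffle=True, random_state=seed).split(
            np.zeros(len(y)), tert)
    return KFold(folds, shuffle=True, random_state=seed).split(np.zeros(len(y)))


def tune_sparsity(X, y, grid=DEFAULT_GRID, folds: int = 5, repeats: int = 10,
                  seed: int = 0, stratify: bool = True, selection: str = "best",
                  tolerance: float = 0.01) -> TuningResult:
    """Repeated k-fold cross-validation of RMSECV over the sparsity grid.

    Folds are (by default) stratified by response tertile.  A grid value that
    thresholds every weight to zero on some training fold falls back to
    predicting the fold-training mean there.

    ``selection="best"`` picks the lowest RMSECV (ties resolve to the
    largest, i.e. sparsest, eta); ``selection="tolerance"`` picks the
    sparsest eta whose RMSECV is within ``tolerance`` (fractional) of the
    minimum, trading a sliver of CV error for parsimony.
    """
    grid = tuple(grid)
    if not grid:
        raise ValueError("sparsity grid is empty")
    X = as_frame(X)
    y = np.asarray(y, dtype=float).ravel()
    if len(y) < 2 * folds:
        raise ValueError(f"need at least {2 * folds} samples for {folds}-fold CV")
    rng = rng_from(seed)
    sse = np.zeros((repeats, len(grid)))
    sst = np.zeros(repeats)
    n_held = np.zeros(repeats)
    V = X.to_numpy(dtype=float)
    for r in range(repeats):
        for train, test in _cv_splitter(y, folds, rng, stratify):
            Ztr, mu, sd = _standardize_cols(V[train])
            y_mu, y_sd = y[train].mean(), y[train].std(ddof=1)
            yz = (y[train] - y_mu) / y_sd
            c = Ztr.T @ yz / (len(train) - 1)
            Zte = (V[test] - mu) / sd
            for g, eta in enumerate(grid):
                w = _soft_threshold_direction(c, eta)
                if np.any(w):
                    s = Ztr @ w
                    slope = float(s @ yz) / float(s @ s)
                    pred = y_mu + y_sd * slope * (Zte @ w)
                else:
                    pred = np.full(len(test), y_mu)
                sse[r, g] += np.sum((y[test] - pred) ** 2)
            sst[r] += np.sum((y[test] - y_mu) ** 2)
            n_held[r] += len(test)
    y_sd_all = y.std(ddof=1)
    rmse_per_repeat = np.sqrt(sse / n_held[:, None]) / y_sd_all
    rmsecv = np.sqrt(sse.sum(axis=0) / n_held.sum()) / y_sd_all
    r2cv = 1.0 - sse.sum(axis=0) / sst.sum()
    best = rmsecv.min()
    if selection == "best":
        cutoff = best + 1e-12
    elif selection == "tolerance":
        cutoff = best * (1.0 + tolerance)
    else:
        raise ValueError(f"selection must be 'best' or 'tolerance'; got {selection!r}")
    selected = max(eta for g, eta in enumerate(grid) if rmsecv[g] <= cutoff)
    idx = pd.Index(grid, name="eta")
    return TuningResult(
        grid=grid,
        rmsecv=pd.Series(rmsecv, index=idx, name="rmsecv"),
        r2cv=pd.Series(r2cv, index=idx, name="r2cv"),
        rmsecv_sd=pd.Series(rmse_per_repeat.std(axis=0, ddof=1) if repeats > 1
                            else np.zeros(len(grid)), index=idx, name="rmsecv_sd"),
        selected_eta=float(selected),
        folds=folds, repeats=repeats, seed=seed,
    )


class SparsePLSCV(SparsePLS):
    """Sparse PLS with the sparsity level tuned by repeated cross-validation,
    then refitted on the full data at the selected eta."""

    def __init__(self, grid=DEFAULT_GRID, folds: int = 5, repeats: int = 10,
                 seed: int = 0, stratify: bool = True):
        self.grid = grid
        self.folds = folds
        self.repeats = repeats
        self.seed = seed
        self.stratify = stratify

    def fit(self, X, y):
        self.tuning_ = tune_sparsity(X, y, grid=self.grid, folds=self.folds,
                                     repeats=self.repeats, seed=self.seed,
                                     stratify=self.stratify)
        self.eta = self.tuning_.selected_eta
        if self.eta >= 1.0:
            # eta=1 is intercept-only (all weights thresholded); keep the best
            # eta that yields a non-empty model for the refit.
            usable = self.tuning_.rmsecv[[e for e in self.tuning_.grid if e < 1.0]]
            self.eta = float(usable.idxmin())
        super().fit(X, y)
        self.rmsecv_ = float(self.tuning_.rmsecv[self.eta])
        self.r2cv_ = float(self.tuning_.r2cv[self.eta])
        return self

    def get_params(self, deep=True):
        return {"grid": self.grid, "folds": self.folds, "repeats": self.repeats,
                "seed": self.seed, "stratify": self.stratify}


def fit_spls_one_component(Z, y, eta: float) -> SparsePLS:
    """Fit a single-component sparse PLS model (thin estimator wrapper)."""
    return SparsePLS(eta=eta).fit(Z, y)


def predict_score(model: SparsePLS, X_ext, pre_standardized: bool = False) -> pd.Series:
    """Project an external cohort onto the model and z-score within cohort.

    The external matrix must carry exactly the model's training columns.  By
    default columns are standardised within the external cohort (mirroring
    the same log/centre/scale preprocessing applied per cohort); pass
    ``pre_standardized=True`` if that was already done.
    """
    X_ext = as_frame(X_ext, columns=model.columns_)
    X_ext = model._check_columns(X_ext)
    V = X_ext.to_numpy(dtype=float)
    Z = V if pre_standardized else _standardize_cols(V)[0]
    raw = Z @ model.weights_.to_numpy()
    sd = raw.std(ddof=1)
    if sd <= 0:
        raise ValueError("projected score is constant; cannot z-score")
    return pd.Series((raw - raw.mean()) / sd, index=X_ext.index, name="metabolite_score")


def transfer_fit(X_train, y_train, overlap_ids, grid=DEFAULT_GRID, folds: int = 5,
                 repeats: int = 10, seed: int = 0, stratify: bool = True) -> SparsePLSCV:
    """Re-tune and refit on the training cohort restricted to the metabolites
    shared with an external cohort (one distinct model per external panel)."""
    X_train = as_frame(X_train)
    overlap = list(overlap_ids)
    if not overlap:
        raise ValueError("overlap_ids is empty")
    missing = [c for c in overlap if c not in X_train.columns]
    if missing:
        raise ValueError(f"overlap_ids not in training matrix: {missing[:5]}")
    return SparsePLSCV(grid=grid, folds=folds, repeats=repeats, seed=seed,
                       stratify=stratify).fit(X_train[overlap], y_train)
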