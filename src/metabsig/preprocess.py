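"""Metabolome preprocessing: missingness filtering, random-forest imputation,
log/centre/scale standardisation, covariate imputation by one-component
iterative PCA, twin de-duplication, and a missingness-vs-outcome diagnostic.

The processing order is filter -> de-duplicate -> log-transform -> impute on
the log scale -> centre/scale.  Imputation runs on the (approximately
Gaussian) log scale; observed cells are never altered by any imputer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestRegressor

from ._utils import rng_from

__all__ = [
    "PreprocessReport",
    "MissingnessFilter",
    "ForestImputer",
    "LogCenterScaler",
    "IterativePCAImputer",
    "filter_by_missingness",
    "rf_impute",
    "log_center_scale",
    "pca_impute_covariates",
    "dedupe_twins",
    "missingness_outcome_association",
]


@dataclass
class PreprocessReport:
    """Bookkeeping for one preprocessing run."""

    n_input_metabolites: int = 0
    n_excluded_missingness: int = 0
    missing_fractions: pd.Series | None = None
    excluded_ids: list = field(default_factory=list)
    imputation_iterations: int = 0
    standardization: pd.DataFrame | None = None  # per-column log-scale mean/sd
    warnings: list = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return self.n_input_metabolites - self.n_excluded_missingness


class MissingnessFilter(TransformerMixin, BaseEstimator):
    """Drop metabolites whose missing fraction is strictly above the threshold.

    "More than 33% missing" reads as strict inequality: a column missing at
    exactly the threshold is retained. Survivor order is preserved.
    """

    def __init__(self, max_missing_frac: float = 1.0 / 3.0):
        self.max_missing_frac = max_missing_frac

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        frac = X.isna().mean(axis=0)
        self.missing_fractions_ = frac
        self.keep_columns_ = [c for c in X.columns if frac[c] <= self.max_missing_frac]
        self.dropped_columns_ = [c for c in X.columns if frac[c] > self.max_missing_frac]
        if not self.keep_columns_:
            raise ValueError(
                f"missingness filter at {self.max_missing_frac:.3f} removed every "
                "metabolite; nothing left to analyse"
            )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X)[self.keep_columns_]


def filter_by_missingness(matrix: pd.DataFrame, max_missing_frac: float = 1.0 / 3.0,
                          ) -> tuple[pd.DataFrame, PreprocessReport]:
    f = MissingnessFilter(max_missing_frac).fit(matrix)
    report = PreprocessReport(
        n_input_metabolites=matrix.shape[1],
        n_excluded_missingness=len(f.dropped_columns_),
        missing_fractions=f.missing_fractions_,
        excluded_ids=list(f.dropped_columns_),
    )
    return f.transform(matrix), report


class ForestImputer(TransformerMixin, BaseEstimator):
    """missForest-style iterative random-forest imputation.

    Missing cells start at column means; columns are then revisited in order
    of descending missingness count (ties by position) and each incomplete
    column is re-predicted from all others by a random forest trained on its
    observed rows.  Sweeps stop when the normalised change in the imputed
    values increases (the previous iterate is returned) or at ``max_iter``.
    No distributional missing-at-random assumption is made.
    """

    def __init__(self, n_estimators: int = 100, max_iter: int = 10,
                 random_state: int = 0, min_samples_leaf: int = 5):
        self.n_estimators = n_estimators
        self.max_iter = max_iter
        self.random_state = random_state
        self.min_samples_leaf = min_samples_leaf

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        X = pd.DataFrame(X)
        mask = X.isna()
        all_missing = mask.all(axis=0)
        if all_missing.any():
            bad = list(X.columns[all_missing])
            raise ValueError(f"columns with no observed values cannot be imputed: {bad}")
        self.n_iter_ = 0
        if not mask.to_numpy().any():
            return X.copy()

        vals = X.to_numpy(dtype=float).copy()
        m = mask.to_numpy()
        col_means = np.nanmean(X.to_numpy(dtype=float), axis=0)
        for j in range(vals.shape[1]):
            vals[m[:, j], j] = col_means[j]

        counts = m.sum(axis=0)
        order = sorted(np.flatnonzero(counts > 0), key=lambda j: (-counts[j], j))
        rng = np.random.RandomState(self.random_state)
        prev_delta = np.inf
        prev_vals = vals.copy()
        for it in range(self.max_iter):
            before = vals.copy()
            for j in order:
                obs = ~m[:, j]
                other = np.delete(np.arange(vals.shape[1]), j)
                rf = RandomForestRegressor(
                    n_estimators=self.n_estimators,
                    min_samples_leaf=self.min_samples_leaf,
                    random_state=rng.randint(0, 2**31 - 1),
                )
                rf.fit(vals[obs][:, other], vals[obs, j])
                vals[m[:, j], j] = rf.predict(vals[m[:, j]][:, other])
            delta = np.sum((vals[m] - before[m]) ** 2) / max(np.sum(vals[m] ** 2), 1e-12)
            self.n_iter_ = it + 1
            if delta >= prev_delta:
                vals = prev_vals  # change grew: keep the previous iterate
                break
            prev_delta = delta
            prev_vals = vals.copy()
        out = pd.DataFrame(vals, index=X.index, columns=X.columns)
        out[~mask] = X[~mask]  # observed cells are authoritative
        return out

    def transform(self, X):
        return self.fit_transform(X)

    def fit(self, X, y=None):
        return self


def rf_impute(matrix: pd.DataFrame, seed: int = 0, max_iter: int = 10,
              n_estimators: int = 100) -> pd.DataFrame:
    return ForestImputer(n_estimators=n_estimators, max_iter=max_iter,
                         random_state=seed).fit_transform(matrix)


class LogCenterScaler(TransformerMixin, BaseEstimator):
    """Per-metabolite natural log, centre, scale; parameters are stored so the
    training transform can be replayed exactly on an external cohort."""

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        vals = X.to_numpy(dtype=float)
        bad = np.argwhere(~(vals > 0))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"non-positive abundance at row {X.index[i]!r}, column "
                f"{X.columns[j]!r} ({vals[i, j]!r}); log transform requires "
                "strictly positive values"
            )
        logs = np.log(vals)
        mean = logs.mean(axis=0)
        sd = logs.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd <= 0)
        if zero.size:
            raise ValueError(f"zero-variance columns cannot be scaled: "
                             f"{list(X.columns[zero])}")
        self.columns_ = list(X.columns)
        self.log_mean_ = pd.Series(mean, index=X.columns)
        self.log_sd_ = pd.Series(sd, index=X.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)[self.columns_]
        vals = X.to_numpy(dtype=float)
        if not (vals > 0).all():
            raise ValueError("non-positive abundance in data to transform")
        z = (np.log(vals) - self.log_mean_.to_numpy()) / self.log_sd_.to_numpy()
        return pd.DataFrame(z, index=X.index, columns=self.columns_)

    def transform_pre_logged(self, L: pd.DataFrame) -> pd.DataFrame:
        """Centre/scale a matrix already on the log scale."""
        L = pd.DataFrame(L)[self.columns_]
        z = (L.to_numpy(dtype=float) - self.log_mean_.to_numpy()) / self.log_sd_.to_numpy()
        return pd.DataFrame(z, index=L.index, columns=self.columns_)


def log_center_scale(matrix: pd.DataFrame) -> tuple[pd.DataFrame, LogCenterScaler]:
    scaler = LogCenterScaler().fit(matrix)
    return scaler.transform(matrix), scaler


class IterativePCAImputer(TransformerMixin, BaseEstimator):
    """Iterative low-rank (default rank-1) PCA imputation of a numeric table.

    Missing cells start at column means; each sweep centres/scales the
    current table, reconstructs it from the leading singular vectors, and
    overwrites the missing cells with the reconstruction, until the imputed
    cells move less than ``tol``.
    """

    def __init__(self, n_components: int = 1, tol: float = 1e-6,
                 max_iter: int = 1000, scale: bool = True):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.scale = scale

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        X = pd.DataFrame(X)
        mask = X.isna().to_numpy()
        vals = X.to_numpy(dtype=float).copy()
        obs_counts = (~mask).sum(axis=0)
        if (obs_counts < 2).any():
            bad = list(X.columns[obs_counts < 2])
            raise ValueError(f"columns need >=2 observed values for PCA imputation: {bad}")
        self.converged_ = True
        self.n_iter_ = 0
        if not mask.any():
            return X.copy()
        col_means = np.nanmean(np.where(mask, np.nan, vals), axis=0)
        vals[mask] = np.broadcast_to(col_means, vals.shape)[mask]
        for it in range(self.max_iter):
            mu = vals.mean(axis=0)
            sd = vals.std(axis=0, ddof=1) if self.scale else np.ones(vals.shape[1])
            sd = np.where(sd > 0, sd, 1.0)
            Z = (vals - mu) / sd
            U, S, Vt = np.linalg.svd(Z, full_matrices=False)
            k = min(self.n_components, len(S))
            recon = (U[:, :k] * S[:k]) @ Vt[:k] * sd + mu
            change = np.max(np.abs(recon[mask] - vals[mask]))
            vals[mask] = recon[mask]
            self.n_iter_ = it + 1
            if change < self.tol:
                break
        else:
            self.converged_ = False
            warnings.warn("IterativePCAImputer did not converge within "
                          f"{self.max_iter} iterations; returning last iterate")
        return pd.DataFrame(vals, index=X.index, columns=X.columns)

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return self.fit_transform(X)


def pca_impute_covariates(covariates: pd.DataFrame, n_components: int = 1,
                          tol: float = 1e-6, max_iter: int = 1000) -> pd.DataFrame:
    """Complete a mixed-type covariate table by one-component iterative PCA.

    Categorical columns are one-hot expanded before imputation and collapsed
    back afterwards to the category with the largest reconstructed indicator;
    numeric columns are imputed in place.
    """
    cat_cols = [c for c in covariates.columns
                if covariates[c].dtype == object
                or isinstance(covariates[c].dtype, pd.CategoricalDtype)]
    num_cols = [c for c in covariates.columns if c not in cat_cols]

    blocks, onehot_map = [], {}
    if num_cols:
        blocks.append(covariates[num_cols].astype(float))
    for c in cat_cols:
        dummies = pd.get_dummies(covariates[c], prefix=c, dtype=float)
        dummies[covariates[c].isna()] = np.nan
        onehot_map[c] = list(dummies.columns)
        blocks.append(dummies)
    expanded = pd.concat(blocks, axis=1)

    imputer = IterativePCAImputer(n_components=n_components, tol=tol, max_iter=max_iter)
    completed = imputer.fit_transform(expanded)

    out = covariates.copy()
    for c in num_cols:
        out[c] = completed[c]
    for c in cat_cols:
        cols = onehot_map[c]
        winner = completed[cols].to_numpy().argmax(axis=1)
        labels = [col[len(c) + 1:] for col in cols]
        filled = pd.Series([labels[w] for w in winner], index=covariates.index)
        out[c] = covariates[c].where(covariates[c].notna(), filled)
    return out


def dedupe_twins(data, seed: int = 0):
    """Keep exactly one pregnancy record per family (seeded uniform choice).

    Accepts a :class:`~metabsig.synthetic.CohortData`; returns a new one with
    duplicated ``family_id`` rows reduced to a single randomly chosen member.
    """
    rng = rng_from(seed)
    fam = data.family_id
    keep = []
    for _, idx in fam.groupby(fam, sort=False).groups.items():
        idx = list(idx)
        keep.append(idx[rng.integers(0, len(idx))] if len(idx) > 1 else idx[0])
    keep = [i for i in fam.index if i in set(keep)]  # preserve sample order
    out = data.copy()
    out.abundances = out.abundances.loc[keep]
    out.covariates = out.covariates.loc[keep]
    out.bmi = out.bmi.loc[keep]
    out.outcomes = out.outcomes.loc[keep]
    out.family_id = out.family_id.loc[keep]
    return out


def missingness_outcome_association(mask: pd.DataFrame, outcome: pd.Series,
                                    metabolite_subset, covariates: pd.DataFrame | None = None,
                                    predictor: str = "any"):
    """Logistic regression of an outcome on missingness among selected
    metabolites — the diagnostic for outcome-dependent (non-random) holes.

    ``predictor`` is ``"any"`` (indicator: at least one selected metabolite
    missing for the sample, the default) or ``"count"`` (z-scored number of
    missing selected metabolites).
    """
    from .association import fit_logistic  # local import avoids a cycle

    subset = list(metabolite_subset)
    if not subset:
        raise ValueError("metabolite_subset must be non-empty")
    sub = mask[subset]
    if predictor == "any":
        x = sub.any(axis=1).astype(float)
    elif predictor == "count":
        x = sub.sum(axis=1).astype(float)
    else:
        raise ValueError(f"predictor must be 'any' or 'count'; got {predictor!r}")
    if x.nunique() < 2:
        raise ValueError(
            "missingness predictor is constant across samples (no or uniform "
            "missingness in the subset); association is inestimable"
        )
    if predictor == "count":
        x = (x - x.mean()) / x.std(ddof=1)
    return fit_logistic(outcome, x.rename("missingness"), covariates)
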