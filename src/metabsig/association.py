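"""Multivariable logistic models of binary pregnancy complications.

Exposures (pre-pregnancy BMI, metabolite scores) are z-scored so odds ratios
read per 1 SD increase in the predictor; inference is by two-sided Wald
tests with normal-quantile 95% intervals, and nested models are compared by
likelihood-ratio tests against the chi-squared distribution. No adjustment
is made for multiple comparisons across the association table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._utils import Z_CRIT

__all__ = [
    "LogisticFit",
    "LRTResult",
    "standardize_predictor",
    "fit_logistic",
    "adjusted_score_model",
    "likelihood_ratio_test",
    "association_table",
    "format_or",
    "parse_or",
]

_SEPARATION_BOUND = 15.0  # |log-odds| beyond this flags (quasi-)separation


@dataclass
class LogisticFit:
    """A fitted logistic model: per-term Wald table plus log-likelihood."""

    table: pd.DataFrame  # term, estimate, se, z, p, OR, ci_low, ci_high
    llf: float
    n: int
    outcome: str
    formula: str
    exposure: str | None = None

    def term(self, name: str) -> pd.Series:
        return self.table.set_index("term").loc[name]

    @property
    def exposure_row(self) -> pd.Series:
        if self.exposure is None:
            raise ValueError("fit has no designated exposure term")
        return self.term(self.exposure)

    @property
    def terms(self) -> list:
        return list(self.table["term"])


def standardize_predictor(v) -> tuple[pd.Series, float, float]:
    """Z-score a continuous predictor; returns (z, mean, SD)."""
    s = pd.Series(v).astype(float)
    sd = s.std(ddof=1)
    if not np.isfinite(sd) or sd <= 0:
        raise ValueError("predictor is constant (zero SD); cannot standardize")
    mu = s.mean()
    return (s - mu) / sd, float(mu), float(sd)


def _build_design(exposure, covariates, extra=None) -> pd.DataFrame:
    parts = []
    if exposure is not None:
        e = pd.Series(exposure)
        parts.append(e.rename(e.name or "exposure").astype(float))
    if extra is not None:
        for s in extra:
            parts.append(pd.Series(s).astype(float))
    if covariates is not None and len(covariates.columns) > 0:
        parts.append(covariates.astype(float))
    X = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=pd.Series(exposure).index)
    return sm.add_constant(X, has_constant="add")


def _check_rank(X: pd.DataFrame) -> None:
    vals = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(vals)
    if rank < vals.shape[1]:
        # name aliased columns via the small diagonal entries of QR's R
        _, r = np.linalg.qr(vals)
        diag = np.abs(np.diag(r))
        aliased = [X.columns[j] for j in range(vals.shape[1])
                   if diag[j] < 1e-8 * max(diag.max(), 1.0)]
        if not aliased:
            aliased = ["<linear combination of columns>"]
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")


def fit_logistic(outcome, exposure=None, covariates: pd.DataFrame | None = None,
                 extra_terms=None, outcome_name: str | None = None) -> LogisticFit:
    """Maximum-likelihood logistic regression with per-SD Wald inference.

    ``exposure`` is the focal continuous (typically z-scored) predictor;
    ``covariates`` enter unpenalised.  Raises on one-class outcomes, rank
    deficiency (naming aliased columns) and separation.
    """
    y = pd.Series(outcome).astype(float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.nunique() < 2:
        raise ValueError(f"outcome {y.name!r} has a single class; inestimable")
    X = _build_design(exposure, covariates, extra_terms)
    X.index = y.index
    keep = X.notna().all(axis=1) & y.notna()
    X, y = X.loc[keep], y.loc[keep]
    _check_rank(X)
    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import (PerfectSeparationError,
                                                 PerfectSeparationWarning)

    model = sm.Logit(y.to_numpy(), X.to_numpy())
    try:
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always", PerfectSeparationWarning)
            res = model.fit(disp=0, maxiter=100, tol=1e-8)
            if not res.mle_retvals.get("converged", True) and \
                    np.max(np.abs(res.params)) <= _SEPARATION_BOUND:
                # Newton stalls on flat likelihoods; retry with L-BFGS
                res = model.fit(disp=0, method="lbfgs", maxiter=1000)
        if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
            raise ValueError("separation detected: an outcome class is perfectly "
                             "predicted; the odds ratio is not estimable")
    except PerfectSeparationError as err:
        raise ValueError(f"separation detected: {err}") from err
    except np.linalg.LinAlgError as err:
        raise ValueError(f"logistic fit failed (singular IRLS step): {err}") from err
    if np.max(np.abs(res.params)) > _SEPARATION_BOUND:
        raise ValueError("separation detected: a coefficient diverged beyond "
                         "any plausible log-odds; the odds ratio is not estimable")
    if not res.mle_retvals.get("converged", True):
        raise ValueError("logistic fit did not converge")
    est, se = np.asarray(res.params), np.asarray(res.bse)
    z = est / se
    p = 2 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame({
        "term": list(X.columns),
        "estimate": est,
        "se": se,
        "z": z,
        "p": p,
        "OR": np.exp(est),
        "ci_low": np.exp(est - Z_CRIT * se),
        "ci_high": np.exp(est + Z_CRIT * se),
    })
    exp_name = None
    if exposure is not None:
        e = pd.Series(exposure)
        exp_name = e.name or "exposure"
    return LogisticFit(
        table=table, llf=float(res.llf), n=int(len(y)),
        outcome=outcome_name or (pd.Series(outcome).name or "outcome"),
        formula=f"{outcome_name or 'outcome'} ~ " + " + ".join(X.columns),
        exposure=exp_name,
    )


def adjusted_score_model(outcome, score, bmi, covariates: pd.DataFrame | None = None,
                         outcome_name: str | None = None) -> LogisticFit:
    """Logistic model with both the metabolite score and BMI; the score's row
    is the BMI-conditional (independent-of-anthropometry) odds ratio."""
    score = pd.Series(score).rename(pd.Series(score).name or "score")
    bmi = pd.Series(bmi).rename(pd.Series(bmi).name or "bmi")
    return fit_logistic(outcome, score, covariates, extra_terms=[bmi],
                        outcome_name=outcome_name)


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio comparison of nested logistic models."""

    statistic: float
    df: int
    p: float


def likelihood_ratio_test(full: LogisticFit, reduced: LogisticFit) -> LRTResult:
    if not set(reduced.terms) <= set(full.terms):
        raise ValueError("models are not nested: reduced terms "
                         f"{set(reduced.terms) - set(full.terms)} absent from full")
    if full.n != reduced.n:
        raise ValueError(f"models fitted on different samples (n={full.n} vs {reduced.n})")
    df = len(full.terms) - len(reduced.terms)
    stat = 2.0 * (full.llf - reduced.llf)
    if stat < -1e-8:
        raise ValueError(f"negative LRT statistic ({stat:.3g}); models are not nested "
                         "or a fit failed to converge")
    stat = max(stat, 0.0)
    if df == 0:  # identical term sets: nothing added, no evidence either way
        return LRTResult(statistic=stat, df=0, p=1.0)
    return LRTResult(statistic=float(stat), df=df, p=float(stats.chi2.sf(stat, df)))


def format_or(or_: float, lo: float, hi: float) -> str:
    return f"{or_:.2f} [{lo:.2f}–{hi:.2f}]"


def parse_or(s: str) -> tuple[float, float, float]:
    body, rest = s.split("[")
    lo, hi = rest.rstrip("]").split("–")
    return float(body), float(lo), float(hi)


def association_table(outcomes: pd.DataFrame, exposures: dict,
                      covariates: pd.DataFrame | None = None,
                      on_error: str = "raise") -> pd.DataFrame:
    """One Wald row per (outcome, exposure): per-SD OR, 95% CI, p, n.

    Exposures are z-scored here; no multiplicity adjustment is applied.
    With ``on_error="note"`` an inestimable model (separation, one-class
    outcome) yields a row of NaNs carrying the error message instead of
    aborting the whole table.
    """
    if on_error not in ("raise", "note"):
        raise ValueError(f"on_error must be 'raise' or 'note'; got {on_error!r}")
    rows = []
    for out_name in outcomes.columns:
        y = outcomes[out_name]
        for exp_name, vec in exposures.items():
            z, _, _ = standardize_predictor(vec)
            try:
                fit = fit_logistic(y, z.rename(exp_name), covariates,
                                   outcome_name=out_name)
            except ValueError as err:
                if on_error == "raise":
                    raise
                rows.append({"outcome": out_name, "exposure": exp_name,
                             "OR": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                             "p": np.nan, "n": int(y.notna().sum()),
                             "pretty": "", "note": str(err)})
                continue
            r = fit.exposure_row
            rows.append({
                "outcome": out_name, "exposure": exp_name,
                "OR": r["OR"], "ci_low": r["ci_low"], "ci_high": r["ci_high"],
                "p": r["p"], "n": fit.n,
                "pretty": format_or(r["OR"], r["ci_low"], r["ci_high"]),
                "note": "",
            })
    return pd.DataFrame(rows)
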