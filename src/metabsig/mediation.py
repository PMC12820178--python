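"""Quasi-Bayesian causal mediation and backward-elimination mediator selection.

The mediation model is the standard two-equation system for a continuous
exposure (z-scored pre-pregnancy BMI), a continuous composite mediator (the
metabolite score) and a binary outcome (gestational diabetes):

    M = a0 + a * T + covariates + e,          e ~ N(0, sigma^2)   (linear)
    logit P(Y=1) = b0 + c' * T + b * M + covariates               (logistic)

Uncertainty is propagated by the quasi-Bayesian simulation scheme: parameter
vectors are drawn from each fitted model's asymptotic normal sampling
distribution; per draw, counterfactual mediator values M(t) and M(c) are
simulated (including the mediator-model residual noise) at the treated and
control exposure values, pushed through the outcome model to probabilities,
and averaged over the sample.  The average causal mediation effect (ACME) on
the probability (risk-difference) scale is

    ACME = 1/2 * sum_{a in {t,c}}  E[Y(a, M(t))] - E[Y(a, M(c))],

the average direct effect (ADE) the analogous contrast over the exposure,
and total = ACME + ADE exactly per draw.  Point estimates are draw means,
intervals are 2.5/97.5 percentiles.

Backward elimination then asks which metabolites carry the mediation: at
each step the metabolite whose removal from the composite score most
*increases* the ACME is dropped (its presence dilutes the mediating signal),
and the loop stops when no single removal raises the ACME further.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._utils import rng_from, sigmoid, spawn_seeds
from .association import LogisticFit, LRTResult, fit_logistic, likelihood_ratio_test

__all__ = [
    "MediationResult",
    "EliminationStep",
    "EliminationTrace",
    "composite_score",
    "fit_mediator_model",
    "fit_outcome_model",
    "acme_quasi_bayes",
    "backward_eliminate",
    "compare_full_vs_subset",
]


@dataclass(frozen=True)
class MediationResult:
    """ACME/ADE/total on the outcome-probability scale, with Monte-Carlo
    percentile intervals over the quasi-Bayesian draws."""

    acme: float
    ade: float
    total: float
    prop_mediated: float | None
    acme_ci: tuple
    ade_ci: tuple
    total_ci: tuple
    n_sim: int
    seed: int
    draws: dict = field(repr=False, default_factory=dict)


def composite_score(X, model, subset=None, pre_standardized: bool = False) -> pd.Series:
    """Weighted metabolite score restricted to a subset of the model's
    metabolites, z-scored within cohort.

    Weights are the fitted sparse-PLS weights; the subset defaults to all
    metabolites with nonzero weight.  Metabolite columns are standardised
    within the cohort unless ``pre_standardized``.
    """
    X = pd.DataFrame(X)
    weights = model.weights_[model.weights_ != 0]
    if subset is None:
        subset = list(weights.index)
    subset = list(subset)
    if not subset:
        raise ValueError("metabolite subset is empty")
    stray = [m for m in subset if m not in model.weights_.index]
    if stray:
        raise ValueError(f"subset metabolites not in the model: {stray[:5]}")
    V = X[subset].to_numpy(dtype=float)
    if not pre_standardized:
        mu = V.mean(axis=0)
        sd = V.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        V = (V - mu) / sd
    raw = V @ model.weights_[subset].to_numpy()
    sd_raw = raw.std(ddof=1)
    if sd_raw <= 0:
        raise ValueError("composite score is constant; cannot z-score")
    return pd.Series((raw - raw.mean()) / sd_raw, index=X.index, name="score")


def fit_mediator_model(score: pd.Series, exposure: pd.Series,
                       covariates: pd.DataFrame | None = None):
    """OLS of the composite score on the exposure (+ covariates)."""
    parts = [pd.Series(exposure).rename(pd.Series(exposure).name or "exposure")]
    if covariates is not None and len(covariates.columns):
        parts.append(covariates.astype(float))
    X = sm.add_constant(pd.concat(parts, axis=1).astype(float), has_constant="add")
    return sm.OLS(np.asarray(score, dtype=float), X).fit()


def fit_outcome_model(outcome: pd.Series, exposure: pd.Series, score: pd.Series,
                      covariates: pd.DataFrame | None = None, binary: bool = True):
    """Logistic (or linear, for the identity-link analogue) outcome model on
    exposure + mediator score (+ covariates)."""
    parts = [pd.Series(exposure).rename(pd.Series(exposure).name or "exposure"),
             pd.Series(score).rename(pd.Series(score).name or "score")]
    if covariates is not None and len(covariates.columns):
        parts.append(covariates.astype(float))
    X = sm.add_constant(pd.concat(parts, axis=1).astype(float), has_constant="add")
    y = np.asarray(outcome, dtype=float)
    if binary:
        model = sm.Logit(y, X)
        try:
            res = model.fit(disp=0, maxiter=100, tol=1e-8)
            if not res.mle_retvals.get("converged", True):
                res = None
        except np.linalg.LinAlgError:
            res = None
        if res is None:
            # Newton stalls or its Hessian goes singular mid-iteration on
            # flat likelihoods (few events); L-BFGS is hardier
            try:
                res = model.fit(disp=0, method="lbfgs", maxiter=1000)
            except np.linalg.LinAlgError as err:
                raise ValueError(f"outcome logistic fit failed ({err}); too "
                                 "few events for the design") from err
        if not res.mle_retvals.get("converged", True):
            raise ValueError("outcome logistic model did not converge")
        if not np.all(np.isfinite(np.asarray(res.cov_params()))):
            raise ValueError("outcome logistic model has a singular information "
                             "matrix; effects are inestimable")
        return res
    return sm.OLS(y, X).fit()


def _exposure_and_mediator_names(mediator_fit, outcome_fit):
    med_exog = list(mediator_fit.model.exog_names)
    out_exog = list(outcome_fit.model.exog_names)
    exposure = med_exog[1]  # first non-constant term by construction
    mediator = [c for c in out_exog if c not in med_exog]
    if len(mediator) != 1:
        raise ValueError("outcome model must add exactly one mediator term to "
                         f"the mediator model's design; extra terms: {mediator}")
    return exposure, mediator[0]


def acme_quasi_bayes(mediator_fit, outcome_fit, treat_value: float = 1.0,
                     control_value: float = 0.0, n_sim: int = 10000,
                     seed: int = 0) -> MediationResult:
    """Quasi-Bayesian ACME/ADE for a continuous mediator.

    ``mediator_fit`` is a fitted OLS of the mediator on exposure+covariates;
    ``outcome_fit`` a fitted Logit (or OLS for the identity-link analogue) of
    the outcome on exposure+mediator+covariates, both on named pandas
    designs over the same samples.  The exposure contrast defaults to one SD
    (0 -> 1 on the standardized scale).  Residual-noise draws for the
    counterfactual mediator are shared between the treated and control arms
    (common random numbers), which leaves the ACME difference free of the
    noise term's Monte-Carlo variance.
    """
    if n_sim < 100:
        raise ValueError(f"n_sim must be >= 100; got {n_sim}")
    if hasattr(mediator_fit, "mle_retvals") or not hasattr(mediator_fit, "scale"):
        raise ValueError("mediator_fit must be a linear (OLS) results object")
    if getattr(outcome_fit, "mle_retvals", {"converged": True}).get("converged", True) is False:
        raise ValueError("outcome model did not converge; refit before mediation")
    sigma = float(np.sqrt(mediator_fit.scale))
    if not np.isfinite(sigma) or sigma < 1e-10:
        raise ValueError("mediator model has (near-)zero residual variance")
    exposure, mediator = _exposure_and_mediator_names(mediator_fit, outcome_fit)
    binary = hasattr(outcome_fit, "mle_retvals")
    link = sigmoid if binary else (lambda x: x)

    rng = rng_from(seed)
    Xm = pd.DataFrame(mediator_fit.model.exog, columns=mediator_fit.model.exog_names)
    Xy = pd.DataFrame(outcome_fit.model.exog, columns=outcome_fit.model.exog_names)
    nobs = len(Xm)
    if len(Xy) != nobs:
        raise ValueError("mediator and outcome models were fitted on different samples")

    def draw_params(fit):
        cov = np.asarray(fit.cov_params())
        cov = (cov + cov.T) / 2.0  # clip asymmetry/negative eigen-noise
        vals, vecs = np.linalg.eigh(cov)
        root = vecs * np.sqrt(np.clip(vals, 0.0, None))
        z = rng.standard_normal((n_sim, cov.shape[0]))
        return np.asarray(fit.params) + z @ root.T

    bm = draw_params(mediator_fit)
    by = draw_params(outcome_fit)
    noise = rng.normal(0.0, sigma, size=(n_sim, nobs))

    med_cols = list(Xm.columns)
    e_idx_m = med_cols.index(exposure)

    def mediator_draws(value):
        Xv = Xm.to_numpy(dtype=float).copy()
        Xv[:, e_idx_m] = value
        return bm @ Xv.T + noise  # (n_sim, nobs)

    M_t = mediator_draws(treat_value)
    M_c = mediator_draws(control_value)

    out_cols = list(Xy.columns)
    e_idx_y = out_cols.index(exposure)
    m_idx_y = out_cols.index(mediator)

    def outcome_mean(exp_value, M):
        Xv = Xy.to_numpy(dtype=float).copy()
        Xv[:, e_idx_y] = exp_value
        Xv[:, m_idx_y] = 0.0
        base = by @ Xv.T                      # (n_sim, nobs)
        eta = base + by[:, [m_idx_y]] * M
        return link(eta).mean(axis=1)         # (n_sim,)

    y_tt = outcome_mean(treat_value, M_t)
    y_tc = outcome_mean(treat_value, M_c)
    y_ct = outcome_mean(control_value, M_t)
    y_cc = outcome_mean(control_value, M_c)

    acme_d = 0.5 * ((y_tt - y_tc) + (y_ct - y_cc))
    ade_d = 0.5 * ((y_tt - y_ct) + (y_tc - y_cc))
    total_d = y_tt - y_cc  # equals acme_d + ade_d identically

    def ci(d):
        return (float(np.percentile(d, 2.5)), float(np.percentile(d, 97.5)))

    acme, ade, total = float(acme_d.mean()), float(ade_d.mean()), float(total_d.mean())
    prop = acme / total if (total != 0 and np.sign(acme) == np.sign(total)) else None
    return MediationResult(
        acme=acme, ade=ade, total=total, prop_mediated=prop,
        acme_ci=ci(acme_d), ade_ci=ci(ade_d), total_ci=ci(total_d),
        n_sim=n_sim, seed=int(seed) if np.isscalar(seed) else 0,
        draws={"acme": acme_d, "ade": ade_d, "total": total_d},
    )


def _mediation_for_subset(X, bmi_z, outcome, covariates, model, subset,
                          n_sim, seed, pre_standardized):
    score = composite_score(X, model, subset, pre_standardized=pre_standardized)
    med_fit = fit_mediator_model(score, bmi_z, covariates)
    out_fit = fit_outcome_model(outcome, bmi_z, score, covariates)
    return acme_quasi_bayes(med_fit, out_fit, n_sim=n_sim, seed=seed)


@dataclass(frozen=True)
class EliminationStep:
    removed_id: str
    acme: float
    acme_ci: tuple


@dataclass(frozen=True)
class EliminationTrace:
    """Ordered record of backward-elimination removals."""

    initial_ids: tuple
    final_ids: tuple
    initial_result: MediationResult
    steps: tuple  # of EliminationStep
    step_results: tuple  # of MediationResult
    stopping_reason: str  # "no_gain" or "min_size"

    @property
    def acme_sequence(self) -> list:
        return [self.initial_result.acme] + [s.acme for s in self.steps]


def backward_eliminate(X, bmi, outcome, covariates, model, n_sim: int = 10000,
                       seed: int = 0, min_size: int = 2,
                       pre_standardized: bool = False) -> EliminationTrace:
    """Iteratively drop the metabolite whose removal most increases the ACME.

    Starting from the model's selected metabolites, each iteration re-forms
    the composite score without each remaining candidate in turn, refits the
    mediator and outcome models, and re-estimates the ACME; the removal
    giving the largest ACME is committed if it exceeds the current set's
    ACME, otherwise the loop stops.  Every evaluation in the trace shares
    one simulation seed (common random numbers), so candidates are compared
    like with like and the keep/remove decision is free of cross-seed
    Monte-Carlo noise.  The ACME sequence along the trace is strictly
    increasing by construction.
    """
    bmi_z = pd.Series(bmi).astype(float)
    bmi_z = ((bmi_z - bmi_z.mean()) / bmi_z.std(ddof=1)).rename("bmi")
    current = [m for m in model.weights_.index if model.weights_[m] != 0]
    if len(current) < min_size:
        raise ValueError(f"model has {len(current)} metabolites; fewer than "
                         f"min_size={min_size}")
    # one common seed for every evaluation: candidates are compared on common
    # random numbers, and a committed candidate's ACME is exactly the
    # incumbent value of the next iteration, so the trace's ACME sequence is
    # strictly increasing by construction of the acceptance rule
    (crn_seed,) = spawn_seeds(seed, 1)
    evaluate = lambda subset: _mediation_for_subset(
        X, bmi_z, outcome, covariates, model, subset, n_sim, crn_seed,
        pre_standardized)

    initial = evaluate(current)
    current_res = initial
    steps, step_results = [], []
    reason = "no_gain"
    while True:
        if len(current) <= min_size:
            reason = "min_size"
            break
        best_id, best_res = None, None
        for cand in current:
            subset = [m for m in current if m != cand]
            try:
                res = evaluate(subset)
            except ValueError as err:
                raise ValueError(f"mediation refit failed when removing "
                                 f"{cand!r}: {err}") from err
            if best_res is None or res.acme > best_res.acme:
                best_id, best_res = cand, res
        if best_res.acme > current_res.acme:
            current = [m for m in current if m != best_id]
            current_res = best_res
            steps.append(EliminationStep(best_id, best_res.acme, best_res.acme_ci))
            step_results.append(best_res)
        else:
            reason = "no_gain"
            break
    return EliminationTrace(
        initial_ids=tuple(m for m in model.weights_.index if model.weights_[m] != 0),
        final_ids=tuple(current),
        initial_result=initial,
        steps=tuple(steps),
        step_results=tuple(step_results),
        stopping_reason=reason,
    )


def compare_full_vs_subset(outcome, full_score, subset_score, bmi,
                           covariates: pd.DataFrame | None = None,
                           outcome_name: str | None = None,
                           ) -> tuple[LogisticFit, LogisticFit, LRTResult]:
    """LRT of whether the mediating-subset score improves on the full score.

    Reduced model: outcome ~ full score + BMI + covariates; full model adds
    the subset score (df = 1).
    """
    full_score = pd.Series(full_score).rename("full_score")
    subset_score = pd.Series(subset_score).rename("subset_score")
    bmi = pd.Series(bmi).rename("bmi")
    reduced = fit_logistic(outcome, full_score, covariates, extra_terms=[bmi],
                           outcome_name=outcome_name)
    full = fit_logistic(outcome, full_score, covariates,
                        extra_terms=[subset_score, bmi], outcome_name=outcome_name)
    return full, reduced, likelihood_ratio_test(full, reduced)
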