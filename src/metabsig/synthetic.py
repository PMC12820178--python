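"""Synthetic pregnancy-cohort generator with planted metabolomic truth.

Emulates the structure of a mother-child cohort in which a latent adiposity
factor drives both pre-pregnancy BMI and a sparse subset of blood metabolites,
and part of the BMI effect on binary pregnancy complications is routed through
a known subset of those metabolites (the planted mediators).  Because the real
cohorts are access-restricted, every downstream stage of the pipeline is
exercised against cohorts generated here, where the signal support, mediator
set, effect sizes and missingness mechanism are all known exactly.

Construction, per sample i:

* latent adiposity ``A_i ~ N(0, 1)``;
* log-abundance of signal metabolite j: ``L_ij = w_j * A_i + N(0,1)``,
  non-signal metabolites pure ``N(0,1)``; stored abundance ``exp(m_j + L_ij)``
  is log-normal, matching the pipeline's log-transform step;
* ``BMI_i = mu + sd * (sqrt(r2) * c_i + covariate part + noise)`` where
  ``c`` is the standardized true-weight metabolite composite ``L w``; the
  noise variance is chosen so the composite explains exactly ``signal_r2``
  of the BMI variance (the best recoverable score R^2);
* outcome logits: ``alpha + b_bmi * z(BMI) + sum_j b_med * z(L_j) + covariate
  terms``, with ``alpha`` solved so the marginal prevalence matches the spec;
  mediators are signal metabolites, so their outcome effect is a BMI-mediated
  path by construction;
* a configurable fraction of samples are duplicated twin pregnancies sharing
  a ``family_id`` (same maternal record), exercising twin de-duplication.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._utils import rng_from, sigmoid

__all__ = [
    "CovariateSpec",
    "OutcomeSpec",
    "CohortConfig",
    "TruthRecord",
    "CohortData",
    "generate_cohort",
    "apply_missingness",
    "inject_covariate_missingness",
]


@dataclass(frozen=True)
class CovariateSpec:
    """One adjustment covariate and its effects.

    Parameters
    ----------
    name : column name.
    kind : "continuous" (standard normal) or "binary" (Bernoulli).
    rate : success probability for binary covariates; ignored otherwise.
    bmi_effect : additive effect on the latent BMI scale (units of the latent
        adiposity SD) per unit of the covariate.
    outcome_log_or : mapping outcome name -> log-odds effect per unit.
    """

    name: str
    kind: str = "continuous"
    rate: float = 0.5
    bmi_effect: float = 0.0
    outcome_log_or: dict = field(default_factory=dict)


@dataclass(frozen=True)
class OutcomeSpec:
    """One binary pregnancy-complication outcome.

    ``bmi_log_or`` is the *direct* per-SD-BMI log-odds effect; each planted
    mediator metabolite additionally contributes ``mediator_log_or`` per SD of
    its log-abundance, so the total BMI association exceeds the direct part.
    """

    name: str
    prevalence: float
    bmi_log_or: float = 0.0
    mediator_log_or: float = 0.0


def _default_covariates() -> tuple[CovariateSpec, ...]:
    # Mirrors the shape of the cohorts' adjustment set: one continuous social
    # circumstances score, binary smoking and child sex, three dietary PCs.
    return (
        CovariateSpec("social_circumstances", "continuous", bmi_effect=-0.15,
                      outcome_log_or={"gestational_diabetes": -0.15, "cesarean_section": -0.05}),
        CovariateSpec("smoking", "binary", rate=0.08, bmi_effect=0.20,
                      outcome_log_or={"induction_of_birth": 0.20}),
        CovariateSpec("child_sex", "binary", rate=0.51),
        CovariateSpec("diet_pc1", "continuous", bmi_effect=-0.10),
        CovariateSpec("diet_pc2", "continuous", bmi_effect=0.12,
                      outcome_log_or={"gestational_diabetes": 0.10}),
        CovariateSpec("diet_pc3", "continuous", bmi_effect=-0.08),
    )


def _default_outcomes() -> tuple[OutcomeSpec, ...]:
    # Prevalences sit inside the ranges observed across the two cohorts
    # (gestational diabetes 2.2-5.2%, cesarean 21.6-29.5%, induction 18-36%,
    # maternal antibiotics 32-39%); gestational diabetes carries the planted
    # mediated path.
    return (
        OutcomeSpec("gestational_diabetes", 0.05, bmi_log_or=0.30, mediator_log_or=0.12),
        OutcomeSpec("preeclampsia", 0.035, bmi_log_or=0.10, mediator_log_or=0.08),
        OutcomeSpec("cesarean_section", 0.22, bmi_log_or=0.20),
        OutcomeSpec("induction_of_birth", 0.20, bmi_log_or=0.35),
        OutcomeSpec("maternal_antibiotics", 0.32, bmi_log_or=0.15),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration; defaults emulate the discovery-cohort scale
    (~700 mothers, 640-metabolite overlap panel, ~7% signal sparsity)."""

    n_samples: int = 700
    n_metabolites: int = 640
    n_signal: int = 46
    n_mediators: int = 16
    signal_r2: float = 0.4
    outcome_specs: tuple = field(default_factory=_default_outcomes)
    covariate_specs: tuple = field(default_factory=_default_covariates)
    missing_rate: float = 0.0
    missing_mechanism: str = "MCAR"
    missing_gamma: float = -0.5
    missing_outcome: str = "cesarean_section"
    signal_weight_range: tuple = (0.3, 0.9)
    mediator_weight_range: tuple | None = None  # defaults to signal range
    n_subpathways: int = 25
    n_enriched_pathways: int = 2
    enrichment_concentration: float = 0.5
    twin_rate: float = 0.02
    bmi_mean: float = 24.6
    bmi_sd: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.n_mediators <= self.n_signal <= self.n_metabolites):
            raise ValueError(
                "require 0 < n_mediators <= n_signal <= n_metabolites; got "
                f"n_mediators={self.n_mediators}, n_signal={self.n_signal}, "
                f"n_metabolites={self.n_metabolites}"
            )
        if not (0.0 < self.signal_r2 < 1.0):
            raise ValueError(f"signal_r2 must lie in (0, 1); got {self.signal_r2}")
        if not (0.0 <= self.missing_rate <= 0.6):
            raise ValueError(f"missing_rate must lie in [0, 0.6]; got {self.missing_rate}")
        if self.missing_mechanism not in ("MCAR", "outcome-dependent"):
            raise ValueError(f"missing_mechanism must be MCAR or outcome-dependent; "
                             f"got {self.missing_mechanism!r}")
        for spec in self.outcome_specs:
            if not (0.0 < spec.prevalence < 1.0):
                raise ValueError(f"outcome_specs: prevalence of {spec.name!r} must lie "
                                 f"in (0, 1); got {spec.prevalence}")
        if not (0.0 <= self.twin_rate < 0.5):
            raise ValueError(f"twin_rate must lie in [0, 0.5); got {self.twin_rate}")
        if self.n_samples < 4:
            raise ValueError(f"n_samples too small: {self.n_samples}")


@dataclass(frozen=True)
class TruthRecord:
    """Planted ground truth accompanying a generated cohort."""

    signal_ids: tuple
    mediator_ids: tuple
    true_weights: pd.Series  # per-metabolite loading on latent adiposity
    true_outcome_coefs: dict  # outcome -> {"intercept", "bmi", mediator ids...}
    pathway_assignment: pd.Series  # metabolite -> sub-pathway

    def to_dict(self) -> dict:
        return {
            "signal_ids": list(self.signal_ids),
            "mediator_ids": list(self.mediator_ids),
            "true_weights": {k: float(v) for k, v in self.true_weights.items()},
            "true_outcome_coefs": {
                o: {k: float(v) for k, v in d.items()}
                for o, d in self.true_outcome_coefs.items()
            },
            "pathway_assignment": dict(self.pathway_assignment),
        }


@dataclass
class CohortData:
    """One generated cohort: abundances are positive where observed, NaN where
    missing; outcomes are 0/1; ``family_id`` groups twin pregnancies."""

    abundances: pd.DataFrame
    covariates: pd.DataFrame
    bmi: pd.Series
    outcomes: pd.DataFrame
    family_id: pd.Series
    annotation: pd.DataFrame

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness mask (True = missing)."""
        return self.abundances.isna()

    def copy(self) -> "CohortData":
        return CohortData(
            self.abundances.copy(), self.covariates.copy(), self.bmi.copy(),
            self.outcomes.copy(), self.family_id.copy(), self.annotation.copy(),
        )


def _assign_pathways(met_ids, signal_idx, config, rng) -> pd.DataFrame:
    """Sub-/super-pathway annotation with signal metabolites concentrated in a
    few sub-pathways (drives a recoverable enrichment signal)."""
    n_sub = config.n_subpathways
    subs = [f"sub_pathway_{k:02d}" for k in range(n_sub)]
    n_super = max(1, n_sub // 4)
    supers = {s: f"super_pathway_{k % n_super:02d}" for k, s in enumerate(subs)}

    assign = rng.integers(0, n_sub, size=len(met_ids))
    enriched = rng.choice(n_sub, size=min(config.n_enriched_pathways, n_sub), replace=False)
    for i in signal_idx:
        if rng.random() < config.enrichment_concentration:
            assign[i] = rng.choice(enriched)
    return pd.DataFrame({
        "metabolite_id": met_ids,
        "sub_pathway": [subs[a] for a in assign],
        "super_pathway": [supers[subs[a]] for a in assign],
    })


def _solve_intercept(eta: np.ndarray, prevalence: float) -> float:
    f = lambda a: sigmoid(a + eta).mean() - prevalence
    return float(brentq(f, -40.0, 40.0))


def generate_cohort(config: CohortConfig,
                    truth: TruthRecord | None = None) -> tuple[CohortData, TruthRecord]:
    """Generate one cohort and its ground truth. Deterministic in config.seed.

    Passing an existing ``truth`` re-samples an independent cohort from the
    *same* planted signal (weights, mediator set, outcome coefficients,
    pathway layout) — the validation-cohort construction.
    """
    config.validate()
    rng = rng_from(config.seed)

    n_pairs = int(round(config.twin_rate * config.n_samples / 2))
    n_unique = config.n_samples - n_pairs
    p = config.n_metabolites

    # covariates
    cov_cols = {}
    for spec in config.covariate_specs:
        if spec.kind == "continuous":
            cov_cols[spec.name] = rng.standard_normal(n_unique)
        elif spec.kind == "binary":
            cov_cols[spec.name] = rng.binomial(1, spec.rate, size=n_unique).astype(float)
        else:
            raise ValueError(f"covariate_specs: unknown kind {spec.kind!r} for {spec.name!r}")
    covariates = pd.DataFrame(cov_cols, index=pd.RangeIndex(n_unique))

    # latent adiposity
    A = rng.standard_normal(n_unique)

    # metabolites on the log scale
    if truth is not None:
        met_ids = list(truth.true_weights.index)
        if len(met_ids) != p:
            raise ValueError(f"truth has {len(met_ids)} metabolites but config asks "
                             f"for {p}")
        weights = truth.true_weights.to_numpy(dtype=float)
        signal_idx = np.flatnonzero(weights != 0)
        mediator_idx = np.array([met_ids.index(m) for m in truth.mediator_ids])
    else:
        met_ids = [f"met_{j:04d}" for j in range(p)]
        signal_idx = np.sort(rng.choice(p, size=config.n_signal, replace=False))
        mediator_idx = np.sort(rng.choice(signal_idx, size=config.n_mediators,
                                          replace=False))
        weights = np.zeros(p)
        lo, hi = config.signal_weight_range
        mags = rng.uniform(lo, hi, size=config.n_signal)
        signs = rng.choice([-1.0, 1.0], size=config.n_signal)
        weights[signal_idx] = mags * signs
        if config.mediator_weight_range is not None:
            mlo, mhi = config.mediator_weight_range
            weights[mediator_idx] = (rng.uniform(mlo, mhi, size=len(mediator_idx))
                                     * rng.choice([-1.0, 1.0], size=len(mediator_idx)))
    L = weights[None, :] * A[:, None] + rng.standard_normal((n_unique, p))
    baseline = rng.uniform(12.0, 18.0, size=p)  # log-scale abundance levels
    abundances = pd.DataFrame(np.exp(baseline[None, :] + L), columns=met_ids)

    # BMI from the standardized true-weight metabolite composite, plus
    # covariate confounding and noise scaled so the composite explains
    # exactly signal_r2 of the BMI variance
    comp = L @ weights
    comp_z = (comp - comp.mean()) / comp.std()
    cov_part = np.zeros(n_unique)
    cov_var = 0.0
    for spec in config.covariate_specs:
        cov_part += spec.bmi_effect * covariates[spec.name].to_numpy()
        var1 = spec.rate * (1 - spec.rate) if spec.kind == "binary" else 1.0
        cov_var += spec.bmi_effect**2 * var1
    resid_var = 1.0 - config.signal_r2 - cov_var
    if resid_var <= 0:
        raise ValueError("covariate_specs: combined bmi_effect variance too large "
                         f"for signal_r2={config.signal_r2}")
    raw = (np.sqrt(config.signal_r2) * comp_z + cov_part
           + rng.normal(0.0, np.sqrt(resid_var), size=n_unique))
    bmi = config.bmi_mean + config.bmi_sd * raw

    # outcomes
    z_bmi = (bmi - bmi.mean()) / bmi.std()
    Lz = (L - L.mean(axis=0)) / L.std(axis=0)
    out_cols, true_coefs = {}, {}
    for spec in config.outcome_specs:
        if truth is not None:
            coefs = dict(truth.true_outcome_coefs[spec.name])
            eta = coefs["bmi"] * z_bmi
            for j in mediator_idx:
                eta = eta + coefs.get(met_ids[j], 0.0) * Lz[:, j]
            for cspec in config.covariate_specs:
                b = coefs.get(cspec.name, 0.0)
                if b:
                    eta = eta + b * covariates[cspec.name].to_numpy()
            alpha = coefs["intercept"]
        else:
            eta = spec.bmi_log_or * z_bmi
            coefs = {"bmi": spec.bmi_log_or}
            for j in mediator_idx:
                # outcome effect sign follows the loading sign, so every
                # mediator's BMI-mediated risk contribution is positive
                b_j = float(np.sign(weights[j]) or 1.0) * spec.mediator_log_or
                eta = eta + b_j * Lz[:, j]
                coefs[met_ids[j]] = b_j
            for cspec in config.covariate_specs:
                b = cspec.outcome_log_or.get(spec.name, 0.0)
                if b:
                    eta = eta + b * covariates[cspec.name].to_numpy()
                    coefs[cspec.name] = b
            alpha = _solve_intercept(eta, spec.prevalence)
            coefs["intercept"] = alpha
        out_cols[spec.name] = rng.binomial(1, sigmoid(alpha + eta)).astype(int)
        true_coefs[spec.name] = coefs
    outcomes = pd.DataFrame(out_cols)

    # duplicate twin pregnancies (same maternal record, shared family_id)
    family = np.array([f"fam_{i:05d}" for i in range(n_unique)])
    order = np.arange(n_unique)
    if n_pairs > 0:
        dup = rng.choice(n_unique, size=n_pairs, replace=False)
        order = np.concatenate([order, dup])
    sample_ids = [f"sample_{i:05d}" for i in range(len(order))]

    def take(df):
        out = df.iloc[order].reset_index(drop=True)
        out.index = pd.Index(sample_ids, name="sample_id")
        return out

    if truth is not None:
        n_super = max(1, config.n_subpathways // 4)
        subs = truth.pathway_assignment.loc[met_ids]
        annotation = pd.DataFrame({
            "metabolite_id": met_ids,
            "sub_pathway": subs.to_numpy(),
            "super_pathway": [f"super_pathway_{int(s.rsplit('_', 1)[1]) % n_super:02d}"
                              for s in subs],
        })
    else:
        annotation = _assign_pathways(met_ids, signal_idx, config, rng)
    data = CohortData(
        abundances=take(abundances),
        covariates=take(covariates),
        bmi=take(pd.DataFrame({"bmi": bmi}))["bmi"],
        outcomes=take(outcomes),
        family_id=take(pd.DataFrame({"family_id": family}))["family_id"],
        annotation=annotation,
    )
    if truth is None:
        truth = TruthRecord(
            signal_ids=tuple(met_ids[j] for j in signal_idx),
            mediator_ids=tuple(met_ids[j] for j in mediator_idx),
            true_weights=pd.Series(weights, index=met_ids, name="true_weight"),
            true_outcome_coefs=true_coefs,
            pathway_assignment=data.annotation.set_index("metabolite_id")["sub_pathway"],
        )
    if config.missing_rate > 0:
        data = apply_missingness(data, config)
    return data, truth


def apply_missingness(data: CohortData, config: CohortConfig,
                      seed: int | None = None) -> CohortData:
    """Blank abundance cells MCAR or with outcome-dependent odds.

    Under the outcome-dependent mechanism the per-sample missingness odds are
    multiplied by ``exp(gamma * outcome)`` for the configured outcome, so a
    negative gamma reproduces the "observed complication -> less missing data"
    pattern seen in real cohorts.
    """
    if not (0.0 <= config.missing_rate <= 0.6):
        raise ValueError(f"missing_rate must lie in [0, 0.6]; got {config.missing_rate}")
    if data.mask.to_numpy().any():
        raise ValueError("apply_missingness expects a fully observed abundance matrix")
    if config.missing_rate == 0:
        return data
    rng = rng_from(config.seed + 104729 if seed is None else seed)
    n, p = data.abundances.shape
    if config.missing_mechanism == "MCAR":
        cell_p = np.full((n, 1), config.missing_rate)
    else:
        if config.missing_outcome not in data.outcomes.columns:
            raise ValueError(f"missing_outcome {config.missing_outcome!r} not among "
                             f"outcomes {list(data.outcomes.columns)}")
        y = data.outcomes[config.missing_outcome].to_numpy()
        base_logit = np.log(config.missing_rate / (1 - config.missing_rate))
        cell_p = sigmoid(base_logit + config.missing_gamma * y)[:, None]
    holes = rng.random((n, p)) < cell_p
    out = data.copy()
    ab = out.abundances.to_numpy(dtype=float)
    ab[holes] = np.nan
    out.abundances = pd.DataFrame(ab, index=data.abundances.index,
                                  columns=data.abundances.columns)
    return out


def inject_covariate_missingness(covariates: pd.DataFrame, rate: float,
                                 seed: int) -> pd.DataFrame:
    """MCAR holes in the covariate table only (rate in [0, 0.3])."""
    if not (0.0 <= rate <= 0.3):
        raise ValueError(f"covariate missing rate must lie in [0, 0.3]; got {rate}")
    out = covariates.copy()
    if rate == 0:
        return out
    rng = rng_from(seed)
    holes = rng.random(out.shape) < rate
    for k, col in enumerate(out.columns):
        col_holes = holes[:, k]
        if col_holes.all():  # keep every column estimable
            col_holes[rng.integers(0, len(out))] = False
        out.loc[col_holes, col] = np.nan
    return out
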