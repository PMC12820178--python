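import numpy as np
import pandas as pd
import pytest

from metabsig import CohortConfig, OutcomeSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """150 x 40 complete cohort with 8 signal / 3 mediator metabolites."""
    cfg = CohortConfig(n_samples=150, n_metabolites=40, n_signal=8,
                       n_mediators=3, signal_r2=0.4, missing_rate=0.0,
                       twin_rate=0.02, seed=42)
    data, truth = generate_cohort(cfg)
    return cfg, data, truth


@pytest.fixture(scope="session")
def standardized_cohort(small_cohort):
    """Log/centre/scaled abundance matrix of the small cohort."""
    _, data, truth = small_cohort
    L = np.log(data.abundances)
    Z = (L - L.mean()) / L.std(ddof=1)
    return Z, data, truth


def make_mediation_cohort(seed, n=3000, prevalence=0.10, mediator_log_or=0.7):
    """Strong-effect planted-mediator cohort: 3 heavily loaded mediators among
    10 signal metabolites, BMI a tight proxy of the latent factor."""
    cfg = CohortConfig(
        n_samples=n, n_metabolites=10, n_signal=10, n_mediators=3,
        signal_r2=0.85, twin_rate=0.0, missing_rate=0.0,
        signal_weight_range=(0.25, 0.35), mediator_weight_range=(0.75, 0.85),
        covariate_specs=(),
        outcome_specs=(OutcomeSpec("gestational_diabetes", prevalence,
                                   bmi_log_or=0.2,
                                   mediator_log_or=mediator_log_or),),
        seed=seed)
    return generate_cohort(cfg)
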