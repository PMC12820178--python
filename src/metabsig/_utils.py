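"""Small shared helpers: seeding, z-scoring, link functions."""

from __future__ import annotations

import numpy as np
import pandas as pd

# Wald critical value for 95% intervals (two-sided normal quantile)
Z_CRIT = 1.959964


def rng_from(seed) -> np.random.Generator:
    """Accept an int seed, SeedSequence or Generator and return a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive `n` independent child seeds (< 2**31) from one global seed."""
    ss = np.random.SeedSequence(int(seed))
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def zscore(v, ddof: int = 0):
    """Z-score a vector; returns (z, mean, sd). Raises on zero variance."""
    v = np.asarray(v, dtype=float)
    mu = v.mean()
    sd = v.std(ddof=ddof)
    if sd <= 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant (zero-variance) vector")
    return (v - mu) / sd, float(mu), float(sd)


def as_frame(X, columns=None) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X), columns=columns)
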