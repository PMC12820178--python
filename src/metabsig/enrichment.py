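"""Hypergeometric over-representation of selected metabolites in sub-pathways.

For each annotation sub-pathway with at least one selected metabolite, the
upper-tail hypergeometric probability P(X >= k) of drawing k or more pathway
members among n selections from a background of N metabolites containing K
pathway members is computed, together with fold enrichment (k/n)/(K/N).
Benjamini-Hochberg (FDR) and Bonferroni corrections are applied over the
tested rows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["hypergeom_upper_tail", "bh_adjust", "bonferroni_adjust", "enrich"]


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n draws).

    Inclusive of the observed count k (one-sided over-representation).
    """
    N, K, n, k = int(N), int(K), int(n), int(k)
    if not (0 <= K <= N):
        raise ValueError(f"require 0 <= K <= N; got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"require 0 <= n <= N; got n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"require 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to adjust")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_adjust(pvals) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    return np.minimum(p * p.size, 1.0)


def enrich(selected_ids, annotation: pd.DataFrame, background_ids=None,
           all_pathways: bool = False) -> pd.DataFrame:
    """Sub-pathway over-representation table for a selected metabolite set.

    Parameters
    ----------
    selected_ids : metabolite identifiers chosen by the model.
    annotation : DataFrame with columns metabolite_id, sub_pathway.
    background_ids : the metabolite universe; defaults to every annotated
        metabolite. Unannotated background members fall into "Unassigned".
    all_pathways : test every background sub-pathway rather than only those
        with at least one selected member (changes the correction's m).

    Returns rows ordered by p: sub_pathway, K, k, n, N, fold_enrichment, p,
    q_fdr, p_bonf.
    """
    ann = annotation.set_index("metabolite_id")["sub_pathway"]
    if background_ids is None:
        background = list(ann.index)
    else:
        background = list(background_ids)
    selected = list(selected_ids)
    if not selected:
        raise ValueError("selected metabolite set is empty")
    stray = set(selected) - set(background)
    if stray:
        raise ValueError(f"selected metabolites outside the background: "
                         f"{sorted(stray)[:5]}")
    path_of = {m: ann.get(m, "Unassigned") for m in background}
    N, n = len(background), len(selected)
    bg_counts = pd.Series([path_of[m] for m in background]).value_counts()
    sel_counts = pd.Series([path_of[m] for m in selected]).value_counts()
    pathways = list(bg_counts.index) if all_pathways else list(sel_counts.index)

    rows = []
    for pw in pathways:
        K = int(bg_counts.get(pw, 0))
        k = int(sel_counts.get(pw, 0))
        rows.append({
            "sub_pathway": pw, "K": K, "k": k, "n": n, "N": N,
            "fold_enrichment": (k / n) / (K / N) if K else np.nan,
            "p": hypergeom_upper_tail(N, K, n, k),
        })
    table = pd.DataFrame(rows)
    table["q_fdr"] = bh_adjust(table["p"].to_numpy())
    table["p_bonf"] = bonferroni_adjust(table["p"].to_numpy())
    return table.sort_values("p", kind="stable").reset_index(drop=True)
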