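"""Tab-separated cohort layouts and JSON model serialisation.

All tables are UTF-8 TSV with an empty cell meaning missing (tabs tolerate
commas inside metabolite names such as "ceramide (d18:2/24:1, d18:1/24:2)").
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .spls import SparsePLS
from .synthetic import CohortData, TruthRecord

__all__ = [
    "write_cohort", "read_cohort", "read_truth",
    "model_to_json", "model_from_json", "trace_to_dict",
]


def write_cohort(out_dir, data: CohortData, truth: TruthRecord | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data.abundances.to_csv(out / "abundances.tsv", sep="\t")
    cov = data.covariates.copy()
    cov.insert(0, "bmi", data.bmi)
    cov.insert(1, "family_id", data.family_id)
    cov.to_csv(out / "covariates.tsv", sep="\t")
    data.outcomes.to_csv(out / "outcomes.tsv", sep="\t")
    data.annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)
    if truth is not None:
        (out / "truth.json").write_text(json.dumps(truth.to_dict(), indent=1))


def _read_tsv(path: Path, index_col=0) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    names = header[1:] if index_col == 0 else header
    dupes = sorted({c for c in names if names.count(c) > 1})
    if dupes:
        raise ValueError(f"{path.name}: duplicated column identifiers: {dupes}")
    return pd.read_csv(path, sep="\t", index_col=index_col)


def _require_numeric(df: pd.DataFrame, name: str) -> pd.DataFrame:
    for col in df.columns:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df[col].notna() & coerced.isna()
            if bad.any():
                row = df.index[np.flatnonzero(bad)[0]]
                raise ValueError(
                    f"{name}: non-numeric value {df.loc[row, col]!r} at row "
                    f"{row!r}, column {col!r}"
                )
            df[col] = coerced
    return df


def read_cohort(in_dir) -> CohortData:
    """Read the TSV cohort layout back; inverse of :func:`write_cohort`."""
    d = Path(in_dir)
    abundances = _require_numeric(_read_tsv(d / "abundances.tsv"), "abundances.tsv")
    covtab = _read_tsv(d / "covariates.tsv")
    if "bmi" not in covtab.columns:
        raise ValueError("covariates.tsv must contain a 'bmi' column")
    bmi = pd.to_numeric(covtab.pop("bmi"))
    family = covtab.pop("family_id") if "family_id" in covtab.columns else pd.Series(
        abundances.index, index=abundances.index, name="family_id")
    outcomes = _require_numeric(_read_tsv(d / "outcomes.tsv"), "outcomes.tsv")
    annotation = _read_tsv(d / "annotation.tsv", index_col=None)
    return CohortData(abundances=abundances, covariates=covtab, bmi=bmi,
                      outcomes=outcomes, family_id=family, annotation=annotation)


def read_truth(in_dir) -> TruthRecord:
    raw = json.loads((Path(in_dir) / "truth.json").read_text())
    return TruthRecord(
        signal_ids=tuple(raw["signal_ids"]),
        mediator_ids=tuple(raw["mediator_ids"]),
        true_weights=pd.Series(raw["true_weights"], name="true_weight"),
        true_outcome_coefs=raw["true_outcome_coefs"],
        pathway_assignment=pd.Series(raw["pathway_assignment"]),
    )


def model_to_json(model: SparsePLS, path=None) -> dict:
    payload = {
        "eta": float(model.eta),
        "columns": list(model.columns_),
        "weights": {k: float(v) for k, v in model.weights_.items() if v != 0},
        "x_mean": [float(v) for v in model.x_mean_],
        "x_scale": [float(v) for v in model.x_scale_],
        "y_mean": model.y_mean_,
        "y_scale": model.y_scale_,
        "slope": model.slope_,
        "rmsecv": getattr(model, "rmsecv_", None),
        "r2cv": getattr(model, "r2cv_", None),
        "seed": getattr(model, "seed", None),
    }
    if path is not None:
        Path(path).write_text(json.dumps(payload, indent=1))
    return payload


def model_from_json(source) -> SparsePLS:
    if isinstance(source, (str, Path)):
        source = json.loads(Path(source).read_text())
    m = SparsePLS(eta=source["eta"])
    m.columns_ = list(source["columns"])
    w = pd.Series(0.0, index=m.columns_, name="weight")
    for k, v in source["weights"].items():
        w[k] = v
    m.weights_ = w
    m.x_mean_ = np.asarray(source["x_mean"], dtype=float)
    m.x_scale_ = np.asarray(source["x_scale"], dtype=float)
    m.y_mean_ = source["y_mean"]
    m.y_scale_ = source["y_scale"]
    m.slope_ = source["slope"]
    m.n_features_in_ = len(m.columns_)
    return m


def trace_to_dict(trace) -> dict:
    def res_dict(r):
        return {"acme": r.acme, "ade": r.ade, "total": r.total,
                "prop_mediated": r.prop_mediated, "acme_ci": list(r.acme_ci),
                "ade_ci": list(r.ade_ci), "total_ci": list(r.total_ci),
                "n_sim": r.n_sim}

    return {
        "initial_ids": list(trace.initial_ids),
        "final_ids": list(trace.final_ids),
        "stopping_reason": trace.stopping_reason,
        "initial": res_dict(trace.initial_result),
        "steps": [{"removed": s.removed_id, **res_dict(r)}
                  for s, r in zip(trace.steps, trace.step_results)],
    }
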