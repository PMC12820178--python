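"""End-to-end orchestration: simulate -> preprocess -> score -> associate ->
enrich -> mediate, as one seeded reproducible run.

One global seed fans out to per-stage seeds through a counter-based spawn, so
any stage can be rerun independently yet reproducibly.  Each stage writes its
outputs before the next begins; a stage failure halts the run with the stage
name while earlier outputs persist.  Defaults are desk-scale (200 samples x
120 metabolites, 3 CV repeats, 500 mediation draws); the cohort-scale
analysis (700 x 640, 10 repeats, 10,000 draws) is a configuration choice.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._utils import spawn_seeds
from . import io as mio
from .association import adjusted_score_model, association_table
from .enrichment import enrich
from .mediation import backward_eliminate, compare_full_vs_subset, composite_score
from .preprocess import (LogCenterScaler, MissingnessFilter, dedupe_twins,
                         pca_impute_covariates, rf_impute)
from .spls import predict_score, transfer_fit
from .synthetic import CohortConfig, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "preprocess_cohort"]

_STAGES = ("simulate", "preprocess", "score", "associate", "enrich", "mediate")


@dataclass
class RunConfig:
    """All stage parameters for one pipeline run."""

    out_dir: str = "metabsig_run"
    seed: int = 0
    stages: tuple = _STAGES

    # simulate
    n_samples: int = 200
    n_validation: int = 200
    n_metabolites: int = 120
    n_signal: int = 12
    n_mediators: int = 4
    signal_r2: float = 0.4
    missing_rate: float = 0.1
    missing_mechanism: str = "MCAR"
    twin_rate: float = 0.02
    validation_panel_frac: float = 0.9  # metabolites shared with validation

    # preprocess
    max_missing_frac: float = 1.0 / 3.0
    rf_trees: int = 30
    rf_max_iter: int = 3

    # score
    grid_step: float = 0.1
    cv_folds: int = 5
    cv_repeats: int = 3

    # mediate
    mediation_outcome: str = "gestational_diabetes"
    mediation_prevalence: float = 0.10  # desk-scale event count; cohort-scale ~0.02-0.05
    mediation_mediator_log_or: float = 0.5
    mediation_bmi_log_or: float = 0.3
    n_sim: int = 500
    min_size: int = 2

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def cohort_config(self, n: int, seed: int) -> CohortConfig:
        from .synthetic import OutcomeSpec, _default_outcomes
        outcomes = tuple(
            OutcomeSpec(o.name, self.mediation_prevalence,
                        bmi_log_or=self.mediation_bmi_log_or,
                        mediator_log_or=self.mediation_mediator_log_or)
            if o.name == self.mediation_outcome else o
            for o in _default_outcomes()
        )
        return CohortConfig(
            n_samples=n, n_metabolites=self.n_metabolites, n_signal=self.n_signal,
            n_mediators=self.n_mediators, signal_r2=self.signal_r2,
            outcome_specs=outcomes,
            missing_rate=self.missing_rate, missing_mechanism=self.missing_mechanism,
            twin_rate=self.twin_rate, seed=seed,
        )


def preprocess_cohort(data, max_missing_frac: float, seed: int,
                      rf_trees: int = 30, rf_max_iter: int = 3):
    """Filter -> de-duplicate twins -> log -> RF-impute (log scale) -> scale.

    Returns (Z, scaler, report_dict, deduped CohortData).
    """
    filt = MissingnessFilter(max_missing_frac).fit(data.abundances)
    deduped = dedupe_twins(data, seed=seed)
    ab = filt.transform(deduped.abundances)
    vals = ab.to_numpy(dtype=float)
    if np.nanmin(vals) <= 0:
        raise ValueError("abundances must be strictly positive where observed")
    logged = pd.DataFrame(np.log(vals), index=ab.index, columns=ab.columns)
    complete = rf_impute(logged, seed=seed, max_iter=rf_max_iter,
                         n_estimators=rf_trees)
    scaler = LogCenterScaler()
    scaler.columns_ = list(complete.columns)
    scaler.log_mean_ = complete.mean(axis=0)
    scaler.log_sd_ = complete.std(axis=0, ddof=1)
    if (scaler.log_sd_ <= 0).any():
        raise ValueError("zero-variance metabolite after imputation")
    Z = scaler.transform_pre_logged(complete)
    covariates = deduped.covariates
    if covariates.isna().to_numpy().any():
        covariates = pca_impute_covariates(covariates)
        deduped = deduped.copy()
        deduped.covariates = covariates
    report = {
        "n_input_metabolites": int(data.abundances.shape[1]),
        "n_excluded_missingness": int(len(filt.dropped_columns_)),
        "n_samples": int(len(Z)),
        "n_twins_removed": int(len(data.abundances) - len(deduped.abundances)),
    }
    return Z, scaler, report, deduped


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the RunReport dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(_STAGES, spawn_seeds(config.seed, len(_STAGES))))
    report = {"seed": config.seed, "stage_seeds": seeds, "stages": {},
              "config": dataclasses.asdict(config)}
    state: dict = {}

    def run_stage(name, fn):
        if name not in config.stages:
            report["stages"][name] = {"status": "skipped"}
            return
        t0 = time.perf_counter()
        try:
            summary = fn(seeds[name])
        except Exception as err:
            report["stages"][name] = {"status": "failed", "error": str(err)}
            _write_report(out, report)
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
        report["stages"][name] = {"status": "completed",
                                  "elapsed_s": round(time.perf_counter() - t0, 3),
                                  **summary}
        _write_report(out, report)

    # ---------------- simulate ----------------
    def _simulate(seed):
        rng = np.random.default_rng(seed)
        disc, truth = generate_cohort(config.cohort_config(config.n_samples, seed))
        vali, _ = generate_cohort(
            config.cohort_config(config.n_validation, seed + 1), truth=truth)
        # validation cohort measures a (random) subset of the panel
        p = config.n_metabolites
        n_keep = max(2, int(round(config.validation_panel_frac * p)))
        keep = sorted(rng.choice(p, size=n_keep, replace=False))
        vali.abundances = vali.abundances.iloc[:, keep]
        mio.write_cohort(out / "discovery", disc, truth)
        mio.write_cohort(out / "validation", vali)
        state.update(disc=disc, vali=vali, truth=truth)
        return {"n_discovery": len(disc.abundances), "n_validation": len(vali.abundances),
                "validation_panel": n_keep}

    # ---------------- preprocess ----------------
    def _preprocess(seed):
        if "disc" not in state:  # resuming from persisted simulate outputs
            state["disc"] = mio.read_cohort(out / "discovery")
            state["vali"] = mio.read_cohort(out / "validation")
        disc, vali = state["disc"], state["vali"]
        Zd, scaler_d, rep_d, disc2 = preprocess_cohort(
            disc, config.max_missing_frac, seed, config.rf_trees, config.rf_max_iter)
        Zv, scaler_v, rep_v, vali2 = preprocess_cohort(
            vali, config.max_missing_frac, seed + 1, config.rf_trees, config.rf_max_iter)
        Zd.to_csv(out / "discovery_Z.tsv", sep="\t")
        Zv.to_csv(out / "validation_Z.tsv", sep="\t")
        state.update(Zd=Zd, Zv=Zv, disc2=disc2, vali2=vali2)
        return {"discovery": rep_d, "validation": rep_v}

    # ---------------- score ----------------
    def _score(seed):
        Zd, Zv = state["Zd"], state["Zv"]
        overlap = [c for c in Zd.columns if c in set(Zv.columns)]
        grid = tuple(np.round(np.arange(0.0, 1.0 + 1e-9, config.grid_step), 10))
        model = transfer_fit(Zd, state["disc2"].bmi, overlap, grid=grid,
                             folds=config.cv_folds, repeats=config.cv_repeats,
                             seed=seed)
        score_d = predict_score(model, Zd[overlap], pre_standardized=True)
        score_v = predict_score(model, Zv[overlap], pre_standardized=True)
        mio.model_to_json(model, out / "model.json")
        score_d.to_frame().to_csv(out / "discovery_scores.tsv", sep="\t")
        score_v.to_frame().to_csv(out / "validation_scores.tsv", sep="\t")
        state.update(model=model, score_d=score_d, score_v=score_v, overlap=overlap)
        return {"n_overlap": len(overlap), "selected_eta": model.eta,
                "n_selected": len(model.selected_ids),
                "rmsecv": round(model.rmsecv_, 4), "r2cv": round(model.r2cv_, 4)}

    # ---------------- associate ----------------
    def _associate(seed):
        rows = []
        for label, cohort, score in (("discovery", state["disc2"], state["score_d"]),
                                     ("validation", state["vali2"], state["score_v"])):
            tab = association_table(
                cohort.outcomes,
                {"bmi": cohort.bmi, "metabolite_score": score},
                cohort.covariates, on_error="note",
            )
            tab.insert(0, "cohort", label)
            try:
                adj = adjusted_score_model(
                    cohort.outcomes[config.mediation_outcome], score,
                    (cohort.bmi - cohort.bmi.mean()) / cohort.bmi.std(ddof=1),
                    cohort.covariates, outcome_name=config.mediation_outcome)
                r = adj.exposure_row
                extra = {"cohort": label, "outcome": config.mediation_outcome,
                         "exposure": "score_adjusted_for_bmi", "OR": r["OR"],
                         "ci_low": r["ci_low"], "ci_high": r["ci_high"],
                         "p": r["p"], "n": adj.n, "pretty": "", "note": ""}
            except ValueError as err:
                extra = {"cohort": label, "outcome": config.mediation_outcome,
                         "exposure": "score_adjusted_for_bmi", "note": str(err)}
            tab = pd.concat([tab, pd.DataFrame([extra])], ignore_index=True)
            rows.append(tab)
        table = pd.concat(rows, ignore_index=True)
        table.to_csv(out / "associations.tsv", sep="\t", index=False)
        state["associations"] = table
        focal = table[(table.outcome == config.mediation_outcome)
                      & (table.exposure == "metabolite_score")]
        return {"n_rows": len(table),
                "score_or_by_cohort": {c: round(v, 3) for c, v in
                                       zip(focal.cohort, focal.OR)}}

    # ---------------- enrich ----------------
    def _enrich(seed):
        model = state["model"]
        annotation = state["disc2"].annotation
        table = enrich(model.selected_ids, annotation, background_ids=state["overlap"])
        table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        state["enrichment"] = table
        return {"n_pathways_tested": len(table),
                "n_fdr_hits": int((table.q_fdr < 0.05).sum()),
                "top_pathway": table.iloc[0]["sub_pathway"]}

    # ---------------- mediate ----------------
    def _mediate(seed):
        model, disc2 = state["model"], state["disc2"]
        Zd = state["Zd"][state["overlap"]]
        trace = backward_eliminate(
            Zd, disc2.bmi, disc2.outcomes[config.mediation_outcome],
            disc2.covariates, model, n_sim=config.n_sim, seed=seed,
            min_size=config.min_size, pre_standardized=True)
        (out / "mediation_trace.json").write_text(
            json.dumps(mio.trace_to_dict(trace), indent=1))
        # subset score in the validation cohort, compared against the full score
        Zv = state["Zv"][state["overlap"]]
        vali2 = state["vali2"]
        subset_v = composite_score(Zv, model, trace.final_ids, pre_standardized=True)
        full_v = state["score_v"]
        lrt_p = None
        try:
            _, _, lrt = compare_full_vs_subset(
                vali2.outcomes[config.mediation_outcome], full_v, subset_v,
                (vali2.bmi - vali2.bmi.mean()) / vali2.bmi.std(ddof=1),
                vali2.covariates, outcome_name=config.mediation_outcome)
            lrt_p = round(lrt.p, 5)
        except ValueError:
            pass  # degenerate subset (e.g. equals full score) has no LRT
        state["trace"] = trace
        return {"n_initial": len(trace.initial_ids), "n_final": len(trace.final_ids),
                "acme_initial": round(trace.initial_result.acme, 5),
                "acme_final": round(trace.acme_sequence[-1], 5),
                "stopping_reason": trace.stopping_reason,
                "validation_lrt_p": lrt_p}

    for name, fn in (("simulate", _simulate), ("preprocess", _preprocess),
                     ("score", _score), ("associate", _associate),
                     ("enrich", _enrich), ("mediate", _mediate)):
        run_stage(name, fn)
    _write_report(out, report)
    return report


def _write_report(out: Path, report: dict) -> None:
    (out / "run_report.json").write_text(json.dumps(report, indent=1, default=str))
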