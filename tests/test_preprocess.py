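"""Preprocessing contracts: missingness filter boundary, missForest-style
imputation, log/centre/scale, iterative-PCA covariate completion, twin
de-duplication and the missingness-vs-outcome diagnostic."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestRegressor

from metabsig import (CohortConfig, apply_missingness, dedupe_twins,
                      filter_by_missingness, generate_cohort, log_center_scale,
                      missingness_outcome_association, pca_impute_covariates,
                      rf_impute)
from metabsig.preprocess import ForestImputer, IterativePCAImputer


def _matrix_with_missing_counts(counts, n=100, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.lognormal(size=(n, len(counts))),
                     columns=[f"m{j}" for j in range(len(counts))])
    for j, c in enumerate(counts):
        X.iloc[rng.choice(n, size=c, replace=False), j] = np.nan
    return X


class TestMissingnessFilter:
    def test_strict_boundary_at_one_third(self):
        # fractions 0, .20, .33, .34, .50 against threshold 1/3: the rule is
        # "more than" so .33 stays, .34 and .50 go
        X = _matrix_with_missing_counts([0, 20, 33, 34, 50])
        kept, report = filter_by_missingness(X, 1.0 / 3.0)
        assert list(kept.columns) == ["m0", "m1", "m2"]
        assert report.n_excluded_missingness == 2
        assert report.excluded_ids == ["m3", "m4"]

    def test_fully_observed_is_identity(self):
        X = _matrix_with_missing_counts([0, 0, 0])
        kept, report = filter_by_missingness(X)
        pd.testing.assert_frame_equal(kept, X)
        assert report.n_excluded_missingness == 0

    def test_reported_fractions_match_planted(self):
        counts = [5, 17, 40]
        X = _matrix_with_missing_counts(counts)
        _, report = filter_by_missingness(X, max_missing_frac=0.5)
        np.testing.assert_allclose(report.missing_fractions.to_numpy(),
                                   np.array(counts) / 100.0)

    def test_everything_filtered_is_an_error(self):
        X = _matrix_with_missing_counts([60, 70])
        with pytest.raises(ValueError, match="every metabolite"):
            filter_by_missingness(X, 1.0 / 3.0)


class TestForestImputation:
    def test_complete_matrix_is_identity(self):
        X = _matrix_with_missing_counts([0, 0, 0, 0])
        out = rf_impute(X, seed=1, n_estimators=10)
        pd.testing.assert_frame_equal(out, X)

    def test_constant_column_imputes_the_constant(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"a": rng.normal(size=50), "b": np.full(50, 7.0)})
        X.loc[X.index[3], "b"] = np.nan
        out = rf_impute(X, seed=1, n_estimators=10)
        assert out.loc[X.index[3], "b"] == pytest.approx(7.0)

    def test_beats_column_mean_on_correlated_data(self):
        rng = np.random.default_rng(3)
        n = 150
        base = rng.normal(size=n)
        X = pd.DataFrame({f"m{j}": base + 0.33 * rng.normal(size=n)
                          for j in range(4)})
        truth = X.copy()
        holes = rng.random(X.shape) < 0.10
        holes[:, 0] = False  # keep one anchor column complete
        X = X.mask(holes)
        imputed = rf_impute(X, seed=4, n_estimators=50)
        mean_filled = X.fillna(X.mean())
        err_rf = ((imputed - truth)[holes] ** 2).sum().sum()
        err_mean = ((mean_filled - truth)[holes] ** 2).sum().sum()
        assert err_rf < err_mean

    def test_observed_cells_never_altered(self):
        X = _matrix_with_missing_counts([10, 20, 5, 0], n=80, seed=5)
        out = rf_impute(X, seed=6, n_estimators=10)
        obs = X.notna()
        assert np.array_equal(out[obs].fillna(0.0), X[obs].fillna(0.0))
        assert not out.isna().any().any()

    def test_all_missing_column_is_an_error(self):
        X = _matrix_with_missing_counts([0, 0])
        X["dead"] = np.nan
        with pytest.raises(ValueError, match="dead"):
            rf_impute(X, seed=1)

    def test_single_sweep_matches_direct_oracle(self):
        # one iteration must equal a hand-rolled sweep: mean-init, columns in
        # descending-missingness order, RF per column with the same seeds
        X = _matrix_with_missing_counts([8, 15, 3, 0], n=60, seed=7)
        out = ForestImputer(n_estimators=20, max_iter=1,
                            random_state=9).fit_transform(X)

        vals = X.to_numpy(dtype=float).copy()
        m = X.isna().to_numpy()
        means = np.nanmean(vals, axis=0)
        for j in range(vals.shape[1]):
            vals[m[:, j], j] = means[j]
        counts = m.sum(axis=0)
        order = sorted(np.flatnonzero(counts > 0), key=lambda j: (-counts[j], j))
        rs = np.random.RandomState(9)
        for j in order:
            obs = ~m[:, j]
            other = np.delete(np.arange(vals.shape[1]), j)
            rf = RandomForestRegressor(n_estimators=20, min_samples_leaf=5,
                                       random_state=rs.randint(0, 2**31 - 1))
            rf.fit(vals[obs][:, other], vals[obs, j])
            vals[m[:, j], j] = rf.predict(vals[m[:, j]][:, other])
        np.testing.assert_allclose(out.to_numpy(), vals)


class TestLogCenterScale:
    def test_columns_standardized(self):
        X = _matrix_with_missing_counts([0, 0, 0], seed=8)
        Z, scaler = log_center_scale(X)
        assert np.all(np.abs(Z.mean()) < 1e-10)
        assert np.all(np.abs(Z.std(ddof=1) - 1) < 1e-10)

    def test_positive_rescaling_is_absorbed(self):
        X = _matrix_with_missing_counts([0, 0], seed=9)
        Z1, _ = log_center_scale(X)
        Z2, _ = log_center_scale(X * 37.5)
        pd.testing.assert_frame_equal(Z1, Z2)

    def test_ranks_preserved(self):
        X = _matrix_with_missing_counts([0, 0], seed=10)
        Z, _ = log_center_scale(X)
        for c in X.columns:
            assert (X[c].rank() == Z[c].rank()).all()

    def test_nonpositive_cell_error_carries_coordinates(self):
        X = _matrix_with_missing_counts([0, 0], seed=11)
        X.iloc[4, 1] = -1.0
        with pytest.raises(ValueError, match="row 4.*column 'm1'"):
            log_center_scale(X)

    def test_zero_variance_column_is_an_error(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [2.0, 2.0, 2.0]})
        with pytest.raises(ValueError, match="flat"):
            log_center_scale(X)

    def test_training_transform_replays_on_external_data(self):
        X = _matrix_with_missing_counts([0, 0, 0], seed=12)
        Z, scaler = log_center_scale(X)
        pd.testing.assert_frame_equal(scaler.transform(X), Z)


class TestPCAImputation:
    def test_complete_table_is_identity(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(30, 4)))
        out = IterativePCAImputer().fit_transform(X)
        pd.testing.assert_frame_equal(out, X)

    def test_rank_one_completion_is_exact(self):
        rng = np.random.default_rng(1)
        u, v = rng.normal(size=40), rng.normal(size=5)
        X = pd.DataFrame(np.outer(u, v), columns=list("abcde"))
        truth = X.iloc[7, 2]
        X.iloc[7, 2] = np.nan
        out = IterativePCAImputer(n_components=1, tol=1e-9,
                                  max_iter=2000).fit_transform(X)
        assert out.iloc[7, 2] == pytest.approx(truth, abs=1e-4)

    def test_beats_column_mean_on_correlated_data(self):
        rng = np.random.default_rng(2)
        n = 200
        f = rng.normal(size=n)
        X = pd.DataFrame({f"c{j}": f + 0.4 * rng.normal(size=n) for j in range(5)})
        truth = X.copy()
        holes = rng.random(X.shape) < 0.10
        X = X.mask(holes)
        out = pca_impute_covariates(X)
        err_pca = ((out - truth)[holes] ** 2).sum().sum()
        err_mean = ((X.fillna(X.mean()) - truth)[holes] ** 2).sum().sum()
        assert err_pca < err_mean

    def test_nonconvergence_warns_and_returns_last_iterate(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(np.outer(rng.normal(size=30), rng.normal(size=4)))
        X.iloc[5, 1] = np.nan
        imp = IterativePCAImputer(tol=1e-14, max_iter=2)
        with pytest.warns(UserWarning, match="did not converge"):
            out = imp.fit_transform(X)
        assert not imp.converged_
        assert not out.isna().any().any()

    def test_categorical_columns_round_trip(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({
            "num": rng.normal(size=120),
            "cat": pd.Series(rng.choice(["lo", "mid", "hi"], size=120)),
        })
        X.loc[X.index[:10], "cat"] = np.nan
        X.loc[X.index[20:30], "num"] = np.nan
        out = pca_impute_covariates(X)
        assert not out.isna().any().any()
        assert set(out["cat"]) <= {"lo", "mid", "hi"}
        # observed categories untouched
        obs = X["cat"].notna()
        assert (out.loc[obs, "cat"] == X.loc[obs, "cat"]).all()


class TestDedupeTwins:
    def test_no_duplicates_is_identity(self):
        cfg = CohortConfig(n_samples=60, n_metabolites=10, n_signal=3,
                           n_mediators=1, twin_rate=0.0, seed=21)
        data, _ = generate_cohort(cfg)
        out = dedupe_twins(data, seed=0)
        pd.testing.assert_frame_equal(out.abundances, data.abundances)

    def test_one_kept_per_family(self, small_cohort):
        cfg, data, _ = small_cohort
        out = dedupe_twins(data, seed=1)
        assert not out.family_id.duplicated().any()
        n_pairs = int(round(cfg.twin_rate * cfg.n_samples / 2))
        assert len(out.abundances) == cfg.n_samples - n_pairs

    def test_seeded_choice_is_reproducible(self, small_cohort):
        _, data, _ = small_cohort
        a = dedupe_twins(data, seed=7)
        b = dedupe_twins(data, seed=7)
        assert list(a.abundances.index) == list(b.abundances.index)


class TestMissingnessOutcomeAssociation:
    @staticmethod
    def _cohort(mechanism, seed, gamma=-0.5):
        cfg = CohortConfig(n_samples=2000, n_metabolites=30, n_signal=5,
                           n_mediators=2, twin_rate=0.0, missing_rate=0.15,
                           missing_mechanism=mechanism, missing_gamma=gamma,
                           missing_outcome="cesarean_section", seed=seed)
        return generate_cohort(cfg)[0]

    def test_mcar_null_coverage(self):
        covered = 0
        for seed in range(50):
            data = self._cohort("MCAR", 100 + seed)
            fit = missingness_outcome_association(
                data.mask, data.outcomes["cesarean_section"],
                data.abundances.columns[:10])
            row = fit.exposure_row
            covered += row["ci_low"] <= 1.0 <= row["ci_high"]
        assert covered >= 45  # >= 90% of 50 null replicates

    def test_planted_mechanism_recovered(self):
        data = self._cohort("outcome-dependent", 7)
        fit = missingness_outcome_association(
            data.mask, data.outcomes["cesarean_section"],
            list(data.abundances.columns), predictor="count")
        row = fit.exposure_row
        assert row["OR"] < 1.0 and row["p"] < 0.05

    def test_constant_predictor_is_an_error(self, small_cohort):
        _, data, _ = small_cohort  # fully observed
        with pytest.raises(ValueError, match="constant"):
            missingness_outcome_association(
                data.mask, data.outcomes["cesarean_section"],
                data.abundances.columns[:5])
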