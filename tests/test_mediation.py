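"""Causal-mediation contracts: composite scores, quasi-Bayesian ACME against
closed forms and independent oracles, backward elimination, and the
full-vs-subset likelihood-ratio comparison."""

import numpy as np
import pandas as pd
import pytest

from metabsig import (acme_quasi_bayes, backward_eliminate,
                      compare_full_vs_subset, composite_score,
                      fit_mediator_model, fit_outcome_model)
from metabsig.spls import SparsePLS

from conftest import make_mediation_cohort


def _sigmoid(x):
    return 1 / (1 + np.exp(-x))


def _linear_system(rng, n=4000, a=0.5, b=0.4, binary=False, b0=-2.0):
    T = rng.standard_normal(n)
    M = a * T + rng.standard_normal(n)
    if binary:
        Y = rng.binomial(1, _sigmoid(b0 + b * M + 0.1 * T)).astype(float)
    else:
        Y = b * M + 0.1 * T + rng.standard_normal(n)
    mf = fit_mediator_model(pd.Series(M, name="score"), pd.Series(T, name="bmi"))
    of = fit_outcome_model(pd.Series(Y), pd.Series(T, name="bmi"),
                           pd.Series(M, name="score"), binary=binary)
    return mf, of


class TestCompositeScore:
    @staticmethod
    def _model(Z):
        rng = np.random.default_rng(0)
        return SparsePLS(eta=0.0).fit(Z, rng.normal(size=len(Z)) + Z.iloc[:, 0])

    def test_full_subset_equals_full_score(self):
        rng = np.random.default_rng(1)
        Z = pd.DataFrame(rng.normal(size=(200, 6)),
                         columns=[f"m{j}" for j in range(6)])
        m = self._model(Z)
        full = composite_score(Z, m)
        again = composite_score(Z, m, subset=list(m.weights_.index))
        np.testing.assert_allclose(full, again)

    def test_singleton_subset_is_signed_zscore(self):
        rng = np.random.default_rng(2)
        Z = pd.DataFrame(rng.normal(size=(300, 5)),
                         columns=[f"m{j}" for j in range(5)])
        m = self._model(Z)
        j = "m3"
        s = composite_score(Z, m, subset=[j])
        col = Z[j]
        z = (col - col.mean()) / col.std(ddof=1)
        sign = np.sign(m.weights_[j])
        np.testing.assert_allclose(s, sign * z, atol=1e-12)

    def test_variance_adds_over_orthogonal_parts(self):
        rng = np.random.default_rng(3)
        # exactly orthogonal zero-mean columns: QR of a centred matrix stays
        # inside the zero-mean subspace
        V = rng.normal(size=(400, 4))
        Q, _ = np.linalg.qr(V - V.mean(axis=0))
        Z = pd.DataFrame(Q * np.sqrt(399), columns=list("abcd"))
        m = self._model(Z)
        w = m.weights_

        def raw_var(subset):
            v = Z[subset].to_numpy() @ w[subset].to_numpy()
            return v.var(ddof=1)

        assert raw_var(["a", "b"]) + raw_var(["c", "d"]) == pytest.approx(
            raw_var(["a", "b", "c", "d"]), rel=1e-10)

    def test_empty_subset_rejected(self):
        rng = np.random.default_rng(4)
        Z = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        with pytest.raises(ValueError, match="empty"):
            composite_score(Z, self._model(Z), subset=[])


class TestQuasiBayesACME:
    def test_no_exposure_mediator_path_means_no_mediation(self):
        rng = np.random.default_rng(5)
        mf, of = _linear_system(rng, n=2000, a=0.0, b=0.6, binary=True, b0=-1.0)
        r = acme_quasi_bayes(mf, of, n_sim=2000, seed=1)
        assert r.acme_ci[0] <= 0.0 <= r.acme_ci[1]
        assert abs(r.acme) < 0.01

    def test_linear_limit_matches_product_of_coefficients(self):
        rng = np.random.default_rng(6)
        mf, of = _linear_system(rng, n=4000, a=0.5, b=0.4, binary=False)
        r = acme_quasi_bayes(mf, of, n_sim=2000, seed=2)
        assert r.acme == pytest.approx(0.5 * 0.4, abs=0.03)
        # and equals the plug-in product of the fitted coefficients tightly
        ab = float(mf.params.iloc[1] * of.params.iloc[2])
        assert r.acme == pytest.approx(ab, abs=0.01)

    def test_logistic_outcome_matches_integration_oracle(self):
        rng = np.random.default_rng(7)
        mf, of = _linear_system(rng, n=4000, a=0.5, b=0.8, binary=True)
        r = acme_quasi_bayes(mf, of, n_sim=2000, seed=3)

        # Gauss-Hermite expectation over the fitted mediator distribution at
        # the point estimates (independent numerical oracle)
        am = mf.params.to_numpy()
        sd = float(np.sqrt(mf.scale))
        bo = of.params.to_numpy()
        T = mf.model.exog[:, 1]
        nodes, wts = np.polynomial.hermite_e.hermegauss(80)
        wts = wts / wts.sum()

        def mean_y(tv, m_arm):
            mu = am[0] + am[1] * m_arm
            m = mu + sd * nodes
            p = _sigmoid(bo[0] + bo[1] * tv + bo[2] * m)
            return float(p @ wts)

        oracle = 0.5 * sum(mean_y(tv, 1.0) - mean_y(tv, 0.0) for tv in (1.0, 0.0))
        assert r.acme == pytest.approx(oracle, abs=0.01)

    def test_per_draw_identity_acme_plus_ade_is_total(self):
        rng = np.random.default_rng(8)
        mf, of = _linear_system(rng, n=1000, binary=True, b=0.6)
        r = acme_quasi_bayes(mf, of, n_sim=500, seed=4)
        d = r.draws
        assert np.max(np.abs(d["acme"] + d["ade"] - d["total"])) < 1e-12
        assert r.acme_ci[0] <= r.acme <= r.acme_ci[1]

    def test_matches_statsmodels_mediation(self):
        # independent implementation of the same quasi-Bayesian estimand
        from statsmodels.stats.mediation import Mediation
        import statsmodels.api as sm

        rng = np.random.default_rng(9)
        n = 3000
        T = rng.standard_normal(n)
        M = 0.5 * T + rng.standard_normal(n)
        Y = rng.binomial(1, _sigmoid(-1.0 + 0.7 * M + 0.2 * T)).astype(float)
        df = pd.DataFrame({"T": T, "M": M, "Y": Y})
        out_model = sm.GLM.from_formula("Y ~ T + M", df,
                                        family=sm.families.Binomial())
        med_model = sm.OLS.from_formula("M ~ T", df)
        np.random.seed(11)
        ref = Mediation(out_model, med_model, "T", "M").fit(
            method="parametric", n_rep=400)
        ref_acme = ref.summary().loc["ACME (average)", "Estimate"]

        mf = fit_mediator_model(df["M"].rename("score"), df["T"].rename("bmi"))
        of = fit_outcome_model(df["Y"], df["T"].rename("bmi"),
                               df["M"].rename("score"))
        ours = acme_quasi_bayes(mf, of, n_sim=2000, seed=5)
        assert ours.acme == pytest.approx(ref_acme, abs=0.01)

    def test_rejects_tiny_simulation_count(self):
        rng = np.random.default_rng(10)
        mf, of = _linear_system(rng, n=500, binary=True)
        with pytest.raises(ValueError, match="n_sim"):
            acme_quasi_bayes(mf, of, n_sim=10)


class TestBackwardElimination:
    def test_planted_mediators_recovered(self):
        hits = 0
        for seed in (1, 2, 3):
            data, truth = make_mediation_cohort(seed, n=2000)
            X = np.log(data.abundances)
            model = SparsePLS(eta=0.0).fit(X, data.bmi)
            tr = backward_eliminate(X, data.bmi,
                                    data.outcomes["gestational_diabetes"],
                                    None, model, n_sim=300, seed=seed)
            final = set(tr.final_ids)
            if set(truth.mediator_ids) <= final and \
                    len(final - set(truth.mediator_ids)) <= 2:
                hits += 1
            seq = tr.acme_sequence
            assert all(b > a for a, b in zip(seq, seq[1:]))
        assert hits >= 2

    def test_null_outcome_keeps_interval_over_zero(self):
        data, truth = make_mediation_cohort(21, n=1500, mediator_log_or=0.0)
        X = np.log(data.abundances)
        model = SparsePLS(eta=0.0).fit(X, data.bmi)
        tr = backward_eliminate(X, data.bmi,
                                data.outcomes["gestational_diabetes"],
                                None, model, n_sim=300, seed=0)
        last = tr.step_results[-1] if tr.step_results else tr.initial_result
        assert last.acme_ci[0] <= 0.0 <= last.acme_ci[1]

    def test_min_size_input_returns_empty_trace(self):
        rng = np.random.default_rng(11)
        Z = pd.DataFrame(rng.normal(size=(300, 2)), columns=["a", "b"])
        bmi = Z["a"] + rng.normal(size=300)
        y = pd.Series(rng.binomial(1, 0.3, 300))
        model = SparsePLS(eta=0.0).fit(Z, bmi)
        tr = backward_eliminate(Z, bmi, y, None, model, n_sim=200, seed=1,
                                min_size=2)
        assert tr.steps == ()
        assert tr.stopping_reason == "min_size"
        assert tr.final_ids == tr.initial_ids

    def test_fixed_seed_reproducible(self):
        data, _ = make_mediation_cohort(31, n=800)
        X = np.log(data.abundances)
        model = SparsePLS(eta=0.0).fit(X, data.bmi)
        y = data.outcomes["gestational_diabetes"]
        a = backward_eliminate(X, data.bmi, y, None, model, n_sim=200, seed=9)
        b = backward_eliminate(X, data.bmi, y, None, model, n_sim=200, seed=9)
        assert a.final_ids == b.final_ids
        assert a.acme_sequence == b.acme_sequence


class TestFullVsSubset:
    def test_identical_scores_are_collinear(self):
        rng = np.random.default_rng(12)
        s = pd.Series(rng.normal(size=400))
        bmi = pd.Series(rng.normal(size=400))
        y = pd.Series(rng.binomial(1, 0.3, 400))
        with pytest.raises(ValueError, match="rank deficient"):
            compare_full_vs_subset(y, s, s, bmi)

    def test_informative_subset_improves_fit(self):
        rng = np.random.default_rng(13)
        wins = 0
        for _ in range(5):
            n = 3000
            bmi = rng.standard_normal(n)
            subset = 0.6 * bmi + 0.8 * rng.standard_normal(n)
            full = 0.7 * subset + 0.7 * rng.standard_normal(n)  # diluted
            y = rng.binomial(1, _sigmoid(-2 + 0.8 * subset))
            _, _, lrt = compare_full_vs_subset(
                pd.Series(y), pd.Series(full), pd.Series(subset),
                pd.Series(bmi))
            wins += lrt.p < 0.05
        assert wins >= 3

    def test_noise_subset_adds_nothing(self):
        rng = np.random.default_rng(14)
        ps = []
        for _ in range(40):
            n = 600
            bmi = rng.standard_normal(n)
            full = 0.5 * bmi + rng.standard_normal(n)
            noise = rng.standard_normal(n)
            y = rng.binomial(1, _sigmoid(-1.2 + 0.5 * full))
            _, _, lrt = compare_full_vs_subset(
                pd.Series(y), pd.Series(full), pd.Series(noise),
                pd.Series(bmi))
            ps.append(lrt.p)
        # roughly uniform: no pile-up of small p-values
        assert np.mean(np.array(ps) < 0.05) < 0.2
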