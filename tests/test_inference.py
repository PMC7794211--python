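"""OLS framework fit, VIF, AIC, bootstrap and partial-regression battery."""

import math

import numpy as np
import pytest
import statsmodels.api as sm

from hpratio.core import FactorMapping, FactorVector, predict_log_ratio
from hpratio.field import TreatmentRecord
from hpratio.inference import (
    PREDICTORS,
    aic_model_selection,
    bootstrap_ci,
    design_matrix,
    fit_framework,
    partial_leverage,
    pearson,
    standardized_coefficients,
    vif,
)
from hpratio.synth import SynthDesign, generate_treatments

TRUTH = dict(a_nut=-7.07, a_edi=1.19, mu=1.80, theta=0.50)
GAMMA = 29.31


def make_records(a_nut, a_edi, mu, cpue, log_ratio=None, rng=None):
    """Records with H back-solved from a given (or framework-true) log ratio."""
    mapping = FactorMapping(eps1=TRUTH["a_nut"], eps2=TRUTH["a_edi"],
                            eps3=TRUTH["mu"], eps4=TRUTH["theta"], gamma=GAMMA)
    records = []
    for i in range(len(a_nut)):
        if log_ratio is None:
            lr = predict_log_ratio(
                mapping,
                FactorVector(a_nut=a_nut[i], a_edi=a_edi[i], mu=mu[i],
                             theta=cpue[i] + 1.0),
            )
        else:
            lr = log_ratio[i]
        p = 300.0
        records.append(
            TreatmentRecord(pond=f"P{i % 2 + 1}", treatment=str(i),
                            h_biomass=p * math.exp(lr), p_biomass=p,
                            a_nut=a_nut[i], a_edi=a_edi[i], mu=mu[i],
                            cpue=cpue[i])
        )
    return records


def random_records(rng, n=8, noise=0.0):
    a_nut = rng.uniform(90, 310, n)
    a_edi = rng.uniform(0.05, 0.95, n)
    mu = rng.uniform(5, 60, n)
    cpue = rng.uniform(0, 20, n)
    recs = make_records(a_nut, a_edi, mu, cpue)
    if noise > 0:
        recs = [
            TreatmentRecord(pond=r.pond, treatment=r.treatment,
                            h_biomass=r.h_biomass * math.exp(rng.normal(0, noise)),
                            p_biomass=r.p_biomass, a_nut=r.a_nut, a_edi=r.a_edi,
                            mu=r.mu, cpue=r.cpue)
            for r in recs
        ]
    return recs


class TestFitFramework:
    def test_noiseless_interpolation_recovers_truth(self):
        rng = np.random.default_rng(0)
        recs = random_records(rng)
        res = fit_framework(recs, n_boot=199, seed=1)
        assert res.gamma_hat == pytest.approx(GAMMA, abs=1e-8)
        for k, v in TRUTH.items():
            assert res.eps_hat[k] == pytest.approx(v, abs=1e-8)
        assert res.r2 == pytest.approx(1.0)

    def test_theta_coefficient_is_negated_raw(self):
        rng = np.random.default_rng(2)
        recs = random_records(rng, noise=0.3)
        res = fit_framework(recs, n_boot=199, seed=1)
        X, y = design_matrix(recs)
        raw = np.linalg.lstsq(X, y, rcond=None)[0]
        assert res.eps_hat["theta"] == pytest.approx(-raw[4], abs=1e-10)
        assert res.eps_hat["a_nut"] == pytest.approx(raw[1], abs=1e-10)

    def test_matches_statsmodels_ols(self):
        """Raw coefficients and R^2 agree with an independent OLS route."""
        rng = np.random.default_rng(3)
        recs = random_records(rng, n=12, noise=0.5)
        X, y = design_matrix(recs)
        sm_fit = sm.OLS(y, X).fit()
        res = fit_framework(recs, n_boot=199, seed=1)
        assert res.gamma_hat == pytest.approx(sm_fit.params[0], abs=1e-8)
        assert res.eps_hat["mu"] == pytest.approx(sm_fit.params[3], abs=1e-8)
        assert res.r2 == pytest.approx(sm_fit.rsquared, abs=1e-10)

    def test_singular_design_rejected(self):
        n = 8
        a_nut = np.linspace(0.5, 0.9, n)
        recs = make_records(a_nut, a_nut.copy(), np.full(n, 20.0),
                            np.linspace(0, 5, n),
                            log_ratio=np.linspace(-1, 1, n))
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            fit_framework(recs, n_boot=199, seed=1)

    def test_needs_more_records_than_parameters(self):
        rng = np.random.default_rng(4)
        recs = random_records(rng, n=5)
        with pytest.raises(ValueError):
            fit_framework(recs, n_boot=199, seed=1)

    def test_slopes_invariant_to_log_base(self):
        """eps are base-free; gamma rescales as gamma_e / ln 10."""
        rng = np.random.default_rng(5)
        recs = random_records(rng, noise=0.4)
        res_e = fit_framework(recs, log_base=math.e, n_boot=199, seed=1)
        res_10 = fit_framework(recs, log_base=10.0, n_boot=199, seed=1)
        for k in PREDICTORS:
            assert res_e.eps_hat[k] == pytest.approx(res_10.eps_hat[k], abs=1e-9)
        assert res_10.gamma_hat == pytest.approx(res_e.gamma_hat / math.log(10),
                                                 abs=1e-9)


class TestVIF:
    def test_orthogonal_predictors_give_unity(self):
        # 2^3 factorial in the first three log-factors, theta constant-free
        signs = np.array([[i >> b & 1 for b in range(3)] for i in range(8)]) * 2 - 1
        a_nut = np.exp(signs[:, 0] * 0.5 + 5.0)
        a_edi = 1.0 / (1.0 + np.exp(-signs[:, 1]))
        mu = np.exp(signs[:, 2] * 0.5 + 3.0)
        cpue = np.exp(signs[:, 0] * signs[:, 1] * 0.5) - np.exp(-0.5)
        recs = make_records(a_nut, a_edi, mu, cpue)
        out = vif(recs)
        for name in ("a_nut", "a_edi", "mu"):
            assert out[name] == pytest.approx(1.0, abs=1e-8)

    def test_perfect_collinearity_reported_infinite(self):
        n = 8
        a_nut = np.linspace(0.5, 0.9, n)
        recs = make_records(a_nut, a_nut**2, np.full(n, 20.0) * np.exp(
            np.linspace(0, 1, n)), np.linspace(0, 5, n),
            log_ratio=np.linspace(-1, 1, n))
        out = vif(recs)
        assert math.isinf(out["a_nut"])
        assert math.isinf(out["a_edi"])


class TestAIC:
    def test_collinear_duplicate_loses_to_smaller_model(self):
        """Equal RSS: the model with fewer coefficients ranks higher."""
        n = 8
        a_nut = np.exp(np.linspace(4.5, 5.7, n))
        rng = np.random.default_rng(6)
        recs = make_records(a_nut, a_nut ** -0.2, np.full(n, 20.0) * np.exp(
            rng.normal(0, 0.3, n)), rng.uniform(0, 5, n),
            log_ratio=rng.normal(0, 1, n))
        ranked = aic_model_selection(recs)
        pos = {r["predictors"]: r["rank"] for r in ranked}
        # a_edi is an exact log-linear copy of a_nut: adding it never helps
        assert pos[("a_nut",)] < pos[("a_nut", "a_edi")]

    def test_aic_value_matches_r_convention(self):
        """Gaussian AIC with sigma counted, as R's AIC(lm(...)) computes it."""
        rng = np.random.default_rng(7)
        recs = random_records(rng, noise=0.5)
        res = fit_framework(recs, n_boot=199, seed=1)
        X, y = design_matrix(recs)
        llf = sm.OLS(y, X).fit().llf
        assert res.aic == pytest.approx(-2 * llf + 2 * 6, abs=1e-8)


class TestBootstrap:
    def test_zero_residuals_zero_width(self):
        rng = np.random.default_rng(8)
        recs = random_records(rng)  # exact framework data
        ci = bootstrap_ci(recs, n_boot=199, seed=3)
        res = fit_framework(recs, n_boot=199, seed=3)
        for k in PREDICTORS:
            lo, hi = ci[k]
            assert hi - lo == pytest.approx(0.0, abs=1e-8)
            assert lo == pytest.approx(res.eps_hat[k], abs=1e-8)

    def test_seed_determinism(self):
        rng = np.random.default_rng(9)
        recs = random_records(rng, noise=0.5)
        a = bootstrap_ci(recs, n_boot=299, seed=5)
        b = bootstrap_ci(recs, n_boot=299, seed=5)
        c = bootstrap_ci(recs, n_boot=299, seed=6)
        assert a == b
        assert a != c

    def test_orientation_follows_expected_sign(self):
        """Negative-effect parameters are bounded above, positive below."""
        rng = np.random.default_rng(10)
        recs = random_records(rng, noise=0.5)
        ci_default = bootstrap_ci(recs, n_boot=299, seed=5)
        flipped = {"a_nut": "positive", "a_edi": "negative", "mu": "negative",
                   "theta": "negative"}
        ci_flipped = bootstrap_ci(recs, n_boot=299, seed=5, directions=flipped)
        res = fit_framework(recs, n_boot=299, seed=5)
        for k in PREDICTORS:
            lo, hi = ci_default[k]
            assert lo <= res.eps_hat[k] <= hi
        # a negative-expected parameter is bounded by its 95th percentile,
        # a positive-expected one by its 5th: the informative bound moves
        # when the a-priori direction is flipped
        assert ci_flipped["a_nut"][0] >= ci_default["a_nut"][0]
        assert ci_flipped["mu"][1] <= ci_default["mu"][1]

    def test_small_n_boot_rejected(self):
        rng = np.random.default_rng(11)
        recs = random_records(rng, noise=0.5)
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_ci(recs, n_boot=50, seed=1)


class TestStandardized:
    def test_single_predictor_equals_pearson(self):
        rng = np.random.default_rng(12)
        recs = random_records(rng, noise=0.8)
        X, y = design_matrix(recs)
        std = standardized_coefficients(recs, predictors=["mu"])
        r, _, _ = pearson(X[:, 3], y)
        assert std["mu"] == pytest.approx(r, abs=1e-10)

    def test_scale_invariance(self):
        rng = np.random.default_rng(13)
        recs = random_records(rng, noise=0.5)
        scaled = [
            TreatmentRecord(pond=r.pond, treatment=r.treatment,
                            h_biomass=r.h_biomass, p_biomass=r.p_biomass,
                            a_nut=r.a_nut, a_edi=r.a_edi, mu=1000 * r.mu,
                            cpue=r.cpue)
            for r in recs
        ]
        a = standardized_coefficients(recs)
        b = standardized_coefficients(scaled)
        for k in PREDICTORS:
            assert a[k] == pytest.approx(b[k], abs=1e-10)

    def test_zero_variance_predictor_rejected(self):
        n = 8
        rng = np.random.default_rng(14)
        recs = make_records(rng.uniform(90, 310, n), rng.uniform(0.1, 0.9, n),
                            np.full(n, 20.0), rng.uniform(0, 5, n))
        with pytest.raises(ValueError, match="mu"):
            standardized_coefficients(recs)


class TestPartialLeverage:
    def test_slope_equals_full_model_coefficient(self):
        """Frisch-Waugh-Lovell identity on 100 random datasets."""
        rng = np.random.default_rng(15)
        for _ in range(100):
            recs = random_records(rng, noise=rng.uniform(0.1, 1.0))
            X, y = design_matrix(recs)
            full = sm.OLS(y, X).fit().params
            for j, name in enumerate(PREDICTORS, start=1):
                pl = partial_leverage(recs, name)
                assert pl.slope == pytest.approx(full[j], abs=1e-8)

    def test_orthogonal_design_partial_equals_simple_r(self):
        signs = np.array([[i >> b & 1 for b in range(3)] for i in range(8)]) * 2 - 1
        a_nut = np.exp(signs[:, 0] * 0.5 + 5.0)
        a_edi = 1.0 / (1.0 + np.exp(-signs[:, 1]))
        mu = np.exp(signs[:, 2] * 0.5 + 3.0)
        cpue = np.exp(signs[:, 0] * signs[:, 1] * 0.5) - np.exp(-0.5)
        rng = np.random.default_rng(16)
        recs = make_records(a_nut, a_edi, mu, cpue,
                            log_ratio=rng.normal(0, 1, 8))
        X, y = design_matrix(recs)
        pl = partial_leverage(recs, "a_nut")
        r_simple, _, _ = pearson(X[:, 1], y)
        # orthogonality removes no y-variance shared with x1's direction,
        # but partial r rescales by the residual y variance
        assert np.sign(pl.partial_r) == np.sign(r_simple)
        assert abs(pl.partial_r) >= abs(r_simple) - 1e-12

    def test_unknown_predictor(self):
        rng = np.random.default_rng(17)
        recs = random_records(rng, noise=0.5)
        with pytest.raises(ValueError, match="unknown predictor"):
            partial_leverage(recs, "chlorophyll")


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(8.0)
        r, p, n = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert n == 8

    def test_type_one_error_calibration(self):
        """|r| >= 0.707 is the p < 0.05 threshold at n = 8 (two-tailed)."""
        rng = np.random.default_rng(18)
        hits = 0
        sims = 2000
        for _ in range(sims):
            x, y = rng.normal(size=8), rng.normal(size=8)
            r, _, _ = pearson(x, y)
            hits += abs(r) >= 0.707
        assert 0.03 <= hits / sims <= 0.07

    def test_input_validation(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [3, 4])
        with pytest.raises(ValueError, match="variance"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestGenerativeRoundTrip:
    def test_default_design_is_estimable(self):
        records, truth = generate_treatments(SynthDesign(), seed=21)
        res = fit_framework(records, n_boot=299, seed=2)
        assert res.n == 8
        assert 0.0 <= res.r2 <= 1.0
        assert all(v >= 1.0 for v in res.vif.values())
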