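"""CJS likelihood (vs enumeration oracle), history building, fitting, selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from spatid import (
    CaptureHistoryMatrix,
    CJSModelSpec,
    build_histories,
    cjs_loglik,
    fit_cjs,
    predict_survival,
    select_models,
    simulate_histories,
)
from spatid.cjs import _design, effective_sample_size, two_sd_standardize


def make_h(y, surveyed=None, svl=None, fgrm=None, site=None, sex=None):
    y = np.asarray(y)
    n, T = y.shape
    return CaptureHistoryMatrix(
        y=y,
        surveyed=np.ones((n, T), bool) if surveyed is None else np.asarray(surveyed),
        years=np.arange(2000, 2000 + T),
        individual_ids=np.array([f"i{k}" for k in range(n)], object),
        site=np.array(["A"] * n, object) if site is None else np.asarray(site, object),
        sex=np.array(["U"] * n, object) if sex is None else np.asarray(sex, object),
        svl_std=np.zeros((n, T)) if svl is None else np.asarray(svl, float),
        fgrm_std=np.zeros(n) if fgrm is None else np.asarray(fgrm, float),
        af2=np.zeros((n, T)),
        meta={"svl_mean": 0.0, "svl_sd": 1.0, "fgrm_mean": 0.0, "fgrm_sd": 1.0},
    )


def enumeration_loglik(h, phis, ps):
    """Oracle: sum over all latent death times, conditional on first capture."""
    total = 0.0
    T = h.n_occasions
    for i in range(h.n_individuals):
        f = int(h.first[i])
        y = h.y[i]
        prob = 0.0
        for d in range(f, T):  # d = last occasion alive
            pr = 1.0
            for t in range(f, d):
                pr *= phis[i, t]
            if d < T - 1:
                pr *= 1.0 - phis[i, d]
            ok = True
            for t in range(f + 1, T):
                if t <= d:
                    pr *= ps[i, t - 1] if y[t] else (1.0 - ps[i, t - 1])
                elif y[t]:
                    ok = False
            if ok:
                prob += pr
        total += np.log(prob)
    return total


class TestLikelihood:
    def test_two_occasion_closed_forms(self):
        phi, p = 0.6, 0.3
        beta = np.array([logit(phi), logit(p)])
        spec = CJSModelSpec((), ())
        assert np.exp(cjs_loglik(make_h([[1, 1]]), spec, beta)) == pytest.approx(
            phi * p
        )
        assert np.exp(cjs_loglik(make_h([[1, 0]]), spec, beta)) == pytest.approx(
            (1 - phi) + phi * (1 - p)
        )

    @pytest.mark.parametrize("T", [2, 3, 4, 5])
    def test_enumeration_oracle_all_histories(self, T, rng):
        """Every nonzero history, with individual covariates, matches the
        brute-force sum over latent alive/dead sequences to 1e-10."""
        histories = [
            [int(b) for b in np.binary_repr(m, T)] for m in range(1, 2**T)
        ]
        y = np.array(histories)
        n = len(y)
        svl = rng.normal(size=(n, T))
        fgrm = rng.normal(size=n)
        h = make_h(y, svl=svl, fgrm=fgrm)
        spec = CJSModelSpec(("svl", "fgrm"), ("svl",))
        beta = rng.normal(size=5) * 0.7
        ll = cjs_loglik(h, spec, beta)
        X_phi, _ = _design(h, spec.phi_terms, "phi")
        X_p, _ = _design(h, spec.p_terms, "p")
        phis = expit(X_phi @ beta[:3])
        ps = expit(X_p @ beta[3:])
        assert ll == pytest.approx(enumeration_loglik(h, phis, ps), abs=1e-10)

    def test_unsurveyed_equals_p_zero(self, rng):
        """Marking occasion t unsurveyed must equal forcing p=0 there."""
        y = np.array([[1, 0, 1, 0], [1, 0, 0, 0], [1, 0, 1, 1]])
        surveyed = np.ones((3, 4), bool)
        surveyed[:, 1] = False
        h = make_h(y, surveyed=surveyed)
        beta = rng.normal(size=2)
        ll = cjs_loglik(h, CJSModelSpec((), ()), beta)
        # oracle with p literally zeroed at occasion 1
        phis = np.full((3, 3), expit(beta[0]))
        ps = np.full((3, 3), expit(beta[1]))
        ps[:, 0] = 0.0
        assert ll == pytest.approx(enumeration_loglik(h, phis, ps), abs=1e-12)

    def test_wrong_beta_length_rejected(self):
        with pytest.raises(ValueError, match="beta length"):
            cjs_loglik(make_h([[1, 1]]), CJSModelSpec((), ()), np.zeros(5))


class TestBuildHistories:
    def _caps(self):
        return pd.DataFrame(
            [
                {"id": "a", "site": "A", "year": 2012, "svl_cm": 50.0, "x": 0, "y": 0},
                {"id": "a", "site": "A", "year": 2014, "svl_cm": 55.0, "x": 0, "y": 0},
                {"id": "b", "site": "A", "year": 2011, "svl_cm": 30.0, "x": 0, "y": 0},
            ]
        )

    def test_detection_pattern(self):
        h = build_histories(self._caps(), {"A": range(2011, 2016)})
        years = list(h.years)
        a = h.y[list(h.individual_ids).index("a")]
        assert a[years.index(2012)] == 1 and a[years.index(2014)] == 1
        assert a.sum() == 2

    def test_adult_prior_capture_flag_two_years_later(self):
        h = build_histories(self._caps(), {"A": range(2011, 2016)})
        years = list(h.years)
        ia = list(h.individual_ids).index("a")
        ib = list(h.individual_ids).index("b")
        assert h.af2[ia, years.index(2014)] == 1.0  # adult (50 cm) in 2012
        assert h.af2[ib, years.index(2013)] == 0.0  # 30 cm is not an adult

    def test_two_sd_standardization(self, rng):
        x = rng.normal(10, 3, size=500)
        z, mu, sd = two_sd_standardize(x)
        assert z.std() == pytest.approx(0.5)

    def test_unsurveyed_years_marked(self):
        h = build_histories(self._caps(), {"A": [2011, 2012, 2014, 2015]})
        assert not h.surveyed[:, list(h.years).index(2013)].any()


class TestFit:
    def test_constant_model_recovery(self):
        h = simulate_histories(800, 8, 0.7, 0.4, seed=5)
        fit = fit_cjs(h, CJSModelSpec((), ()), n_starts=1)
        est = expit(fit.coef.to_numpy())
        assert est[0] == pytest.approx(0.7, abs=0.06)
        assert est[1] == pytest.approx(0.4, abs=0.06)

    def test_perfect_detection_gives_return_fraction(self):
        # all survivors detected -> phi-hat = observed year-to-year returns
        rng = np.random.default_rng(3)
        n, T, phi = 400, 6, 0.65
        y = np.zeros((n, T), int)
        y[:, 0] = 1
        alive = np.ones(n, bool)
        for t in range(T - 1):
            alive &= rng.random(n) < phi
            y[alive, t + 1] = 1
        h = make_h(y)
        spec = CJSModelSpec((), ())
        fit = fit_cjs(h, spec, n_starts=1)
        released = y[:, :-1].sum()
        returned = sum(
            y[i, t + 1] for i in range(n) for t in range(T - 1) if y[i, t]
        )
        assert expit(fit.coef.iloc[0]) == pytest.approx(returned / released, abs=1e-3)

    def test_covariate_shift_changes_only_intercept(self):
        h = simulate_histories(300, 6, 0.7, 0.4, seed=7)
        rng = np.random.default_rng(1)
        h.fgrm_std = rng.normal(size=300)
        spec = CJSModelSpec(("fgrm",), ())
        fit1 = fit_cjs(h, spec, n_starts=1)
        h.fgrm_std = h.fgrm_std + 2.0
        fit2 = fit_cjs(h, spec, n_starts=1)
        assert fit1.lnl == pytest.approx(fit2.lnl, abs=1e-5)
        assert fit1.coef["phi:fgrm"] == pytest.approx(fit2.coef["phi:fgrm"], abs=1e-3)

    def test_effective_sample_size_conventions(self):
        h = make_h([[1, 1, 0], [1, 0, 0]])
        assert effective_sample_size(h, "releases") == 3
        assert effective_sample_size(h, "individuals") == 2


class TestSelection:
    def test_duplicate_model_identical_aicc_and_weights_sum(self):
        h = simulate_histories(200, 6, 0.7, 0.4, seed=9)
        spec = CJSModelSpec((), ())
        tab, fits = select_models([spec, CJSModelSpec((), ())], h, seed=0)
        assert tab["aicc"].iloc[0] == pytest.approx(tab["aicc"].iloc[1], abs=1e-6)
        assert tab["weight"].sum() == pytest.approx(1.0)

    def test_true_covariate_model_ranked_first(self):
        rng = np.random.default_rng(11)
        n = 500
        f = rng.normal(0, 0.5, n)
        phi = expit(1.0 - 2.0 * f)
        h = simulate_histories(n, 8, phi, 0.5, seed=12)
        h.fgrm_std = f
        tab, _ = select_models(
            [CJSModelSpec(("fgrm",), ()), CJSModelSpec((), ())], h, seed=0
        )
        assert "fgrm" in tab.iloc[0]["model"]


class TestPredict:
    def test_zero_coefficients_give_half(self):
        h = simulate_histories(100, 5, 0.7, 0.4, seed=13)
        spec = CJSModelSpec(("fgrm",), ())
        fit = fit_cjs(h, spec, n_starts=1)
        fit.coef[:] = 0.0
        out = predict_survival(fit, {"fgrm": 0.0})
        assert out["survival"] == 0.5

    def test_unknown_covariate_rejected(self):
        h = simulate_histories(100, 5, 0.7, 0.4, seed=13)
        fit = fit_cjs(h, CJSModelSpec(("fgrm",), ()), n_starts=1)
        with pytest.raises(KeyError):
            predict_survival(fit, {})

    def test_predicted_curve_tracks_logit_truth(self):
        rng = np.random.default_rng(17)
        n = 800
        f = rng.normal(0, 0.5, n)
        a, b = 1.2, -1.5
        h = simulate_histories(n, 10, expit(a + b * f), 0.5, seed=18)
        h.fgrm_std = f
        h.meta["fgrm_mean"], h.meta["fgrm_sd"] = 0.0, 0.5
        fit = fit_cjs(h, CJSModelSpec(("fgrm",), ()), n_starts=1)
        for raw in (-0.5, 0.0, 0.5):
            out = predict_survival(fit, {"fgrm": raw})
            truth = expit(a + b * raw)
            assert out["ci_low"] - 0.05 <= truth <= out["ci_high"] + 0.05
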