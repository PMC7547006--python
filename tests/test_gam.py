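"""Spline bases, penalized IRLS fitting, response curves, tensor smooths."""

import numpy as np
import pandas as pd
import pytest

from locustgam._bases import (
    cubic_design,
    cubic_knots,
    cubic_penalty,
    cyclic_design,
    cyclic_penalty,
    doy_phase,
)
from locustgam.gam import NegativeBinomialGAM, SmoothSpec, nb_deviance


def _nb_draw(rng, mu, theta):
    return rng.poisson(rng.gamma(theta, mu / theta))


class TestBases:
    def test_cyclic_basis_identical_at_wrap(self):
        B1 = cyclic_design(doy_phase(1.0), 6)
        B366 = cyclic_design(doy_phase(366.0), 6)
        assert np.max(np.abs(B1 - B366)) < 1e-10

    def test_cyclic_continuity_of_derivatives(self):
        eps = 1e-6
        for deriv in (0, 1, 2):
            lo = cyclic_design(np.array([eps]), 8, deriv=deriv)
            hi = cyclic_design(np.array([365.0 - eps]), 8, deriv=deriv)
            assert np.max(np.abs(lo - hi)) < 1e-3

    def test_straight_line_in_penalty_null_space(self):
        knots = cubic_knots(0.0, 1.0, 8)
        S = cubic_penalty(knots)
        # coefficients reproducing the line y = 2x + 1 on a fine grid
        x = np.linspace(0, 1, 200)
        B = cubic_design(x, knots)
        beta, *_ = np.linalg.lstsq(B, 2 * x + 1, rcond=None)
        assert beta @ S @ beta < 1e-16 * max(np.abs(beta).max(), 1.0)
        # and the line is reproduced exactly (cubic splines contain linears)
        assert np.max(np.abs(B @ beta - (2 * x + 1))) < 1e-8

    def test_penalty_equals_integrated_curvature(self):
        """beta' S beta matches the finite-difference integral of f''(x)^2
        within 5% (independent numerical oracle)."""
        rng = np.random.default_rng(0)
        knots = cubic_knots(0.0, 2.0, 9)
        S = cubic_penalty(knots)
        beta = rng.normal(size=S.shape[0])
        h = 1e-4
        x = np.arange(5 * h, 2.0 - 5 * h, 2e-4)
        f = lambda v: cubic_design(v, knots) @ beta
        d2 = (f(x + h) - 2 * f(x) + f(x - h)) / h**2
        integral = np.trapezoid(d2**2, x)
        quad_form = beta @ S @ beta
        assert abs(integral - quad_form) / quad_form < 0.05

    def test_cyclic_penalty_null_space_is_constants(self):
        S = cyclic_penalty(7)
        ones = np.ones(7)
        assert ones @ S @ ones < 1e-12
        eigs = np.linalg.eigvalsh(S)
        assert np.sum(eigs < 1e-8 * eigs.max()) == 1  # only the constant

    def test_k_exceeding_distinct_values_raises(self):
        x = np.repeat(np.arange(5.0), 4)
        with pytest.raises(ValueError, match="distinct"):
            NegativeBinomialGAM([SmoothSpec(("x",), "cubic_spline", 8)]).fit(
                pd.DataFrame({"x": x}), np.ones(20)
            )


class TestFitting:
    def test_null_signal_gives_flat_smooths(self):
        rng = np.random.default_rng(1)
        n = 2000
        df = pd.DataFrame({"x": rng.uniform(0, 1, n)})
        y = _nb_draw(rng, np.full(n, 1.44), theta=5.0)
        m = NegativeBinomialGAM([SmoothSpec(("x",), "cubic_spline", 10)],
                                theta=5.0).fit(df, y)
        assert m.edf_per_smooth_["s(x)"] < 1.5
        rc = m.response_curve("x")
        cover = np.mean(np.abs(rc.fit) <= 2 * rc.se + 1e-9)
        assert cover >= 0.95
        assert not rc.snr_mask.any()  # nothing passes SNR 2 on null signal

    def test_sine_recovery(self):
        rng = np.random.default_rng(2)
        n = 5000
        x = rng.uniform(0, 1, n)
        eta = 1.5 + 0.7 * np.sin(2 * np.pi * x)
        y = _nb_draw(rng, eta**2, theta=3.0)
        m = NegativeBinomialGAM([SmoothSpec(("x",), "cubic_spline", 10)]).fit(
            pd.DataFrame({"x": x}), y
        )
        rc = m.response_curve("x")
        truth = 0.7 * np.sin(2 * np.pi * rc.grid)
        truth -= truth.mean()
        assert np.corrcoef(rc.fit, truth)[0, 1] >= 0.95

    def test_infinite_lambda_collapses_to_line(self):
        rng = np.random.default_rng(3)
        n = 1000
        x = rng.uniform(0, 1, n)
        y = _nb_draw(rng, (1 + 0.5 * np.sin(2 * np.pi * x)) ** 2, theta=2.0)
        m = NegativeBinomialGAM(
            [SmoothSpec(("x",), "cubic_spline", 10)],
            select_lambda=False, lambda_init=1e9, theta=2.0,
        ).fit(pd.DataFrame({"x": x}), y)
        rc = m.response_curve("x")
        second_diff = np.diff(rc.fit, 2)
        assert np.max(np.abs(second_diff)) < 1e-4 * max(np.abs(rc.fit).max(), 1.0)

    def test_penalized_deviance_monotone_over_accepted_steps(self, fitted_gam):
        t = np.asarray(fitted_gam.deviance_trace_)
        # smoothing parameters / theta change between segments; within the
        # final segment the objective is non-increasing
        assert np.all(np.diff(t[-5:]) <= 1e-6 * (np.abs(t[-5:][1:]) + 0.1))

    def test_theta_large_matches_poisson_glm(self):
        """theta -> infinity limit equals an independent Poisson GLM with
        square-root link (statsmodels oracle) on an unpenalized design."""
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        n = 800
        x1, x2 = rng.uniform(0, 1, n), rng.uniform(0, 1, n)
        y = rng.poisson((1.0 + 0.4 * x1 - 0.3 * x2) ** 2)
        df = pd.DataFrame({"x1": x1, "x2": x2})
        m = NegativeBinomialGAM(
            [SmoothSpec(("x1",), "linear"), SmoothSpec(("x2",), "linear")],
            theta=1e6, select_lambda=False,
        ).fit(df, y)
        D = sm.add_constant(np.column_stack([x1 - x1.mean(), x2 - x2.mean()]))
        ref = sm.GLM(
            y, D, family=sm.families.Poisson(link=sm.families.links.Sqrt())
        ).fit()
        assert np.max(np.abs(m.coef_ - ref.params)) < 1e-4

    def test_deviance_at_most_null_deviance(self, fitted_gam):
        assert fitted_gam.deviance_ <= fitted_gam.null_deviance_
        assert 0.0 <= fitted_gam.deviance_explained_ <= 1.0

    def test_edf_within_bounds(self, fitted_gam):
        for term in fitted_gam.terms_:
            edf = fitted_gam.edf_per_smooth_[term.spec.name]
            kmax = np.prod(term.spec.k) - 1 if term.spec.basis == "tensor3" else (
                term.spec.k[0] - 1
            )
            assert -1e-6 <= edf <= kmax + 1e-6

    def test_covariance_is_psd(self, fitted_gam):
        eigs = np.linalg.eigvalsh(fitted_gam.cov_)
        assert eigs.min() > -1e-10 * eigs.max()

    def test_negative_response_rejected(self):
        with pytest.raises(ValueError):
            NegativeBinomialGAM([SmoothSpec(("x",), "linear")]).fit(
                pd.DataFrame({"x": [0.0, 1.0]}), np.array([1.0, -1.0])
            )

    def test_theta_estimate_recovers_truth(self):
        rng = np.random.default_rng(5)
        n = 4000
        x = rng.uniform(0, 1, n)
        y = _nb_draw(rng, np.full(n, 4.0), theta=2.0)
        m = NegativeBinomialGAM([SmoothSpec(("x",), "cubic_spline", 6)]).fit(
            pd.DataFrame({"x": x}), y
        )
        assert 1.5 < m.theta_ < 2.7


class TestPrediction:
    def test_training_rows_reproduce_fitted_values(self, fitted_gam, table):
        mu = fitted_gam.predict(table)
        assert np.allclose(mu, fitted_gam.fitted_values_, atol=1e-10)

    def test_duplicated_row_identical(self, fitted_gam, table):
        row = table.iloc[[10]]
        two = pd.concat([row, row], ignore_index=True)
        eta, mu, se = fitted_gam.predict_terms(two)
        assert mu[0] == mu[1] and se[0] == se[1]

    def test_se_matches_dense_recomputation(self, fitted_gam, table):
        sub = table.head(50)
        D, _ = fitted_gam._build_design(sub, training=False)
        _, _, se = fitted_gam.predict_terms(sub)
        dense = np.sqrt(np.diag(D @ fitted_gam.cov_ @ D.T))
        assert np.allclose(se, dense, atol=1e-8)
        assert np.all(np.isfinite(se)) and np.all(se >= 0)

    def test_out_of_range_covariates_clamped_and_counted(self, fitted_gam, table):
        row = table.iloc[[0]].copy()
        row["ndvi"] = table["ndvi"].max() + 1.0
        fitted_gam.predict(row)
        assert fitted_gam.last_clamp_count_ >= 1

    def test_save_load_round_trip(self, fitted_gam, table, tmp_path):
        path = tmp_path / "model.json"
        fitted_gam.save(path)
        back = NegativeBinomialGAM.load(path)
        a = fitted_gam.predict(table.head(100))
        b = back.predict(table.head(100))
        assert np.allclose(a, b, atol=1e-12)


class TestResponseCurves:
    def test_monotone_truth_recovered_on_masked_region(self):
        rng = np.random.default_rng(6)
        n = 4000
        x = rng.normal(size=n)
        eta = np.maximum(1.5 + 0.5 * x, 0.05)
        y = _nb_draw(rng, eta**2, theta=5.0)
        m = NegativeBinomialGAM([SmoothSpec(("x",), "cubic_spline", 10)]).fit(
            pd.DataFrame({"x": x}), y
        )
        rc = m.response_curve("x")
        d = np.diff(rc.fit)[rc.snr_mask[:-1]]
        assert (d < 0).mean() <= 0.02

    def test_smooth_centred_over_training_values(self, fitted_gam, table):
        term = fitted_gam.terms_[0]
        block, _ = term.design(table)
        sl = fitted_gam.term_slices_[term.spec.name]
        contrib = block @ fitted_gam.coef_[sl]
        assert abs(contrib.mean()) < 1e-6

    def test_tensor_covariate_rejected(self, fitted_gam):
        with pytest.raises(ValueError, match="tensor"):
            fitted_gam.response_curve("lon")


class TestTensor:
    def test_slice_continuous_across_wrap(self, fitted_gam):
        _, _, f1 = fitted_gam.tensor_slice(1)
        _, _, f366 = fitted_gam.tensor_slice(366)
        assert np.max(np.abs(f1 - f366)) < 1e-6

    def test_contribution_centred_over_training_rows(self, fitted_gam, table):
        for term in fitted_gam.terms_:
            if term.spec.basis == "tensor3":
                break
        block, _ = term.design(table)
        sl = fitted_gam.term_slices_[term.spec.name]
        assert abs((block @ fitted_gam.coef_[sl]).mean()) < 1e-6

    def test_slice_consistent_with_predict(self, fitted_gam, table):
        """Holding all other covariates at a reference row and varying only
        position, predict() differences equal tensor-slice differences."""
        lons, lats, fld = fitted_gam.tensor_slice(60, n_lon=5, n_lat=4)
        ref = table.iloc[0]
        rows = []
        for la in lats:
            for lo in lons:
                r = ref.copy()
                r["lon"], r["lat"], r["doy"] = lo, la, 60.0
                rows.append(r)
        df = pd.DataFrame(rows).reset_index(drop=True)
        eta, _, _ = fitted_gam.predict_terms(df)
        eta = eta.reshape(4, 5)
        assert np.allclose(eta - eta[0, 0], fld - fld[0, 0], atol=1e-8)

    def test_doy_out_of_range_rejected(self, fitted_gam):
        with pytest.raises(ValueError):
            fitted_gam.tensor_slice(400)

    def test_gam_beats_linear_model_on_nonlinear_truth(self):
        rng = np.random.default_rng(7)
        n = 3000
        x = rng.uniform(0, 1, n)
        eta = 1.2 + 0.8 * np.sin(2 * np.pi * x)
        y = _nb_draw(rng, eta**2, theta=3.0)
        df = pd.DataFrame({"x": x})
        gam = NegativeBinomialGAM([SmoothSpec(("x",), "cubic_spline", 10)]).fit(df, y)
        glm = NegativeBinomialGAM([SmoothSpec(("x",), "linear")]).fit(df, y)
        assert gam.deviance_explained_ > glm.deviance_explained_
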