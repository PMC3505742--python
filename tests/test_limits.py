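"""Detection limits: pmfs, closed-form IDLs, dilution fits, MDL, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from purelim import (
    CountMatrix,
    DilutionDesign,
    ExpressionMatrix,
    SimConfig,
    fit_gaussian_dilution,
    fit_nb_dilution,
    gaussian_idl,
    mdl_curve,
    model_diagnostics,
    nb_idl,
    nb_logpmf,
    nb_pmf,
    required_purity,
    simulate_exon_dilution,
    simulate_tag_dilution,
)


def idl_by_bisection(theta, model, confidence=0.95, rtol=1e-12):
    """Independent oracle: smallest mu with P(Y=0 | mu, theta) <= 1-conf,
    found by bisection on log(mu) over the implemented pmf."""
    alpha = 1.0 - confidence

    def p0(mu):
        return nb_pmf(0, mu, theta, model)

    lo, hi = 1e-12, 1e12
    while p0(hi) > alpha:
        hi *= 10
    llo, lhi = np.log(lo), np.log(hi)
    for _ in range(200):
        mid = 0.5 * (llo + lhi)
        if p0(np.exp(mid)) > alpha:
            llo = mid
        else:
            lhi = mid
        if lhi - llo < rtol:
            break
    return np.exp(lhi)


class TestPmf:
    @pytest.mark.parametrize("model", ["NB1", "NB2"])
    @pytest.mark.parametrize("theta", [0.1, 1.0, 5.0])
    @pytest.mark.parametrize("mu", [0.5, 3.0, 40.0])
    def test_zero_count_closed_form(self, model, theta, mu):
        direct = (
            (1 + theta) ** (-mu / theta)
            if model == "NB1"
            else (1 + mu * theta) ** (-1 / theta)
        )
        assert nb_pmf(0, mu, theta, model) == pytest.approx(direct, abs=1e-12)

    @pytest.mark.parametrize("model", ["NB1", "NB2"])
    @pytest.mark.parametrize("theta,mu", [(0.0, 3.0), (0.5, 2.0), (2.0, 10.0), (5.0, 1.0)])
    def test_normalises_to_one(self, model, theta, mu):
        K = 20000
        total = nb_pmf(np.arange(K), mu, theta, model).sum()
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_matches_sampler_moments(self):
        from purelim import sample_nb

        rng = np.random.default_rng(0)
        for model, var in (("NB1", 10 + 2 * 10), ("NB2", 10 + 2 * 100)):
            draws = sample_nb(rng, 10.0, 2.0, model, size=(100_000,))
            k = np.arange(3000)
            pmf = nb_pmf(k, 10.0, 2.0, model)
            mean_th = (k * pmf).sum()
            var_th = ((k - mean_th) ** 2 * pmf).sum()
            assert mean_th == pytest.approx(10.0, rel=1e-6)
            assert var_th == pytest.approx(var, rel=1e-5)
            assert abs(draws.mean() - mean_th) < 4 * np.sqrt(var / 1e5)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            nb_logpmf(-1, 5.0, 1.0, "NB1")
        with pytest.raises(ValueError):
            nb_logpmf(1, 5.0, -1.0, "NB1")
        with pytest.raises(ValueError):
            nb_logpmf(1, 5.0, 1.0, "NB3")


class TestGaussianIdl:
    def test_printed_residual_sd_gives_printed_idl(self):
        assert round(gaussian_idl(224.0, 1.64)) == 367

    def test_zero_sigma(self):
        assert gaussian_idl(0.0) == 0.0

    def test_linear_in_sigma(self):
        assert gaussian_idl(100.0) == pytest.approx(164.0)
        for c in (0.5, 2.0, 10.0):
            assert gaussian_idl(c * 37.0) == pytest.approx(c * gaussian_idl(37.0))

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_idl(-1.0)


class TestNBIdl:
    def test_nb1_theta_one(self):
        assert nb_idl(1.0, "NB1") == pytest.approx(np.log(20) / np.log(2))

    def test_nb2_theta_one(self):
        assert nb_idl(1.0, "NB2") == pytest.approx(19.0)

    def test_poisson_limit(self):
        ln20 = np.log(20)
        assert nb_idl(0.0, "NB1") == pytest.approx(ln20)
        assert nb_idl(0.0, "NB2") == pytest.approx(ln20)
        assert nb_idl(1e-10, "NB1") == pytest.approx(ln20, rel=1e-6)
        assert nb_idl(1e-10, "NB2") == pytest.approx(ln20, rel=1e-6)

    @pytest.mark.parametrize("model", ["NB1", "NB2"])
    def test_strictly_increasing_in_theta(self, model):
        thetas = np.linspace(1e-3, 50, 400)
        vals = [nb_idl(t, model) for t in thetas]
        assert (np.diff(vals) > 0).all()

    @pytest.mark.parametrize("model", ["NB1", "NB2"])
    @pytest.mark.parametrize("theta", [0.01, 0.5, 2.0, 17.5])
    def test_matches_bisection_oracle(self, model, theta):
        closed = nb_idl(theta, model)
        root = idl_by_bisection(theta, model)
        assert abs(closed - root) / closed < 1e-8

    def test_confidence_out_of_range(self):
        with pytest.raises(ValueError):
            nb_idl(1.0, "NB1", confidence=1.0)


class TestGaussianFit:
    def test_noiseless_fit_is_exact(self):
        design = DilutionDesign((0.0, 0.5, 1.0))
        df = pd.DataFrame(
            [[10.0, 60.0, 110.0], [10.0, 35.0, 60.0]],
            index=["a", "b"],
            columns=list(design.sample_ids),
        )
        fit = fit_gaussian_dilution(ExpressionMatrix(df, design))
        assert fit.background == pytest.approx(10.0, abs=1e-9)
        assert fit.abundances["a"] == pytest.approx(100.0, abs=1e-9)
        assert fit.abundances["b"] == pytest.approx(50.0, abs=1e-9)
        assert fit.sigma_hat == pytest.approx(0.0, abs=1e-9)
        assert fit.idl == pytest.approx(0.0, abs=1e-9)

    def test_degrees_of_freedom_invariant(self):
        cfg = SimConfig(n_genes=7, seed=1)
        mat, _ = simulate_exon_dilution(cfg)
        fit = fit_gaussian_dilution(mat)
        assert fit.df == 7 * 8 - 7 - 1

    def test_recovers_sigma_on_reference_design(self):
        sigs = [
            fit_gaussian_dilution(
                simulate_exon_dilution(SimConfig(n_genes=79, seed=300 + s))[0]
            ).sigma_hat
            for s in range(5)
        ]
        assert abs(np.mean(sigs) / 224.0 - 1.0) < 0.15

    def test_idl_always_z_times_sigma(self):
        mat, _ = simulate_exon_dilution(SimConfig(n_genes=5, seed=2))
        fit = fit_gaussian_dilution(mat)
        assert fit.idl == fit.z_factor * fit.sigma_hat


class TestNBFit:
    def test_recovers_theta_single_seed(self):
        mat, _ = simulate_tag_dilution(
            SimConfig(n_genes=60, theta=2.0, seed=100), "NB1"
        )
        fit = fit_nb_dilution(mat, model="NB1")
        assert 1.2 <= fit.theta_hat <= 3.0

    def test_true_model_has_lower_deviance(self):
        wins = 0
        for s in range(5):
            mat, _ = simulate_tag_dilution(
                SimConfig(n_genes=60, theta=2.0, seed=500 + s), "NB1"
            )
            f1 = fit_nb_dilution(mat, model="NB1")
            f2 = fit_nb_dilution(mat, model="NB2")
            wins += f1.deviance < f2.deviance
        assert wins >= 4

    def test_all_zero_rows_dropped_with_warning(self):
        design = DilutionDesign((0.0, 0.5, 1.0))
        df = pd.DataFrame(
            [[0, 10, 30], [0, 0, 0]],
            index=["a", "b"],
            columns=list(design.sample_ids),
        )
        with pytest.warns(UserWarning, match="all-zero"):
            fit = fit_nb_dilution(CountMatrix(df, design), model="NB2")
        assert list(fit.log_abundances.index) == ["a"]

    def test_background_leak_genes_dropped_by_default(self):
        design = DilutionDesign((0.0, 1.0, 1.0))
        df = pd.DataFrame(
            [[3, 10, 30], [0, 20, 25]],
            index=["leaky", "clean"],
            columns=list(design.sample_ids),
        )
        with pytest.warns(UserWarning, match="purity 0"):
            fit = fit_nb_dilution(CountMatrix(df, design), model="NB2")
        assert list(fit.log_abundances.index) == ["clean"]

    def test_quantile_residuals_standard_normal_under_truth(self):
        # large correctly-specified simulation: randomised quantile
        # residuals should look N(0,1)
        mat, truth = simulate_tag_dilution(
            SimConfig(n_genes=700, theta=1.0, seed=6), "NB2"
        )
        fit = fit_nb_dilution(mat, model="NB2")
        q = fit.quantile_residuals(seed=1).to_numpy().ravel()
        assert abs(q.mean()) < 0.05
        assert abs(q.std() - 1.0) < 0.1


class TestMdl:
    def test_idl_at_full_purity(self):
        curve = mdl_curve(367.0, [1.0])
        assert curve.mdl[0] == 367.0

    def test_half_purity_doubles(self):
        assert mdl_curve(367.0, [0.5]).mdl[0] == pytest.approx(734.0)

    @given(
        st.floats(min_value=0.0, max_value=1e6),
        st.lists(
            st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=20
        ),
    )
    def test_identity_mdl_times_p(self, idl, purities):
        curve = mdl_curve(idl, purities)
        for p, m in zip(curve.purities, curve.mdl):
            assert m * p == pytest.approx(idl, rel=1e-12, abs=1e-12)

    def test_zero_purity_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            mdl_curve(10.0, [0.0, 0.5])


class TestRequiredPurity:
    def test_abundance_equal_idl_needs_full_purity(self):
        assert required_purity(367.0, 367.0) == 1.0

    def test_tenfold_abundance_needs_ten_percent(self):
        assert required_purity(3670.0, 367.0) == pytest.approx(0.1)

    def test_non_elevated_genes_are_na(self):
        out = required_purity([-5.0, 0.0, 734.0], 367.0)
        assert np.isnan(out[0]) and np.isnan(out[1])
        assert out[2] == pytest.approx(0.5)

    def test_clamped_at_one(self):
        assert required_purity(100.0, 367.0) == 1.0


class TestDiagnostics:
    def test_gaussian_residuals_look_normal_when_model_true(self):
        ok = 0
        for s in range(10):
            mat, _ = simulate_exon_dilution(SimConfig(n_genes=40, seed=700 + s))
            diag = model_diagnostics(fit_gaussian_dilution(mat), seed=s)
            ok += diag["shapiro_p"] > 0.01
        assert ok >= 9

    def test_degenerate_constant_fit_flagged(self):
        design = DilutionDesign((0.0, 0.5, 1.0))
        df = pd.DataFrame(
            [[10.0, 60.0, 110.0]], index=["a"], columns=list(design.sample_ids)
        )
        diag = model_diagnostics(fit_gaussian_dilution(ExpressionMatrix(df, design)))
        assert diag["degenerate"]

    def test_nb_diagnostics_report_deviance(self):
        mat, _ = simulate_tag_dilution(SimConfig(n_genes=30, theta=1.0, seed=8), "NB1")
        fit = fit_nb_dilution(mat, model="NB1")
        diag = model_diagnostics(fit, seed=0)
        assert diag["deviance"] == pytest.approx(fit.deviance)
        assert {"fitted", "quantile_residual"} <= set(diag["residual_table"].columns)

    def test_outliers_reported_not_removed(self):
        mat, _ = simulate_exon_dilution(SimConfig(n_genes=50, seed=9))
        # plant one gross outlier
        vals = mat.values.copy()
        vals.iloc[0, 3] += 4000.0
        fit = fit_gaussian_dilution(ExpressionMatrix(vals, mat.design))
        assert len(fit.outliers) >= 1
        assert fit.std_residuals.shape == vals.shape  # nothing dropped
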