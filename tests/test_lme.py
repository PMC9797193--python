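"""Mixed-effect fitting, likelihood-ratio testing, single-step post hoc."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spinemorph.errors import InsufficientDataError, InvalidInputError
from spinemorph.lme import (
    BUILTIN_MODELS,
    LMEFit,
    ModelSpec,
    distribution_shape,
    fit_lme,
    lrt_condition,
    lrt_from_fits,
    posthoc_pairwise,
    residual_diagnostics,
    single_step_adjust,
)

from _oracles import mc_max_abs_z_adjusted, ml_lme_oracle


def simulate_dendrite_data(seed, effects=(0.0, 0.0), mouse_sd=0.05, resid_sd=0.14,
                           n_mice=(4, 4, 6), n_dendrites=7, intercept=1.35):
    """sqrt-scale LME world for a dendrite-level density response."""
    rng = np.random.default_rng(seed)
    rows = []
    for cond, n, eff in zip(("EW", "W", "S"), n_mice, (0.0, *effects)):
        for m in range(n):
            u = rng.normal(0, mouse_sd)
            for d in range(n_dendrites):
                y_sqrt = intercept + eff + u + rng.normal(0, resid_sd)
                rows.append(
                    {"mouse_id": f"{cond}{m}", "condition": cond,
                     "synapse_density_per_um2": max(y_sqrt, 0.05) ** 2}
                )
    return pd.DataFrame(rows)


SPEC = BUILTIN_MODELS["spine_density_with_synapse"]


class TestFitting:
    def test_zero_between_mouse_variance_collapses_to_group_means(self):
        # balanced, every mouse identical: fixed effects = sqrt group means
        rows = []
        vals = {"EW": 1.96, "W": 1.44, "S": 1.69}
        for cond, v in vals.items():
            for m in range(3):
                for d in range(4):
                    rows.append(
                        {"mouse_id": f"{cond}{m}", "condition": cond,
                         "synapse_density_per_um2": v + 0.01 * (d - 1.5)}
                    )
        fit = fit_lme(SPEC, pd.DataFrame(rows))
        means = {c: np.sqrt(np.array([v + 0.01 * (d - 1.5) for d in range(4)])).mean()
                 for c, v in vals.items()}
        assert fit.random_sd["mouse"] == pytest.approx(0.0, abs=1e-4)
        assert fit.params["Intercept"] == pytest.approx(means["EW"], abs=1e-6)
        assert fit.params["condition[W]"] == pytest.approx(means["W"] - means["EW"], abs=1e-6)
        assert fit.params["condition[S]"] == pytest.approx(means["S"] - means["EW"], abs=1e-6)

    def test_matches_direct_likelihood_oracle(self):
        data = simulate_dendrite_data(seed=5, effects=(-0.08, -0.12))
        fit = fit_lme(SPEC, data)
        y = np.sqrt(data["synapse_density_per_um2"].to_numpy())
        X = np.column_stack(
            [np.ones(len(data)), (data.condition == "W"), (data.condition == "S")]
        ).astype(float)
        Z = pd.get_dummies(data["mouse_id"]).to_numpy(dtype=float)
        llf, beta, _ = ml_lme_oracle(y, X, [Z])
        assert fit.llf == pytest.approx(llf, abs=1e-4)
        assert np.allclose(fit.params.to_numpy()[:3], beta, atol=1e-4)

    def test_sqrt_of_negative_response_rejected(self):
        data = simulate_dendrite_data(seed=1)
        data.loc[0, "synapse_density_per_um2"] = -1.0
        with pytest.raises(InvalidInputError):
            fit_lme(SPEC, data)

    def test_single_group_rejected(self):
        data = simulate_dendrite_data(seed=1)
        with pytest.raises(InvalidInputError):
            fit_lme(SPEC, data[data.mouse_id == "EW0"])

    def test_nested_dendrite_intercepts_recovered(self, spine_table):
        fit = fit_lme(BUILTIN_MODELS["asi"], spine_table)
        assert fit.converged
        assert set(fit.random_sd) == {"mouse", "dendrite"}
        assert fit.residual_sd > 0
        # sqrt-scale intercept should sit near sqrt of the configured W/EW/S means
        assert 0.30 < fit.params["Intercept"] < 0.50


class TestLRT:
    def test_condition_effect_detected_and_null_not(self):
        alt = simulate_dendrite_data(seed=2, effects=(-0.02, -0.25))
        null = simulate_dendrite_data(seed=2, effects=(0.0, 0.0))
        assert lrt_condition(SPEC, alt).p < 0.01
        assert lrt_condition(SPEC, null).p > 0.05

    def test_identical_logliks_give_chi2_zero_p_one(self):
        data = simulate_dendrite_data(seed=3)
        fit = fit_lme(SPEC, data)
        res = lrt_from_fits(fit, fit)
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_reml_fits_refused(self):
        data = simulate_dendrite_data(seed=3)
        full = fit_lme(SPEC, data, reml=True)
        reduced = fit_lme(SPEC.drop_condition(), data, reml=True)
        with pytest.raises(InvalidInputError):
            lrt_from_fits(full, reduced)

    def test_loglik_ordering_full_vs_reduced(self):
        for seed in range(4):
            data = simulate_dendrite_data(seed=seed)
            full = fit_lme(SPEC, data)
            reduced = fit_lme(SPEC.drop_condition(), data)
            assert full.llf >= reduced.llf - 1e-8


class TestPosthoc:
    def test_single_contrast_collapses_to_raw(self):
        p = single_step_adjust(np.array([1.7]), np.eye(1))
        assert p[0] == pytest.approx(2 * stats.norm.sf(1.7))

    def test_adjusted_geq_raw_and_order_invariant(self):
        data = simulate_dendrite_data(seed=4, effects=(-0.1, -0.2))
        fit = fit_lme(SPEC, data)
        ph = posthoc_pairwise(fit).table
        assert (ph["p_adjusted"] >= ph["p_raw"] - 1e-12).all()
        assert ph["p_adjusted"].between(0, 1).all()
        # invariance to contrast ordering: adjust a permuted z vector
        z = ph["z"].to_numpy()
        perm = [2, 0, 1]
        cov = fit.cov_fixed.to_numpy()
        Lm = np.zeros((3, len(fit.params)))
        iW = list(fit.params.index).index("condition[W]")
        iS = list(fit.params.index).index("condition[S]")
        Lm[0, iS], Lm[0, iW] = 1, -1
        Lm[1, iS] = 1
        Lm[2, iW] = 1
        C = Lm @ cov @ Lm.T
        R = C / np.sqrt(np.outer(np.diag(C), np.diag(C)))
        p1 = single_step_adjust(z, R)
        p2 = single_step_adjust(z[perm], R[np.ix_(perm, perm)])
        # identical up to quasi-MC integration error
        assert np.allclose(p1[perm], p2, atol=1e-5)

    def test_matches_monte_carlo_oracle(self):
        data = simulate_dendrite_data(seed=6, effects=(-0.05, -0.15))
        fit = fit_lme(SPEC, data)
        ph = posthoc_pairwise(fit).table
        Lm = np.zeros((3, len(fit.params)))
        iW = list(fit.params.index).index("condition[W]")
        iS = list(fit.params.index).index("condition[S]")
        Lm[0, iS], Lm[0, iW] = 1, -1
        Lm[1, iS] = 1
        Lm[2, iW] = 1
        C = Lm @ fit.cov_fixed.to_numpy() @ Lm.T
        R = C / np.sqrt(np.outer(np.diag(C), np.diag(C)))
        mc = mc_max_abs_z_adjusted(ph["z"].to_numpy(), R, n_draws=1_000_000, seed=9)
        assert np.allclose(ph["p_adjusted"].to_numpy(), mc, atol=0.005)

    def test_requires_condition(self):
        data = simulate_dendrite_data(seed=3)
        fit = fit_lme(SPEC.drop_condition(), data)
        with pytest.raises(InvalidInputError):
            posthoc_pairwise(fit)


class TestDiagnostics:
    def test_gaussian_residuals_pass(self):
        data = simulate_dendrite_data(seed=7)
        report = residual_diagnostics(fit_lme(SPEC, data))
        assert report["qq_corr"] > 0.99
        assert not report["flagged"]

    def test_heavy_tailed_residuals_flagged(self):
        rng = np.random.default_rng(1)
        rows = []
        for cond, n in (("EW", 4), ("W", 4), ("S", 6)):
            for m in range(n):
                for d in range(15):
                    y = 1.35 + 0.1 * stats.t.rvs(2, random_state=rng)
                    rows.append(
                        {"mouse_id": f"{cond}{m}", "condition": cond,
                         "synapse_density_per_um2": max(y, 0.05) ** 2}
                    )
        report = residual_diagnostics(fit_lme(SPEC, pd.DataFrame(rows)))
        assert report["qq_corr"] < 0.95 and report["flagged"]

    def test_constant_response_degenerate_warning(self):
        rows = [
            {"mouse_id": f"m{m}", "condition": c, "synapse_density_per_um2": 1.69}
            for c in ("EW", "W", "S")
            for m in range(6)
        ]
        fit = fit_lme(SPEC, pd.DataFrame(rows))
        with pytest.warns(UserWarning, match="degenerate"):
            report = residual_diagnostics(fit)
        assert report["degenerate"]

    def test_plot_file_written(self, tmp_path):
        data = simulate_dendrite_data(seed=8)
        path = tmp_path / "diag.png"
        residual_diagnostics(fit_lme(SPEC, data), plot_path=str(path))
        assert path.exists() and path.stat().st_size > 0


class TestDistributionShape:
    def test_gaussian_sqrt_scale_is_unimodal(self, rng):
        x = rng.normal(0.45, 0.06, size=1000) ** 2
        assert distribution_shape(x)["call"] == "unimodal"

    def test_well_separated_mixture_is_bimodal(self, rng):
        s = np.concatenate([rng.normal(0.3, 0.05, 800), rng.normal(0.7, 0.05, 800)])
        assert distribution_shape(s**2)["call"] == "bimodal"

    def test_cerebellar_gamma_sample_unimodal_not_lognormal(self, rng):
        mean, sd = 0.187, 0.109
        x = rng.gamma((mean / sd) ** 2, sd**2 / mean, size=3000)
        report = distribution_shape(x)
        assert report["call"] == "unimodal"
        assert not report["lognormal_like"]

    def test_lognormal_sample_detected(self, rng):
        x = rng.lognormal(-1.8, 0.6, size=3000)
        assert distribution_shape(x)["lognormal_like"]

    def test_insufficient_data_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            distribution_shape(rng.gamma(2.0, 0.1, size=50))
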