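"""Linear mixed-effect inference for the three-condition cohort.

The model is the Gaussian LME ``y = X beta + Z u + e`` with ``u ~ N(0, Sigma)``
and ``e ~ N(0, sigma^2 I)``.  Two structures are used: dendrite-level
responses (densities, proportions) get a mouse random intercept; synapse-level
responses (ASI) get mouse and dendrite-within-mouse random intercepts plus
dendrite diameter as a covariate.  Condition enters as a fixed effect with EW
(extended wake) as the reference level.  Fits are by maximum likelihood (not
REML) so that nested models can be compared with an asymptotic likelihood
ratio test; pairwise condition contrasts are adjusted with the single-step
max-|z| method under the joint multivariate-normal distribution of the
contrast statistics.

Fitting is delegated to :class:`statsmodels.regression.mixed_linear_model.MixedLM`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from .errors import InsufficientDataError, InvalidInputError

logger = logging.getLogger(__name__)

CONDITION_LEVELS = ("EW", "W", "S")  # EW is the reference
CONTRAST_NAMES = ("S-W", "S-EW", "W-EW")

#: fixed seed for the quasi-Monte-Carlo integration of the max-|z| reference
SINGLE_STEP_SEED = 20221228


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one LME analysis."""

    name: str
    response: str
    transform: Literal["identity", "sqrt"] = "identity"
    level: Literal["dendrite", "spine"] = "dendrite"
    include_condition: bool = True
    include_diameter: bool = False
    include_branched: bool = False
    random_intercepts: tuple[str, ...] = ("mouse_id",)

    def drop_condition(self) -> "ModelSpec":
        return replace(self, name=self.name + "_reduced", include_condition=False)


#: every analysis of the published tables, by name
BUILTIN_MODELS: dict[str, ModelSpec] = {
    "dendrite_diameter": ModelSpec("dendrite_diameter", "diameter_um"),
    "dendrite_length": ModelSpec("dendrite_length", "length_um"),
    "spine_density_all": ModelSpec("spine_density_all", "spine_density_per_um2", "sqrt"),
    "spine_density_with_synapse": ModelSpec(
        "spine_density_with_synapse", "synapse_density_per_um2", "sqrt"
    ),
    "branched_density": ModelSpec("branched_density", "branched_synapse_density_per_um2", "sqrt"),
    "naked_density": ModelSpec("naked_density", "naked_density_per_um2", "sqrt"),
    "prop_without_synapse": ModelSpec("prop_without_synapse", "prop_without_synapse", "sqrt"),
    "prop_spinula": ModelSpec("prop_spinula", "prop_spinula", "sqrt"),
    "asi": ModelSpec(
        "asi",
        "asi_um2",
        "sqrt",
        level="spine",
        include_diameter=True,
        random_intercepts=("mouse_id", "dendrite_id"),
    ),
    "asi_with_branched": ModelSpec(
        "asi_with_branched",
        "asi_um2",
        "sqrt",
        level="spine",
        include_diameter=True,
        include_branched=True,
        random_intercepts=("mouse_id", "dendrite_id"),
    ),
    "asi_density": ModelSpec("asi_density", "cumulative_asi_density"),
}


@dataclass
class LMEFit:
    """Result of one maximum-likelihood LME fit."""

    spec: ModelSpec
    params: pd.Series  # fixed effects
    bse: pd.Series
    cov_fixed: pd.DataFrame
    random_sd: dict[str, float]
    residual_sd: float
    llf: float
    n_obs: int
    n_groups: int
    converged: bool
    reml: bool = False
    result: object = field(default=None, repr=False)  # statsmodels wrapper

    @property
    def condition_effects(self) -> dict[str, float]:
        return {lvl: float(self.params.get(f"condition[{lvl}]", 0.0)) for lvl in ("W", "S")}


@dataclass
class LRTResult:
    """Asymptotic likelihood-ratio test of the condition effect."""

    chi2: float
    df: int
    p: float
    llf_full: float
    llf_reduced: float


def _prepare(spec: ModelSpec, data: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Transformed response and design columns, with NaN responses dropped."""
    cols = [spec.response, "mouse_id"]
    if spec.include_condition or True:
        cols.append("condition")
    if spec.include_diameter:
        cols.append("diameter_um")
    if spec.include_branched:
        cols.append("branched")
    if "dendrite_id" in spec.random_intercepts:
        cols.append("dendrite_id")
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise InvalidInputError(f"model {spec.name}: missing column(s) {missing}")
    d = data[list(dict.fromkeys(cols))].copy()
    n_nan = int(d[spec.response].isna().sum())
    if n_nan:
        logger.info("model %s: dropping %d NaN response value(s)", spec.name, n_nan)
        d = d[d[spec.response].notna()]
    y = d[spec.response].astype(float)
    if spec.transform == "sqrt":
        if (y < 0).any():
            raise InvalidInputError(f"model {spec.name}: negative response under sqrt transform")
        y = np.sqrt(y)
    d["_y"] = y
    fixed = ["Intercept"]
    if spec.include_condition:
        d["condition"] = pd.Categorical(d["condition"], categories=CONDITION_LEVELS)
        if d["condition"].isna().any():
            raise InvalidInputError(f"model {spec.name}: unknown condition label")
        for lvl in ("W", "S"):
            d[f"condition[{lvl}]"] = (d["condition"] == lvl).astype(float)
            fixed.append(f"condition[{lvl}]")
    if spec.include_diameter:
        # centred for conditioning; the intercept is reported at the mean diameter
        d["diameter_c"] = d["diameter_um"].astype(float) - d["diameter_um"].astype(float).mean()
        fixed.append("diameter_c")
    if spec.include_branched:
        d["branched[Yes]"] = d["branched"].astype(float)
        fixed.append("branched[Yes]")
    d["Intercept"] = 1.0
    return d, fixed


def fit_lme(spec: ModelSpec, data: pd.DataFrame, reml: bool = False) -> LMEFit:
    """Fit one LME by numerical maximum likelihood.

    Deterministic given the data (L-BFGS with fixed starting values).  A fit
    that fails to converge is returned with ``converged=False`` and a warning
    rather than raising, so that partial output can be inspected.
    """
    d, fixed = _prepare(spec, data)
    for g in spec.random_intercepts:
        if d[g].nunique() < 2:
            raise InvalidInputError(f"model {spec.name}: fewer than 2 levels of {g}")
    exog = d[fixed].to_numpy()
    groups = d["mouse_id"].to_numpy()
    vc_formula = None
    if "dendrite_id" in spec.random_intercepts:
        # dendrite intercepts nested within mouse
        vc_formula = {"dendrite": "0 + C(dendrite_id)"}
        model = MixedLM.from_formula(
            "_y ~ " + " + ".join(f"Q('{c}')" for c in fixed if c != "Intercept"),
            data=d,
            groups="mouse_id",
            re_formula="1",
            vc_formula=vc_formula,
        )
    else:
        model = MixedLM(d["_y"].to_numpy(), exog, groups=groups)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        # powell on the profiled deviance is the most reliable of the available
        # optimizers here (gradient methods stall at the variance boundary)
        res = model.fit(reml=reml, method=["powell", "lbfgs"], maxiter=2000, disp=False)
    converged = bool(getattr(res, "converged", True))
    if not converged:
        warnings.warn(f"model {spec.name}: LME fit did not converge; partial output", stacklevel=2)
    params = pd.Series(np.asarray(res.fe_params), index=fixed, dtype=float)
    bse = pd.Series(np.asarray(res.bse_fe), index=fixed, dtype=float)
    cov = pd.DataFrame(
        np.asarray(res.cov_params())[: len(fixed), : len(fixed)], index=fixed, columns=fixed
    )
    random_sd = {"mouse": float(np.sqrt(max(np.asarray(res.cov_re)[0, 0], 0.0)))}
    if vc_formula is not None and len(res.vcomp):
        random_sd["dendrite"] = float(np.sqrt(max(res.vcomp[0], 0.0)))
    return LMEFit(
        spec=spec,
        params=params,
        bse=bse,
        cov_fixed=cov,
        random_sd=random_sd,
        residual_sd=float(np.sqrt(res.scale)),
        llf=float(res.llf),
        n_obs=int(len(d)),
        n_groups=int(d["mouse_id"].nunique()),
        converged=converged,
        reml=reml,
        result=res,
    )


def lrt_condition(spec: ModelSpec, data: pd.DataFrame) -> LRTResult:
    """Likelihood-ratio test of the condition fixed effect (df = 2).

    Both the full model and the reduced model (condition removed) are fitted
    by maximum likelihood; REML fits are refused because REML likelihoods of
    models with different fixed effects are not comparable.
    """
    full = fit_lme(spec, data, reml=False)
    reduced = fit_lme(spec.drop_condition(), data, reml=False)
    return lrt_from_fits(full, reduced)


def lrt_from_fits(full: LMEFit, reduced: LMEFit) -> LRTResult:
    if full.reml or reduced.reml:
        raise InvalidInputError("LRT requires ML fits (REML fits passed in)")
    chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
    df = 2
    return LRTResult(
        chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)), llf_full=full.llf,
        llf_reduced=reduced.llf,
    )


@dataclass
class PosthocResult:
    """Pairwise condition contrasts with single-step adjusted p-values."""

    table: pd.DataFrame  # contrast, estimate, se, z, p_raw, p_adjusted
    method: str = "single-step (max-|z|, MVN)"


def single_step_adjust(z: np.ndarray, corr: np.ndarray, seed: int = SINGLE_STEP_SEED) -> np.ndarray:
    """Adjusted p-values ``1 - P(max_j |Z_j| <= |z_i|)`` for ``Z ~ N(0, corr)``.

    Quasi-Monte-Carlo integration with a fixed seed keeps the result
    deterministic.  Falls back to Bonferroni when the correlation matrix is
    degenerate.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    k = len(z)
    if k == 1:
        return 2.0 * stats.norm.sf(np.abs(z))
    raw = 2.0 * stats.norm.sf(np.abs(z))
    try:
        # contrast sets are often rank-deficient (S-W = S-EW - W-EW), hence
        # allow_singular; fixed rng keeps the quasi-MC integral deterministic
        adj = np.array(
            [
                1.0
                - stats.multivariate_normal.cdf(
                    np.full(k, abs(zi)),
                    mean=np.zeros(k),
                    cov=corr,
                    allow_singular=True,
                    lower_limit=np.full(k, -abs(zi)),
                    abseps=1e-8,
                    releps=0.0,
                    maxpts=1_000_000,
                    rng=np.random.default_rng(seed),
                )
                for zi in z
            ]
        )
    except (np.linalg.LinAlgError, ValueError):
        warnings.warn("degenerate contrast covariance; Bonferroni fallback", stacklevel=2)
        adj = np.minimum(1.0, k * raw)
    # the joint event is a subset of each marginal event, so adj >= raw holds
    # mathematically; enforce it against QMC integration noise
    return np.clip(np.maximum(adj, raw), 0.0, 1.0)


def posthoc_pairwise(fit: LMEFit, seed: int = SINGLE_STEP_SEED) -> PosthocResult:
    """Three pairwise condition contrasts (S-W, S-EW, W-EW), single-step adjusted."""
    if not fit.converged:
        warnings.warn("post hoc on a non-converged fit", stacklevel=2)
    if "condition[W]" not in fit.params.index:
        raise InvalidInputError("post hoc requires condition in the model")
    fixed = list(fit.params.index)
    L = np.zeros((3, len(fixed)))
    iW, iS = fixed.index("condition[W]"), fixed.index("condition[S]")
    L[0, iS], L[0, iW] = 1.0, -1.0  # S - W
    L[1, iS] = 1.0  # S - EW
    L[2, iW] = 1.0  # W - EW
    est = L @ fit.params.to_numpy()
    cov = L @ fit.cov_fixed.to_numpy() @ L.T
    se = np.sqrt(np.diag(cov))
    zstat = est / se
    dd = np.outer(se, se)
    corr = cov / dd
    p_raw = 2.0 * stats.norm.sf(np.abs(zstat))
    p_adj = single_step_adjust(zstat, corr, seed=seed)
    table = pd.DataFrame(
        {
            "contrast": list(CONTRAST_NAMES),
            "estimate": est,
            "se": se,
            "z": zstat,
            "p_raw": p_raw,
            "p_adjusted": p_adj,
        }
    )
    return PosthocResult(table=table)


def residual_diagnostics(fit: LMEFit, plot_path: str | None = None) -> dict[str, float | bool]:
    """Descriptive residual checks: normal-quantile correlation and spread-vs-fitted.

    ``qq_corr`` below 0.95 flags departure from normality; the report is purely
    descriptive and never alters the fit.
    """
    res = fit.result
    try:
        resid = np.asarray(res.resid, dtype=float)
        fitted = np.asarray(res.fittedvalues, dtype=float)
    except (ValueError, np.linalg.LinAlgError):
        # singular random-effect covariance (e.g. constant response): no BLUPs
        warnings.warn("degenerate fit: random-effect covariance is singular", stacklevel=2)
        return {"n": fit.n_obs, "qq_corr": np.nan, "flagged": True, "degenerate": True}
    if np.std(resid) < 1e-12:
        warnings.warn("degenerate fit: residuals have (near) zero variance", stacklevel=2)
        return {"n": len(resid), "qq_corr": np.nan, "flagged": True, "degenerate": True}
    (osm, osr), (slope, intercept, qq_corr) = stats.probplot(resid)
    abs_corr = float(np.corrcoef(np.abs(resid), fitted)[0, 1])
    report = {
        "n": int(len(resid)),
        "resid_mean": float(np.mean(resid)),
        "resid_sd": float(np.std(resid, ddof=1)),
        "qq_corr": float(qq_corr),
        "abs_resid_vs_fitted_corr": abs_corr,
        "flagged": bool(qq_corr < 0.95),
        "degenerate": False,
    }
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(8, 3.2))
        axes[0].scatter(fitted, resid, s=6, alpha=0.5)
        axes[0].axhline(0.0, color="k", lw=0.6)
        axes[0].set(xlabel="fitted", ylabel="residual", title=fit.spec.name)
        axes[1].scatter(osm, osr, s=6, alpha=0.5)
        axes[1].plot(osm, slope * np.asarray(osm) + intercept, "r", lw=0.8)
        axes[1].set(xlabel="normal quantile", ylabel="residual", title=f"r={qq_corr:.3f}")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return report


def distribution_shape(
    asi_values: Sequence[float] | np.ndarray, seed: int = 0
) -> dict[str, object]:
    """Shape report for a sample of interface areas.

    Bimodality: 1- vs 2-component Gaussian mixtures on the sqrt scale compared
    by BIC; "bimodal" requires both that the 2-component model wins *and* that
    the fitted mixture density actually has two modes (a 2-component win alone
    can reflect mere skewness).  Tail shape: log-normal vs gamma maximum-
    likelihood fits on the raw scale compared by AIC.
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(asi_values, dtype=float)
    if len(x) < 100:
        raise InsufficientDataError(f"distribution_shape needs >= 100 values, got {len(x)}")
    if (x <= 0).any():
        raise InvalidInputError("interface areas must be > 0")
    s = np.sqrt(x)[:, None]
    gmm1 = GaussianMixture(1, random_state=seed, n_init=1).fit(s)
    gmm2 = GaussianMixture(2, random_state=seed, n_init=5).fit(s)
    bic1, bic2 = float(gmm1.bic(s)), float(gmm2.bic(s))
    grid = np.linspace(s.min(), s.max(), 2048)[:, None]
    dens = np.exp(gmm2.score_samples(grid))
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    n_modes = int(interior.sum())
    bimodal = (bic2 < bic1) and (n_modes >= 2)

    logn = stats.lognorm.fit(x, floc=0)
    gam = stats.gamma.fit(x, floc=0)
    aic_logn = 2 * 2 - 2 * float(np.sum(stats.lognorm.logpdf(x, *logn)))
    aic_gam = 2 * 2 - 2 * float(np.sum(stats.gamma.logpdf(x, *gam)))
    lognormal_like = aic_logn < aic_gam

    return {
        "call": "bimodal" if bimodal else "unimodal",
        "lognormal_like": bool(lognormal_like),
        "tail_call": "log-normal-like" if lognormal_like else "gamma-like",
        "n": int(len(x)),
        "bic_1_component": bic1,
        "bic_2_component": bic2,
        "n_mixture_modes": n_modes,
        "aic_lognormal": aic_logn,
        "aic_gamma": aic_gam,
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)),
    }
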