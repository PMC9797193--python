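"""Synthetic three-condition cohorts.

Generates mice -> dendrites -> spines tables with the hierarchical structure
the mixed-model analysis assumes, parameterised by the published cerebellar
cohort: three conditions (W spontaneous wake, EW extended wake, S sleep) with
4/4/6 mice, ~7 sampled dendrites per mouse, per-condition synapse / naked /
branched densities per um^2 of dendrite surface, a mouse-level random
intercept acting on the square-root density scale, and gamma-distributed
axon-spine interface (ASI) areas whose mean is lower for branched synapses.

Spine counts are Poisson given the dendrite area and the mouse effect — the
simplest count model consistent with per-area densities, under which the LME
on sqrt-densities is approximately variance stabilised.  Organelle flags are
drawn independently per synapse (a documented simplification: the real joint
distribution of ASI size and organelle content is unknown).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import census as census_mod
from .errors import InvalidInputError

CONDITIONS = ("W", "EW", "S")


def _per_condition(value) -> dict[str, float]:
    if isinstance(value, Mapping):
        return {c: float(value[c]) for c in CONDITIONS}
    return {c: float(value) for c in CONDITIONS}


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters; defaults are the published cerebellar cohort.

    Densities are #/um^2 of dendrite surface; percentages of spines with a
    synapse unless noted.  ``mouse_intercept_sd`` and ``residual`` noise act on
    the sqrt-density scale used by the dendrite-level models.
    """

    n_mice: Mapping[str, int] = field(
        default_factory=lambda: {"W": 4, "EW": 4, "S": 6}
    )
    dendrites_per_mouse: int = 7
    # dendrite geometry (inclusion window: length >= 3.122, diameter 0.940-1.966)
    length_mean_um: float = 8.5
    length_sd_um: float = 3.3
    diameter_mean_um: float = 1.35
    diameter_sd_um: float = 0.17
    surface_noise_cv: float = 0.10
    # per-condition rates (#/um^2)
    synapse_density: Mapping[str, float] = field(
        default_factory=lambda: {"W": 1.76, "EW": 2.04, "S": 1.78}
    )
    naked_density: Mapping[str, float] = field(
        default_factory=lambda: {"W": 0.08, "EW": 0.13, "S": 0.19}
    )
    branched_synapse_density: Mapping[str, float] = field(
        default_factory=lambda: {"W": 0.29, "EW": 0.38, "S": 0.16}
    )
    mouse_intercept_sd: float = 0.0605  # sqrt-density scale
    triple_branch_fraction: float = 0.03
    # naked-spine taxonomy weights: single, both-naked pair, one-naked pair, head protrusion
    naked_type_weights: tuple[float, float, float, float] = (0.55, 0.15, 0.20, 0.10)
    # ASI (um^2), gamma or truncated-normal family
    asi_family: str = "gamma"
    asi_mean: Mapping[str, float] = field(
        default_factory=lambda: {"W": 0.187, "EW": 0.158, "S": 0.174}
    )
    asi_sd: Mapping[str, float] = field(
        default_factory=lambda: {"W": 0.109, "EW": 0.095, "S": 0.104}
    )
    branched_asi_factor: float = 0.88  # branched synapses have smaller interfaces
    oblique_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"W": 0.070, "EW": 0.056, "S": 0.018}
    )
    incomplete_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"W": 0.008, "EW": 0.012, "S": 0.012}
    )
    # organelle probabilities per spine-with-synapse
    organelle_probs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "spine_apparatus": {"W": 0.022, "EW": 0.064, "S": 0.018},
            "endosome": {"W": 0.963, "EW": 0.989, "S": 0.998},
            "coated_vesicle": {"W": 0.015, "EW": 0.002, "S": 0.001},
            "spinula": {"W": 0.016, "EW": 0.103, "S": 0.227},
            "multivesicular_body": {"W": 0.034, "EW": 0.057, "S": 0.028},
            "presynaptic_mitochondrion": {"W": 0.580, "EW": 0.618, "S": 0.573},
        }
    )
    branched_different_fiber: float = 0.93
    seed: int = 0

    def validate(self) -> None:
        for name in ("synapse_density", "naked_density", "branched_synapse_density"):
            for c, v in _per_condition(getattr(self, name)).items():
                if v < 0:
                    raise InvalidInputError(f"{name}[{c}] must be >= 0")
                if name == "branched_synapse_density" and v > _per_condition(self.synapse_density)[c]:
                    raise InvalidInputError(f"branched density exceeds synapse density for {c}")
        for name in ("oblique_fraction", "incomplete_fraction", "branched_different_fiber"):
            vals = getattr(self, name)
            vals = _per_condition(vals) if not isinstance(vals, float) else {"all": vals}
            for c, v in vals.items():
                if not 0.0 <= v <= 1.0:
                    raise InvalidInputError(f"{name}[{c}] must be in [0, 1]")
        if abs(sum(self.naked_type_weights) - 1.0) > 1e-9:
            raise InvalidInputError("naked_type_weights must sum to 1")
        if self.asi_family not in ("gamma", "truncated-normal"):
            raise InvalidInputError(f"unknown asi_family {self.asi_family!r}")

    def with_effect_removed(self) -> "CohortConfig":
        """Null configuration: every condition gets the W rates (no condition effect)."""
        w = lambda m: {c: _per_condition(m)["W"] for c in CONDITIONS}  # noqa: E731
        return replace(
            self,
            synapse_density=w(self.synapse_density),
            naked_density=w(self.naked_density),
            branched_synapse_density=w(self.branched_synapse_density),
            asi_mean=w(self.asi_mean),
            asi_sd=w(self.asi_sd),
            oblique_fraction=w(self.oblique_fraction),
            incomplete_fraction=w(self.incomplete_fraction),
        )


def _draw_asi(rng: np.random.Generator, mean: float, sd: float, family: str) -> float:
    if family == "gamma":
        shape = (mean / sd) ** 2
        return float(rng.gamma(shape, sd**2 / mean))
    while True:  # truncated normal, reject non-positive
        v = rng.normal(mean, sd)
        if v > 0:
            return v


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(mice, dendrites, spines) tables; bit-identical for identical configs."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    syn_rate = _per_condition(config.synapse_density)
    naked_rate = _per_condition(config.naked_density)
    branched_rate = _per_condition(config.branched_synapse_density)

    mice_rows, den_rows, spine_rows = [], [], []
    for cond in CONDITIONS:
        for i in range(int(config.n_mice[cond])):
            mouse_id = f"{cond}{i + 1}"
            mice_rows.append({"mouse_id": mouse_id, "condition": cond})
            u = rng.normal(0.0, config.mouse_intercept_sd)  # sqrt-scale intercept
            rates = {
                # a zero configured rate stays zero; the mouse effect shifts
                # the sqrt-scale location of nonzero rates only
                name: 0.0 if r[cond] == 0.0 else max(0.0, math.sqrt(r[cond]) + u) ** 2
                for name, r in (
                    ("syn", syn_rate),
                    ("naked", naked_rate),
                    ("branched", branched_rate),
                )
            }
            for j in range(config.dendrites_per_mouse):
                dendrite_id = f"{mouse_id}_d{j + 1}"
                length = max(
                    census_mod.MIN_DENDRITE_LENGTH_UM,
                    rng.normal(config.length_mean_um, config.length_sd_um),
                )
                lo, hi = census_mod.DIAMETER_RANGE_UM
                diameter = float(
                    np.clip(rng.normal(config.diameter_mean_um, config.diameter_sd_um), lo, hi)
                )
                area = (
                    math.pi * diameter * length * math.exp(rng.normal(0.0, config.surface_noise_cv))
                )
                den_rows.append(
                    {
                        "dendrite_id": dendrite_id,
                        "mouse_id": mouse_id,
                        "surface_area_um2": area,
                        "length_um": length,
                        "diameter_um": diameter,
                        "is_terminal_branch": bool(rng.random() < 2 / 3),
                    }
                )
                spine_rows.extend(
                    _dendrite_spines(rng, config, cond, dendrite_id, area, rates)
                )
    mice = pd.DataFrame(mice_rows)
    dendrites = pd.DataFrame(den_rows)
    spines = pd.DataFrame(
        spine_rows,
        columns=[
            "spine_id",
            "dendrite_id",
            "branch_group_id",
            "has_synapse",
            "head_protrusion_of",
            "oblique",
            "incomplete",
            "asi_um2",
            *census_mod.ORGANELLE_COLUMNS,
            "presyn_fiber_id",
        ],
    )
    for col in census_mod.SPINE_FLAG_COLUMNS:
        spines[col] = spines[col].astype(bool)
    spines["asi_um2"] = pd.to_numeric(spines["asi_um2"])
    census_mod.validate_tables(dendrites, spines, mice)
    return mice, dendrites, spines


_DENSITY_FIELD = {
    "branched_density": "branched_synapse_density",
    "naked_density": "naked_density",
    "spine_density_with_synapse": "synapse_density",
}


def _sample_sqrt_density(config: CohortConfig, cond: str, which: str,
                         n: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorised draws of per-dendrite sqrt(count / area) under the generator.

    Used to evaluate the population value of the sqrt-scale fixed effects: the
    mixed model estimates E[sqrt(density)], which sits slightly below
    sqrt(configured rate) because the square root of a Poisson count is a
    concave transform (the gap shrinks with the expected count, not with the
    number of mice).
    """
    syn = _per_condition(config.synapse_density)[cond]
    naked = _per_condition(config.naked_density)[cond]
    branched = _per_condition(config.branched_synapse_density)[cond]
    u = rng.normal(0.0, config.mouse_intercept_sd, size=n)

    def rate(r):
        return np.where(r == 0.0, 0.0, np.maximum(0.0, math.sqrt(r) + u) ** 2)

    syn_r, naked_r, branched_r = rate(syn), rate(naked), rate(branched)
    length = np.maximum(
        census_mod.MIN_DENDRITE_LENGTH_UM,
        rng.normal(config.length_mean_um, config.length_sd_um, size=n),
    )
    lo, hi = census_mod.DIAMETER_RANGE_UM
    diam = np.clip(rng.normal(config.diameter_mean_um, config.diameter_sd_um, size=n), lo, hi)
    area = math.pi * diam * length * np.exp(rng.normal(0.0, config.surface_noise_cv, size=n))

    w_single, w_both, w_one, w_head = config.naked_type_weights
    one_naked_r = np.minimum(naked_r * w_one, branched_r)
    full_branched_r = branched_r - one_naked_r
    pair_r = full_branched_r / (2.0 + config.triple_branch_fraction)
    n_groups = rng.poisson(pair_r * area)
    n_triples = rng.binomial(n_groups, config.triple_branch_fraction)
    branched_count = 2 * n_groups + n_triples + rng.poisson(one_naked_r * area)
    if which == "branched":
        count = branched_count
    elif which == "naked":
        count = (
            rng.poisson(naked_r * w_single * area)
            + 2 * rng.poisson(naked_r * w_both / 2.0 * area)
            + rng.poisson(one_naked_r * area)
            + rng.poisson(naked_r * w_head * area)
        )
    elif which == "syn":
        count = branched_count + rng.poisson(np.maximum(0.0, syn_r - branched_r) * area)
    else:
        raise InvalidInputError(f"unknown density family {which!r}")
    return np.sqrt(count / area)


_WHICH = {
    "branched_synapse_density": "branched",
    "naked_density": "naked",
    "synapse_density": "syn",
}


def population_sqrt_contrasts(
    config: CohortConfig, field_name: str, n_mc: int = 400_000, seed: int = 12345
) -> dict[str, float]:
    """Population sqrt-scale condition contrasts (vs EW) under the generator,
    by high-precision Monte Carlo; the recovery estimand."""
    rng = np.random.default_rng(seed)
    which = _WHICH[field_name]
    means = {
        cond: float(_sample_sqrt_density(config, cond, which, n_mc, rng).mean())
        for cond in CONDITIONS
    }
    return {"W": means["W"] - means["EW"], "S": means["S"] - means["EW"]}


def recovery_experiment(
    config: CohortConfig,
    n_replicates: int,
    model_name: str = "branched_density",
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, object]:
    """Parameter-recovery simulation: generate -> census -> LME per replicate.

    Reports the likelihood-ratio rejection rate for the condition effect and,
    for models whose generative truth is known (sqrt-scale contrasts of the
    configured densities), the bias of the fixed-effect estimates with their
    Monte-Carlo standard errors.
    """
    from . import census as census_mod  # local import to avoid cycle at module load
    from .lme import BUILTIN_MODELS, fit_lme, lrt_from_fits

    spec = BUILTIN_MODELS[model_name]
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    pvals, est_w, est_s = [], [], []
    for s in rep_seeds:
        mice, dendrites, spines = generate_cohort(replace(config, seed=int(s)))
        table = census_mod.dendrite_level_table(dendrites, spines, mice)
        full = fit_lme(spec, table)
        reduced = fit_lme(spec.drop_condition(), table)
        pvals.append(lrt_from_fits(full, reduced).p)
        eff = full.condition_effects
        est_w.append(eff["W"])
        est_s.append(eff["S"])
    pvals = np.asarray(pvals)
    report: dict[str, object] = {
        "model": model_name,
        "n_replicates": int(n_replicates),
        "alpha": float(alpha),
        "rejection_rate": float(np.mean(pvals < alpha)),
        "rejection_rate_mc_se": float(
            np.sqrt(np.mean(pvals < alpha) * (1 - np.mean(pvals < alpha)) / n_replicates)
        ),
    }
    field_name = _DENSITY_FIELD.get(model_name)
    if field_name is not None and spec.transform == "sqrt":
        r = _per_condition(getattr(config, field_name))
        truth = population_sqrt_contrasts(config, field_name)
        plugin = {
            "W": math.sqrt(r["W"]) - math.sqrt(r["EW"]),
            "S": math.sqrt(r["S"]) - math.sqrt(r["EW"]),
        }
        for lvl, estimates in (("W", np.asarray(est_w)), ("S", np.asarray(est_s))):
            mc_se = float(estimates.std(ddof=1) / math.sqrt(n_replicates))
            report[f"effect_{lvl}"] = {
                "truth": truth[lvl],
                "sqrt_rate_contrast": plugin[lvl],
                "mean_estimate": float(estimates.mean()),
                "bias": float(estimates.mean() - truth[lvl]),
                "mc_se": mc_se,
            }
    return report


def _dendrite_spines(rng, config, cond, dendrite_id, area, rates):
    """Spine records of one dendrite."""
    rows = []
    counter = 0
    fiber_counter = 0

    def new_spine(**kw):
        nonlocal counter
        counter += 1
        base = {
            "spine_id": f"{dendrite_id}_s{counter}",
            "dendrite_id": dendrite_id,
            "branch_group_id": None,
            "has_synapse": False,
            "head_protrusion_of": None,
            "oblique": False,
            "incomplete": False,
            "asi_um2": None,
            **{org: False for org in census_mod.ORGANELLE_COLUMNS},
            "presyn_fiber_id": None,
        }
        base.update(kw)
        rows.append(base)
        return base

    def new_fiber():
        nonlocal fiber_counter
        fiber_counter += 1
        return f"{dendrite_id}_f{fiber_counter}"

    def dress_synapse(spine, branched: bool, fiber: str):
        spine["has_synapse"] = True
        spine["presyn_fiber_id"] = fiber
        spine["oblique"] = bool(rng.random() < _per_condition(config.oblique_fraction)[cond])
        spine["incomplete"] = bool(
            (not spine["oblique"])
            and rng.random() < _per_condition(config.incomplete_fraction)[cond]
        )
        for org, probs in config.organelle_probs.items():
            spine[org] = bool(rng.random() < _per_condition(probs)[cond])
        if not (spine["oblique"] or spine["incomplete"]):
            mean = _per_condition(config.asi_mean)[cond]
            sd = _per_condition(config.asi_sd)[cond]
            if branched:
                mean *= config.branched_asi_factor
                sd *= config.branched_asi_factor
            spine["asi_um2"] = _draw_asi(rng, mean, sd, config.asi_family)

    w_single, w_both, w_one, w_head = config.naked_type_weights

    # mixed groups (one member naked, one synapsed) contribute both a naked
    # spine and a branched synapse; their rate is carved out of both budgets
    # so that the configured densities are met in expectation
    one_naked_rate = min(rates["naked"] * w_one, rates["branched"])
    full_branched_rate = rates["branched"] - one_naked_rate
    pair_rate = full_branched_rate / (2.0 + config.triple_branch_fraction)
    n_groups = rng.poisson(pair_rate * area)
    for g in range(n_groups):
        gid = f"{dendrite_id}_g{g + 1}"
        size = 3 if rng.random() < config.triple_branch_fraction else 2
        same_fiber = rng.random() >= config.branched_different_fiber
        shared = new_fiber()
        for _ in range(size):
            sp = new_spine(branch_group_id=gid)
            dress_synapse(sp, branched=True, fiber=shared if same_fiber else new_fiber())

    # single synapses
    n_single = rng.poisson(max(0.0, rates["syn"] - rates["branched"]) * area)
    singles = []
    for _ in range(n_single):
        sp = new_spine()
        dress_synapse(sp, branched=False, fiber=new_fiber())
        singles.append(sp)

    # naked spines by taxonomy type (a both-naked pair carries two naked spines)
    for _ in range(rng.poisson(rates["naked"] * w_single * area)):
        new_spine()
    for _ in range(rng.poisson(rates["naked"] * w_both / 2.0 * area)):
        gid = f"{dendrite_id}_gn{counter}"
        new_spine(branch_group_id=gid)
        new_spine(branch_group_id=gid)
    for _ in range(rng.poisson(one_naked_rate * area)):
        gid = f"{dendrite_id}_gm{counter}"
        new_spine(branch_group_id=gid)
        sp = new_spine(branch_group_id=gid)
        dress_synapse(sp, branched=True, fiber=new_fiber())
    for _ in range(rng.poisson(rates["naked"] * w_head * area)):
        if singles:
            host = singles[int(rng.integers(len(singles)))]
        else:
            host = new_spine()
            dress_synapse(host, branched=False, fiber=new_fiber())
            singles.append(host)
        new_spine(head_protrusion_of=host["spine_id"])
    return rows
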