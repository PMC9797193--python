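"""Top-level pipeline: cohort -> census -> mixed models -> report bundle.

``run_pipeline`` executes the requested stages in order and writes per-stage
CSV outputs plus a machine-readable, versioned JSON report of every statistic.
All randomness flows from the single configuration seed, so a rerun with the
same configuration regenerates the bundle bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from . import census as census_mod
from . import io as io_mod
from . import lme as lme_mod
from .cohort import CohortConfig, generate_cohort
from .contours import SmoothingSpec, measure_stack
from .errors import InvalidInputError

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

#: model names fitted by default, mirroring the published analyses
DEFAULT_MODELS = tuple(lme_mod.BUILTIN_MODELS)


def format_p(p: float) -> str:
    """p to 4 significant figures; values below 1e-12 reported as a bound."""
    if p < 1e-12:
        return "<1e-12"
    return f"{p:.4g}"


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    out_dir: str | Path
    seed: int = 0
    cohort: CohortConfig | None = None  # None -> defaults with this seed
    dendrite_csv: str | Path | None = None  # load instead of simulate
    spine_csv: str | Path | None = None
    schema: io_mod.SchemaMap | None = None
    stacks_json: str | Path | None = None  # optional surface stage input
    smoothing: SmoothingSpec = field(default_factory=SmoothingSpec)
    models: tuple[str, ...] = DEFAULT_MODELS
    log_level: str = "INFO"

    def validate(self) -> None:
        unknown = [m for m in self.models if m not in lme_mod.BUILTIN_MODELS]
        if unknown:
            raise InvalidInputError(f"unknown model name(s): {unknown}")
        if (self.dendrite_csv is None) != (self.spine_csv is None):
            raise InvalidInputError("dendrite_csv and spine_csv must be given together")


def _fit_report(name: str, dtable: pd.DataFrame, stable: pd.DataFrame) -> dict:
    spec = lme_mod.BUILTIN_MODELS[name]
    data = stable if spec.level == "spine" else dtable
    fit = lme_mod.fit_lme(spec, data)
    lrt = lme_mod.lrt_from_fits(fit, lme_mod.fit_lme(spec.drop_condition(), data))
    posthoc = lme_mod.posthoc_pairwise(fit)
    diag = lme_mod.residual_diagnostics(fit)
    return {
        "response": spec.response,
        "transform": spec.transform,
        "level": spec.level,
        "n_obs": fit.n_obs,
        "n_mice": fit.n_groups,
        "converged": fit.converged,
        "fixed_effects": {k: float(v) for k, v in fit.params.items()},
        "fixed_effects_se": {k: float(v) for k, v in fit.bse.items()},
        "random_intercept_sd": fit.random_sd,
        "residual_sd": fit.residual_sd,
        "loglik": fit.llf,
        "lrt": {
            "chi2": lrt.chi2,
            "df": lrt.df,
            "p": lrt.p,
            "p_formatted": format_p(lrt.p),
        },
        "posthoc": [
            {
                "contrast": r.contrast,
                "estimate": float(r.estimate),
                "se": float(r.se),
                "z": float(r.z),
                "p_raw": float(r.p_raw),
                "p_adjusted": float(r.p_adjusted),
                "p_adjusted_formatted": format_p(float(r.p_adjusted)),
            }
            for r in posthoc.table.itertuples()
        ],
        "diagnostics": diag,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages and write the report bundle.

    Returns the report dictionary (also written to ``report.json``).
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("spinemorph %s, seed %d", _pkg_version, config.seed)

    # --- cohort stage: simulate or load -----------------------------------
    if config.dendrite_csv is not None:
        mice, dendrites, spines = io_mod.read_tables(
            config.dendrite_csv, config.spine_csv, config.schema
        )
        source = {"kind": "files", "dendrites": str(config.dendrite_csv),
                  "spines": str(config.spine_csv)}
    else:
        cohort_cfg = config.cohort or CohortConfig(seed=config.seed)
        mice, dendrites, spines = generate_cohort(cohort_cfg)
        io_mod.write_tables(out / "tables", mice, dendrites, spines)
        source = {"kind": "synthetic", "seed": cohort_cfg.seed}

    # --- optional surface stage -------------------------------------------
    surfaces = None
    if config.stacks_json is not None:
        stacks = io_mod.read_stacks(config.stacks_json)
        surfaces = pd.DataFrame([measure_stack(s, config.smoothing) for s in stacks])
        surfaces.to_csv(out / "surfaces.csv", index=False)

    # --- census stage ------------------------------------------------------
    per_dendrite = census_mod.dendrite_level_table(dendrites, spines, mice)
    per_mouse_syn = census_mod.per_mouse_proportions(spines, dendrites, mice, "with_synapse")
    per_mouse_all = census_mod.per_mouse_proportions(spines, dendrites, mice, "all_spines")
    summary = census_mod.group_summary(per_dendrite, per_mouse_syn, mice)
    per_dendrite.to_csv(out / "per_dendrite.csv", index=False)
    per_mouse_syn.to_csv(out / "per_mouse_with_synapse.csv", index=False)
    per_mouse_all.to_csv(out / "per_mouse_all_spines.csv", index=False)
    summary.to_csv(out / "group_summary.csv", index=False)

    # --- statistics stage --------------------------------------------------
    spine_table = census_mod.spine_level_table(dendrites, spines, mice)
    models = {}
    for name in config.models:
        logger.info("fitting model %s", name)
        models[name] = _fit_report(name, per_dendrite, spine_table)

    asi_values = spine_table["asi_um2"].to_numpy(dtype=float)
    shape = (
        lme_mod.distribution_shape(asi_values, seed=config.seed)
        if len(asi_values) >= 100
        else {"call": "insufficient data", "n": int(len(asi_values))}
    )

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": _pkg_version,
        "seed": config.seed,
        "source": source,
        "census": {
            "n_mice": int(len(mice)),
            "n_dendrites": int(len(dendrites)),
            "n_spines": int(len(spines)),
            "n_spines_with_synapse": int(spines["has_synapse"].sum()),
            "n_asi_measured": int(spines["asi_um2"].notna().sum()),
            "prop_with_synapse": census_mod.prop_with_synapse(spines, dendrites),
            "group_summary": json.loads(summary.to_json(orient="records")),
        },
        "asi_distribution_shape": shape,
        "models": models,
    }
    if surfaces is not None:
        report["surfaces"] = json.loads(surfaces.to_json(orient="records"))
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
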