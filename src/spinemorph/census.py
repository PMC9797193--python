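"""Spine and synapse census.

The annotation data model is hierarchical: mice (one of three sleep/wake
conditions: W spontaneous wake, EW extended wake, S sleep) own dendritic
segments, dendrites own protrusions ("spines").  Every protrusion counts as a
spine; a spine may house a synapse (presynaptic bouton, cleft, PSD), may share
a neck with other spines (a *branched* group, whose synapses each count
separately), or may lack a synapse entirely (*naked*).  This module computes
the classifications, counts, densities and per-mouse proportions that the
summary tables and the mixed-model analyses consume.

Tables are plain pandas DataFrames with canonical columns:

mice:      mouse_id, condition
dendrites: dendrite_id, mouse_id, surface_area_um2, length_um, diameter_um,
           is_terminal_branch (optional)
spines:    spine_id, dendrite_id, branch_group_id, has_synapse,
           head_protrusion_of, oblique, incomplete, asi_um2,
           spine_apparatus, endosome, coated_vesicle, spinula,
           multivesicular_body, presynaptic_mitochondrion, presyn_fiber_id
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .errors import DataIntegrityError, InvalidInputError

logger = logging.getLogger(__name__)

CONDITIONS = ("W", "EW", "S")

#: dendrite inclusion criteria from the sampling protocol
MIN_DENDRITE_LENGTH_UM = 3.122
DIAMETER_RANGE_UM = (0.940, 1.966)

ORGANELLE_COLUMNS = (
    "spine_apparatus",
    "endosome",
    "coated_vesicle",
    "spinula",
    "multivesicular_body",
    "presynaptic_mitochondrion",
)

SPINE_FLAG_COLUMNS = ("has_synapse", "oblique", "incomplete") + ORGANELLE_COLUMNS

NakedType = Literal[
    "single_naked", "branched_both_naked", "branched_one_naked", "head_protrusion", "not_naked"
]


# ---------------------------------------------------------------------------
# validation


def validate_tables(
    dendrites: pd.DataFrame, spines: pd.DataFrame, mice: pd.DataFrame | None = None
) -> None:
    """Enforce the census invariants; warn (not fail) on inclusion-criteria outliers.

    Raises
    ------
    DataIntegrityError
        Orphan spines, undersized branch groups, or ASI on naked/oblique/
        incomplete spines.
    """
    if mice is not None:
        bad = set(mice["condition"]) - set(CONDITIONS)
        if bad:
            raise DataIntegrityError(f"unknown condition label(s): {sorted(bad)}")
        unknown_mouse = set(dendrites["mouse_id"]) - set(mice["mouse_id"])
        if unknown_mouse:
            raise DataIntegrityError(f"dendrites reference unknown mice: {sorted(unknown_mouse)[:5]}")
    if (dendrites["surface_area_um2"] <= 0).any():
        raise DataIntegrityError("dendrite surface areas must be > 0")
    n_short = int((dendrites["length_um"] < MIN_DENDRITE_LENGTH_UM).sum())
    lo, hi = DIAMETER_RANGE_UM
    n_diam = int((~dendrites["diameter_um"].between(lo, hi)).sum()) if len(dendrites) else 0
    if n_short or n_diam:
        warnings.warn(
            f"{n_short} dendrite(s) below {MIN_DENDRITE_LENGTH_UM} um length and "
            f"{n_diam} outside the {lo}-{hi} um diameter inclusion range",
            stacklevel=2,
        )
    orphans = set(spines["dendrite_id"]) - set(dendrites["dendrite_id"])
    if orphans:
        raise DataIntegrityError(f"spines reference unknown dendrites: {sorted(orphans)[:5]}")
    grouped = spines[spines["branch_group_id"].notna()]
    sizes = grouped.groupby("branch_group_id").size()
    if (sizes < 2).any():
        raise DataIntegrityError(
            f"branch group(s) with a single member: {list(sizes[sizes < 2].index)[:5]}"
        )
    hp = grouped["head_protrusion_of"].notna()
    if hp.any():
        raise DataIntegrityError("head protrusions must not be branch-group members")
    has_asi = spines["asi_um2"].notna()
    bad_asi = has_asi & (
        ~spines["has_synapse"] | spines["oblique"] | spines["incomplete"]
    )
    if bad_asi.any():
        raise DataIntegrityError(
            "ASI recorded on naked/oblique/incomplete spine(s): "
            f"{list(spines.loc[bad_asi, 'spine_id'])[:5]}"
        )
    if (spines.loc[has_asi, "asi_um2"] <= 0).any():
        raise DataIntegrityError("ASI areas must be > 0 when present")


# ---------------------------------------------------------------------------
# classification


def classify_naked_type(spine: pd.Series, group: pd.DataFrame) -> NakedType:
    """Type of a synapse-lacking protrusion (taxonomy of the naked-spine figure).

    ``group`` must contain every spine sharing this spine's branch group (or
    just the spine itself when ungrouped).
    """
    if spine["has_synapse"]:
        return "not_naked"
    gid = spine["branch_group_id"]
    if pd.notna(gid):
        if (group["branch_group_id"] != gid).any() or spine["spine_id"] not in set(
            group["spine_id"]
        ):
            raise DataIntegrityError("group does not match the spine's branch_group_id")
        if len(group) < 2:
            raise DataIntegrityError(f"branch group {gid} has fewer than 2 members")
        if group["has_synapse"].any():
            return "branched_one_naked"
        return "branched_both_naked"
    if pd.notna(spine["head_protrusion_of"]):
        return "head_protrusion"
    return "single_naked"


def classify_naked_types(spines: pd.DataFrame) -> pd.Series:
    """Vectorised naked-type label for every spine (index-aligned)."""
    out = pd.Series("not_naked", index=spines.index, dtype=object)
    naked = ~spines["has_synapse"]
    grouped = spines["branch_group_id"].notna()
    _tr = spines.groupby("branch_group_id")["has_synapse"].transform("any")
    group_has_syn = _tr.where(_tr.notna(), False).astype(bool)
    out[naked & grouped & group_has_syn] = "branched_one_naked"
    out[naked & grouped & ~group_has_syn] = "branched_both_naked"
    head = naked & ~grouped & spines["head_protrusion_of"].notna()
    out[head] = "head_protrusion"
    out[naked & ~grouped & ~spines["head_protrusion_of"].notna()] = "single_naked"
    return out


def synapse_counts(spines: pd.DataFrame) -> dict[str, int]:
    """Census counts for a set of spine records.

    Branched synapses (members of a >=2 spine group that carry a synapse) each
    count as one synapse, so a fully-synapsed pair contributes two.
    """
    grouped = spines["branch_group_id"].notna()
    group_size = spines.groupby("branch_group_id")["spine_id"].transform("size")
    in_branch = grouped & (group_size >= 2)
    syn = spines["has_synapse"]
    counts = {
        "all_spines": int(len(spines)),
        "synapses": int(syn.sum()),
        "branched_synapses": int((syn & in_branch).sum()),
        "single_synapses": int((syn & ~in_branch).sum()),
        "branched_spines": int(in_branch.sum()),
        "naked_spines": int((~syn).sum()),
    }
    assert counts["single_synapses"] + counts["branched_synapses"] == counts["synapses"]
    assert counts["synapses"] + counts["naked_spines"] == counts["all_spines"]
    return counts


def density(
    count: float,
    dendrite: pd.Series,
    denominator: Literal["surface_area", "length"] = "surface_area",
) -> float:
    """Count normalised by dendrite surface area (#/um^2) or length (#/um)."""
    col = "surface_area_um2" if denominator == "surface_area" else "length_um"
    denom = float(dendrite[col])
    if denom <= 0:
        raise InvalidInputError(f"dendrite {dendrite.get('dendrite_id')}: {col} must be > 0")
    return float(count) / denom


def cumulative_asi_density(spines: pd.DataFrame, dendrite: pd.Series) -> tuple[float, int]:
    """(sum of measured ASIs per dendrite surface area, n synapses without ASI)."""
    area = float(dendrite["surface_area_um2"])
    if area <= 0:
        raise InvalidInputError("dendrite surface area must be > 0")
    measured = spines["asi_um2"].dropna()
    n_excluded = int((spines["has_synapse"] & spines["asi_um2"].isna()).sum())
    return float(measured.sum()) / area, n_excluded


# ---------------------------------------------------------------------------
# tables


def per_dendrite_table(dendrites: pd.DataFrame, spines: pd.DataFrame) -> pd.DataFrame:
    """One row per dendrite: counts, densities by area and length, ASI summaries.

    Every density column is exactly count / denominator, no rounding.
    """
    if (dendrites["surface_area_um2"] <= 0).any() or (dendrites["length_um"] <= 0).any():
        raise InvalidInputError("dendrite surface areas and lengths must be > 0")
    idx = dendrites["dendrite_id"]
    sp = spines.copy()
    group_size = sp.groupby("branch_group_id")["spine_id"].transform("size")
    sp["_in_branch"] = sp["branch_group_id"].notna() & (group_size >= 2)
    sp["_naked_type"] = classify_naked_types(sp)

    def agg(series: pd.Series) -> pd.Series:
        return series.reindex(idx).fillna(0.0)

    sp["_branched_syn"] = sp["has_synapse"] & sp["_in_branch"]
    sp["_syn_no_asi"] = sp["has_synapse"] & sp["asi_um2"].isna()
    sp["_syn_spinula"] = sp["has_synapse"] & sp["spinula"]
    g = sp.groupby("dendrite_id")
    all_spines = agg(g.size())
    synapses = agg(g["has_synapse"].sum())
    branched_syn = agg(g["_branched_syn"].sum())
    branched_spines = agg(g["_in_branch"].sum())
    naked = all_spines - synapses
    asi_sum = agg(g["asi_um2"].sum())
    asi_mean = g["asi_um2"].mean().reindex(idx)
    n_no_asi = agg(g["_syn_no_asi"].sum())
    spinula = agg(g["_syn_spinula"].sum())
    type_counts = pd.crosstab(sp["dendrite_id"], sp["_naked_type"])

    area = dendrites["surface_area_um2"].to_numpy(dtype=float)
    length = dendrites["length_um"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        out = pd.DataFrame(
            {
                "dendrite_id": idx.to_numpy(),
                "mouse_id": dendrites["mouse_id"].to_numpy(),
                "surface_area_um2": area,
                "length_um": length,
                "diameter_um": dendrites["diameter_um"].to_numpy(dtype=float),
                "all_spines": all_spines.to_numpy(dtype=int),
                "synapses": synapses.to_numpy(dtype=int),
                "branched_synapses": branched_syn.to_numpy(dtype=int),
                "single_synapses": (synapses - branched_syn).to_numpy(dtype=int),
                "branched_spines": branched_spines.to_numpy(dtype=int),
                "naked_spines": naked.to_numpy(dtype=int),
                "spine_density_per_um2": all_spines.to_numpy() / area,
                "synapse_density_per_um2": synapses.to_numpy() / area,
                "single_synapse_density_per_um2": (synapses - branched_syn).to_numpy() / area,
                "branched_synapse_density_per_um2": branched_syn.to_numpy() / area,
                "branched_spine_density_per_um2": branched_spines.to_numpy() / area,
                "naked_density_per_um2": naked.to_numpy() / area,
                "synapse_density_per_um": synapses.to_numpy() / length,
                "prop_without_synapse": np.where(
                    all_spines > 0, naked.to_numpy() / np.maximum(all_spines.to_numpy(), 1), np.nan
                ),
                "prop_with_synapse": np.where(
                    all_spines > 0, synapses.to_numpy() / np.maximum(all_spines.to_numpy(), 1), np.nan
                ),
                "prop_branched_of_all": np.where(
                    all_spines > 0,
                    branched_syn.to_numpy() / np.maximum(all_spines.to_numpy(), 1),
                    np.nan,
                ),
                "cumulative_asi_density": asi_sum.to_numpy() / area,
                "n_synapses_without_asi": n_no_asi.to_numpy(dtype=int),
                "mean_asi_um2": asi_mean.to_numpy(dtype=float),
                "prop_spinula": np.where(
                    synapses > 0, spinula.to_numpy() / np.maximum(synapses.to_numpy(), 1), np.nan
                ),
            }
        )
    for t in ("single_naked", "branched_both_naked", "branched_one_naked", "head_protrusion"):
        col = (
            type_counts[t].reindex(idx).fillna(0)
            if t in type_counts.columns
            else pd.Series(0, index=idx)
        )
        out[f"n_{t}"] = col.to_numpy(dtype=int)
    return out.reset_index(drop=True)


def per_mouse_proportions(
    spines: pd.DataFrame,
    dendrites: pd.DataFrame,
    mice: pd.DataFrame,
    denominator: Literal["with_synapse", "all_spines"] = "with_synapse",
) -> pd.DataFrame:
    """Per-mouse percentage table (values in percent).

    Two denominator conventions exist in the literature this mirrors: *all
    spines* (used for the branched-synapse share of all spines) and *spines
    with a synapse* (used for the organelle and oblique/incomplete rows).  The
    convention used is recorded in the ``denominator`` column.
    """
    sp = spines.merge(
        dendrites[["dendrite_id", "mouse_id"]], on="dendrite_id", how="left", validate="m:1"
    )
    if sp["mouse_id"].isna().any():
        raise DataIntegrityError("orphan spine(s): no dendrite/mouse mapping")
    rows = []
    for _, mouse in mice.iterrows():
        s = sp[sp["mouse_id"] == mouse["mouse_id"]]
        c = synapse_counts(s)
        denom = c["synapses"] if denominator == "with_synapse" else c["all_spines"]
        syn = s[s["has_synapse"]]

        def pct(n: float) -> float:
            return 100.0 * n / denom if denom else np.nan

        row = {
            "mouse_id": mouse["mouse_id"],
            "condition": mouse["condition"],
            "denominator": denominator,
            "n_denominator": denom,
            "branched_pct": pct(c["branched_synapses"]),
            "naked_pct": pct(c["naked_spines"]),
            "oblique_pct": pct(int(syn["oblique"].sum())),
            "incomplete_pct": pct(int(syn["incomplete"].sum())),
        }
        for org in ORGANELLE_COLUMNS:
            row[f"{org}_pct"] = pct(int(syn[org].sum()))
        rows.append(row)
    return pd.DataFrame(rows)


def group_summary(
    per_dendrite: pd.DataFrame,
    per_mouse: pd.DataFrame,
    mice: pd.DataFrame,
) -> pd.DataFrame:
    """Per-condition summary in the style of the cohort overview table.

    Density rows are mean +- SD across dendrites; percentage rows mean +- SD
    across mice.  Sample SD (ddof=1); a single-mouse condition reports SD 0
    with a warning.
    """
    pden = (
        per_dendrite
        if "condition" in per_dendrite.columns
        else per_dendrite.merge(mice, on="mouse_id", validate="m:1")
    )
    rows = []
    for cond in CONDITIONS:
        d = pden[pden["condition"] == cond]
        m = per_mouse[per_mouse["condition"] == cond]
        if len(m) == 1:
            warnings.warn(f"condition {cond}: single mouse, group SD reported as 0", stacklevel=2)
        row: dict[str, object] = {
            "condition": cond,
            "n_mice": len(m),
            "n_dendrites": len(d),
            "n_spines": int(d["all_spines"].sum()),
            "n_spines_with_synapse": int(d["synapses"].sum()),
            "n_asi_measured": int(d["synapses"].sum() - d["n_synapses_without_asi"].sum()),
        }
        for col in (
            "spine_density_per_um2",
            "synapse_density_per_um2",
            "naked_density_per_um2",
            "branched_synapse_density_per_um2",
            "single_synapse_density_per_um2",
            "synapse_density_per_um",
            "diameter_um",
            "length_um",
            "mean_asi_um2",
        ):
            row[f"{col}_mean"] = float(d[col].mean())
            row[f"{col}_sd"] = float(d[col].std(ddof=1)) if len(d) > 1 else 0.0
        for col in [c for c in m.columns if c.endswith("_pct")]:
            row[f"{col}_mean"] = float(m[col].mean())
            row[f"{col}_sd"] = float(m[col].std(ddof=1)) if len(m) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def prop_with_synapse(spines: pd.DataFrame, dendrites: pd.DataFrame) -> dict[str, float]:
    """Fraction of spines housing a synapse, under both conventions.

    ``pooled`` is the ratio over all spines of the cohort; ``per_mouse_mean``
    averages the per-mouse ratios.  The two differ slightly whenever mice
    contribute unequal spine counts, so both are reported.
    """
    pooled = float(spines["has_synapse"].mean())
    sp = spines.merge(dendrites[["dendrite_id", "mouse_id"]], on="dendrite_id", validate="m:1")
    per_mouse = sp.groupby("mouse_id")["has_synapse"].mean()
    return {"pooled": pooled, "per_mouse_mean": float(per_mouse.mean())}


def dendrite_level_table(
    dendrites: pd.DataFrame, spines: pd.DataFrame, mice: pd.DataFrame
) -> pd.DataFrame:
    """Per-dendrite table joined with condition, ready for dendrite-level models."""
    t = per_dendrite_table(dendrites, spines).merge(mice, on="mouse_id", validate="m:1")
    t["dendrite_id"] = t["dendrite_id"].astype(str)
    return t


def spine_level_table(
    dendrites: pd.DataFrame, spines: pd.DataFrame, mice: pd.DataFrame
) -> pd.DataFrame:
    """Per-synapse table (measured ASIs only) for spine-level models."""
    grouped = spines["branch_group_id"].notna()
    group_size = spines.groupby("branch_group_id")["spine_id"].transform("size")
    sp = spines.assign(branched=(grouped & (group_size >= 2)))
    sp = sp[sp["asi_um2"].notna()].merge(
        dendrites[["dendrite_id", "mouse_id", "diameter_um"]], on="dendrite_id", validate="m:1"
    )
    sp = sp.merge(mice, on="mouse_id", validate="m:1")
    sp["dendrite_id"] = sp["dendrite_id"].astype(str)
    return sp
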