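"""Readers and writers: schema-mapped CSV tables and contour-stack JSON.

The published source tables use their own column headers; a
:class:`SchemaMap` translates them to the canonical names used throughout the
package so the files can be ingested without editing.  Contour stacks use a
small JSON dialect::

    {"object_id": ..., "object_kind": ..., "section_thickness_nm": ...,
     "xy_pixel_size_nm": ..., "contours": [{"section": k, "vertices": [[x, y], ...]}]}
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .census import ORGANELLE_COLUMNS, validate_tables
from .contours import Contour, ContourStack
from .errors import SchemaError

DENDRITE_REQUIRED = ("dendrite_id", "mouse_id", "surface_area_um2", "length_um", "diameter_um")
DENDRITE_OPTIONAL = ("condition", "is_terminal_branch")
SPINE_REQUIRED = ("spine_id", "dendrite_id", "has_synapse")
SPINE_OPTIONAL = (
    "branch_group_id",
    "head_protrusion_of",
    "oblique",
    "incomplete",
    "asi_um2",
    *ORGANELLE_COLUMNS,
    "presyn_fiber_id",
)

_BOOL_MAP = {
    "true": True, "false": False, "yes": True, "no": False, "1": True, "0": False,
    "1.0": True, "0.0": False, "t": True, "f": False,
}


@dataclass(frozen=True)
class SchemaMap:
    """Mapping from canonical column names to the file's column names.

    Identity by default; must be bijective on the required columns.
    """

    dendrites: Mapping[str, str] = field(default_factory=dict)
    spines: Mapping[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SchemaMap":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(dendrites=raw.get("dendrites", {}), spines=raw.get("spines", {}))

    def _check(self, mapping: Mapping[str, str], label: str) -> None:
        values = list(mapping.values())
        if len(set(values)) != len(values):
            raise SchemaError(f"{label} schema map is not injective: {mapping}")


def _rename(df: pd.DataFrame, mapping: Mapping[str, str], required: Iterable[str], label: str
            ) -> pd.DataFrame:
    inv = {file_col: canon for canon, file_col in mapping.items()}
    df = df.rename(columns=inv)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{label} table: missing required column(s) {missing}")
    return df


def _numeric(df: pd.DataFrame, col: str, label: str) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna() & df[col].notna()
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise SchemaError(f"{label} table: non-numeric value {df[col].iloc[idx]!r} in column "
                          f"{col!r} at row {idx}")
    return out


def _boolean(df: pd.DataFrame, col: str, label: str) -> pd.Series:
    s = df[col]
    if s.dtype == bool:
        return s
    out = s.astype(str).str.strip().str.lower().map(_BOOL_MAP)
    bad = out.isna() & s.notna()
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise SchemaError(f"{label} table: non-boolean value {s.iloc[idx]!r} in column "
                          f"{col!r} at row {idx}")
    return out.fillna(False).astype(bool)


def read_tables(
    dendrite_path: str | Path,
    spine_path: str | Path,
    schema: SchemaMap | None = None,
    validate: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read (mice, dendrites, spines) from the two CSV files.

    The mouse table is derived from the dendrite table's (mouse_id, condition)
    pairs.  Unmapped extra columns are preserved as passthrough.
    """
    schema = schema or SchemaMap()
    schema._check(schema.dendrites, "dendrite")
    schema._check(schema.spines, "spine")
    den = _rename(pd.read_csv(dendrite_path), schema.dendrites, DENDRITE_REQUIRED, "dendrite")
    sp = _rename(pd.read_csv(spine_path), schema.spines, SPINE_REQUIRED, "spine")
    if "condition" not in den.columns:
        raise SchemaError("dendrite table: missing required column(s) ['condition']")

    for col in ("surface_area_um2", "length_um", "diameter_um"):
        den[col] = _numeric(den, col, "dendrite")
    if (den["surface_area_um2"] <= 0).any():
        idx = int(np.flatnonzero(den["surface_area_um2"] <= 0)[0])
        raise SchemaError(f"dendrite table: non-positive surface area at row {idx}")
    den["dendrite_id"] = den["dendrite_id"].astype(str)
    den["mouse_id"] = den["mouse_id"].astype(str)
    if "is_terminal_branch" in den.columns:
        den["is_terminal_branch"] = _boolean(den, "is_terminal_branch", "dendrite")

    sp["spine_id"] = sp["spine_id"].astype(str)
    sp["dendrite_id"] = sp["dendrite_id"].astype(str)
    for col in ("has_synapse", "oblique", "incomplete", *ORGANELLE_COLUMNS):
        if col in sp.columns:
            sp[col] = _boolean(sp, col, "spine")
        else:
            sp[col] = False
    for col in ("branch_group_id", "head_protrusion_of", "presyn_fiber_id"):
        if col not in sp.columns:
            sp[col] = None
    if "asi_um2" in sp.columns:
        sp["asi_um2"] = _numeric(sp, "asi_um2", "spine")
    else:
        sp["asi_um2"] = np.nan

    mice = (
        den[["mouse_id", "condition"]].drop_duplicates().reset_index(drop=True)
    )
    if validate:
        validate_tables(den, sp, mice)
    return mice, den, sp


def write_tables(
    out_dir: str | Path,
    mice: pd.DataFrame,
    dendrites: pd.DataFrame,
    spines: pd.DataFrame,
) -> dict[str, Path]:
    """Write the three cohort tables as UTF-8 comma-separated CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    den = dendrites.merge(mice, on="mouse_id", validate="m:1")
    paths = {
        "mice": out / "mice.csv",
        "dendrites": out / "dendrites.csv",
        "spines": out / "spines.csv",
    }
    mice.to_csv(paths["mice"], index=False)
    den.to_csv(paths["dendrites"], index=False)
    spines.to_csv(paths["spines"], index=False)
    return paths


# ---------------------------------------------------------------------------
# contour stacks


def stack_to_dict(stack: ContourStack) -> dict:
    return {
        "object_id": stack.object_id,
        "object_kind": stack.object_kind,
        "section_thickness_nm": stack.section_thickness_nm,
        "xy_pixel_size_nm": stack.xy_pixel_size_nm,
        "contours": [
            {"section": int(c.section_index), "vertices": np.asarray(c.vertices).tolist()}
            for c in stack.contours
        ],
    }


def stack_from_dict(d: dict) -> ContourStack:
    return ContourStack(
        object_id=str(d["object_id"]),
        object_kind=d["object_kind"],
        contours=[
            Contour(int(c["section"]), np.asarray(c["vertices"], dtype=float))
            for c in d["contours"]
        ],
        section_thickness_nm=float(d.get("section_thickness_nm", 50.0)),
        xy_pixel_size_nm=float(d.get("xy_pixel_size_nm", 4.0)),
    )


def write_stacks(path: str | Path, stacks: Iterable[ContourStack]) -> None:
    Path(path).write_text(json.dumps([stack_to_dict(s) for s in stacks]))


def read_stacks(path: str | Path) -> list[ContourStack]:
    return [stack_from_dict(d) for d in json.loads(Path(path).read_text())]


def stacks_from_polygon_lists(
    polygons: Mapping[str, Mapping[int, list]],
    object_kind: str,
    section_thickness_nm: float = 50.0,
    xy_pixel_size_nm: float = 4.0,
) -> list[ContourStack]:
    """Convert ``{object_id: {section: [vertex list or list of vertex lists]}}``
    exports from generic segmentation tools into contour stacks."""
    out = []
    for oid, sections in polygons.items():
        contours = []
        for k, polys in sections.items():
            arr = np.asarray(polys, dtype=float)
            if arr.ndim == 2:  # single polygon
                contours.append(Contour(int(k), arr))
            else:
                contours.extend(Contour(int(k), np.asarray(p, dtype=float)) for p in polys)
        out.append(
            ContourStack(
                object_id=str(oid),
                object_kind=object_kind,  # type: ignore[arg-type]
                contours=contours,
                section_thickness_nm=section_thickness_nm,
                xy_pixel_size_nm=xy_pixel_size_nm,
            )
        )
    return out
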