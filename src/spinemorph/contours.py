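"""Serial-section contour geometry.

Objects reconstructed from serial block-face EM (dendritic shafts, spines,
axon-spine interfaces) arrive as stacks of closed planar polygons, one or more
per 50 nm section, with sub-pixel xy coordinates in nanometers.  This module
turns such stacks into the surface-area, length and diameter measurements the
downstream census and statistics operate on.

The central quantity is the *smoothed upper bound surface* (SUBS): every traced
element contributes its smoothed perimeter times the section thickness (half a
thickness for its top face, half for its bottom face), and consecutive elements
contribute the absolute difference of their areas as a step term::

    SUBS = sum_k [ Ps(top_k) * T/2 + Ps(bottom_k) * T/2 ] + sum_k |A_k - A_{k+1}|

For a quasi-two-dimensional interface sheet (the axon-spine interface, ASI,
traced one pixel wide on the spine-head side), the apposed surface is obtained
by subtracting the first and last element areas from SUBS and halving, which
removes the double-counting of the sheet's two faces::

    AS = (SUBS - A_first - A_last) / 2

All internal math is in nanometers; reporting helpers convert to um/um^2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from shapely.geometry import LinearRing

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

NM2_PER_UM2 = 1e6
NM_PER_UM = 1e3

ObjectKind = Literal["dendrite_shaft", "spine", "asi_sheet"]


@dataclass(frozen=True)
class SmoothingSpec:
    """Closed-curve vertex smoothing applied before perimeter measurement.

    A symmetric moving average over ``+-kernel_halfwidth`` neighbouring
    vertices with periodic boundary; ``kernel_halfwidth=0`` (or
    ``enabled=False``) is the identity.  The default halfwidth of 2 mimics the
    perimeter smoothing of the segmentation tool the traces come from.
    """

    enabled: bool = True
    kernel_halfwidth: int = 2

    def __post_init__(self) -> None:
        if self.kernel_halfwidth < 0:
            raise InvalidInputError("kernel_halfwidth must be >= 0")

    @property
    def is_identity(self) -> bool:
        return (not self.enabled) or self.kernel_halfwidth == 0


#: Smoothing disabled entirely; raw polygon perimeters.
NO_SMOOTHING = SmoothingSpec(enabled=False, kernel_halfwidth=0)


@dataclass(frozen=True)
class Contour:
    """One closed planar polygon on one section.

    ``vertices`` are (x, y) positions in nanometers, continuous (sub-pixel);
    the last vertex must not repeat the first.  ``section_index`` is 0-based;
    section ``k`` occupies z in ``[k*T, (k+1)*T)``.
    """

    section_index: int
    vertices: np.ndarray  # (n, 2) float64, nm
    closed: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise InvalidInputError("vertices must be an (n, 2) array")
        # drop an explicitly repeated closing vertex
        if len(v) > 1 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        object.__setattr__(self, "vertices", v)
        if self.section_index < 0:
            raise InvalidInputError("section_index must be >= 0")
        if self.closed and len(v) < 3:
            raise InvalidInputError("a closed contour needs at least 3 vertices")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def is_simple(self) -> bool:
        """True when the polygon does not self-intersect (degenerate rings pass)."""
        try:
            return LinearRing(self.vertices).is_simple
        except Exception:
            # collinear / zero-area rings: treat as degenerate-but-simple
            return True


@dataclass
class ContourStack:
    """All contours of one 3D object, ordered by section.

    Multiple contours may share a section (in-plane branching); their
    perimeters and areas are summed per section.  Section indices must be
    non-decreasing; gaps (untraced sections) are tolerated and logged.
    """

    object_id: str
    object_kind: ObjectKind
    contours: list[Contour]
    section_thickness_nm: float = 50.0
    xy_pixel_size_nm: float = 4.0
    _gap_count: int = field(default=0, repr=False)

    def __post_init__(self) -> None:
        if not self.contours:
            raise InvalidInputError(f"{self.object_id}: stack has no contours")
        if self.section_thickness_nm <= 0:
            raise InvalidInputError("section_thickness_nm must be > 0")
        if self.xy_pixel_size_nm <= 0:
            raise InvalidInputError("xy_pixel_size_nm must be > 0")
        self.contours = sorted(self.contours, key=lambda c: c.section_index)
        for c in self.contours:
            if not c.closed:
                raise InvalidInputError(f"{self.object_id}: open contour in stack")
        sections = self.section_indices
        gaps = np.diff(sections) - 1
        self._gap_count = int((gaps > 0).sum())
        if self._gap_count:
            logger.warning(
                "%s: %d gap(s) in section coverage; bridged with mean-perimeter slabs",
                self.object_id,
                self._gap_count,
            )

    @property
    def section_indices(self) -> np.ndarray:
        """Sorted unique section indices present in the stack."""
        return np.unique([c.section_index for c in self.contours])

    @property
    def n_sections(self) -> int:
        return len(self.section_indices)

    @property
    def gap_count(self) -> int:
        return self._gap_count

    def grouped(self) -> list[list[Contour]]:
        """Contours grouped per section, in section order."""
        out: dict[int, list[Contour]] = {}
        for c in self.contours:
            out.setdefault(c.section_index, []).append(c)
        return [out[k] for k in sorted(out)]


# ---------------------------------------------------------------------------
# per-contour measures


def smooth_vertices(vertices: np.ndarray, halfwidth: int) -> np.ndarray:
    """Symmetric periodic moving average of the vertex chain (both coordinates)."""
    if halfwidth == 0:
        return np.asarray(vertices, dtype=float)
    return uniform_filter1d(
        np.asarray(vertices, dtype=float), size=2 * halfwidth + 1, axis=0, mode="wrap"
    )


def _ring_length(vertices: np.ndarray) -> float:
    d = np.diff(np.vstack([vertices, vertices[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def smoothed_perimeter(contour: Contour, spec: SmoothingSpec = SmoothingSpec()) -> float:
    """Perimeter (nm) of the contour after vertex smoothing.

    With smoothing disabled this is the raw polygon perimeter.
    """
    if not contour.closed:
        raise InvalidInputError("perimeter requires a closed contour")
    if contour.n_vertices < 3:
        raise InvalidInputError("perimeter requires >= 3 vertices")
    v = contour.vertices
    if not spec.is_identity:
        v = smooth_vertices(v, spec.kernel_halfwidth)
    return _ring_length(v)


def polygon_area(contour: Contour) -> float:
    """Nonnegative shoelace area (nm^2), independent of winding direction."""
    if not contour.closed:
        raise InvalidInputError("area requires a closed contour")
    x, y = contour.vertices[:, 0], contour.vertices[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def _section_measures(
    stack: ContourStack, spec: SmoothingSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-section (sections, summed smoothed perimeter, summed area)."""
    sections, peri, area = [], [], []
    for group in stack.grouped():
        sections.append(group[0].section_index)
        peri.append(sum(smoothed_perimeter(c, spec) for c in group))
        area.append(sum(polygon_area(c) for c in group))
    return np.asarray(sections), np.asarray(peri), np.asarray(area)


# ---------------------------------------------------------------------------
# stack-level surfaces


def smoothed_upper_bound_surface(
    stack: ContourStack, spec: SmoothingSpec = SmoothingSpec()
) -> float:
    """Total surface area (nm^2) of the stack by the upper-bound accumulation.

    Every traced element contributes ``Ps * T`` (half a thickness for each of
    its faces) plus the absolute area difference to the next element.  A gap of
    ``g`` sections between consecutive elements bridges the missing
    ``(g - 1) * T`` of slab with the mean of the two flanking perimeters.
    """
    T = stack.section_thickness_nm
    sections, peri, area = _section_measures(stack, spec)
    total = float(peri.sum()) * T
    if len(sections) > 1:
        total += float(np.abs(np.diff(area)).sum())
        gaps = np.diff(sections) - 1
        if (gaps > 0).any():
            bridge = gaps * T * (peri[:-1] + peri[1:]) / 2.0
            total += float(bridge[gaps > 0].sum())
    return total


def apposed_surface(stack: ContourStack, spec: SmoothingSpec = SmoothingSpec()) -> float:
    """Apposed surface (nm^2) of a quasi-2D interface sheet.

    ``AS = (SUBS - A_first - A_last) / 2``; negative results (possible only for
    degenerate traces) are clamped to 0 with a logged warning.
    """
    if stack.object_kind != "asi_sheet":
        raise InvalidInputError(
            f"{stack.object_id}: apposed_surface expects an asi_sheet stack"
        )
    _, _, area = _section_measures(stack, spec)
    asv = (smoothed_upper_bound_surface(stack, spec) - area[0] - area[-1]) / 2.0
    if asv < 0:
        logger.warning("%s: negative apposed surface %.3g clamped to 0", stack.object_id, asv)
        return 0.0
    return float(asv)


def dendrite_surface_area(
    stack: ContourStack, spec: SmoothingSpec = SmoothingSpec()
) -> float:
    """Shaft surface area in um^2 (SUBS, endcaps excluded, spines not included)."""
    if stack.object_kind != "dendrite_shaft":
        raise InvalidInputError(
            f"{stack.object_id}: dendrite_surface_area expects a dendrite_shaft stack"
        )
    if stack.n_sections < 2:
        raise InvalidInputError("dendrite_surface_area needs >= 2 sections")
    return smoothed_upper_bound_surface(stack, spec) / NM2_PER_UM2


def dendrite_length_and_diameter(stack: ContourStack) -> tuple[float, float]:
    """(length_um, diameter_um) of a shaft stack.

    Length is the 3D arc length of the per-section area-weighted centroid
    polyline (z step = section gap times T), extrapolated by half a step at
    each end so that n co-axial sections span ``n * T``; diameter is that of
    the circle with the mean per-section cross-sectional area.
    """
    if stack.object_kind != "dendrite_shaft":
        raise InvalidInputError(
            f"{stack.object_id}: length/diameter expects a dendrite_shaft stack"
        )
    if stack.n_sections < 2:
        raise InvalidInputError("length/diameter needs >= 2 sections")
    T = stack.section_thickness_nm
    sections, cx, cy, areas = [], [], [], []
    for group in stack.grouped():
        a = np.array([polygon_area(c) for c in group])
        cents = np.array([c.vertices.mean(axis=0) for c in group])
        if a.sum() > 0:
            cent = (cents * a[:, None]).sum(axis=0) / a.sum()
        else:  # degenerate: plain vertex mean
            cent = cents.mean(axis=0)
        sections.append(group[0].section_index)
        cx.append(cent[0])
        cy.append(cent[1])
        areas.append(a.sum())
    z = np.asarray(sections, dtype=float) * T
    dx, dy, dz = np.diff(cx), np.diff(cy), np.diff(z)
    steps = np.sqrt(dx**2 + dy**2 + dz**2)
    # half-step extrapolation at both ends: n co-axial sections -> n*T
    length_nm = float(steps.sum() + 0.5 * (steps[0] + steps[-1]))
    mean_area = float(np.mean(areas))
    diameter_nm = 2.0 * math.sqrt(mean_area / math.pi)
    return length_nm / NM_PER_UM, diameter_nm / NM_PER_UM


def measure_stack(
    stack: ContourStack, spec: SmoothingSpec = SmoothingSpec()
) -> dict[str, float | str | None]:
    """One-row summary used by the pipeline's surface stage (um / um^2 units)."""
    row: dict[str, float | str | None] = {
        "object_id": stack.object_id,
        "object_kind": stack.object_kind,
        "surface_um2": smoothed_upper_bound_surface(stack, spec) / NM2_PER_UM2,
        "asi_um2": None,
        "length_um": None,
        "diameter_um": None,
    }
    if stack.object_kind == "asi_sheet":
        row["asi_um2"] = apposed_surface(stack, spec) / NM2_PER_UM2
    if stack.object_kind == "dendrite_shaft" and stack.n_sections >= 2:
        length, diam = dendrite_length_and_diameter(stack)
        row["surface_um2"] = dendrite_surface_area(stack, spec)
        row["length_um"] = length
        row["diameter_um"] = diam
    return row
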