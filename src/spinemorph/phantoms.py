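"""Geometric phantoms with known analytic surfaces.

Contour stacks for shapes whose surface area, length and diameter are known in
closed form, used to validate the serial-section surface estimators.  All
dimensions in nanometers; section ``k`` spans z in ``[k*T, (k+1)*T)`` and the
contour of section ``k`` is drawn at the slab centre ``(k + 1/2) * T``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .contours import Contour, ContourStack
from .errors import InvalidInputError

PhantomShape = Literal["cylinder", "sphere", "sheet", "tilted_sheet"]


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of one phantom stack.

    dimensions_nm:
      cylinder     -- {"radius", "n_sections"}
      sphere       -- {"radius"}
      sheet        -- {"length", "width", "n_sections"}
      tilted_sheet -- {"length", "width", "n_sections", "tilt_deg"}
    jitter_nm adds seeded iid Gaussian noise to every vertex.
    """

    shape: PhantomShape
    dimensions_nm: dict[str, float] = field(default_factory=dict)
    section_thickness_nm: float = 50.0
    n_vertices: int = 256
    jitter_nm: float = 0.0
    seed: int = 0

    def dim(self, key: str, default: float | None = None) -> float:
        if key in self.dimensions_nm:
            return float(self.dimensions_nm[key])
        if default is None:
            raise InvalidInputError(f"phantom {self.shape}: missing dimension {key!r}")
        return default


def _circle(radius: float, center: tuple[float, float], n: int) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)]
    )


def _thin_rect(length: float, width: float, x0: float = 0.0) -> np.ndarray:
    return np.array(
        [
            [x0, 0.0],
            [x0 + width, 0.0],
            [x0 + width, length],
            [x0, length],
        ]
    )


def generate_phantom(spec: PhantomSpec) -> ContourStack:
    """Build the contour stack for one phantom."""
    T = spec.section_thickness_nm
    rng = np.random.default_rng(spec.seed)
    contours: list[Contour] = []

    if spec.shape == "cylinder":
        r = spec.dim("radius")
        n_sec = int(spec.dim("n_sections"))
        if r <= 0 or n_sec < 1:
            raise InvalidInputError("cylinder needs radius > 0 and n_sections >= 1")
        drift = spec.dim("drift_per_section", 0.0)  # optional x-shift per section
        for k in range(n_sec):
            contours.append(Contour(k, _circle(r, (k * drift, 0.0), spec.n_vertices)))
        kind = "dendrite_shaft"

    elif spec.shape == "sphere":
        r = spec.dim("radius")
        if r <= 0:
            raise InvalidInputError("sphere needs radius > 0")
        n_sec = int(math.floor(2.0 * r / T))
        for k in range(n_sec):
            z = (k + 0.5) * T - r  # slab centre relative to sphere centre
            rho2 = r * r - z * z
            if rho2 <= 0:
                continue
            contours.append(Contour(k, _circle(math.sqrt(rho2), (0.0, 0.0), spec.n_vertices)))
        kind = "spine"

    elif spec.shape in ("sheet", "tilted_sheet"):
        length = spec.dim("length")
        width = spec.dim("width", 4.0)  # 1-pixel trace by default
        n_sec = int(spec.dim("n_sections"))
        tilt = math.radians(spec.dim("tilt_deg", 0.0)) if spec.shape == "tilted_sheet" else 0.0
        shift = T * math.tan(tilt)
        for k in range(n_sec):
            contours.append(Contour(k, _thin_rect(length, width, x0=k * shift)))
        kind = "asi_sheet"

    else:
        raise InvalidInputError(f"unknown phantom shape {spec.shape!r}")

    if spec.jitter_nm > 0:
        contours = [
            Contour(c.section_index, c.vertices + rng.normal(0.0, spec.jitter_nm, c.vertices.shape))
            for c in contours
        ]

    return ContourStack(
        object_id=f"phantom_{spec.shape}",
        object_kind=kind,  # type: ignore[arg-type]
        contours=contours,
        section_thickness_nm=T,
    )


def sphere_subs_analytic(radius: float, section_thickness_nm: float) -> float:
    """Analytic limit of SUBS for the sphere phantom (disk-stack accumulation).

    Sums the exact per-slab perimeter and |dA| contributions of the disk stack
    the phantom discretizes, i.e. the staircase surface the upper-bound formula
    measures -- NOT the smooth sphere area 4*pi*r^2 (which it exceeds by
    ~(pi+2)/4).
    """
    T = section_thickness_nm
    r = radius
    n_sec = int(math.floor(2.0 * r / T))
    zs = (np.arange(n_sec) + 0.5) * T - r
    rho2 = np.clip(r * r - zs * zs, 0.0, None)
    rho = np.sqrt(rho2)
    keep = rho > 0
    peri = 2.0 * math.pi * rho[keep]
    area = math.pi * rho2[keep]
    return float(peri.sum() * T + np.abs(np.diff(area)).sum())
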