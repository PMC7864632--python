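"""Solvent-accessible surface area and buried interface area.

Shrake-Rupley style numerical SASA: each atom carries a near-uniform set of
test points on its solvent-expanded sphere (radius + probe); points falling
inside any neighboring expanded sphere are occluded, and the accessible
fraction times the sphere area gives the atom's SASA.

The interface area between two disjoint selections A and B is the standard
buried-surface half-sum (SASA_A + SASA_B − SASA_AB) / 2, computed by default
on the A∪B atoms in isolation.  This is a generic buried-SASA measure, not a
re-implementation of any particular interface server's algorithm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .model import CoordinateSet, EnsembleSet

__all__ = [
    "VDW_RADII",
    "InterfaceReport",
    "sphere_points",
    "sasa",
    "interface",
    "interface_track",
]

VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "P": 1.8, "S": 1.8, "H": 1.2}
FALLBACK_RADIUS = 1.8
DEFAULT_PROBE = 1.4
DEFAULT_POINTS = 960


@dataclass
class InterfaceReport:
    name_a: str
    name_b: str
    sasa_a: float
    sasa_b: float
    sasa_ab: float
    interface_area: float  # (sasa_a + sasa_b − sasa_ab) / 2, Å²
    probe_radius: float
    points_per_atom: int

    def __post_init__(self) -> None:
        assert self.sasa_ab <= self.sasa_a + self.sasa_b + 1e-6


def sphere_points(n: int) -> np.ndarray:
    """n near-uniform unit-sphere points (golden-spiral / Fibonacci lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _radii(elements, allow_fallback: bool = True) -> np.ndarray:
    out = np.empty(len(elements))
    for i, e in enumerate(elements):
        r = VDW_RADII.get(e)
        if r is None:
            if not allow_fallback:
                raise ValueError(f"unknown element {e!r} and fallback disabled")
            warnings.warn(f"unknown element {e!r}: using fallback radius {FALLBACK_RADIUS} Å")
            r = FALLBACK_RADIUS
        out[i] = r
    return out


def sasa(
    coords: np.ndarray,
    elements,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
    radii: dict[str, float] | None = None,
    allow_fallback: bool = True,
) -> tuple[np.ndarray, float]:
    """Per-atom and total solvent-accessible surface area in Å²."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (n, 3)")
    table = dict(VDW_RADII)
    if radii:
        table.update(radii)
    r = np.empty(len(elements))
    for i, e in enumerate(elements):
        v = table.get(e)
        if v is None:
            if not allow_fallback:
                raise ValueError(f"unknown element {e!r} and fallback disabled")
            warnings.warn(f"unknown element {e!r}: using fallback radius {FALLBACK_RADIUS} Å")
            v = FALLBACK_RADIUS
        r[i] = v
    expanded = r + probe
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    areas = np.empty(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + expanded[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], max_reach) if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            exposed &= d2 > expanded[j] ** 2
        areas[i] = exposed.mean() * 4.0 * math.pi * expanded[i] ** 2
    return areas, float(areas.sum())


def interface(
    set_a: CoordinateSet,
    set_b: CoordinateSet,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
    context: CoordinateSet | None = None,
) -> InterfaceReport:
    """Buried-SASA interface area between two disjoint selections.

    By default the calculation sees only the A∪B atoms; pass ``context`` to
    include surrounding atoms in the occlusion environment of both terms.
    Overlapping selections are an error.
    """
    overlap = set(set_a.keys) & set(set_b.keys)
    if overlap:
        raise ValueError(f"selections overlap on {len(overlap)} atoms, e.g. {sorted(overlap)[:3]}")

    ctx = [context] if context is not None else []

    areas_a, _ = sasa(
        np.vstack([set_a.coords] + [c.coords for c in ctx]),
        list(set_a.elements) + [e for c in ctx for e in c.elements],
        probe=probe, n_points=n_points,
    )
    sasa_a = float(areas_a[: len(set_a)].sum())
    areas_b, _ = sasa(
        np.vstack([set_b.coords] + [c.coords for c in ctx]),
        list(set_b.elements) + [e for c in ctx for e in c.elements],
        probe=probe, n_points=n_points,
    )
    sasa_b = float(areas_b[: len(set_b)].sum())
    areas_ab, _ = sasa(
        np.vstack([set_a.coords, set_b.coords] + [c.coords for c in ctx]),
        list(set_a.elements) + list(set_b.elements) + [e for c in ctx for e in c.elements],
        probe=probe, n_points=n_points,
    )
    sasa_ab = float(areas_ab[: len(set_a) + len(set_b)].sum())

    buried = (sasa_a + sasa_b - sasa_ab) / 2.0
    if buried < -0.5:
        raise ValueError(f"interface area {buried:.2f} Å² below the numerical floor")
    if buried < 0.0:
        warnings.warn(f"clamping slightly negative interface area {buried:.3f} Å² to 0")
        buried = 0.0
    return InterfaceReport(
        name_a=set_a.selection_name,
        name_b=set_b.selection_name,
        sasa_a=sasa_a,
        sasa_b=sasa_b,
        sasa_ab=sasa_ab,
        interface_area=buried,
        probe_radius=probe,
        points_per_atom=n_points,
    )


def interface_track(
    ensemble: EnsembleSet,
    selection_a: str,
    selection_b: str,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
) -> tuple[dict[str, InterfaceReport], float, float, str]:
    """Interface area per state plus (mean, max, argmax state label)."""
    reports: dict[str, InterfaceReport] = {}
    for label in ensemble.labels:
        a = ensemble.resolve(label, selection_a)
        b = ensemble.resolve(label, selection_b)
        reports[label] = interface(a, b, probe=probe, n_points=n_points)
    values = {lab: r.interface_area for lab, r in reports.items()}
    mean = float(np.mean(list(values.values())))
    argmax = max(values, key=values.get)
    return reports, mean, values[argmax], argmax
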