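"""Solvent-accessibility features from a native Shrake-Rupley surface.

A probe sphere (default radius 1.4 Å) is rolled over the van-der-Waals
spheres of the heavy atoms by deterministic point sampling (a golden-
spiral lattice, default 960 points per atom).  The same sampled surface
serves four features:

* per-atom and per-residue solvent-accessible surface area (SASA);
* relative solvent accessibility (RSA): residue SASA divided by a
  residue-type maximum accessible area, capped at 1.0;
* residue depth: mean distance of a residue's heavy atoms to the
  exposed-surface point cloud (a solvent-accessible-surface analogue of
  the classical solvent-excluded-surface depth; the difference is a
  constant-order offset);
* buried surface area: SASA(A) + SASA(B) - SASA(A u B).

The module also houses the per-structure min-max normalizer used to map
depth, coordination-number, and protrusion columns into [0, 1].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import Atom, Chain, Residue, Structure

__all__ = [
    "SasaParams",
    "SasaResult",
    "NormalizationSpec",
    "MAX_ASA_TIEN",
    "DEFAULT_VDW_RADII",
    "unit_sphere_points",
    "shrake_rupley_sasa",
    "relative_solvent_accessibility",
    "residue_depth",
    "residue_depths",
    "buried_surface_area",
    "minmax_normalize",
]

#: Van-der-Waals radii (Å) for the elements common in protein structures.
DEFAULT_VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "SE": 1.90,
    "P": 1.80,
    "H": 1.20,
    "D": 1.20,
}

#: Theoretical maximum accessible surface areas (Å^2) per residue type
#: (Tien et al. 2013, theoretical set), used to normalize RSA.
MAX_ASA_TIEN: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


@dataclass
class SasaParams:
    probe_radius: float = 1.4  # Å
    n_sphere_points: int = 960
    radii_table: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VDW_RADII)
    )
    default_radius: float = 1.8  # Å, for elements missing from the table

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise ValueError("probe_radius must be positive")
        if self.n_sphere_points < 92:
            raise ValueError("n_sphere_points must be at least 92")

    def radius_of(self, element: str) -> float:
        key = element.upper()
        if key in self.radii_table:
            return self.radii_table[key]
        warnings.warn(
            f"no van-der-Waals radius for element {element!r}; "
            f"using default {self.default_radius} Å",
            stacklevel=2,
        )
        return self.default_radius


@dataclass
class SasaResult:
    """Per-atom SASA plus (optionally) the exposed surface point cloud."""

    atoms: list[Atom]
    areas: np.ndarray  # Å^2, aligned with `atoms`
    params: SasaParams
    exposed_points: np.ndarray | None = None  # (M, 3) Å

    def __post_init__(self) -> None:
        self._area_by_id = {id(a): float(s) for a, s in zip(self.atoms, self.areas)}

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def atom_area(self, atom: Atom) -> float:
        return self._area_by_id[id(atom)]

    def residue_area(self, residue: Residue) -> float:
        return sum(
            self._area_by_id[id(a)]
            for a in residue.heavy_atoms()
            if id(a) in self._area_by_id
        )


def unit_sphere_points(n: int) -> np.ndarray:
    """n deterministic, near-uniform points on the unit sphere
    (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def _collect_heavy_atoms(obj) -> list[Atom]:
    if isinstance(obj, (Structure, Chain)):
        return obj.heavy_atoms()
    if isinstance(obj, Residue):
        return obj.heavy_atoms()
    return [a for a in obj if not a.is_hydrogen]


def shrake_rupley_sasa(
    structure,
    params: SasaParams | None = None,
    keep_points: bool = False,
) -> SasaResult:
    """Shrake-Rupley SASA over the heavy atoms of a structure, chain,
    or atom list.

    Each atom's sphere of radius ``vdW + probe`` is sampled with
    ``n_sphere_points`` points; a point is exposed when no other atom's
    probe-extended sphere contains it.  ``keep_points`` additionally
    returns the exposed points (the accessible-surface cloud used by
    :func:`residue_depth`).
    """
    if params is None:
        params = SasaParams()
    atoms = _collect_heavy_atoms(structure)
    n = len(atoms)
    areas = np.zeros(n)
    if n == 0:
        return SasaResult(atoms, areas, params,
                          np.empty((0, 3)) if keep_points else None)

    coords = np.array([a.coords for a in atoms])
    radii = np.array([params.radius_of(a.element) for a in atoms]) + params.probe_radius
    unit = unit_sphere_points(params.n_sphere_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    exposed_clouds: list[np.ndarray] = []

    for i in range(n):
        pts = coords[i] + radii[i] * unit
        neighbor_idx = [
            j for j in tree.query_ball_point(coords[i], radii[i] + max_r)
            if j != i
            and np.linalg.norm(coords[j] - coords[i]) < radii[i] + radii[j]
        ]
        exposed = np.ones(len(pts), dtype=bool)
        for j in neighbor_idx:
            exposed &= np.linalg.norm(pts - coords[j], axis=1) >= radii[j]
        frac = exposed.mean()
        areas[i] = 4.0 * math.pi * radii[i] ** 2 * frac
        if keep_points and exposed.any():
            exposed_clouds.append(pts[exposed])

    cloud = None
    if keep_points:
        cloud = (
            np.concatenate(exposed_clouds) if exposed_clouds else np.empty((0, 3))
        )
    return SasaResult(atoms, areas, params, cloud)


def relative_solvent_accessibility(
    residue: Residue,
    sasa: SasaResult,
    table: dict[str, float] | None = None,
) -> float:
    """Residue SASA over its maximum accessible area, capped at 1.0.

    NaN (with a warning) for residue types missing from the table.
    """
    if table is None:
        table = MAX_ASA_TIEN
    max_asa = table.get(residue.name3)
    if max_asa is None:
        warnings.warn(
            f"residue {residue.name3!r} has no maximum-ASA constant; RSA is NaN",
            stacklevel=2,
        )
        return float("nan")
    return min(sasa.residue_area(residue) / max_asa, 1.0)


def residue_depth(
    residue: Residue,
    surface,
    params: SasaParams | None = None,
) -> float:
    """Mean distance (Å) of a residue's heavy atoms to the accessible
    surface.

    ``surface`` may be a :class:`SasaResult` computed with
    ``keep_points=True`` or a structure (in which case the surface is
    computed here).  Returns NaN for residues without heavy atoms or for
    degenerate structures with an empty surface.
    """
    if not isinstance(surface, SasaResult):
        surface = shrake_rupley_sasa(surface, params, keep_points=True)
    points = surface.exposed_points
    if points is None:
        raise ValueError("surface must be computed with keep_points=True")
    atoms = residue.heavy_atoms()
    if not atoms:
        return float("nan")
    if len(points) == 0:
        warnings.warn("empty accessible surface; residue depth is NaN", stacklevel=2)
        return float("nan")
    tree = cKDTree(points)
    dists, _ = tree.query(np.array([a.coords for a in atoms]))
    return float(np.mean(dists))


def residue_depths(
    structure: Structure,
    params: SasaParams | None = None,
    surface: SasaResult | None = None,
) -> dict[tuple, float]:
    """Depth for every residue of a structure against one shared surface."""
    if surface is None:
        surface = shrake_rupley_sasa(structure, params, keep_points=True)
    points = surface.exposed_points
    depths: dict[tuple, float] = {}
    if points is None or len(points) == 0:
        warnings.warn("empty accessible surface; all depths are NaN", stacklevel=2)
        return {r.key: float("nan") for c in structure.chains for r in c.residues}
    tree = cKDTree(points)
    for chain in structure.chains:
        for res in chain.residues:
            atoms = res.heavy_atoms()
            if not atoms:
                depths[res.key] = float("nan")
                continue
            dists, _ = tree.query(np.array([a.coords for a in atoms]))
            depths[res.key] = float(np.mean(dists))
    return depths


def buried_surface_area(
    chain_a,
    chain_b,
    params: SasaParams | None = None,
) -> float:
    """SASA(A) + SASA(B) - SASA(A u B), clamped at zero."""
    atoms_a = _collect_heavy_atoms(chain_a)
    atoms_b = _collect_heavy_atoms(chain_b)
    if not atoms_a or not atoms_b:
        raise ValueError("both chains must contain heavy atoms")
    sasa_a = shrake_rupley_sasa(atoms_a, params).total_area
    sasa_b = shrake_rupley_sasa(atoms_b, params).total_area
    sasa_ab = shrake_rupley_sasa(atoms_a + atoms_b, params).total_area
    return max(sasa_a + sasa_b - sasa_ab, 0.0)


@dataclass
class NormalizationSpec:
    """Min-max mapping of an observed range [b, t] onto [l, u]."""

    l: float = 0.0
    u: float = 1.0
    b: float | None = None
    t: float | None = None

    def __post_init__(self) -> None:
        if self.l >= self.u:
            raise ValueError("lower bound must be below upper bound")
        if self.b is not None and self.t is not None and self.b > self.t:
            raise ValueError("observed minimum exceeds observed maximum")


def minmax_normalize(values, spec: NormalizationSpec | None = None) -> np.ndarray:
    """Structure-specific min-max normalization with NaN passthrough.

    The observed bounds ``b, t`` are taken from the spec when provided,
    otherwise from the non-NaN values.  A degenerate column (b == t)
    maps every value to ``l``; an all-NaN column is returned unchanged
    with a warning.
    """
    if spec is None:
        spec = NormalizationSpec()
    x = np.asarray(values, dtype=float).copy()
    finite = ~np.isnan(x)
    if not finite.any():
        warnings.warn("all-NaN column left unnormalized", stacklevel=2)
        return x
    b = spec.b if spec.b is not None else float(x[finite].min())
    t = spec.t if spec.t is not None else float(x[finite].max())
    if t == b:
        x[finite] = spec.l
        return x
    x[finite] = (x[finite] - b) / (t - b) * (spec.u - spec.l) + spec.l
    return x
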