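"""Geometric residue descriptors.

Four purely geometric feature families:

* the amide-plane normal vector ``(x_CA - x_CB) x (x_CB - x_N)``,
  returned unnormalized, NaN for residues without a beta carbon;
* the Gaussian significance score ``s = exp(-d^2 / (2 sigma^2))`` of an
  inter-residue minimum heavy-atom distance ``d``, and the coordination
  number counting neighbors whose score exceeds the significance
  threshold ``st``;
* the half-sphere amino-acid composition (HSAAC): neighbor-type
  compositions split into the half-spaces along and against the
  side-chain axis (CB - CA, with an idealized pseudo-CB for glycine);
* the protrusion index: per-atom fraction of a 10 Å sphere not occupied
  by protein atoms, summarized per residue by six statistics.

All distances use heavy atoms only.  Neighbor searches are brute-force
NumPy reductions -- fixture-scale inputs make acceleration unnecessary,
and exactness against the double-loop definition is part of the contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structure import HSAAC_ALPHABET, Atom, Residue

__all__ = [
    "SignificanceParams",
    "HalfSphereParams",
    "ProtrusionParams",
    "amide_normal_vector",
    "significance_score",
    "min_heavy_atom_distance",
    "coordination_number",
    "side_chain_axis",
    "half_sphere_partition",
    "hsaac",
    "protrusion_index",
]

NAN3 = np.full(3, np.nan)


@dataclass
class SignificanceParams:
    """Parameters of the Gaussian significance score.

    ``st`` is the significance threshold (default 1e-3).  ``sigma`` is the
    Gaussian length scale in Å; by default it equals ``st`` (the literal
    published parameterization, under which essentially no residue pair
    at physical distances is significant).  Exposing ``sigma``
    independently gives a practical mode without changing the default.
    """

    st: float = 1e-3
    sigma: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.st < 1.0:
            raise ValueError(f"st must lie in (0, 1), got {self.st}")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    @property
    def effective_sigma(self) -> float:
        return self.st if self.sigma is None else self.sigma


@dataclass
class HalfSphereParams:
    radius: float = 8.0  # Å; standard half-sphere-exposure radius
    norm: str = "L1"
    alphabet: str = HSAAC_ALPHABET

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.norm not in {"L1", "L2"}:
            raise ValueError(f"norm must be 'L1' or 'L2', got {self.norm!r}")
        if len(self.alphabet) != 21:
            raise ValueError("alphabet must have exactly 21 symbols")


@dataclass
class ProtrusionParams:
    sphere_radius: float = 10.0  # Å
    atom_volume: float = 20.1  # Å^3, mean heavy-atom volume (CX convention)

    def __post_init__(self) -> None:
        if self.sphere_radius <= 0 or self.atom_volume <= 0:
            raise ValueError("sphere_radius and atom_volume must be positive")

    @property
    def sphere_volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.sphere_radius**3


def amide_normal_vector(residue: Residue) -> np.ndarray:
    """Unnormalized cross product (CA - CB) x (CB - N); NaN triple if any
    of the three atoms is missing (e.g. glycine has no CB)."""
    ca, cb, n = residue.get_atom("CA"), residue.get_atom("CB"), residue.get_atom("N")
    if ca is None or cb is None or n is None:
        return NAN3.copy()
    return np.cross(ca.coords - cb.coords, cb.coords - n.coords)


def significance_score(d: float, params: SignificanceParams | None = None) -> float:
    """Gaussian significance of a distance d >= 0 (Å); 1 iff d == 0."""
    if params is None:
        params = SignificanceParams()
    if d < 0:
        raise ValueError(f"distance must be non-negative, got {d}")
    sigma = params.effective_sigma
    return float(np.exp(-(d**2) / (2.0 * sigma**2)))


def min_heavy_atom_distance(res_a: Residue, res_b: Residue) -> float:
    """Minimum distance between any heavy atoms of two residues."""
    a = np.array([at.coords for at in res_a.heavy_atoms()])
    b = np.array([at.coords for at in res_b.heavy_atoms()])
    if a.size == 0 or b.size == 0:
        return math.inf
    return float(cdist(a, b).min())


def coordination_number(
    residue: Residue,
    all_residues: list[Residue],
    params: SignificanceParams | None = None,
) -> int:
    """Number of other residues whose significance score exceeds ``st``.

    The distance entering the score is the minimum heavy-atom distance
    between the residue pair; the residue never counts itself.
    """
    if params is None:
        params = SignificanceParams()
    count = 0
    for other in all_residues:
        if other is residue:
            continue
        d = min_heavy_atom_distance(residue, other)
        if math.isfinite(d) and significance_score(d, params) > params.st:
            count += 1
    return count


# Idealized tetrahedral CB placement from backbone N, CA, C (used for
# glycine, which has no real beta carbon).
_PSEUDO_CB_COEFF = (-0.58273431, 0.56802827, -0.54067466)


def pseudo_cb_coords(residue: Residue) -> np.ndarray | None:
    n, ca, c = residue.get_atom("N"), residue.get_atom("CA"), residue.get_atom("C")
    if n is None or ca is None or c is None:
        return None
    b = ca.coords - n.coords
    c_v = c.coords - ca.coords
    a = np.cross(b, c_v)
    ka, kb, kc = _PSEUDO_CB_COEFF
    return ka * a + kb * b + kc * c_v + ca.coords


def side_chain_axis(residue: Residue) -> np.ndarray | None:
    """Side-chain direction u = CB - CA (pseudo-CB for glycine).

    Returns None when the axis is undefined (no CA, or no CB and the
    backbone is too incomplete for the tetrahedral construction).
    """
    ca = residue.get_atom("CA")
    if ca is None:
        return None
    cb = residue.get_atom("CB")
    if cb is not None:
        return cb.coords - ca.coords
    pseudo = pseudo_cb_coords(residue)
    if pseudo is None:
        return None
    return pseudo - ca.coords


def half_sphere_partition(
    residue: Residue,
    neighbor: Residue,
    params: HalfSphereParams | None = None,
) -> str:
    """Classify a neighbor as 'UP', 'DOWN', or 'OUT' relative to the
    residue's side-chain axis; CA-CA distance beyond the radius is OUT,
    a boundary dot product of zero counts as UP."""
    if params is None:
        params = HalfSphereParams()
    ca = residue.get_atom("CA")
    n_ca = neighbor.get_atom("CA")
    axis = side_chain_axis(residue)
    if ca is None or n_ca is None or axis is None:
        return "OUT"
    delta = n_ca.coords - ca.coords
    if float(np.linalg.norm(delta)) > params.radius:
        return "OUT"
    return "UP" if float(np.dot(axis, delta)) >= 0.0 else "DOWN"


def hsaac(
    residue: Residue,
    all_residues: list[Residue],
    params: HalfSphereParams | None = None,
) -> np.ndarray:
    """Half-sphere amino-acid composition: a 1x42 vector.

    Entries 0-20 are the normalized composition of neighbor residue
    types in the upward half-sphere (along the side chain), entries
    21-41 the downward composition; slot 20 of each half collects types
    outside the 20-letter alphabet.  Empty halves stay all-zero; a
    residue without a CA (or a definable axis) gets a 1x42 NaN vector.
    """
    if params is None:
        params = HalfSphereParams()
    if residue.get_atom("CA") is None or side_chain_axis(residue) is None:
        return np.full(42, np.nan)
    up = np.zeros(21)
    down = np.zeros(21)
    for other in all_residues:
        if other is residue:
            continue
        part = half_sphere_partition(residue, other, params)
        if part == "OUT":
            continue
        idx = params.alphabet.find(other.one_letter)
        if idx < 0:
            idx = 20
        if part == "UP":
            up[idx] += 1
        else:
            down[idx] += 1
    return np.concatenate([_normalize_half(up, params.norm),
                           _normalize_half(down, params.norm)])


def _normalize_half(counts: np.ndarray, norm: str) -> np.ndarray:
    total = counts.sum() if norm == "L1" else np.linalg.norm(counts)
    if total > 0:
        return counts / total
    return counts


def protrusion_index(
    residue: Residue,
    all_atoms: list[Atom],
    params: ProtrusionParams | None = None,
) -> np.ndarray:
    """Six protrusion statistics for a residue's heavy atoms.

    Per-atom protrusion is ``clamp((V - k v) / V, 0, 1)`` with ``V`` the
    volume of the probe sphere, ``v`` the mean atom volume, and ``k`` the
    number of heavy atoms (the center included) within the sphere radius
    of the atom.  Returned vector: (mean, std, min, max, side-facing
    mean, side-facing std), where "side-facing" atoms lie on the CB side
    of the plane through CA normal to CA->CB; glycine (no CB) gets NaN
    side-facing entries, and a residue with no heavy atoms a 1x6 NaN
    vector.
    """
    if params is None:
        params = ProtrusionParams()
    res_atoms = residue.heavy_atoms()
    if not res_atoms:
        return np.full(6, np.nan)
    coords = np.array([a.coords for a in all_atoms if not a.is_hydrogen])
    res_coords = np.array([a.coords for a in res_atoms])
    dists = cdist(res_coords, coords)
    k = (dists <= params.sphere_radius).sum(axis=1)  # includes the atom itself
    v_sphere = params.sphere_volume
    protrusion = np.clip((v_sphere - k * params.atom_volume) / v_sphere, 0.0, 1.0)

    ca, cb = residue.get_atom("CA"), residue.get_atom("CB")
    if ca is None or cb is None:
        side_mean = side_std = np.nan
    else:
        axis = cb.coords - ca.coords
        facing = np.array([float(np.dot(a.coords - ca.coords, axis)) > 0.0
                           for a in res_atoms])
        if facing.any():
            side_mean = float(protrusion[facing].mean())
            side_std = float(protrusion[facing].std())
        else:
            side_mean = side_std = np.nan
    return np.array([
        float(protrusion.mean()),
        float(protrusion.std()),
        float(protrusion.min()),
        float(protrusion.max()),
        side_mean,
        side_std,
    ])
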