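"""Normal vectors, significance/coordination, HSAAC, and protrusion."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pairfeat.geometry import (
    HalfSphereParams,
    ProtrusionParams,
    SignificanceParams,
    amide_normal_vector,
    coordination_number,
    half_sphere_partition,
    hsaac,
    min_heavy_atom_distance,
    protrusion_index,
    side_chain_axis,
    significance_score,
)
from pairfeat.structure import Atom, Residue, HSAAC_ALPHABET

from conftest import backbone_residue, single_atom_residue


def residue_with(coords_by_name, name3="ALA"):
    atoms = [
        Atom(serial=i + 1, name=n, element=n[0], coords=np.asarray(c, float))
        for i, (n, c) in enumerate(coords_by_name.items())
    ]
    return Residue(chain_id="A", resseq=1, icode=" ", name3=name3,
                   is_standard_aa=True, is_water=False, atoms=atoms)


class TestAmideNormalVector:
    def test_manual_cross_product(self):
        res = residue_with({"CA": (0, 0, 0), "CB": (1, 0, 0), "N": (0, 1, 0)})
        # (CA-CB) x (CB-N) = (-1,0,0) x (1,-1,0) = (0,0,1)
        assert np.allclose(amide_normal_vector(res), [0, 0, 1])

    def test_glycine_without_cb_is_nan(self):
        res = residue_with({"CA": (0, 0, 0), "N": (0, 1, 0)}, name3="GLY")
        assert np.all(np.isnan(amide_normal_vector(res)))

    def test_collinear_atoms_give_zero_vector(self):
        res = residue_with({"CA": (0, 0, 0), "CB": (1, 0, 0), "N": (2, 0, 0)})
        assert np.allclose(amide_normal_vector(res), [0, 0, 0])

    def test_orthogonal_to_generating_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            ca, cb, n = rng.normal(size=(3, 3))
            res = residue_with({"CA": ca, "CB": cb, "N": n})
            nv = amide_normal_vector(res)
            assert abs(np.dot(nv, ca - cb)) < 1e-9
            assert abs(np.dot(nv, cb - n)) < 1e-9


class TestSignificance:
    def test_zero_distance_gives_one(self):
        assert significance_score(0.0, SignificanceParams()) == 1.0

    def test_half_value_at_sigma_sqrt_2ln2(self):
        params = SignificanceParams(st=0.5, sigma=1.0)
        d = math.sqrt(2.0 * math.log(2.0))
        assert significance_score(d, params) == pytest.approx(0.5, abs=1e-12)

    def test_underflow_at_literal_defaults(self):
        # sigma = st = 1e-3: any physical separation underflows to zero
        assert significance_score(10.0, SignificanceParams()) == 0.0

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            significance_score(-0.1)

    def test_matches_closed_form_at_random_points(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            d = float(rng.uniform(0, 10))
            sigma = float(rng.uniform(0.1, 5))
            got = significance_score(d, SignificanceParams(st=0.5, sigma=sigma))
            assert got == pytest.approx(math.exp(-d * d / (2 * sigma * sigma)),
                                        rel=1e-12)

    @given(st.floats(0, 50), st.floats(0, 50))
    def test_monotone_non_increasing(self, d1, d2):
        params = SignificanceParams(st=0.5, sigma=2.0)
        lo, hi = sorted([d1, d2])
        assert significance_score(hi, params) <= significance_score(lo, params)


class TestCoordinationNumber:
    def test_isolated_residue(self):
        res = single_atom_residue([0, 0, 0])
        assert coordination_number(res, [res]) == 0

    def test_practical_sigma_counts_close_neighbors_only(self):
        params = SignificanceParams(st=0.5, sigma=4.0)
        center = single_atom_residue([0, 0, 0])
        near = single_atom_residue([3.0, 0, 0], resseq=2)
        far = single_atom_residue([6.0, 0, 0], resseq=3)
        # exp(-9/32)=0.755 > 0.5 counts; exp(-36/32)=0.325 does not
        assert coordination_number(center, [center, near, far], params) == 1

    def test_literal_defaults_underflow(self):
        center = single_atom_residue([0, 0, 0])
        near = single_atom_residue([2.0, 0, 0], resseq=2)
        assert coordination_number(center, [center, near]) == 0

    def test_agrees_with_brute_force_double_loop(self, toy_complex):
        structure, _ = toy_complex
        params = SignificanceParams(st=0.5, sigma=4.0)
        residues = [r for c in structure.chains for r in c.residues
                    if r.is_standard_aa]
        for res in residues:
            expected = 0
            for other in residues:
                if other is res:
                    continue
                d = min_heavy_atom_distance(res, other)
                if math.exp(-d * d / (2 * 16.0)) > 0.5:
                    expected += 1
            assert coordination_number(res, residues, params) == expected


class TestHalfSphere:
    def test_partition_up_down_out(self):
        center = backbone_residue([0, 0, 0])  # side chain axis = +z
        up = backbone_residue([0, 0, 4], resseq=2)
        down = backbone_residue([0, 0, -4], resseq=3)
        out = backbone_residue([0, 9, 0], resseq=4)
        params = HalfSphereParams(radius=8.0)
        assert half_sphere_partition(center, up, params) == "UP"
        assert half_sphere_partition(center, down, params) == "DOWN"
        assert half_sphere_partition(center, out, params) == "OUT"

    def test_single_up_neighbor_is_one_hot(self):
        center = backbone_residue([0, 0, 0])
        neighbor = backbone_residue([0, 0, 4], resseq=2, name3="ALA")
        vec = hsaac(center, [center, neighbor])
        expected = np.zeros(42)
        expected[HSAAC_ALPHABET.index("A")] = 1.0
        assert np.allclose(vec, expected)

    def test_isolated_residue_is_all_zero(self):
        center = backbone_residue([0, 0, 0])
        assert np.allclose(hsaac(center, [center]), np.zeros(42))

    def test_two_up_neighbors_split_half(self):
        center = backbone_residue([0, 0, 0])
        ala = backbone_residue([0, 0, 4], resseq=2, name3="ALA")
        gly = backbone_residue([2, 0, 4], resseq=3, name3="GLY")
        vec = hsaac(center, [center, ala, gly])
        assert vec[HSAAC_ALPHABET.index("A")] == pytest.approx(0.5)
        assert vec[HSAAC_ALPHABET.index("G")] == pytest.approx(0.5)
        assert vec[:21].sum() == pytest.approx(1.0)
        assert np.allclose(vec[21:], 0.0)

    def test_missing_ca_gives_nan_vector(self):
        res = residue_with({"N": (0, 0, 0)})
        assert np.all(np.isnan(hsaac(res, [res])))

    def test_glycine_axis_from_pseudo_cb(self):
        gly = backbone_residue([0, 0, 0], name3="GLY")
        assert gly.get_atom("CB") is None
        axis = side_chain_axis(gly)
        assert axis is not None and np.linalg.norm(axis) > 0

    def test_halves_normalized_on_toy_complex(self, toy_complex):
        structure, _ = toy_complex
        residues = [r for c in structure.chains for r in c.residues
                    if r.is_standard_aa]
        for res in residues:
            vec = hsaac(res, residues)
            for half in (vec[:21], vec[21:]):
                total = half.sum()
                assert total == pytest.approx(0.0) or total == pytest.approx(1.0)
            assert np.all((vec >= 0) & (vec <= 1))

    def test_matches_brute_force_partition(self, toy_complex):
        structure, _ = toy_complex
        params = HalfSphereParams()
        residues = [r for c in structure.chains for r in c.residues
                    if r.is_standard_aa]
        for res in residues:
            axis = side_chain_axis(res)
            ca = res.get_atom("CA").coords
            up = np.zeros(21)
            down = np.zeros(21)
            for other in residues:
                if other is res:
                    continue
                delta = other.get_atom("CA").coords - ca
                if np.linalg.norm(delta) > params.radius:
                    continue
                idx = HSAAC_ALPHABET.index(other.one_letter)
                if np.dot(axis, delta) >= 0:
                    up[idx] += 1
                else:
                    down[idx] += 1
            expected = np.concatenate([
                up / up.sum() if up.sum() else up,
                down / down.sum() if down.sum() else down,
            ])
            assert np.array_equal(hsaac(res, residues, params), expected)


class TestProtrusionIndex:
    def test_single_isolated_atom(self):
        res = single_atom_residue([0, 0, 0])
        vec = protrusion_index(res, res.atoms)
        v_sphere = 4.0 / 3.0 * math.pi * 1000.0
        expected = (v_sphere - 20.1) / v_sphere  # ~0.99520
        assert vec[0] == pytest.approx(expected, abs=1e-5)
        assert vec[1] == 0.0
        assert vec[2] == pytest.approx(expected, abs=1e-5)
        assert vec[3] == pytest.approx(expected, abs=1e-5)
        assert np.isnan(vec[4]) and np.isnan(vec[5])  # no CB: side stats NaN

    def test_fully_occupied_sphere_clamps_to_zero(self):
        offsets = np.arange(-3, 4) * 1.5
        grid = [np.array([x, y, z]) for x in offsets for y in offsets for z in offsets]
        center = single_atom_residue([0, 0, 0])
        all_atoms = [
            Atom(serial=i + 2, name="C", element="C", coords=c)
            for i, c in enumerate(grid)
            if np.linalg.norm(c) > 0
        ] + center.atoms
        # 343 atoms within 10 Å: occupancy 343*20.1 exceeds the sphere volume
        vec = protrusion_index(center, all_atoms)
        assert vec[0] == 0.0 and vec[3] == 0.0

    def test_identical_atoms_have_zero_std(self, toy_complex):
        structure, _ = toy_complex
        res = single_atom_residue([500.0, 0, 0])
        vec = protrusion_index(res, res.atoms)
        assert vec[1] == 0.0

    def test_values_in_unit_interval_and_monotone(self):
        res = backbone_residue([0, 0, 0])
        atoms = list(res.atoms)
        base = protrusion_index(res, atoms)
        assert np.all((base[:4] >= 0) & (base[:4] <= 1))
        atoms.append(Atom(serial=99, name="C", element="C", coords=[3.0, 0, 0]))
        denser = protrusion_index(res, atoms)
        # adding an atom inside the sphere never increases protrusion
        assert np.all(denser[:4] <= base[:4] + 1e-12)
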