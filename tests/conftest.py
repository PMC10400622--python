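import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pairfeat.fixtures import ToyComplexSpec, make_toy_complex
from pairfeat.structure import Atom, Chain, Residue, Structure

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def toy_complex():
    """Small two-chain complex with a handful of contacts."""
    return make_toy_complex(
        ToyComplexSpec(n_res_per_chain=8, n_contact_pairs=5, n_waters=2, seed=11)
    )


@pytest.fixture
def contact_free_complex():
    return make_toy_complex(
        ToyComplexSpec(n_res_per_chain=6, inter_chain_gap=50.0, seed=4)
    )


def pdb_line(record, serial, name, resname, chain, resseq, x, y, z,
             element, altloc=" "):
    """One correctly columned PDB coordinate line."""
    name4 = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"{record:<6s}{serial:5d} {name4}{altloc:1s}{resname:>3s} "
        f"{chain:1s}{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
        f"{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )


def single_atom_residue(
    coords, name="CA", element="C", chain_id="A", resseq=1, name3="ALA"
):
    atom = Atom(serial=1, name=name, element=element, coords=np.asarray(coords, float))
    return Residue(
        chain_id=chain_id,
        resseq=resseq,
        icode=" ",
        name3=name3,
        is_standard_aa=True,
        is_water=False,
        atoms=[atom],
    )


def backbone_residue(ca, chain_id="A", resseq=1, name3="ALA", with_cb=True):
    """Residue with N, CA, C (and CB) placed around a CA position."""
    ca = np.asarray(ca, float)
    offsets = {
        "N": np.array([-0.6, 0.75, 0.0]),
        "CA": np.zeros(3),
        "C": np.array([0.6, 0.75, 0.0]),
    }
    if with_cb and name3 != "GLY":
        offsets["CB"] = np.array([0.0, 0.0, 0.8])
    atoms = [
        Atom(serial=i + 1, name=n, element=n[0], coords=ca + off)
        for i, (n, off) in enumerate(offsets.items())
    ]
    return Residue(
        chain_id=chain_id,
        resseq=resseq,
        icode=" ",
        name3=name3,
        is_standard_aa=True,
        is_water=False,
        atoms=atoms,
    )


def structure_from_chains(*chains, pdb_id="test", resolution=None):
    return Structure(pdb_id=pdb_id, models=[list(chains)], resolution=resolution)


def chain_of(residues, chain_id="A"):
    for r in residues:
        r.chain_id = chain_id
    return Chain(id=chain_id, residues=list(residues))
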