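"""Deterministic synthetic fixtures: toy complexes and toy profile files.

``make_toy_complex`` builds a two-chain structure with backbone atoms
(N, CA, C, CB; glycines omit CB) whose number of inter-chain residue
pairs under the 6 Å heavy-atom rule is *exactly* the requested count.
Exactness is achieved with a block construction: the requested count is
decomposed into disjoint p x q contact blocks; each block's p chain-A
and q chain-B residues are packed into one tight spatial cluster (every
cross-chain CA-CA distance below 6 Å, hence every pair a contact), and
blocks sit 150 Å apart from each other and from the extended remainder
of both chains (3.8 Å CA spacing, chains separated by the configured
gap), so no other pair comes close.  The generator verifies the contact
set by brute force before returning and raises
:class:`GenerationError` if the target cannot be represented (e.g. a
count exceeding n^2, or one needing more residues than the chains
hold).  Every count a test might need is recorded in the returned
ledger.

All randomness (sequence draws, toy profile frequencies) flows through
one seeded generator; the same spec yields byte-identical PDB output.
Conformations are geometrically valid but make no claim to physical
realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .profiles import STANDARD_AA_ORDER, ProfileHMM
from .structure import ONE_TO_THREE, Atom, Chain, Residue, Structure

__all__ = [
    "ToyComplexSpec",
    "ToyLedger",
    "GenerationError",
    "make_toy_complex",
    "write_pdb",
    "make_toy_hhm",
    "write_hhm",
]

_BLOCK_SPACING = 150.0  # Å between contact blocks and the extended chains
_GRID_SPACING = 0.8  # Å between clustered CA positions within a block
_CONTACT_THRESHOLD = 6.0  # Å, heavy-atom rule used for the ledger

# Residue-local heavy-atom offsets from CA (non-collinear backbone so a
# pseudo-CB is constructible for glycine).
_ATOM_OFFSETS = {
    "N": np.array([-0.6, 0.75, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([0.6, 0.75, 0.0]),
    "CB": np.array([0.0, 0.0, 0.8]),
}


class GenerationError(RuntimeError):
    """Raised when a fixture spec cannot be satisfied."""


@dataclass
class ToyComplexSpec:
    n_res_per_chain: int = 10
    inter_chain_gap: float = 25.0  # Å between the extended chain rows
    n_contact_pairs: int = 0
    n_waters: int = 0
    sequence: str = "random"
    seed: int = 0
    water_offsets: list[tuple[float, float, float]] | None = None
    pdb_id: str = "toy1"

    def __post_init__(self) -> None:
        if self.n_res_per_chain < 1:
            raise ValueError("n_res_per_chain must be positive")
        if self.n_contact_pairs > self.n_res_per_chain**2:
            raise GenerationError(
                f"cannot place {self.n_contact_pairs} contacts with "
                f"{self.n_res_per_chain} residues per chain"
            )
        if self.inter_chain_gap < 8.0:
            raise ValueError("inter_chain_gap below 8 Å risks spurious contacts")
        if self.sequence != "random" and len(self.sequence) != self.n_res_per_chain:
            raise ValueError("sequence length must equal n_res_per_chain")


@dataclass
class ToyLedger:
    """Ground truth for every count the tests need."""

    n_residues_per_chain: dict[str, int]
    n_atoms: int
    n_waters: int
    positives: list[tuple[int, int]]
    n_chain_pairs: int
    blocks: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_positives(self) -> int:
        return len(self.positives)

    @property
    def n_residues(self) -> int:
        return sum(self.n_residues_per_chain.values())


def _contact_blocks(k: int, na: int, nb: int) -> list[tuple[int, int]]:
    """Decompose k into disjoint p x q blocks with sum(p) <= na,
    sum(q) <= nb; raises GenerationError when the greedy decomposition
    cannot represent k."""
    blocks: list[tuple[int, int]] = []
    rem, a_avail, b_avail = k, na, nb
    while rem > 0:
        if a_avail == 0 or b_avail == 0:
            raise GenerationError(
                f"contact target {k} not representable as disjoint blocks "
                f"within {na}x{nb} residues"
            )
        p = min(a_avail, max(1, math.ceil(rem / b_avail)))
        q = min(b_avail, rem // p)
        if p + q > 120:
            raise GenerationError(
                f"contact block {p}x{q} too large for the cluster lattice"
            )
        blocks.append((p, q))
        rem -= p * q
        a_avail -= p
        b_avail -= q
    return blocks


def _cluster_points(n: int) -> np.ndarray:
    """n closest points of a cubic lattice around the origin (tight
    cluster; max pairwise distance well under 6 Å for n <= 120)."""
    r = np.arange(-3, 4) * _GRID_SPACING
    grid = np.array([(x, y, z) for x in r for y in r for z in r])
    order = np.lexsort((grid[:, 2], grid[:, 1], grid[:, 0],
                        np.linalg.norm(grid, axis=1)))
    if n > len(grid):
        raise GenerationError(f"cluster lattice exhausted ({n} > {len(grid)})")
    return grid[order][:n]


def _make_residue(chain_id: str, resseq: int, aa: str, ca: np.ndarray,
                  serial_start: int) -> tuple[Residue, int]:
    name3 = ONE_TO_THREE[aa]
    atoms = []
    serial = serial_start
    for atom_name, offset in _ATOM_OFFSETS.items():
        if atom_name == "CB" and name3 == "GLY":
            continue
        element = atom_name[0]
        atoms.append(Atom(serial=serial, name=atom_name, element=element,
                          coords=ca + offset))
        serial += 1
    residue = Residue(chain_id=chain_id, resseq=resseq, icode=" ", name3=name3,
                      is_standard_aa=True, is_water=False, atoms=atoms)
    return residue, serial


def _brute_force_positives(chain_a: Chain, chain_b: Chain,
                           threshold: float) -> set[tuple[int, int]]:
    found = set()
    res_a = [r for r in chain_a.residues if r.is_standard_aa]
    res_b = [r for r in chain_b.residues if r.is_standard_aa]
    for i, ra in enumerate(res_a):
        ca = np.array([a.coords for a in ra.heavy_atoms()])
        for j, rb in enumerate(res_b):
            cb = np.array([a.coords for a in rb.heavy_atoms()])
            if cdist(ca, cb).min() < threshold:
                found.add((i, j))
    return found


def make_toy_complex(spec: ToyComplexSpec) -> tuple[Structure, ToyLedger]:
    """Build a deterministic two-chain complex with an exact contact count."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_res_per_chain
    if spec.sequence == "random":
        letters = np.array(list(STANDARD_AA_ORDER))
        seq_a = "".join(rng.choice(letters, size=n))
        seq_b = "".join(rng.choice(letters, size=n))
    else:
        seq_a = seq_b = spec.sequence

    # default extended positions
    pos_a = np.zeros((n, 3))
    pos_a[:, 0] = 3.8 * np.arange(n)
    pos_b = np.zeros((n, 3))
    pos_b[:, 0] = 3.8 * np.arange(n)
    pos_b[:, 1] = spec.inter_chain_gap

    blocks = _contact_blocks(spec.n_contact_pairs, n, n) if spec.n_contact_pairs else []
    planned: set[tuple[int, int]] = set()
    next_a = next_b = 0
    for b_idx, (p, q) in enumerate(blocks):
        center = np.array([-_BLOCK_SPACING * (b_idx + 1), 0.0, 0.0])
        cluster = _cluster_points(p + q) + center
        a_rows = range(next_a, next_a + p)
        b_rows = range(next_b, next_b + q)
        for offset, row in enumerate(a_rows):
            pos_a[row] = cluster[offset]
        for offset, row in enumerate(b_rows):
            pos_b[row] = cluster[p + offset]
        planned.update((i, j) for i in a_rows for j in b_rows)
        next_a += p
        next_b += q

    serial = 1
    chains = []
    for chain_id, seq, positions in [("A", seq_a, pos_a), ("B", seq_b, pos_b)]:
        residues = []
        for i in range(n):
            residue, serial = _make_residue(chain_id, i + 1, seq[i],
                                            positions[i], serial)
            residues.append(residue)
        chains.append(Chain(id=chain_id, residues=residues))

    # waters appended to chain A under high residue numbers
    water_positions = spec.water_offsets
    if water_positions is None:
        water_positions = [(3.0 * i, 0.0, 40.0) for i in range(spec.n_waters)]
    elif len(water_positions) != spec.n_waters:
        raise ValueError("water_offsets length must equal n_waters")
    for w, xyz in enumerate(water_positions):
        atom = Atom(serial=serial, name="O", element="O",
                    coords=np.asarray(xyz, dtype=float))
        serial += 1
        chains[0].residues.append(
            Residue(chain_id="A", resseq=1000 + w, icode=" ", name3="HOH",
                    is_standard_aa=False, is_water=True, atoms=[atom])
        )

    structure = Structure(pdb_id=spec.pdb_id, models=[chains])

    observed = _brute_force_positives(chains[0], chains[1], _CONTACT_THRESHOLD)
    if observed != planned:
        raise GenerationError(
            f"contact verification failed: planned {len(planned)} pairs, "
            f"brute force found {len(observed)}"
        )
    ledger = ToyLedger(
        n_residues_per_chain={"A": n, "B": n},
        n_atoms=structure.n_atoms,
        n_waters=spec.n_waters,
        positives=sorted(planned),
        n_chain_pairs=1,
        blocks=blocks,
    )
    return structure, ledger


def write_pdb(structure: Structure, path: str | Path) -> Path:
    """Write a structure as a plain PDB file re-readable by
    ``read_structure`` (coordinates to 3 decimals; waters as HETATM)."""
    path = Path(path)
    lines: list[str] = []
    multi_model = len(structure.models) > 1
    for model_idx, chains in enumerate(structure.models):
        if multi_model:
            lines.append(f"MODEL     {model_idx + 1:4d}")
        serial = 1
        for chain in chains:
            if len(chain.id) != 1:
                raise ValueError(f"PDB chain ids are single characters: {chain.id!r}")
            for res in chain.residues:
                record = "ATOM  " if res.is_standard_aa else "HETATM"
                for atom in res.atoms:
                    name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                    x, y, z = atom.coords
                    lines.append(
                        f"{record}{serial:5d} {name}{atom.altloc:1s}"
                        f"{res.name3:>3s} {chain.id}{res.resseq:4d}{res.icode:1s}"
                        f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                        f"          {atom.element:>2s}"
                    )
                    serial += 1
        if multi_model:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_hhm(hmm: ProfileHMM, path: str | Path | None = None) -> str:
    """Serialize a profile HMM back to ``.hhm`` text (fixture use)."""
    n = len(hmm)
    null_freqs = " ".join(["3000"] * 20)
    lines = [
        "HHsearch 1.5",
        "NAME  toy",
        f"LENG  {n} match states, {n} columns in multiple alignment",
        "SEQ",
        ">toy",
        hmm.sequence,
        "#",
        f"NULL   {null_freqs}",
        "HMM    " + "\t".join(hmm.aa_order),
        "       M->M\tM->I\tM->D\tI->M\tI->I\tD->M\tD->D\tNeff\tNeff_I\tNeff_D",
        "       0\t*\t*\t0\t*\t0\t*\t*\t*\t*",
    ]
    for i in range(n):
        emis = "\t".join(str(f) for f in hmm.emission_freqs[i])
        lines.append(f"{hmm.sequence[i]} {i + 1}\t{emis}\t{i + 1}")
        trans = "\t".join(str(f) for f in hmm.transition_freqs[i])
        div = "\t".join(str(f) for f in hmm.diversity[i])
        lines.append(f"       {trans}\t{div}")
        lines.append("")
    lines.append("//")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def make_toy_hhm(
    sequence: str,
    pattern: str = "uniform",
    seed: int = 0,
    m: int = 1000,
    path: str | Path | None = None,
) -> str:
    """Write a syntactically valid toy ``.hhm`` for a sequence.

    ``onehot`` emits frequency 0 for the position's true residue and
    ``*`` elsewhere (a delta emission distribution after conversion);
    ``uniform`` emits ``round(m * log2(20))`` everywhere (probability
    1/20 each); ``random`` draws frequencies from a seeded generator.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if pattern not in {"uniform", "onehot", "random"}:
        raise ValueError(f"unknown pattern {pattern!r}")
    rng = np.random.default_rng(seed)
    uniform_freq = round(m * math.log2(20))
    emissions: list[list] = []
    for aa in sequence:
        if pattern == "uniform":
            emissions.append([uniform_freq] * 20)
        elif pattern == "onehot":
            row: list = ["*"] * 20
            idx = STANDARD_AA_ORDER.find(aa)
            if idx >= 0:
                row[idx] = 0
            emissions.append(row)
        else:
            emissions.append([int(f) for f in rng.integers(0, 6000, size=20)])
    transitions = [[0, "*", "*", "*", "*", "*", "*"] for _ in sequence]
    diversity = [[1000, 0, 0] for _ in sequence]
    hmm = ProfileHMM(
        sequence=sequence,
        emission_freqs=emissions,
        transition_freqs=transitions,
        diversity=diversity,
        m=m,
    )
    return write_hhm(hmm, path)
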