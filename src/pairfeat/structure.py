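"""Typed structural model for protein complexes read from PDB files.

The model is deliberately small: atoms carry Cartesian coordinates in
ångström, residues carry an identity key ``(chain_id, resseq, icode)``,
chains are ordered residue lists, and a structure is an ordered list of
models (each a list of chains).  Parsing is delegated to Bio.PDB; this
module only flattens its entity hierarchy into plain dataclasses and
applies the conventions used throughout the package:

* the first alternate location encountered per atom name is kept;
* hydrogens are parsed but flagged, and every distance computation in the
  package uses heavy atoms only;
* selenomethionine (MSE) is mapped to MET by default, so it counts as a
  standard residue.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "ChainPair",
    "StructureError",
    "StructureParseError",
    "read_structure",
    "first_model",
    "strip_non_standard",
    "enumerate_chain_pairs",
    "STANDARD_AA3",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
    "DEFAULT_MODIFIED_AA",
    "HSAAC_ALPHABET",
]

#: The 20 canonical amino acids, three-letter codes.
STANDARD_AA3 = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

#: Modified residues mapped onto their canonical parent (configurable).
DEFAULT_MODIFIED_AA: dict[str, str] = {"MSE": "MET"}

#: 21-symbol alphabet used by half-sphere compositions: 20 amino acids in
#: one-letter alphabetical order plus '-' for unknown / unmappable types.
HSAAC_ALPHABET = "ACDEFGHIKLMNPQRSTVWY-"

_WATER_NAMES = {"HOH", "DOD", "WAT", "H2O"}
_HYDROGEN_ELEMENTS = {"H", "D"}


class StructureError(ValueError):
    """Base error for structural-model violations."""


class StructureParseError(StructureError):
    """Raised when a PDB file cannot be parsed into a structure."""


@dataclass
class Atom:
    """A single atom with coordinates in Å."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    altloc: str = " "
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(
                f"atom {self.name!r} has invalid coordinates {self.coords!r}"
            )
        if not self.element:
            self.element = _element_from_name(self.name)
        self.is_hydrogen = self.element.upper() in _HYDROGEN_ELEMENTS


@dataclass
class Residue:
    """A residue keyed by ``(chain_id, resseq, icode)``."""

    chain_id: str
    resseq: int
    icode: str
    name3: str
    is_standard_aa: bool
    is_water: bool
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.resseq, self.icode)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name3, "X")

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def get_atom(self, name: str) -> Atom | None:
        """First heavy atom with the given PDB name, or None."""
        for atom in self.atoms:
            if atom.name == name and not atom.is_hydrogen:
                return atom
        return None


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        """One-letter sequence of the standard residues, in chain order."""
        return "".join(r.one_letter for r in self.residues if r.is_standard_aa)

    def atoms(self) -> Iterator[Atom]:
        for residue in self.residues:
            yield from residue.atoms

    def heavy_atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.heavy_atoms()]

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Structure:
    """Models -> chains -> residues -> atoms."""

    pdb_id: str
    models: list[list[Chain]]
    resolution: float | None = None
    experiment_method: str | None = None

    def __post_init__(self) -> None:
        if not self.models:
            raise StructureError("structure must contain at least one model")
        for chains in self.models:
            ids = [c.id for c in chains]
            if len(ids) != len(set(ids)):
                raise StructureError(f"duplicate chain ids within a model: {ids}")

    @property
    def chains(self) -> list[Chain]:
        """Chains of the first model."""
        return self.models[0]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(chain_id)

    def atoms(self) -> Iterator[Atom]:
        for chain in self.chains:
            yield from chain.atoms()

    def heavy_atoms(self) -> list[Atom]:
        return [a for c in self.chains for a in c.heavy_atoms()]

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)


@dataclass(frozen=True)
class ChainPair:
    """An unordered pair of chains treated as one binary complex."""

    pdb_id: str
    chain_a: str
    chain_b: str
    pair_index: int

    def __post_init__(self) -> None:
        if self.chain_a == self.chain_b:
            raise StructureError("chain pair must reference two distinct chains")

    def name(self, assembly: int = 1) -> str:
        """``<pdb_id>.pdb<assembly>_<pair_index>`` record name."""
        return f"{self.pdb_id}.pdb{assembly}_{self.pair_index}"


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if stripped[0] in _HYDROGEN_ELEMENTS and len(name.strip()) > 1:
        return stripped[0]
    if len(stripped) >= 2 and stripped[:2].upper() in {"SE", "FE", "ZN", "MG", "CL", "BR"}:
        return stripped[:2].capitalize()
    return stripped[0].upper()


def read_structure(
    path: str | Path,
    parse_header: bool = True,
    modified_aa: Mapping[str, str] | None = None,
) -> Structure:
    """Parse a PDB file into a :class:`Structure`.

    All models are parsed.  Resolution and experiment method are taken
    from the header when present.  For alternate locations the first
    conformer encountered per atom name is kept.  Residues whose (mapped)
    name is one of the 20 canonical amino acids are flagged standard;
    waters (HOH/DOD/WAT) are flagged as such.

    Raises :class:`StructureParseError` for unreadable files or files
    with no atom records.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionWarning

    if modified_aa is None:
        modified_aa = DEFAULT_MODIFIED_AA
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    parser = PDBParser(PERMISSIVE=True, QUIET=True, get_header=parse_header)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            bio_structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # Bio raises with the offending line number
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc

    models: list[list[Chain]] = []
    for bio_model in bio_structure:
        chains: list[Chain] = []
        for bio_chain in bio_model:
            residues: list[Residue] = []
            for bio_res in bio_chain:
                hetfield, resseq, icode = bio_res.id
                raw_name = bio_res.get_resname().strip()
                name3 = modified_aa.get(raw_name, raw_name)
                is_water = hetfield == "W" or raw_name in _WATER_NAMES
                atoms: list[Atom] = []
                seen_names: set[str] = set()
                for bio_atom in bio_res.get_unpacked_list():
                    if bio_atom.get_name() in seen_names:
                        continue  # keep first altloc encountered
                    seen_names.add(bio_atom.get_name())
                    atoms.append(
                        Atom(
                            serial=bio_atom.get_serial_number() or 0,
                            name=bio_atom.get_name(),
                            element=(bio_atom.element or "").strip(),
                            coords=np.array(bio_atom.get_coord(), dtype=float),
                            altloc=bio_atom.get_altloc() or " ",
                        )
                    )
                if not atoms:
                    continue
                residues.append(
                    Residue(
                        chain_id=bio_chain.id,
                        resseq=resseq,
                        icode=icode if icode.strip() else " ",
                        name3=name3,
                        is_standard_aa=name3 in STANDARD_AA3,
                        is_water=is_water,
                        atoms=atoms,
                    )
                )
            if residues:
                chains.append(Chain(id=bio_chain.id, residues=residues))
        models.append(chains)

    if not models or not any(chains for chains in models):
        raise StructureParseError(f"no ATOM records found in {path}")

    resolution = None
    method = None
    if parse_header:
        header = bio_structure.header or {}
        resolution = header.get("resolution")
        method = header.get("structure_method") or None
        if method:
            method = method.strip().upper()
    return Structure(
        pdb_id=path.stem.lower(),
        models=models,
        resolution=resolution,
        experiment_method=method,
    )


def first_model(structure: Structure) -> Structure:
    """Keep only the first model (idempotent)."""
    if len(structure.models) == 1:
        return structure
    return replace(structure, models=[structure.models[0]])


def strip_non_standard(structure: Structure) -> Structure:
    """Remove hetero residues and waters, keeping standard amino acids only.

    Chains left empty by the filter are dropped; atom and residue order is
    preserved.  An all-water input yields a structure with no chains in
    its (single) model, which downstream operations treat as empty rather
    than as an error.
    """
    struct = first_model(structure)
    chains: list[Chain] = []
    for chain in struct.chains:
        kept = [r for r in chain.residues if r.is_standard_aa and not r.is_water]
        if kept:
            chains.append(Chain(id=chain.id, residues=kept))
    return Structure(
        pdb_id=struct.pdb_id,
        models=[chains] if chains else [[]],
        resolution=struct.resolution,
        experiment_method=struct.experiment_method,
    )


def enumerate_chain_pairs(structure: Structure) -> list[ChainPair]:
    """All C(n, 2) unordered chain pairs, lexicographic by chain id."""
    chain_ids = sorted(c.id for c in structure.chains)
    if len(chain_ids) < 2:
        raise StructureError("fewer than two chains")
    pairs = []
    for index, (a, b) in enumerate(itertools.combinations(chain_ids, 2)):
        pairs.append(
            ChainPair(pdb_id=structure.pdb_id, chain_a=a, chain_b=b, pair_index=index)
        )
    return pairs
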