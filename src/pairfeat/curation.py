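"""Complex-level curation filters, redundancy reduction, and splits.

The curation criteria mirror standard dataset-quality practice for
interface-prediction corpora: at least two chains, resolution no worse
than 3.5 Å, chains longer than 50 residues, at least 500 Å^2 of buried
surface area, first model only, plus inclusive size caps of 17,500
atoms and 1,000 residues per binary complex.  Complexes sharing more
than 30% sequence identity with any held-out test chain are removed to
prevent leakage.  An 80/20 complex-level split is drawn with a seeded
shuffle and written as one record name per line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure import Chain, ChainPair, Structure
from .surface import SasaParams, buried_surface_area

__all__ = [
    "CurationCriteria",
    "SplitSpec",
    "FilterVerdict",
    "filter_complex",
    "sequence_identity",
    "redundancy_filter",
    "split_dataset",
    "apply_size_caps",
    "load_removal_list",
]


@dataclass
class CurationCriteria:
    min_chains: int = 2
    max_resolution: float = 3.5  # Å; smaller is better
    min_chain_length: int = 50  # chains must have MORE residues than this
    min_bsa: float = 500.0  # Å^2
    max_atoms: int = 17_500  # inclusive cap on CA + non-CA atoms
    max_residues: int = 1_000  # inclusive cap per binary complex
    identity_threshold: float = 0.30
    allow_missing_resolution: bool = False
    #: True (default) keeps resolution <= max_resolution (the standard
    #: quality direction); False selects the literal opposite reading.
    resolution_better_than: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.identity_threshold < 1.0:
            raise ValueError("identity_threshold must lie in (0, 1)")
        for name in ("min_chains", "max_resolution", "min_chain_length",
                     "min_bsa", "max_atoms", "max_residues"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SplitSpec:
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class FilterVerdict:
    accepted: bool
    reasons: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.accepted


def filter_complex(
    structure: Structure,
    pair: ChainPair,
    criteria: CurationCriteria | None = None,
    bsa: float | None = None,
    sasa_params: SasaParams | None = None,
) -> FilterVerdict:
    """Accept or reject one chain pair against all complex-level criteria.

    Every failing criterion is listed in the verdict.  The structure
    should already be stripped to standard residues.  ``bsa`` may be
    passed to avoid recomputation; otherwise it is computed here.
    """
    if criteria is None:
        criteria = CurationCriteria()
    reasons: list[str] = []
    if len(structure.chains) < criteria.min_chains:
        reasons.append("fewer than two chains")

    if structure.resolution is None:
        if not criteria.allow_missing_resolution:
            reasons.append("resolution missing")
    elif criteria.resolution_better_than:
        if structure.resolution > criteria.max_resolution:
            reasons.append(f"resolution worse than {criteria.max_resolution} Å")
    elif structure.resolution <= criteria.max_resolution:
        reasons.append(f"resolution not above {criteria.max_resolution} Å")

    chains: list[Chain] = []
    for cid in (pair.chain_a, pair.chain_b):
        try:
            chains.append(structure.chain(cid))
        except KeyError:
            reasons.append(f"chain {cid!r} absent from structure")
    if len(chains) == 2:
        for chain in chains:
            n_standard = sum(1 for r in chain.residues if r.is_standard_aa)
            if n_standard <= criteria.min_chain_length:
                reasons.append(f"chain length ≤ {criteria.min_chain_length}")
                break
        if bsa is None:
            bsa = buried_surface_area(chains[0], chains[1], sasa_params)
        if bsa < criteria.min_bsa:
            reasons.append(f"buried surface area < {criteria.min_bsa} Å²")
    return FilterVerdict(accepted=not reasons, reasons=reasons)


_ALIGNER = None


def _global_aligner():
    """Global aligner: match +1, mismatch 0, affine gaps -11/-1."""
    global _ALIGNER
    if _ALIGNER is None:
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1.0
        aligner.mismatch_score = 0.0
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
        _ALIGNER = aligner
    return _ALIGNER


def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical aligned residues, over the shorter length.

    Uses a global alignment (match +1, mismatch 0, affine gap -11/-1);
    matches are counted from the aligner's first optimal alignment.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    alignment = _global_aligner().align(seq_a, seq_b)[0]
    matches = 0
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        matches = matches + sum(
            seq_a[a_start + k] == seq_b[b_start + k]
            for k in range(a_end - a_start)
        )
    return matches / min(len(seq_a), len(seq_b))


def redundancy_filter(
    candidates: dict[str, list[str]],
    test_seqs: list[str],
    threshold: float = 0.30,
) -> list[str]:
    """Retain complexes with no chain above the identity threshold.

    ``candidates`` maps complex names to their chain sequences.  A
    complex is removed iff ANY of its chains has identity strictly above
    the threshold with ANY test sequence.  Order is preserved.
    """
    retained = []
    for name, seqs in candidates.items():
        leaky = any(
            sequence_identity(seq, test_seq) > threshold
            for seq in seqs
            for test_seq in test_seqs
        )
        if not leaky:
            retained.append(name)
    return retained


def split_dataset(
    names: list[str],
    spec: SplitSpec | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[str], list[str]]:
    """Shuffled, reproducible train/validation partition of record names.

    ``|train| = round(train_fraction * N)`` with half-away-from-zero
    rounding.  When ``out_dir`` is given, ``pairs-postprocessed.txt``
    and the ``-train`` / ``-val`` partition files are written, one name
    per line.
    """
    if spec is None:
        spec = SplitSpec()
    names = list(names)
    duplicates = sorted({n for n in names if names.count(n) > 1})
    if duplicates:
        raise ValueError(f"duplicate record names: {duplicates}")
    rng = np.random.default_rng(spec.seed)
    shuffled = [names[i] for i in rng.permutation(len(names))]
    n_train = int(np.floor(spec.train_fraction * len(names) + 0.5))
    train, val = shuffled[:n_train], shuffled[n_train:]
    if names and not val:
        warnings.warn("validation partition is empty", stacklevel=2)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "pairs-postprocessed.txt").write_text(
            "".join(f"{n}\n" for n in names)
        )
        (out_dir / "pairs-postprocessed-train.txt").write_text(
            "".join(f"{n}\n" for n in train)
        )
        (out_dir / "pairs-postprocessed-val.txt").write_text(
            "".join(f"{n}\n" for n in val)
        )
    return train, val


def apply_size_caps(
    pair_records,
    criteria: CurationCriteria | None = None,
) -> tuple[list, list[dict]]:
    """Drop records exceeding the atom or residue caps (both inclusive).

    Records must expose ``n_atoms`` and ``n_residues`` in their
    ``metadata``.  Returns (retained records, removal ledger).
    """
    if criteria is None:
        criteria = CurationCriteria()
    retained, ledger = [], []
    for record in pair_records:
        n_atoms = int(record.metadata["n_atoms"])
        n_residues = int(record.metadata["n_residues"])
        reasons = []
        if n_atoms > criteria.max_atoms:
            reasons.append(f"atom count {n_atoms} > {criteria.max_atoms}")
        if n_residues > criteria.max_residues:
            reasons.append(f"residue count {n_residues} > {criteria.max_residues}")
        if reasons:
            ledger.append({"name": record.name, "reasons": reasons})
        else:
            retained.append(record)
    return retained, ledger


def load_removal_list(path: str | Path) -> list[str]:
    """Read an externally produced removal list (e.g. from a structure-
    similarity search), one chain-pair record name per line."""
    lines = Path(path).read_text().splitlines()
    return [line.strip() for line in lines if line.strip()]
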