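"""Profile-HMM sequence features from HH-suite3 ``.hhm`` files.

An ``.hhm`` file stores, per match state, 20 amino-acid emission
frequencies and 7 state-transition frequencies as negative scaled
log-probabilities (integers), with ``*`` marking an impossible event,
plus three alignment-diversity columns (Neff, Neff_I, Neff_D).  A
frequency is converted to a probability as ``p = 2^(-Freq / m)`` with
``m`` the number of alignments behind the profile (1000 by default), so
``Freq = 0`` gives probability 1 and ``*`` the limit 0.

Each residue contributes a 1x27 feature vector: the 20 emission
probabilities in the file's amino-acid column order followed by the 7
transition probabilities (M->M, M->I, M->D, I->M, I->I, D->M, D->D).
The diversity columns are parsed but never emitted as features, and the
27-vector is not renormalized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure import Chain, Residue

__all__ = [
    "ProfileHMM",
    "HhmParseError",
    "parse_hhm",
    "freq_to_prob",
    "residue_profile_features",
    "align_profile_to_chain",
    "STANDARD_AA_ORDER",
    "TRANSITION_ORDER",
]

#: Amino-acid column order of HH-suite ``.hhm`` emission tables.
STANDARD_AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
TRANSITION_ORDER = ("M->M", "M->I", "M->D", "I->M", "I->I", "D->M", "D->D")

Freq = int | str  # an integer frequency or the '*' token


class HhmParseError(ValueError):
    """Raised for malformed ``.hhm`` input, with the offending line."""


@dataclass
class ProfileHMM:
    """Raw per-position frequencies of an HH-suite3 profile HMM."""

    sequence: str
    emission_freqs: list[list[Freq]]  # one 20-list per match state
    transition_freqs: list[list[Freq]]  # one 7-list per match state
    diversity: list[list[Freq]]  # one 3-list per match state (Neff values)
    aa_order: str = STANDARD_AA_ORDER
    m: int = 1000

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if not (len(self.emission_freqs) == len(self.transition_freqs)
                == len(self.diversity) == n):
            raise HhmParseError(
                f"row count mismatch: sequence has {n} residues, "
                f"{len(self.emission_freqs)} emission rows"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _parse_token(token: str, path, line_no: int) -> Freq:
    if token == "*":
        return "*"
    try:
        return int(token)
    except ValueError as exc:
        raise HhmParseError(
            f"{path}:{line_no}: expected integer frequency or '*', got {token!r}"
        ) from exc


def parse_hhm(path: str | Path, m: int = 1000) -> ProfileHMM:
    """Parse an HH-suite3 ``.hhm`` text file.

    One row is produced per match state; ``*`` entries are preserved as
    tokens.  Truncated files or malformed rows raise
    :class:`HhmParseError` naming the line.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    # locate the HMM table header, which names the emission column order
    aa_order = STANDARD_AA_ORDER
    start = None
    for i, line in enumerate(lines):
        if line.startswith("HMM"):
            tokens = line.split()
            if len(tokens) >= 21:
                aa_order = "".join(tokens[1:21])
            start = i
            break
    if start is None:
        raise HhmParseError(f"{path}: no HMM table found (empty or truncated file)")

    sequence: list[str] = []
    emissions: list[list[Freq]] = []
    transitions: list[list[Freq]] = []
    diversity: list[list[Freq]] = []

    i = start + 1
    # skip the transition-header line and the begin-state transition line
    skipped = 0
    while i < len(lines) and skipped < 2:
        if lines[i].strip():
            skipped += 1
        i += 1

    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if line.startswith("//"):
            break
        tokens = line.split()
        # residue letter, position, 20 frequencies, trailing column index
        if len(tokens) < 22 or len(tokens[0]) != 1:
            raise HhmParseError(
                f"{path}:{i + 1}: malformed emission row: {line[:60]!r}"
            )
        sequence.append(tokens[0])
        emissions.append([_parse_token(t, path, i + 1) for t in tokens[2:22]])
        # find the matching transition row
        i += 1
        while i < len(lines) and not lines[i].strip():
            i += 1
        if i >= len(lines) or lines[i].strip().startswith("//"):
            raise HhmParseError(
                f"{path}:{min(i + 1, len(lines))}: truncated file: emission row "
                f"for position {len(sequence)} has no transition row"
            )
        trans_tokens = lines[i].split()
        if len(trans_tokens) < 10:
            raise HhmParseError(
                f"{path}:{i + 1}: transition row needs 10 entries, "
                f"got {len(trans_tokens)}"
            )
        transitions.append([_parse_token(t, path, i + 1) for t in trans_tokens[:7]])
        diversity.append([_parse_token(t, path, i + 1) for t in trans_tokens[7:10]])
        i += 1

    if not sequence:
        raise HhmParseError(f"{path}: HMM table contains no match states")
    return ProfileHMM(
        sequence="".join(sequence),
        emission_freqs=emissions,
        transition_freqs=transitions,
        diversity=diversity,
        aa_order=aa_order,
        m=m,
    )


def freq_to_prob(freq: Freq, m: int = 1000) -> float:
    """Convert a scaled frequency to a probability, ``p = 2^(-Freq/m)``.

    ``*`` (impossible) maps to 0.0, the limit of the formula as the
    frequency grows without bound.
    """
    if m <= 0:
        raise ValueError("m must be positive")
    if freq == "*":
        return 0.0
    freq = int(freq)
    if freq < 0:
        raise ValueError(f"frequency must be non-negative, got {freq}")
    return float(2.0 ** (-freq / m))


def residue_profile_features(hmm: ProfileHMM, position: int) -> np.ndarray:
    """The 1x27 probability vector for one match state: 20 emissions
    (file column order) then 7 transitions; diversity columns excluded."""
    if not 0 <= position < len(hmm):
        raise IndexError(
            f"position {position} out of range for profile of length {len(hmm)}"
        )
    emis = [freq_to_prob(f, hmm.m) for f in hmm.emission_freqs[position]]
    trans = [freq_to_prob(f, hmm.m) for f in hmm.transition_freqs[position]]
    return np.array(emis + trans)


def _best_ungapped_offset(profile_seq: str, chain_seq: str) -> tuple[int, int]:
    """Offset of the profile relative to the chain maximizing exact
    character matches over the overlap; returns (offset, n_matches).
    Offset k means profile position i maps to chain position i + k."""
    best_offset, best_matches = 0, -1
    for offset in range(-len(profile_seq) + 1, len(chain_seq)):
        matches = 0
        for i, aa in enumerate(profile_seq):
            j = i + offset
            if 0 <= j < len(chain_seq) and chain_seq[j] == aa:
                matches += 1
        if matches > best_matches:
            best_offset, best_matches = offset, matches
    return best_offset, best_matches


def align_profile_to_chain(
    hmm: ProfileHMM,
    chain: Chain | list[Residue],
) -> np.ndarray:
    """Map profile rows onto chain residues; (n_residues, 27) array.

    Identical sequences map one-to-one.  Otherwise the best ungapped
    offset is used and only positions whose residue letters agree are
    mapped; everything unmapped (including a chain with no credible
    match at all) receives 1x27 NaN rows, with a warning.
    """
    residues = chain.residues if isinstance(chain, Chain) else list(chain)
    chain_seq = "".join(r.one_letter for r in residues)
    out = np.full((len(residues), 27), np.nan)
    if not residues:
        return out
    if hmm.sequence == chain_seq:
        for i in range(len(residues)):
            out[i] = residue_profile_features(hmm, i)
        return out
    offset, matches = _best_ungapped_offset(hmm.sequence, chain_seq)
    if matches <= 0 or matches < 0.5 * min(len(hmm.sequence), len(chain_seq)):
        warnings.warn(
            "profile sequence does not match the chain sequence; "
            "all profile features are NaN",
            stacklevel=2,
        )
        return out
    for i, aa in enumerate(hmm.sequence):
        j = i + offset
        if 0 <= j < len(residues) and chain_seq[j] == aa:
            out[j] = residue_profile_features(hmm, i)
    return out
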