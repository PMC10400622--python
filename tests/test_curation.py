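"""Complex filters, sequence-identity redundancy reduction, splits,
and size caps."""

import itertools

import numpy as np
import pytest

from pairfeat.curation import (
    CurationCriteria,
    SplitSpec,
    apply_size_caps,
    filter_complex,
    redundancy_filter,
    sequence_identity,
    split_dataset,
)
from pairfeat.fixtures import ToyComplexSpec, make_toy_complex
from pairfeat.structure import ChainPair, enumerate_chain_pairs, strip_non_standard

from conftest import backbone_residue, chain_of, structure_from_chains

AA = "ACDEFGHIKLMNPQRSTVWY"


def gotoh_identity_bounds(seq_a, seq_b, open_gap=-11.0, extend_gap=-1.0):
    """Independent affine-gap global alignment oracle.

    Returns (optimal score, min matches, max matches) over all optimal
    alignments, via a lexicographic DP on (score, ±matches).
    """

    def solve(sign):
        neg = float("-inf")
        la, lb = len(seq_a), len(seq_b)
        M = [[(neg, 0)] * (lb + 1) for _ in range(la + 1)]
        X = [[(neg, 0)] * (lb + 1) for _ in range(la + 1)]  # gap in seq_b
        Y = [[(neg, 0)] * (lb + 1) for _ in range(la + 1)]  # gap in seq_a
        M[0][0] = (0.0, 0)
        for i in range(1, la + 1):
            X[i][0] = (open_gap + (i - 1) * extend_gap, 0)
        for j in range(1, lb + 1):
            Y[0][j] = (open_gap + (j - 1) * extend_gap, 0)
        for i in range(la + 1):
            for j in range(lb + 1):
                if i > 0 and j > 0:
                    match = 1 if seq_a[i - 1] == seq_b[j - 1] else 0
                    best = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
                    M[i][j] = (best[0] + match, best[1] + sign * match)
                if i > 0 and (i, j) != (1, 0) and j > 0:
                    X[i][j] = max(
                        (M[i - 1][j][0] + open_gap, M[i - 1][j][1]),
                        (X[i - 1][j][0] + extend_gap, X[i - 1][j][1]),
                        (Y[i - 1][j][0] + open_gap, Y[i - 1][j][1]),
                    )
                if j > 0 and (i, j) != (0, 1) and i > 0:
                    Y[i][j] = max(
                        (M[i][j - 1][0] + open_gap, M[i][j - 1][1]),
                        (X[i][j - 1][0] + open_gap, X[i][j - 1][1]),
                        (Y[i][j - 1][0] + extend_gap, Y[i][j - 1][1]),
                    )
        return max(M[la][lb], X[la][lb], Y[la][lb])

    score_max, signed_max = solve(+1)
    score_min, signed_min = solve(-1)
    assert score_max == score_min
    return score_max, -signed_min, signed_max


class TestFilterComplex:
    def toy_pair(self, **spec_kwargs):
        structure, _ = make_toy_complex(ToyComplexSpec(**spec_kwargs))
        stripped = strip_non_standard(structure)
        return stripped, enumerate_chain_pairs(stripped)[0]

    def test_single_chain_rejected(self):
        chain = chain_of([backbone_residue([0, 0, 0])])
        structure = structure_from_chains(chain, resolution=2.0)
        pair = ChainPair(pdb_id="test", chain_a="A", chain_b="B", pair_index=0)
        verdict = filter_complex(structure, pair, bsa=0.0)
        assert not verdict
        assert "fewer than two chains" in verdict.reasons

    def test_short_chains_rejected(self):
        structure, pair = self.toy_pair(n_res_per_chain=40, n_contact_pairs=10, seed=2)
        structure.resolution = 2.0
        verdict = filter_complex(structure, pair, bsa=1000.0)
        assert "chain length ≤ 50" in verdict.reasons

    def test_zero_bsa_rejected(self):
        structure, pair = self.toy_pair(
            n_res_per_chain=6, inter_chain_gap=60.0, seed=3
        )
        structure.resolution = 2.0
        criteria = CurationCriteria(min_chain_length=5)
        verdict = filter_complex(structure, pair, criteria)
        assert any("buried surface area" in r for r in verdict.reasons)

    def test_missing_resolution_rejected_by_default(self):
        structure, pair = self.toy_pair(n_res_per_chain=6, n_contact_pairs=4, seed=4)
        criteria = CurationCriteria(min_chain_length=5, min_bsa=1.0)
        verdict = filter_complex(structure, pair, criteria, bsa=100.0)
        assert "resolution missing" in verdict.reasons
        lenient = CurationCriteria(
            min_chain_length=5, min_bsa=1.0, allow_missing_resolution=True
        )
        assert filter_complex(structure, pair, lenient, bsa=100.0)

    def test_resolution_direction_configurable(self):
        structure, pair = self.toy_pair(n_res_per_chain=6, n_contact_pairs=4, seed=5)
        structure.resolution = 4.0
        criteria = CurationCriteria(min_chain_length=5, min_bsa=1.0)
        assert not filter_complex(structure, pair, criteria, bsa=100.0)
        literal = CurationCriteria(
            min_chain_length=5, min_bsa=1.0, resolution_better_than=False
        )
        assert filter_complex(structure, pair, literal, bsa=100.0)

    def test_all_failing_criteria_listed(self):
        structure, pair = self.toy_pair(
            n_res_per_chain=6, inter_chain_gap=60.0, seed=6
        )
        verdict = filter_complex(structure, pair)
        assert len(verdict.reasons) >= 3  # resolution, length, BSA


class TestSequenceIdentity:
    def test_identical_sequences(self):
        assert sequence_identity("ACDEFG", "ACDEFG") == 1.0

    def test_three_quarters(self):
        assert sequence_identity("AAAA", "AAAT") == pytest.approx(0.75)

    def test_disjoint_alphabets(self):
        assert sequence_identity("AAAA", "WWWW") == 0.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            sequence_identity("", "AAAA")

    def test_denominator_is_shorter_length(self):
        # a perfect substring match scores 1.0 against the shorter length
        assert sequence_identity("ACD", "ACDEFGH") == pytest.approx(1.0)

    def test_against_affine_dp_oracle_on_random_8mers(self):
        rng = np.random.default_rng(23)
        for _ in range(300):
            a = "".join(rng.choice(list(AA), size=8))
            b = "".join(rng.choice(list(AA), size=8))
            identity_ab = sequence_identity(a, b)
            identity_ba = sequence_identity(b, a)
            _, lo, hi = gotoh_identity_bounds(a, b)
            assert lo / 8 - 1e-12 <= identity_ab <= hi / 8 + 1e-12
            assert lo / 8 - 1e-12 <= identity_ba <= hi / 8 + 1e-12


class TestRedundancyFilter:
    def test_exact_shared_chain_removed(self):
        candidates = {"c1": ["ACDEFGHIKL"], "c2": ["MNPQRSTVWY"]}
        retained = redundancy_filter(candidates, ["ACDEFGHIKL"])
        assert retained == ["c2"]

    def test_low_identity_retained(self):
        candidates = {"c1": ["AAAACCCC"], "c2": ["DDDDEEEE"]}
        retained = redundancy_filter(candidates, ["WWWWYYYY"])
        assert retained == ["c1", "c2"]

    def test_matches_brute_force_on_mixed_fixture(self):
        rng = np.random.default_rng(31)
        test_seqs = ["".join(rng.choice(list(AA), size=10)) for _ in range(3)]
        candidates = {}
        for k in range(10):
            if k % 3 == 0:  # leaky: contains a test sequence verbatim
                seqs = [test_seqs[k % len(test_seqs)],
                        "".join(rng.choice(list(AA), size=10))]
            else:
                seqs = ["".join(rng.choice(list(AA), size=10)) for _ in range(2)]
            candidates[f"c{k}"] = seqs
        retained = redundancy_filter(candidates, test_seqs, threshold=0.30)
        expected = [
            name for name, seqs in candidates.items()
            if not any(
                sequence_identity(s, t) > 0.30
                for s, t in itertools.product(seqs, test_seqs)
            )
        ]
        assert retained == expected


class TestSplitDataset:
    def test_eighty_twenty(self, tmp_path):
        names = [f"rec_{i}" for i in range(1000)]
        train, val = split_dataset(names, SplitSpec(seed=3), out_dir=tmp_path)
        assert len(train) == 800 and len(val) == 200
        assert set(train) | set(val) == set(names)
        assert not set(train) & set(val)
        master = (tmp_path / "pairs-postprocessed.txt").read_text().splitlines()
        assert master == names
        train_file = (tmp_path / "pairs-postprocessed-train.txt").read_text()
        assert train_file.splitlines() == train

    def test_same_seed_gives_identical_files(self, tmp_path):
        names = [f"rec_{i}" for i in range(37)]
        split_dataset(names, SplitSpec(seed=8), out_dir=tmp_path / "run1")
        split_dataset(names, SplitSpec(seed=8), out_dir=tmp_path / "run2")
        for fname in ("pairs-postprocessed-train.txt", "pairs-postprocessed-val.txt"):
            assert (tmp_path / "run1" / fname).read_text() == (
                tmp_path / "run2" / fname
            ).read_text()

    def test_single_name_degenerate_split_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            train, val = split_dataset(["only"], SplitSpec(seed=0))
        assert train == ["only"] and val == []

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            split_dataset(["a", "b", "a"])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_partitions_disjoint_and_exhaustive(self, seed):
        for n in range(1, 51, 7):
            names = [f"r{i}" for i in range(n)]
            with pytest.warns() if n * 0.2 < 0.5 else _no_warning():
                train, val = split_dataset(names, SplitSpec(seed=seed))
            assert sorted(train + val) == sorted(names)
            assert not set(train) & set(val)
            assert len(train) == int(np.floor(0.8 * n + 0.5))


class _no_warning:
    def __enter__(self):
        return self

    def __exit__(self, *args):
        return False


class TestApplySizeCaps:
    class FakeRecord:
        def __init__(self, name, n_atoms, n_residues):
            self.name = name
            self.metadata = {"n_atoms": n_atoms, "n_residues": n_residues}

    def test_caps_are_inclusive(self):
        records = [
            self.FakeRecord("at_cap", 17_500, 900),
            self.FakeRecord("over_atoms", 17_501, 900),
            self.FakeRecord("at_res_cap", 100, 1_000),
            self.FakeRecord("over_res", 100, 1_001),
        ]
        retained, ledger = apply_size_caps(records)
        assert [r.name for r in retained] == ["at_cap", "at_res_cap"]
        assert {entry["name"] for entry in ledger} == {"over_atoms", "over_res"}
        assert all(entry["reasons"] for entry in ledger)
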