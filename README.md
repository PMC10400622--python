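# pairfeat

Residue-level featurization, interface labeling, and curation for
protein–protein complex datasets.

Protein interface prediction models need more than coordinates: they
learn from per-residue descriptors of burial, geometry, neighborhood
composition, and evolutionary conservation, together with labels saying
which inter-protein residue pairs actually touch. `pairfeat` builds
that feature bank from plain PDB files. It is aimed at structural
bioinformaticians assembling training corpora for interface prediction
(or benchmarking such corpora) who want the whole preprocessing path —
features, labels, quality filters, splits — reproducible from a config
and a seed, and testable on synthetic structures without downloading
anything.

## What it computes

For each binary complex (every unordered chain pair of a PDB entry,
first model, hetero residues and waters stripped), one record with a
feature table per chain and interface labels:

| Feature | Shape/row | Definition |
| --- | --- | --- |
| Secondary structure | 1 | 8-state character, `-` when unknown (ingested) |
| Relative solvent accessibility | 1 | Shrake–Rupley SASA / max ASA, capped at 1 |
| Residue depth | 1 | mean atom distance to the accessible surface, min-max scaled |
| Protrusion index | 6 | stats of the unoccupied fraction of a 10 Å sphere per atom |
| Half-sphere composition | 42 | neighbor amino-acid compositions along/against the side chain |
| Coordination number | 1 | neighbors with Gaussian significance exp(−d²/2σ²) > st |
| Profile HMM | 27 | 20 emission + 7 transition probabilities, p = 2^(−Freq/m) |
| Amide normal vector | 3 | (x_CA − x_CB) × (x_CB − x_N), unnormalized |
| Disorder | 2 | propensity in [0,1] and binary flag (ingested) |

Labels are the inter-chain residue pairs with minimum heavy-atom
distance under 6 Å (positives) plus an equally sized, seeded random
sample of non-interacting pairs (negatives). Curation applies the
standard complex-quality filters (≥ 2 chains, resolution ≤ 3.5 Å,
chains > 50 residues, buried surface area ≥ 500 Å², ≤ 17,500 atoms,
≤ 1,000 residues), a 30% sequence-identity filter against a held-out
test set, and a seeded 80/20 train/validation split written as
`pairs-postprocessed{,-train,-val}.txt`. Records serialize to HDF5 or
pickle and export to node-link JSON graphs whose edges carry distances
and inter-normal-vector angles. See `docs/methods.md` for every
definition, default, and deliberate approximation.

## Worked example

The synthetic fixture generator builds valid two-chain PDB complexes
with a brute-force-verified number of contacts, so the whole pipeline
runs in seconds with no downloads:

```python
from pairfeat import (
    CurationCriteria, PipelineConfig, ToyComplexSpec,
    enumerate_chain_pairs, featurize_pair, make_toy_complex,
    strip_non_standard,
)

structure, ledger = make_toy_complex(
    ToyComplexSpec(n_res_per_chain=20, n_contact_pairs=100, seed=1)
)
config = PipelineConfig(
    criteria=CurationCriteria(min_chain_length=3, min_bsa=1.0,
                              allow_missing_resolution=True),
    seed=1,
)
pair = enumerate_chain_pairs(strip_non_standard(structure))[0]
record = featurize_pair(structure, pair, config)
print(record.name, record.table_0.shape, len(record.positives),
      len(record.negatives))
```

prints

```
toy1.pdb1_0 (20, 91) 100 100
```

one record (complex `toy1`, chain pair 0), a 20-residue feature table
with 91 columns (residue keys, SS, RSA, depth, the 6 protrusion
statistics, the 42 half-sphere slots, coordination number, the 27
profile probabilities, normal vector, disorder, CA coordinates), and —
because the fixture was built with exactly 100 interacting pairs — 100
positives matched by 100 sampled negatives, disjoint from the
positives by construction. The same run from a shell:

```sh
pairfeat make-fixtures --out-dir pdbs --n-complexes 3 --contacts 4
pairfeat featurize --input-dir pdbs --out-dir records --config config.yaml
pairfeat curate --records-dir records --out pairs-postprocessed.txt
pairfeat split --names-file pairs-postprocessed.txt --out-dir splits --seed 1
```

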