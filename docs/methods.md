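# Methods

`pairfeat` turns PDB structures of protein complexes into residue-level
feature tables with interface labels, the preprocessing that
interface-prediction models consume. This note documents the models and
conventions behind each stage, the parameters that matter, and what the
synthetic fixtures do and do not establish.

## Structural model and preprocessing

A structure is parsed (via Bio.PDB) into models → chains → residues →
atoms with coordinates in Å. Downstream processing always uses the
first model, strips hetero residues and waters, and measures every
distance over heavy atoms only, since hydrogens are usually absent from
experimental structures. Conventions where the field has no single
standard:

* **Alternate locations.** The first conformer encountered per atom
  name is kept; occupancy is ignored.
* **Modified residues.** MSE is mapped to MET by default (configurable
  map); "standard" means the mapped name is one of the 20 canonical
  amino acids.
* **Residue identity.** `(chain_id, resseq, icode)` with PDB 1-based
  numbering preserved; feature-table rows use 0-based indices.

Every binary complex is an unordered pair of chains; an n-chain complex
yields C(n, 2) pairs, ordered lexicographically by chain id.

## Feature families

**Relative solvent accessibility (RSA).** Solvent-accessible surface
area comes from a Shrake–Rupley construction: a probe of radius 1.4 Å
is rolled over van-der-Waals spheres (C 1.70, N 1.55, O 1.52, S 1.80 Å;
default 1.8 Å with a warning for unlisted elements) by sampling each
atom's probe-extended sphere with 960 deterministic golden-spiral
points. A residue's SASA is divided by its residue-type maximum
accessible area (Tien-style theoretical constants) and capped at 1.0.
The point count trades accuracy for time; doubling it changes totals by
under 1% on the test fixtures.

**Residue depth (RD).** Mean distance of a residue's heavy atoms to
the exposed Shrake–Rupley point cloud. Classical residue depth is
defined against the solvent-excluded surface; using the accessible
surface instead shifts every depth by a roughly constant probe-scale
offset, which the subsequent per-structure min-max normalization
absorbs. Depth is normalized to [0, 1] per structure via
`(x − b)/(t − b)`, with the observed minimum `b` and maximum `t` taken
jointly over both chains of the pair; a degenerate column (b = t) maps
to the lower bound, and NaNs pass through untouched.

**Protrusion index (PI).** For each heavy atom, the fraction of a
10 Å sphere centered on it that is not occupied by protein atoms,
computed as `clamp((V − k·v)/V, 0, 1)` with `v = 20.1 Å³` per atom and
`k` the number of heavy atoms (the center included) within the radius.
Six statistics summarize a residue: mean, standard deviation, minimum,
maximum, and the mean and standard deviation over the atoms facing the
side chain (on the CB side of the plane through CA normal to CA→CB).
Glycine has no CB, so its side-facing entries are NaN. Columns are
min-max normalized per structure.

**Half-sphere amino-acid composition (HSAAC).** Neighbors within
8.0 Å (CA–CA) are split by the sign of their projection onto the
side-chain axis `u = CB − CA`; a boundary projection of zero counts as
"up". Glycine uses an idealized tetrahedral pseudo-CB built from N,
CA, C. Each half is a 21-slot composition (20 amino acids plus `-` for
unknown types), L1-normalized so it sums to one (L2 selectable), with
empty halves left all-zero; the two halves concatenate to the 1×42
feature. A residue with no CA (or no definable axis) gets a 1×42 NaN
vector. The neighborhood radius is not standardized in the literature
that defines the feature; 8.0 Å is the conventional half-sphere
exposure radius and is recorded in output metadata.

**Coordination number (CN).** Two residues are significant neighbors
when `exp(−d²/(2σ²)) > st`, where `d` is their minimum heavy-atom
distance. The published parameterization sets the length scale equal
to the threshold, σ = st = 1e−3, under which the score underflows for
any physical separation and every CN is 0; the implementation keeps
that literal default (the normalized column then degenerates to the
lower bound) but exposes σ independently so a practical scale, e.g.
σ = 4 Å, can be configured. CN is min-max normalized per structure.

**Profile-HMM features.** HH-suite3 `.hhm` files store per-position
emission (20) and transition (7) frequencies as scaled negative log
probabilities with `*` for impossible events; `p = 2^(−Freq/m)` with
m = 1000 recovers probabilities, `*` mapping to 0 as the limit of the
formula. The 1×27 vector per residue is emissions (file column order,
A…Y) followed by transitions (M→M, M→I, M→D, I→M, I→I, D→M, D→D); the
three alignment-diversity columns are parsed but never emitted, and the
vector is not renormalized. Profiles are matched to chains by exact
sequence comparison, falling back to the best ungapped offset; any
unmapped residue gets a 1×27 NaN row, and a profile matching less than
half the chain maps nothing.

**Amide normal vector (NV).** The unnormalized cross product
`(x_CA − x_CB) × (x_CB − x_N)`; glycine and incomplete backbones give a
1×3 NaN vector. Graph export derives the inter-residue edge angle as
the arccosine of the clamped dot product of the normalized vectors.

**Secondary structure and disorder.** Ingest-only annotations: SS is
one character of the 8-state alphabet with `-` as the default for
unknown values; disorder is a propensity in [0, 1] plus a binary flag,
NaN when absent. The package does not predict either.

## Labels and records

Positives are inter-chain residue pairs whose minimum heavy-atom
distance is strictly below 6.0 Å. The alternative CA–CA reading of the
contact rule is available as `ca_only` mode; the heavy-atom definition
is the default because it is the more specific statement of the rule.
Negatives are an equally sized uniform sample, without replacement,
from the remaining pairs — drawn over the lexicographically sorted
candidate list with a seeded generator (seed recorded in metadata), so
records are reproducible across platforms; when fewer candidates than
positives exist, all candidates are taken with a warning. Missing
numeric features can be imputed columnwise (median by default; mean,
min, max, constant selectable), with an all-NaN column falling back to
zero.

Records serialize to HDF5 (per-column datasets under `/table_0` and
`/table_1`, N×2 label arrays under `/labels`, the resolved
configuration under `/meta`) or pickle, named
`<pdb_id>.pdb<assembly>_<pair_index>` and bucketed by the PDB id's 2nd
and 3rd characters.

## Curation and splits

A pair passes curation when the complex has ≥ 2 chains, resolution
≤ 3.5 Å (the source text reads "greater than", which contradicts the
stated intent of a standard quality threshold; we implement the quality
direction and leave the literal reading selectable), both chains exceed
50 residues, and the buried surface area SASA(A) + SASA(B) − SASA(A∪B)
is at least 500 Å². Size caps of 17,500 atoms and 1,000 residues are
inclusive ("no more than"). Redundancy against a held-out test set
removes any complex with a chain above 30% sequence identity to any
test chain, where identity is matches over the shorter length from a
global alignment (match +1, mismatch 0, affine gaps −11/−1); the
original tool and denominator are unpublished, so exact parity is not
claimed. Matches are counted from the aligner's canonical optimal
alignment; co-optimal alignments can differ by a match, which is far
below the 30% decision margin. Structure-based split removals are
ingested from an external one-name-per-line list rather than
recomputed. The 80/20 split shuffles complex names with a seeded
generator; the train share is rounded half away from zero.

## Synthetic fixtures

The toy generator emulates the geometry the pipeline contracts depend
on — two chains with N/CA/C/CB backbones (3.8 Å CA spacing, glycines
without CB), a controllable and brute-force-verified number of
inter-chain contacts, waters, and valid PDB output — not protein
physics. Exact contact counts come from a block construction:
the target is decomposed into disjoint p×q blocks, each realized as one
tight cluster (every cross-chain CA pair under 6 Å) placed 150 Å from
everything else. Targets that cannot be written as such a disjoint
decomposition within the chain capacity (e.g. n²−1) raise a generation
error rather than approximating. Toy `.hhm` files support uniform,
one-hot, and random frequency patterns. Passing tests therefore
establish the bookkeeping contracts (shapes, counts, determinism,
filter logic) and the closed-form feature math; they do not establish
feature quality on real, physically plausible structures.

## Numerical and design choices

* Strict inequality at the 6 Å contact boundary (configurable);
  inclusive boundaries for the 10 Å interface-water radius and both
  size caps.
* SASA exposure tests points with strict `< R_j` occlusion; distance
  ties at machine precision are immaterial at the default sampling.
* Neighbor-search acceleration (KD-trees) is a pure optimization:
  results are identical to the brute-force double loop, which the test
  suite enforces on fixtures.
* Min-max normalization is idempotent and affine-invariant; all-NaN
  columns are returned unchanged with a warning.
* Negative sampling is frozen at build time with a recorded seed (not
  resampled per training epoch).
* Test problem sizes: fixtures of 3–20 residues per chain, 92–1920
  sphere points, 100-fixture label-parity sweeps — sizes at which the
  brute-force oracles are exact and fast.

## Limitations

* RSA/depth derive from a sampled accessible surface, not DSSP or a
  solvent-excluded surface; values are approximations with documented
  tolerances, and exact parity with those tools is out of scope.
* SS and disorder are ingested, never predicted.
* The literal CN parameterization yields all-zero counts by design;
  meaningful coordination numbers require configuring σ.
* Sequence-identity filtering approximates an unpublished protocol.
* mmCIF input, biological-assembly generation, and model training are
  out of scope.
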