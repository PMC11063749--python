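# Methods

This note documents the models, conventions and numerical choices behind
`narescore`, and what its synthetic benchmarks do and do not demonstrate.

## Distance-fingerprint featurization

For a receptor–pose pair, the feature vector collects, for every ordered
(receptor label, ligand label) pair and every fingerprint function
*f* ∈ {1/r, 1/r⁶, 1/r¹²}, the sum of *f(r_ij)* over inter-molecular atom
pairs with *r_ij* strictly below the cutoff `R_c`. Conventions:

- **Half-open cutoff.** The interval is `[0, R_c)`: a pair at exactly
  `R_c` contributes zero. `R_c` is validated to 4–10 Å (the range over
  which the cutoff is worth scanning; 8 Å is the default).
- **Kinds.** `inv_r` and `inv_r6` are on by default. `inv_r12` is
  implemented but off: close-contact pairs that would make a repulsive
  1/r¹² term informative are rare in nucleic-acid–ligand complexes, and in
  our ablation configuration it adds columns without signal.
- **Hydrogens excluded** by default (`include_hydrogens` flag exists):
  docking outputs carry inconsistent protonation, and heavy-atom
  fingerprints keep featurization independent of the protonation tool.
- **Degenerate geometry.** An inter-molecular distance below 1e-6 Å raises
  rather than producing a divergent feature; overlapping atoms indicate a
  corrupt pose.
- **Units.** Distances in Å exactly as stored in the input files; no
  periodicity or crystal-symmetry handling.
- **Neighbour search** uses a scipy k-d tree, giving near-linear scaling
  in atom counts. A brute-force O(N·M) double loop is kept in the test
  suite as an independent oracle; the two agree to 1e-10 relative on
  hundreds of randomized fixtures, and the tree path is the only one used
  in production.
- **Intramolecular terms** (receptor–receptor, ligand–ligand) are out of
  scope by design: the score rates the interface, not conformer strain.

Fingerprint invariants verified by property tests: monotone growth in
`R_c`, exact invariance under rigid motion of the complex, and additivity
over disjoint ligand fragments.

## Interaction labels and the type registry

Receptor atoms map to `RES_rec` labels: residue class × SYBYL group, with
seven residue classes `{A, C, G, U, N, OTH, Metal}`:

- backbone atom names (primed sugar atoms, `P`, `OP1/OP2/...`) → class `N`
  regardless of residue;
- canonical base atoms of A/C/G/U (DNA residues and a table of common
  modified residues aliased to their parent base; thymine to the U class)
  → the base's class, with a per-atom SYBYL lookup;
- atoms in the modified region of an aliased residue, and atoms of
  unrecognized residues, → `OTH`, typed by element (the sparse "other
  element" bin is shared);
- monoatomic ions → `Metal`.

Ligand atoms map to grouped SYBYL types; rare raw types are binned with
their closest chemistry (e.g. `S.2 → S.3`, `S.o → S.o2`, all metal
elements → one ligand `Metal` group that keeps organometallics such as
ruthenium polypyridyl complexes in scope). SYBYL types from mol2 input are
used verbatim; for SDF input they are perceived from the bond graph with
rdkit (aromaticity, hybridization, amide/carboxylate/guanidinium special
cases) — deliberately not a general-purpose Tripos typing engine, only the
vocabulary the grouping distinguishes. An atom whose raw type has no
grouping entry raises; the registry must be extended explicitly rather
than guessed.

The default registry (26 receptor × 24 ligand labels, 624 pairs) ships as
a human-readable YAML file and is **a reconstruction**: the exact published
grouping tables for this label vocabulary are not publicly enumerable, so
the defaults were chosen once from standard nucleotide nomenclature and
SYBYL conventions to land on the documented cardinalities. Every label
assignment is data-driven; swapping the YAML (CLI `--registry`) changes the
typing without code changes. A SHA-256 digest of the registry travels with
trained models and is checked at scoring time to prevent silent schema
drift.

**Column pruning** removes fingerprint columns that are zero in every
training row, per column (pair × kind), not per pair — the two kinds of a
pair can die independently. The retained-column mask is persisted and
replayed on scoring inputs; missing score-component columns at scoring
time are zero-filled with a warning (poses from other docking tools may
not carry rDock tags), while a missing fingerprint column is a hard schema
error.

## RMSD labels and dataset filters

Pose labels are **in-place symmetry-corrected RMSDs**: the minimum over
all automorphisms of the ligand's heavy-atom molecular graph (element- and
bond-order-preserving, aromatic bonds matched as a distinct order) of the
RMSD between mapped coordinates, with **no Kabsch superposition** — a
docked pose's deviation is meaningful in the receptor frame, and
realigning would hide exactly the displacement being measured.
Automorphisms are enumerated with networkx's VF2 matcher, capped at 10⁴
mappings; past the cap (pathologically symmetric molecules) the best
mapping seen is used with a warning. The result never exceeds the
identity-mapping RMSD, and a non-isomorphic reference raises (wrong
ligand).

Dataset construction mirrors redocking practice: a dock attempt is a
*success* when its RMSD is ≤ 10 Å; a ligand enters the dataset only with
at least 100 successes (out of a nominal 400 attempts), and then
contributes exactly 100 successful poses. Which 100 is not dictated by the
data, so the default draws uniformly without replacement under a recorded
seed — avoiding any docking-order bias — with a `first` mode available for
strict file-order selection. A pose is *close to native* when its RMSD is
≤ 2.0 Å (inclusive).

## Training

Rows are split by structure ID with systematic sampling: IDs are sorted
lexicographically and the ID at sorted position *p* goes to fold *p* mod
*k* (default *k* = 5). This guarantees by construction that no structure's
poses appear on both sides of any fold; the property is asserted on every
plan.

The learner is an XGBoost regressor (squared-error objective, `hist` tree
method, single-threaded for determinism). A random search (default 100
draws) samples: boosting rounds 100–1000, max depth 3–10, learning rate
10⁻²–0.3 (log-uniform), row/column subsampling 0.5–1.0, L1/L2 weights
10⁻³–10 (log-uniform) — standard effective ranges for boosted trees on
sparse tabular data, all exposed in configuration. Each draw trains *k*
fold models; the draw with the highest mean validation R² wins (ties to
the lower draw index) and is **refit on the full training table** — the
refit maximizes data use, while the winning draw's per-fold CV statistics
are kept as the honest generalization estimate. Given the seed, the
selected draw, CV metrics and predictions are bit-reproducible.

Persistence is a bundle directory: the booster as JSON, plus the column
mask, featurizer config, registry digest, hyperparameter draw and CV
metrics. Loading verifies the bundle format and that the mask width
matches the model; predictions after a round trip are identical.

## Evaluation

- `R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)²` (may be negative; undefined for constant
  actuals).
- Per-ligand PCC, and SRCC as Pearson on midranks — this generalization
  handles tied scores and reduces exactly to the classical
  `1 − 6Σd²/(n(n²−1))` form on tie-free inputs (property-tested; both
  metrics are cross-checked against scipy to 1e-12 but computed
  independently).
- Top-*n* success: whether a close-to-native pose appears among the *n*
  best-scored poses; lower score = better, ties broken by stable input
  order so results are reproducible. Two denominators are reported side by
  side — all evaluated ligands, and only ligands whose pose set contains
  at least one close-to-native pose — because both conventions are in
  circulation and the choice materially changes the number; neither is
  anointed canonical.
- Feature importance by column ablation: for each fold, a model with the
  selected hyperparameters is refit on the fold's training rows, and ΔR² =
  R²(validation with the column group zeroed) − R²(original validation) is
  recorded. Negative ΔR² means the feature mattered. A (receptor, ligand)
  pair is one group spanning all its fingerprint kinds; each score
  component is its own group. Zeroing an already-zero column is the
  identity, giving ΔR² = 0 exactly.

## Synthetic fixtures: what they show and what they don't

The fixture module generates three kinds of inputs, all bit-reproducible
from a seed:

- **Toy complexes** — residues on a coarse helix (radius 9 Å, twist 36°,
  rise 2.8 Å) with correctly named backbone/base atoms, one modified
  residue and one ion, so every typing rule fires; ligand templates with
  an aromatic ring (non-trivial automorphism group), a plain chain, and a
  metal complex. Geometry is *not* physically refined; featurization only
  needs names, types and coordinates.
- **Pose ladders** — rigid translations of the reference at specified
  displacements, so the symmetry-corrected RMSD label of pose *k* equals
  the *k*-th ladder value exactly, plus seeded jittered decoys and
  synthetic `SCORE*` tags emulating a docking program's output.
- **Planted tables** — sparse non-negative feature columns with one
  informative column and label = 10 − 4·x + N(0, 0.3), grouped into
  pseudo-structure IDs. The defaults used by the acceptance checks are 40
  groups × 50 rows with a 10-draw search.

Passing tests on these fixtures demonstrate the *mechanics*: featurization
exactness against an oracle, label exactness, filter and split semantics,
and that the training stack can recover a known monotone
feature–RMSD relation out of noise on held-out groups. They deliberately do
not demonstrate chemical accuracy on real nucleic-acid complexes — toy
geometry has none of the pocket shape, pose clustering, or score-component
correlations of real docking output, and results on it say nothing about
ranking performance on experimental structures. Training on real rDock
output through the same interfaces is the intended production path.

## Known limitations

- The default registry approximates grouping tables that could not be
  recovered exactly; users with their own conventions should supply a
  registry file.
- SYBYL perception covers common organic chemistry plus the special cases
  above; exotic valence states fall back to element-level types or raise.
- The published corpus-scale headline correlations require hundreds of
  experimentally solved complexes plus docking runs and are outside what
  this repository's synthetic benchmarks can or try to reproduce.
- mmCIF receptors, docking execution, receptor preparation and molecular-
  dynamics validation are out of scope.
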