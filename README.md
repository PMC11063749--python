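# narescore

Rescoring of nucleic-acid–ligand docking poses by machine-learned RMSD
prediction.

Docking programs are reasonably good at *generating* near-native poses of a
small molecule in an RNA or DNA binding site, and much worse at *ranking*
them: the pose with the best docking score is often far from the
crystallographic ligand. `narescore` rescoring treats pose ranking as a
regression problem — predict the symmetry-corrected RMSD of each docked
pose from the native ligand, and use the prediction itself as the docking
score (lower = better). It is aimed at structural bioinformaticians running
pose prediction or virtual screening against nucleic-acid targets with
tools such as rDock.

## Model

Each pose is encoded by pairwise **distance fingerprints**. Every receptor
atom *i* carries a label `RES_rec` — residue class
`RES ∈ {A, C, G, U/T, N, OTH, Metal}` (N = ribose/phosphate backbone, OTH =
modified-residue region, thymine grouped with uracil) crossed with a SYBYL
atom-type group — and every ligand atom *j* carries a grouped SYBYL type.
For each of the 26 × 24 = 624 label pairs and each fingerprint function
*f* ∈ {1/r, 1/r⁶, 1/r¹²} the feature is

```
F(f(r_ij)) = Σ f(r_ij)   over atom pairs with r_ij ∈ [0, R_c)
```

with cutoff `R_c = 8 Å` by default (the interval is half-open: a pair at
exactly `R_c` contributes nothing). The physical prefactors of the
electrostatic and Lennard-Jones terms these functions resemble are not
supplied — they are absorbed into the constants a gradient-boosted tree
ensemble (XGBoost, squared-error objective) learns from data. Per-pose
docking-score components (SD tags prefixed `SCORE`, as written by rDock)
are appended as extra features, and all-zero fingerprint columns are
pruned.

Training uses grouped five-fold cross-validation — systematic sampling over
sorted structure IDs, so no structure contributes poses to both sides of a
fold — with a random hyperparameter search selected by mean validation R².
Evaluation reports per-ligand Pearson (PCC) and Spearman (SRCC)
correlations between score and true RMSD, the fraction of ligands with a
close-to-native pose (RMSD ≤ 2 Å) among the top-*n* scored poses, and
column-ablation feature importance (ΔR² on zeroing a column group; negative
= important).

Labels come from the **symmetry-corrected RMSD**: the minimum in-place
(no realignment) heavy-atom RMSD over all automorphisms of the ligand's
molecular graph, which removes artificial RMSD inflation from chemically
equivalent atom relabelings such as a flipped aromatic ring. Ligands enter
a training set only when at least 100 of their dock attempts are successful
(RMSD ≤ 10 Å), and contribute exactly 100 successful poses.

## Worked example

The package ships a deterministic fixture generator, so the whole pipeline
can be exercised without any external data. Build six toy nucleic-acid
complexes, each with a 12-pose ladder at known displacements, then
featurize, label, train, score and evaluate:

```sh
for seed in 0 1 2 3 4 5; do
  narescore make-fixtures --seed $seed --n-poses 12 --out fx$seed
  narescore featurize --receptor fx$seed/receptor.pdb --poses fx$seed/poses.sdf \
      --label-ref fx$seed/native.sdf --out fx$seed/feats.csv
  narescore label --reference fx$seed/native.sdf --poses fx$seed/poses.sdf \
      --out fx$seed/labels.csv
done
# concatenate fx*/feats.csv -> feats.csv and fx*/labels.csv -> labels.csv, then:
narescore train --features feats.csv --folds 3 --trials 3 --seed 7 --out model
narescore predict --model model --features feats.csv --out scores.csv
narescore evaluate --scores scores.csv --labels labels.csv --topn 1,5 --out report.json
narescore importance --model model --features feats.csv --folds 3 --out importance.csv
```

which prints, step by step:

```
fixture written to fx0 (12 poses)
wrote 12 rows x 1255 columns to fx0/feats.csv
8/12 successful docks (RMSD <= 10.0 Å)
...
best mean validation R^2 = 0.94877 ± 0.01117; bundle at model
scored 72 poses -> scores.csv
mean PCC 1.00000, mean SRCC 1.00000
wrote importance for 45 column groups -> importance.csv
```

The 1255 columns are the 624 pairs × 2 fingerprint kinds plus three
synthetic `SCORE*` components and four identity/label columns. The
validation R² of 0.949 says the model predicts pose RMSD on structures
whose other poses it never saw; the per-ligand PCC/SRCC of 1.0 say that on
this easy rigid-displacement fixture the predicted-RMSD score ranks every
ligand's poses in exactly the true order. The first lines of
`importance.csv` show the most important column groups — here the synthetic
`SCORE` tag, whose ablation costs 0.32 of validation R²:

```
column,mean_delta_r2,...
SCORE,-0.323996290269,...
SCORE.INTER,-0.0724881632591,...
```

Real data enter through the same commands: `--receptor` takes a PDB or
mol2 receptor, `--poses` an SDF written by the docking program (score
components are read from its SD tags), and `--registry` swaps in a custom
atom-typing table (`src/narescore/data/default_registry.yaml` documents
the format).

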