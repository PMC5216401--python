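# docksel

Machine-learned pose selection and binding-affinity scoring for
**ensemble docking**.

## The problem

Docking a ligand against several crystal conformations of a flexible
binding site yields a combinatorial candidate set — with S protein
structures, K conformers per ligand and P poses kept per docking
calculation, each ligand arrives with S × K × P candidates (typically
7 × 10 × 3 = 210).  Scoring functions correlate only weakly with pose
quality: pooled across structures, a single scoring term rarely explains
more than half the variance in pose RMSD, and the score↔RMSD relationship
is nonlinear and protein-conformation-specific.  Picking the top pose by
one score, or even by consensus rescoring, is therefore unreliable — and a
bad pose poisons any downstream affinity prediction.

docksel addresses this for computational chemists building
structure-based QSAR/scoring models:

1. **Pose selection** — one RBF-kernel support-vector regressor (SVR) per
   protein structure maps the pose's scoring-term vector **x** to its
   RMSD (Å) from the native binding mode.  Hyperparameters (ε-SVR vs
   ν-SVR, C, γ, ε/ν) are chosen by maximizing the 10-fold cross-validated
   q²cv = 1 − PRESS/Σ(yᵢ−ȳ)² over a lattice.  Each candidate is scored by
   *its own* structure's model; the ligand's selected pose is the
   ensemble-wide argmin of predicted RMSD.
2. **Affinity scoring** — the selected pose's interaction terms plus
   molecular descriptors (cleaned, decorrelated at r² ≥ 0.64, selected by
   a genetic algorithm + recursive feature elimination, z-normalized with
   training statistics) feed a second RBF-SVR regressing
   pKi = −log₁₀ Ki [M], trained on a deterministic Kennard–Stone 2:1
   split.
3. **Validation** — the complete external-validation battery: r², q²,
   q²cv, through-origin slopes k, k′ and coefficients r0², r0′², Roy's
   rm² = r²(1 − √|r² − r0²|) family, Lin's concordance correlation
   coefficient, the stringent pass/fail criteria built on them, and
   confusion-matrix statistics (sensitivity, specificity, accuracy, MCC,
   Kubat's G-mean) for qualitative top-pose selection.
4. **Baselines** — single-term ranking and the three classical consensus
   schemes (rank-by-number, rank-by-rank, rank-by-vote) for head-to-head
   benchmarking.
5. **Synthetic benchmarks** — a seeded generator of complete
   pose/descriptor/affinity bundles with known ground truth, emulating
   the statistical structure above so every pipeline stage is testable
   end-to-end without proprietary docking software.

Estimators follow scikit-learn conventions (`fit`/`predict`,
`get_params`, fitted attributes with trailing underscores) and compose
with sklearn tooling; tables are plain pandas DataFrames read from
CSV/TSV.

## Worked example

```python
from docksel import (SyntheticConfig, generate_benchmark, select_top_pose,
                     predict_pose_rmsd, regression_report)
from docksel.pose import PoseModelSet
from docksel.benchmark import benchmark_grid

cfg = SyntheticConfig(n_structures=3, n_ligands=20,
                      conformers_per_ligand=5, seed=7)
poses, descriptors, affinities, truth = generate_benchmark(cfg)
print("candidates per ligand:", len(poses) // cfg.n_ligands)

train = poses.groupby("structure_id", group_keys=False).head(100)
models = PoseModelSet.train(train, grid=benchmark_grid(), seed=0)
print(models.metadata_frame()[["structure_id", "n_train", "train_r2", "q2cv"]]
      .round(3).to_string(index=False))

preds = predict_pose_rmsd(models, poses)
best = select_top_pose(preds, group_by="ligand_id")
print(best.head(3).to_string(index=False))

rep = regression_report(poses["observed_rmsd"], preds["predicted_rmsd"])
print(f"pooled r2 = {rep.r2:.3f}, rmse = {rep.rmse:.3f} A")
```

Output:

```
candidates per ligand: 45
structure_id  n_train  train_r2  q2cv
          S1      100     0.969 0.959
          S2      100     0.984 0.953
          S3      100     0.973 0.952
ligand_id structure_id  conformer_id  run_id  pose_id  predicted_rmsd
     L001           S3             2       1        3        0.000000
     L002           S1             5       1        1        0.000000
     L003           S2             1       1        3        0.055018
pooled r2 = 0.963, rmse = 0.505 A
```

Each ligand's 45 candidates (3 structures × 5 conformers × 3 poses) are
reduced to one selected pose; `train_r2`/`q2cv` are each structure
model's training fit and cross-validated predictivity, and the pooled r²
compares predicted vs observed RMSD over all candidates.  Predicted RMSDs
of 0.0 are negative raw regression outputs clipped at the physical lower
bound.

The same flow is available from the shell:

```bash
docksel simulate --seed 7 --out bundle/
docksel pose train bundle/pose_table.tsv --grid fast --out models/
docksel pose predict bundle/pose_table.tsv models/ --out preds.csv
docksel pose select preds.csv --out best.csv
docksel pipeline --seed 7 --out run/        # full end-to-end with manifest
```

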