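# Methods

## Problem setting

Ensemble docking places each ligand into several crystal conformations of
the same binding site.  With S protein structures, K conformers per ligand
and P poses kept per docking calculation, every ligand arrives with
S × K × P candidate poses (default 7 × 10 × 3 = 210), each described by the
numeric terms of a panel of scoring functions.  Two decisions follow:

1. **Pose selection** — which single candidate best approximates the
   native binding mode (lowest RMSD to the native pose, in the fixed
   protein frame, correspondence by atom order, no re-superposition)?
2. **Affinity scoring** — given that pose, what is the ligand's binding
   affinity, expressed as pKi = −log10(Ki in molar)?

Single scoring terms correlate weakly with pose RMSD when pooled across
protein structures, because the score↔RMSD relationship is nonlinear and
structure-specific.  docksel therefore trains one RBF-kernel support-vector
regressor (SVR) per protein structure mapping the scoring-term vector of a
pose to its RMSD, selects the candidate with the lowest predicted RMSD
across the whole ensemble, and feeds the selected pose's interaction terms,
together with curated molecular descriptors, into a second RBF-SVR that
regresses pKi.

## Models

### Per-structure pose-RMSD regressors

For structure s, poses with observed RMSD provide training pairs
(x, y) where x is the scoring-term vector and y the RMSD in Å.  Features
are z-normalized with training statistics (sample sd, ddof = 1) inside the
estimator; the kernel is RBF.  Both ε-SVR and ν-SVR formulations are
scanned along with C, γ and the tube parameter; the selected lattice point
maximizes 10-fold cross-validated

    q²cv = 1 − PRESS / Σ(yᵢ − ȳ)²

with out-of-fold predictions pooled over a seeded fold assignment shared by
all lattice points (the scan is embarrassingly parallel and independent of
execution order).  Ties prefer smaller C, then a flatter tube.  The default
lattice spans C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵}, γ ∈ {2⁻¹⁵, …, 2³},
ε ∈ {0.01, 0.05, 0.1, 0.2, 0.5} and ν ∈ {0.2, 0.4, 0.5, 0.6, 0.8}
(`full_grid()`, 1100 points); benchmark runs use the coarser 48-point
lattice in `docksel.benchmark.benchmark_grid()` and smoke tests a 12-point
`tiny_grid()` — the lattice is a runtime-quality dial, not part of the
model definition.  Raw predictions below zero are clipped to 0 Å and
flagged (RMSD is non-negative; the regression output is not).

Fitted models are persisted as versioned JSON artifacts holding the
support-vector expansion (support vectors, dual coefficients, intercept,
γ) and the normalization statistics explicitly; prediction is evaluated
from those arrays, so a reloaded model predicts bit-identically.

### Ensemble selection

Across a ligand's whole candidate set, each candidate is scored by the
model of *its own* structure and the minimum predicted RMSD wins; ties
break lexicographically on (structure, conformer, run, pose).  Selection is
invariant under any strictly increasing transform applied uniformly to the
predictions.

### Affinity regressor

One feature row per ligand: the selected pose's scoring terms named in the
feature configuration (default: the first two terms, mirroring the
external/internal interaction contributions a practitioner would adopt)
plus the descriptors surviving selection.  The same grid-scanned RBF-SVR
machinery is reused; the response is always pKi, never raw Ki, keeping the
regression scale log-linear.

## Descriptor preparation

* **Cleaning** removes descriptors missing for any compound, with at most
  one distinct value, or with sample sd < 1e−8.
* **Intercorrelation filter**: no surviving pair may have squared Pearson
  correlation ≥ 0.64.  Within an offending pair the column more correlated
  (|r|) with the response survives when a response is supplied, otherwise
  the earlier column — a greedy pass in decreasing relevance order.
* **Normalization** centers at the training mean and divides by the
  training sample sd; test rows always use training statistics.
* **GFA** (genetic function algorithm): descriptor bitmasks with bounded
  cardinality evolve under tournament selection, uniform crossover,
  per-bit mutation and elitism; fitness is the negated 5-fold
  cross-validated MSE of a ridge fit on the subset (a fast, deterministic
  surrogate for a full QSAR fit; the best-so-far fitness is non-decreasing
  by construction).  Defaults: population 100, 50 generations, seeded.
* **RFE** prunes the GFA subset to the final size with scikit-learn's
  recursive feature elimination around a ridge estimator, recording the
  elimination order.
* **Kennard–Stone split**: the maximum-distance pair seeds the training
  set; points join by maximal minimum distance to the selected set until
  |train| = floor(n·r/(r+1)) for ratio r:1 (2:1 by default, reproducing a
  24/13 split of 37 compounds).  Ties break to the lowest row index, so the
  split is deterministic given input order.  The historical data set this
  pipeline emulates described its split both as Kennard–Stone and as
  random assignment; the deterministic Kennard–Stone reading is taken as
  authoritative.

## Validation battery

`regression_report` computes r², the external q² (squared Pearson on the
test set, with the predictive form 1 − Σ(y−ŷ)²/Σ(y−ȳ)² reported alongside
as `q2_f1`), MAE, RMSE, the residual sd s, Δmax, the through-origin slopes
k = Σyŷ/Σŷ² and k′ = Σyŷ/Σy², their determination coefficients r0² and
r0′², Roy's rm² = r²·(1 − √|r² − r0²|) family (primed, average, Δ), and
Lin's concordance correlation coefficient from population moments,
CCC = 2·cov/(var_y + var_ŷ + (ȳ − ȳ̂)²).  |r² − r0²| is used under the
radical so rm² stays defined when r0² > r².

`criteria_battery` applies the stringent external-validation thresholds:
q²cv > 0.5; test r² > 0.6; (r² − r0²)/r² < 0.1 for at least one
through-origin variant; a through-origin slope within [0.85, 1.15];
|r0² − r0′²| < 0.3; rm²_avg > 0.5 with Δrm² < 0.2; CCC > 0.85.  All
thresholds are overridable; verdicts render as the conventional "x" marks.

Qualitative top-pose selection is scored by a confusion matrix over
candidate groups: a candidate is actual-positive when its observed RMSD
equals the group minimum (ties: all tied candidates) and
predicted-positive when selected.  Sensitivity, specificity, accuracy, MCC
(0 with a flag on degenerate margins) and Kubat's G-mean
(√(sensitivity·specificity)) follow.

## Consensus baselines

Every term carries a higher-better/lower-better annotation; consensus
arithmetic first aligns all terms to higher-better.  *Rank-by-number*
averages (by default z-standardized) aligned scores — standardization
guards against the differing numeric spans of scoring functions and makes
this the one scheme sensitive to monotone transforms of a term.
*Rank-by-rank* averages per-term within-group ranks (ties share average
ranks).  *Rank-by-vote* lets each term vote for its top ⌈m/3⌉ candidates
per group (the natural one-vote-per-docking choice with 3 poses per
calculation; configurable), ordering by votes, then mean rank, then key.
All schemes reduce to single-term ranking for one term, and the rank-based
schemes are invariant under strictly increasing per-term transforms.

## Synthetic benchmark generator

No public data set accompanies this problem shape, so the generator
fabricates complete, seeded bundles whose *statistical* structure matches
what an ensemble-docking campaign against a flexible site produces:

* Candidate RMSDs are a mixture: near-native (probability 1/3, |N(0.35 Å,
  0.25 Å)|— redocked native ligands cluster well under 1 Å) and decoy
  (uniform 1–8 Å).
* Scoring term t on structure s is
  α_{s,t}·exp(−R/τ_{s,t}) + β_{s,t}·R + c_t·u_ℓ + ε, with amplitudes
  α structure-specific in magnitude *and occasionally in sign*
  (flip probability 0.3) — scoring terms whose score/RMSD relationship
  inverts between protein conformations are what defeats globally aligned
  single-term and consensus ranking while leaving per-structure learning
  intact.  τ ∈ U(0.5, 3), a signed linear leak β, a ligand-level
  confounder u_ℓ shared across a ligand's candidates, and Gaussian noise
  scaled to each structure's own signal spread (factor 0.45).
* A calibration loop (≤ 20 retries, scaling noise by 1.3) enforces that no
  single term's pooled linear r² against RMSD exceeds 0.5, the regime in
  which linear rescoring is known to be unreliable.
* Descriptors: 8 informative columns (named for typical roles — H-bond
  donors, chirality counts, charge indices, …) among 60, plus deliberately
  dirty columns (missing cells, constants, near-duplicates) for the
  preprocessing chain to remove.  pKi combines linear descriptor effects,
  one descriptor×descriptor interaction, one effect conditional on the
  bound/unbound flag, and a small contribution from the true best pose,
  rescaled to span ≥ 7 log units (base 3, span 8 — a realistic nM-to-mM
  assay range) before adding N(0, 0.3) noise.
* The returned truth object stores every parameter and noise draw, so each
  table entry is exactly recomputable, and records the true top pose per
  ligand for recovery tests.

**What passing tests do and do not show.**  The generator reproduces the
relational structure (nonlinear, structure-specific, weakly linearly
correlated links; a low-dimensional informative descriptor subset) but not
the marginal distributions of real scoring functions or real descriptor
blocks, pose-to-pose geometric correlation within a docking run, activity
cliffs, or assay heterogeneity.  Success here demonstrates that the
machinery recovers the intended signal under the stated noise model — not
that any particular real target will yield the same accuracy.

## Benchmark protocol and problem sizes

`docksel.benchmark` fixes the standard evaluation: default bundle
(7 × 40 × 10 × 3), half the ligands held out; per structure the RMSD
regressor trains on 150 poses sampled from training ligands over the
48-point lattice with 10-fold scans; selection is benchmarked per docking
calculation (groups of 3 poses — the granularity at which a practitioner
keeps one pose per run) on held-out ligands against every single term and
all three consensus schemes.  The affinity protocol uses 150 ligands,
cleaning → filter → GFA (population 40, 20 generations, subsets 8–16) →
RFE to 10 descriptors on the Kennard–Stone training split, then the
regressor with the same lattice; a permuted-response control repeats the
fit with destroyed signal.  These sizes keep a full run around a minute on
one CPU while leaving the measured quantities comfortably inside their
expected regimes.

## Numerical and design notes

* Sample (ddof = 1) standard deviations throughout normalization; zero-sd
  features are an error directing the user to cleaning, never silently
  skipped.
* Fold assignment for q²cv is a seeded permutation dealt round-robin
  (grid scans) or stratified by response quantile
  (`q2_cross_validation`), and recorded.
* Missing values in all CSV/TSV dialects are empty fields; NaN never
  propagates into a model (feature building and training validate).
* Bound (co-crystallized) ligands pass through the same predicted-RMSD
  selection as unbound ones — uniform treatment is simpler and introduces
  no special case.
* The end-to-end pipeline derives stage seeds from the global seed by a
  stable hash of the stage name, so any stage re-runs independently yet
  reproducibly; reruns with the same configuration are byte-identical.
* Model artifacts refuse to load across format-version changes or kind
  mismatches (pose vs score).

## Known limitations

* Heavy-atom, order-based RMSD without symmetry correction will overstate
  the RMSD of symmetric ligands; callers with symmetric scaffolds should
  pre-canonicalize atom order.
* The GFA fitness is a ridge surrogate: descriptor subsets whose value is
  purely non-additive may be under-selected (RFE and the SVR downstream
  partially compensate).
* External q² conventions differ across the QSAR literature; both the
  Pearson and predictive forms are reported, and criteria thresholds are
  configurable rather than hard-wired.
* Per-structure models need ≥ 10 labeled poses (30+ recommended); the
  framework does not pool information across structures by design.
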