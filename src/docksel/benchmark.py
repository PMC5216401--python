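"""Reference benchmark procedures on the synthetic ensemble-docking bundle.

These routines define the package's standard evaluation protocol — the
problem sizes, splits and hyperparameter lattice used when the toolkit
is exercised end-to-end on generated data — so that the test suite, the
acceptance script and the CLI all measure the same quantities the same
way.

Protocol (pose side): generate the default 7-structure x 40-ligand
bundle; hold out half the ligands; per structure, train the RMSD
regressor on 150 poses sampled from the training ligands and evaluate
held-out r2, the cross-structure r2 matrix and top-pose selection
(groups = one docking calculation, i.e. the 3 poses of a
ligand/structure/conformer triple) against single-term and consensus
baselines on the held-out ligands.

Protocol (affinity side): generate a 150-ligand bundle; run the full
descriptor chain (clean -> intercorrelation filter -> GFA -> RFE) on the
Kennard-Stone training split; train the affinity regressor on the
training split with two selected-pose scoring terms plus the selected
descriptors; report train/test statistics and a permuted-response
control.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import consensus as cns
from .io import RMSD_COLUMN
from .metrics import (classification_report, pose_selection_confusion,
                      regression_report)
from .pose import (PoseModelSet, cross_structure_r2_matrix,
                   predict_pose_rmsd, select_top_pose, train_pose_model)
from .prep import clean_descriptors, filter_intercorrelated, gfa_select, \
    kennard_stone_split, rfe_select
from .score import (AffinityRegressor, ScoreFeatureConfig,
                    build_score_features, train_score_model)
from .svr import build_grid
from .synth import SyntheticConfig, generate_benchmark, truth_summary

SELECTION_GROUP = ["ligand_id", "structure_id", "conformer_id"]


def benchmark_grid():
    """The hyperparameter lattice used by the standard benchmark runs
    (48 points; both SVR modes)."""
    return build_grid(
        C_values=[2.0**k for k in (0, 3, 6)],
        gamma_values=[2.0**k for k in (-5, -3, -1, 1)],
        eps_values=[0.05, 0.2],
        nu_values=[0.3, 0.6],
    )


def run_pose_benchmark(seed: int = 1, config: SyntheticConfig | None = None,
                       n_train_poses: int = 150) -> dict:
    """Train per-structure pose models and benchmark top-pose selection.

    Returns a dict with per-structure native held-out r2, the
    cross-structure r2 matrix, pooled single-term linear r2, and G-mean
    of learned selection vs the best single-term and consensus baselines
    on held-out ligands.
    """
    cfg = config or SyntheticConfig(seed=seed)
    pose_table, desc, aff, truth = generate_benchmark(cfg, seed=seed)
    summary = truth_summary(pose_table, desc, aff, truth)

    rng = np.random.default_rng(seed + 1000)
    ligs = np.array(truth.ligand_ids)
    perm = rng.permutation(len(ligs))
    half = len(ligs) // 2
    train_ligs = set(ligs[perm[:half]])
    pt_train = pose_table[pose_table["ligand_id"].isin(train_ligs)]
    pt_eval = pose_table[~pose_table["ligand_id"].isin(train_ligs)].reset_index(drop=True)

    grid = benchmark_grid()
    artifacts, native_r2 = {}, {}
    for k, sid in enumerate(truth.structure_ids):
        sub = pt_train[pt_train["structure_id"] == sid].reset_index(drop=True)
        take = rng.permutation(len(sub))[:n_train_poses]
        artifacts[sid] = train_pose_model(sid, sub.iloc[take], grid=grid,
                                          seed=seed + k)
        ev = pt_eval[pt_eval["structure_id"] == sid]
        pred = np.clip(artifacts[sid].predict_frame(ev), 0, None)
        y = ev[RMSD_COLUMN].to_numpy(dtype=float)
        native_r2[sid] = float(np.corrcoef(y, pred)[0, 1] ** 2)
    model_set = PoseModelSet(artifacts)

    mat = cross_structure_r2_matrix(model_set, pt_eval)
    diag = np.diag(mat.to_numpy())
    off = mat.to_numpy()[~np.eye(len(mat), dtype=bool)]
    diag_dominant = all(
        mat.iloc[i, i] >= mat.iloc[i, j]
        for i in range(len(mat)) for j in range(len(mat)) if i != j)

    preds = predict_pose_rmsd(model_set, pt_eval)
    selected = select_top_pose(preds, group_by=SELECTION_GROUP)
    cm = pose_selection_confusion(selected, pt_eval, SELECTION_GROUP)
    learned = classification_report(cm)

    single = {}
    for term, direction in truth.term_directions.items():
        r = cns.single_function_ranking(pt_eval, term, direction,
                                        group_cols=SELECTION_GROUP)
        c = pose_selection_confusion(cns.top_candidates(r), pt_eval,
                                     SELECTION_GROUP)
        single[term] = classification_report(c).g_mean
    schemes = {
        "rank_by_number": cns.rank_by_number(pt_eval, truth.term_directions,
                                             group_cols=SELECTION_GROUP),
        "rank_by_rank": cns.rank_by_rank(pt_eval, truth.term_directions,
                                         group_cols=SELECTION_GROUP),
        "rank_by_vote": cns.rank_by_vote(pt_eval, truth.term_directions,
                                         group_cols=SELECTION_GROUP),
    }
    consensus_g = {}
    for name, ranking in schemes.items():
        c = pose_selection_confusion(cns.top_candidates(ranking), pt_eval,
                                     SELECTION_GROUP)
        consensus_g[name] = classification_report(c).g_mean

    best_single = max(single.values())
    best_consensus = max(consensus_g.values())
    return {
        "native_r2": native_r2,
        "min_native_r2": min(native_r2.values()),
        "cross_matrix": mat,
        "diag_mean": float(diag.mean()),
        "offdiag_mean": float(off.mean()),
        "diag_dominant": bool(diag_dominant),
        "pooled_term_r2": summary["pooled_term_r2"],
        "max_pooled_term_r2": summary["max_pooled_term_r2"],
        "g_mean_learned": learned.g_mean,
        "sensitivity_learned": learned.sensitivity,
        "specificity_learned": learned.specificity,
        "g_mean_single": single,
        "g_mean_consensus": consensus_g,
        "g_mean_best_single": best_single,
        "g_mean_best_consensus": best_consensus,
        "g_mean_margin": learned.g_mean - max(best_single, best_consensus),
        "model_set": model_set,
        "pose_table_eval": pt_eval,
    }


def run_affinity_benchmark(seed: int = 1, n_ligands: int = 150,
                           permuted_control: bool = True) -> dict:
    """Descriptor chain + affinity regression on a synthetic ligand set.

    Trains on the Kennard-Stone 2:1 training split after cleaning,
    intercorrelation filtering (r2 >= 0.64), GFA pre-selection and RFE
    pruning to 10 descriptors; features add the selected pose's first
    two scoring terms.  Reports train r2, test q2 (squared Pearson and
    predictive forms) and, optionally, the same statistic after randomly
    permuting the training/test responses (signal-destroyed control).
    """
    cfg = SyntheticConfig(n_ligands=n_ligands, seed=seed)
    pose_table, desc, aff, truth = generate_benchmark(cfg, seed=seed)

    pki = aff.set_index("ligand_id")["pki"]
    cleaned = clean_descriptors(desc)
    y_all = cleaned["ligand_id"].map(pki).to_numpy(dtype=float)
    filtered = filter_intercorrelated(cleaned, 0.64, target=y_all)

    cols = [c for c in filtered.columns if c != "ligand_id"]
    X = filtered[cols].to_numpy(dtype=float)
    Xz = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)

    split = kennard_stone_split(Xz, ids=filtered["ligand_id"].tolist(),
                                ratio=(2, 1))
    tr_mask = filtered["ligand_id"].isin(set(split.train_ids)).to_numpy()

    pre = gfa_select(Xz[tr_mask], y_all[tr_mask], population=40,
                     generations=20, subset_size_range=(8, 16), seed=seed,
                     feature_names=cols)
    idx = [cols.index(c) for c in pre]
    kept, _ = rfe_select(Xz[tr_mask][:, idx], y_all[tr_mask],
                         n_keep=min(10, len(pre)), feature_names=pre)

    feature_config = ScoreFeatureConfig(
        scoring_terms=truth.term_names[:2], descriptors=kept)
    features = build_score_features(
        truth.true_top_pose[[c for c in truth.true_top_pose.columns
                             if c != RMSD_COLUMN]],
        pose_table, filtered, feature_config)

    model = train_score_model(features, aff, split.train_ids,
                              grid=benchmark_grid(), seed=seed)
    te_rows = features[features["ligand_id"].isin(set(split.test_ids))]
    tr_rows = features[features["ligand_id"].isin(set(split.train_ids))]
    rep_tr = regression_report(
        tr_rows["ligand_id"].map(pki).to_numpy(), model.predict(tr_rows))
    rep_te = regression_report(
        te_rows["ligand_id"].map(pki).to_numpy(), model.predict(te_rows))

    out = {
        "n_train": len(split.train_ids),
        "n_test": len(split.test_ids),
        "selected_descriptors": kept,
        "train_r2": rep_tr.r2,
        "train_q2cv": model.q2cv_,
        "test_q2": rep_te.q2,
        "test_q2_f1": rep_te.q2_f1,
        "test_rmse": rep_te.rmse,
        "overfit_gap": rep_tr.r2 - rep_te.q2,
        "train_report": rep_tr,
        "test_report": rep_te,
        "pki_span": float(aff["pki"].max() - aff["pki"].min()),
    }
    if permuted_control:
        rng = np.random.default_rng(seed + 2000)
        aff_perm = aff.copy()
        aff_perm["pki"] = rng.permutation(aff_perm["pki"].to_numpy())
        pki_perm = aff_perm.set_index("ligand_id")["pki"]
        model_p = train_score_model(features, aff_perm, split.train_ids,
                                    grid=benchmark_grid(), seed=seed)
        rep_p = regression_report(
            te_rows["ligand_id"].map(pki_perm).to_numpy(),
            model_p.predict(te_rows))
        out["permuted_test_q2"] = rep_p.r2
    return out
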