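"""Descriptor-augmented binding-affinity (pKi) regression.

After the ensemble pose selector has reduced each ligand's candidate set
to a single best pose, that pose's scoring-term values are joined with
the ligand's selected molecular descriptors into one feature row per
ligand, and an RBF-SVR is trained against pKi.  The end-to-end pipeline
(select pose -> build features -> predict pKi) is exposed both as a
single call and as its composable stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .io import KEY_COLUMNS, ModelArtifact
from .pose import PoseModelSet, predict_pose_rmsd, select_top_pose
from .svr import fit_svr_artifact


@dataclass
class ScoreFeatureConfig:
    """Which columns feed the affinity regressor.

    ``scoring_terms`` are taken from each ligand's single selected pose;
    ``descriptors`` from the per-ligand descriptor table.  Column order
    in the built matrix is scoring terms first, then descriptors, in
    config order.
    """

    scoring_terms: list[str] = field(default_factory=list)
    descriptors: list[str] = field(default_factory=list)

    @property
    def columns(self) -> list[str]:
        return list(self.scoring_terms) + list(self.descriptors)


def build_score_features(
    selected_poses: pd.DataFrame,
    pose_table: pd.DataFrame,
    descriptor_table: pd.DataFrame,
    feature_config: ScoreFeatureConfig,
) -> pd.DataFrame:
    """One feature row per ligand from its selected pose + descriptors.

    Output row order follows ``selected_poses``; columns are fixed by the
    config regardless of input column order.  Raises when a selected
    ligand is missing from the descriptor table or any cell is missing.
    """
    missing_terms = [t for t in feature_config.scoring_terms
                     if t not in pose_table.columns]
    if missing_terms:
        raise KeyError(f"scoring term(s) not in pose table: {missing_terms}")
    missing_desc = [d for d in feature_config.descriptors
                    if d not in descriptor_table.columns]
    if missing_desc:
        raise KeyError(f"descriptor(s) not in descriptor table: {missing_desc}")

    pose_rows = selected_poses[KEY_COLUMNS].merge(
        pose_table, on=KEY_COLUMNS, how="left", validate="one_to_one")
    absent = set(selected_poses["ligand_id"]) - set(descriptor_table["ligand_id"])
    if absent:
        raise KeyError(f"ligand(s) missing from descriptor table: {sorted(absent)}")
    desc = descriptor_table.set_index("ligand_id")
    out = pose_rows[["ligand_id"] + list(feature_config.scoring_terms)].copy()
    for d in feature_config.descriptors:
        out[d] = pose_rows["ligand_id"].map(desc[d]).to_numpy()
    out = out[["ligand_id"] + feature_config.columns]
    if out.drop(columns="ligand_id").isna().any().any():
        bad = out.columns[out.isna().any()].tolist()
        raise ValueError(f"missing cells in feature column(s): {bad}")
    return out.reset_index(drop=True)


class AffinityRegressor(BaseEstimator, RegressorMixin):
    """RBF-SVR from score features to pKi, sklearn-style.

    Hyperparameters are selected by 10-fold cross-validated q2 over
    ``grid``; inputs are z-normalized with training statistics inside
    the estimator.  Columns are name-keyed: prediction frames may order
    columns freely but must carry exactly the training columns.

    Attributes
    ----------
    artifact_ : fitted ModelArtifact (kind ``"score"``).
    q2cv_, train_r2_ : scan optimum and training-set fit.
    """

    def __init__(self, grid=None, folds: int = 10, seed: int = 0):
        self.grid = grid
        self.folds = folds
        self.seed = seed

    def fit(self, X, y, feature_names: list[str] | None = None):
        if isinstance(X, pd.DataFrame):
            feature_names = [c for c in X.columns if c != "ligand_id"]
            X = X[feature_names].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if y.size < 10:
            raise ValueError(f"need at least 10 training ligands, got {y.size}")
        if np.ptp(y) == 0:
            raise ValueError("degenerate response: pKi has zero variance")
        names = feature_names or [f"x{j}" for j in range(X.shape[1])]
        self.artifact_ = fit_svr_artifact(
            X, y, names, kind="score", grid=self.grid, folds=self.folds,
            seed=self.seed)
        self.best_params_ = self.artifact_.hyperparams
        self.q2cv_ = self.artifact_.metadata["q2cv"]
        self.train_r2_ = self.artifact_.metadata["train_r2"]
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        if isinstance(X, pd.DataFrame):
            extra = [c for c in X.columns
                     if c not in self.artifact_.feature_names + ["ligand_id"]]
            if extra:
                raise ValueError(f"unknown feature column(s): {extra}")
            return self.artifact_.predict_frame(X)
        return self.artifact_.predict(np.asarray(X, dtype=float))


def train_score_model(
    features: pd.DataFrame,
    affinities: pd.DataFrame,
    train_ids,
    grid=None,
    seed: int = 0,
    folds: int = 10,
) -> AffinityRegressor:
    """Fit the affinity regressor on the training split only."""
    train_ids = list(train_ids)
    rows = features[features["ligand_id"].isin(train_ids)]
    pki = affinities.set_index("ligand_id")["pki"]
    y = rows["ligand_id"].map(pki).to_numpy(dtype=float)
    if np.isnan(y).any():
        missing = rows.loc[np.isnan(y), "ligand_id"].tolist()
        raise ValueError(f"no affinity for training ligand(s): {missing}")
    reg = AffinityRegressor(grid=grid, folds=folds, seed=seed)
    reg.fit(rows, y)
    return reg


def predict_pki(model, features: pd.DataFrame) -> pd.DataFrame:
    """Per-ligand pKi predictions from a fitted regressor or artifact."""
    artifact = model.artifact_ if hasattr(model, "artifact_") else model
    if not isinstance(artifact, ModelArtifact):
        raise TypeError("model must be an AffinityRegressor or ModelArtifact")
    preds = artifact.predict_frame(features)
    return pd.DataFrame({"ligand_id": features["ligand_id"].to_numpy(),
                         "predicted_pki": preds})


def run_pipeline(
    pose_table: pd.DataFrame,
    descriptor_table: pd.DataFrame,
    pose_model_set: PoseModelSet,
    score_model,
    feature_config: ScoreFeatureConfig,
) -> pd.DataFrame:
    """Full prediction chain: pose selection -> features -> pKi.

    Returns one row per ligand with the selected pose key, its predicted
    RMSD and the predicted pKi.  Identical by construction to chaining
    the stages manually.
    """
    try:
        preds = predict_pose_rmsd(pose_model_set, pose_table)
    except Exception as exc:
        raise RuntimeError(f"pose-prediction stage failed: {exc}") from exc
    if preds.empty:
        return pd.DataFrame(columns=KEY_COLUMNS + ["predicted_rmsd", "predicted_pki"])
    try:
        selected = select_top_pose(preds, group_by="ligand_id")
    except Exception as exc:
        raise RuntimeError(f"pose-selection stage failed: {exc}") from exc
    try:
        features = build_score_features(
            selected, pose_table, descriptor_table, feature_config)
    except Exception as exc:
        raise RuntimeError(f"feature-building stage failed: {exc}") from exc
    try:
        pki = predict_pki(score_model, features)
    except Exception as exc:
        raise RuntimeError(f"affinity-prediction stage failed: {exc}") from exc
    report = selected.merge(pki, on="ligand_id", validate="one_to_one")
    return report.sort_values("ligand_id").reset_index(drop=True)
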