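"""Per-protein-structure pose-RMSD regressors and ensemble pose selection.

Ensemble docking produces a candidate set per ligand spanning several
protein structures, ligand conformers, docking runs and poses.  Because
scoring-term/RMSD relationships are structure-specific, one RBF-SVR RMSD
regressor is trained per protein structure on poses with observed RMSD;
at prediction time each candidate is scored by its own structure's model
and the candidate with the lowest predicted RMSD is selected per ligand
(or any other grouping).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .io import (KEY_COLUMNS, RMSD_COLUMN, ModelArtifact, feature_columns,
                 load_model, save_model)
from .svr import SvrHyperParams, fit_svr_artifact, grid_scan_svr  # noqa: F401


class PoseRmsdRegressor(BaseEstimator, RegressorMixin):
    """RBF-SVR regressor from scoring-term features to pose RMSD.

    Hyperparameters (epsilon- vs nu-mode, C, gamma, tube parameter) are
    selected by 10-fold cross-validated q2 over ``grid``; features are
    z-normalized with training statistics inside the estimator.  Raw
    predictions below zero are clipped to 0 (RMSD is non-negative) and
    flagged.

    Parameters
    ----------
    grid : list of SvrHyperParams or None
        Lattice to scan; None uses the full default lattice.
    folds : int
        Cross-validation folds for the scan.
    seed : int
        Seed for fold assignment.

    Attributes
    ----------
    artifact_ : ModelArtifact with the fitted expansion.
    best_params_ : chosen SvrHyperParams (as dict).
    q2cv_ : cross-validated q2 at the optimum.
    train_r2_ : squared Pearson correlation on the training rows.
    n_clipped_ : number of negative raw predictions clipped at the last
        ``predict`` call.
    """

    def __init__(self, grid=None, folds: int = 10, seed: int = 0,
                 structure_id: str | None = None):
        self.grid = grid
        self.folds = folds
        self.seed = seed
        self.structure_id = structure_id

    def fit(self, X, y, feature_names: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.size:
            raise ValueError("X and y length mismatch")
        if np.isnan(y).any():
            raise ValueError("observed RMSD contains missing values")
        names = feature_names or [f"x{j}" for j in range(X.shape[1])]
        self.artifact_ = fit_svr_artifact(
            X, y, names, kind="pose", grid=self.grid, folds=self.folds,
            seed=self.seed, structure_id=self.structure_id)
        self.best_params_ = self.artifact_.hyperparams
        self.q2cv_ = self.artifact_.metadata["q2cv"]
        self.train_r2_ = self.artifact_.metadata["train_r2"]
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        raw = self.artifact_.predict(np.asarray(X, dtype=float))
        self.n_clipped_ = int((raw < 0).sum())
        return np.clip(raw, 0.0, None)


def train_pose_model(
    structure_id: str,
    pose_table: pd.DataFrame,
    grid=None,
    seed: int = 0,
    folds: int = 10,
    min_poses: int = 10,
) -> ModelArtifact:
    """Train one structure's RMSD regressor from its labeled poses."""
    sub = pose_table[pose_table["structure_id"] == structure_id]
    if RMSD_COLUMN not in sub.columns or sub[RMSD_COLUMN].isna().any():
        bad = (sub.loc[sub[RMSD_COLUMN].isna(), KEY_COLUMNS].values.tolist()
               if RMSD_COLUMN in sub.columns else "all rows")
        raise ValueError(f"poses without observed RMSD for {structure_id}: {bad}")
    if len(sub) < min_poses:
        raise ValueError(
            f"structure {structure_id} has {len(sub)} labeled poses; "
            f"need >= {min_poses}")
    feats = feature_columns(sub)
    reg = PoseRmsdRegressor(grid=grid, folds=folds, seed=seed,
                            structure_id=structure_id)
    reg.fit(sub[feats].to_numpy(dtype=float), sub[RMSD_COLUMN].to_numpy(),
            feature_names=feats)
    return reg.artifact_


class PoseModelSet:
    """One fitted pose-RMSD regressor per protein structure."""

    def __init__(self, artifacts: dict[str, ModelArtifact]):
        if not artifacts:
            raise ValueError("empty model set")
        feats = None
        for sid, art in artifacts.items():
            if feats is None:
                feats = art.feature_names
            elif art.feature_names != feats:
                raise ValueError(
                    f"feature list of {sid} differs from the set's")
        self.artifacts = dict(artifacts)
        self.feature_names = list(feats)

    @property
    def structure_ids(self) -> list[str]:
        return sorted(self.artifacts)

    def metadata_frame(self) -> pd.DataFrame:
        rows = [{"structure_id": sid, **art.metadata, **{
            f"hp_{k}": v for k, v in art.hyperparams.items()}}
            for sid, art in sorted(self.artifacts.items())]
        return pd.DataFrame(rows)

    @classmethod
    def train(cls, pose_table: pd.DataFrame, grid=None, seed: int = 0,
              folds: int = 10, min_poses: int = 10) -> "PoseModelSet":
        arts = {}
        for k, sid in enumerate(sorted(pose_table["structure_id"].unique())):
            arts[sid] = train_pose_model(
                sid, pose_table, grid=grid, seed=seed + k, folds=folds,
                min_poses=min_poses)
        return cls(arts)

    def predict(self, pose_table: pd.DataFrame) -> pd.Series:
        """Predicted RMSD per row, each row scored by its own structure's
        model; unknown structure ids raise."""
        unknown = set(pose_table["structure_id"]) - set(self.artifacts)
        if unknown:
            raise ValueError(f"no model for structure(s): {sorted(unknown)}")
        preds = pd.Series(np.nan, index=pose_table.index, name="predicted_rmsd")
        for sid, sub in pose_table.groupby("structure_id", sort=False):
            art = self.artifacts[sid]
            raw = art.predict_frame(sub)
            preds.loc[sub.index] = np.clip(raw, 0.0, None)
        return preds

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        index = []
        for sid, art in sorted(self.artifacts.items()):
            fname = f"pose_{sid}.json"
            save_model(art, path / fname)
            index.append({"structure_id": sid, "file": fname})
        (path / "model_set.json").write_text(json.dumps({"models": index}))

    @classmethod
    def load(cls, path: str | Path) -> "PoseModelSet":
        path = Path(path)
        index = json.loads((path / "model_set.json").read_text())
        arts = {e["structure_id"]: load_model(path / e["file"], expected_kind="pose")
                for e in index["models"]}
        return cls(arts)


def predict_pose_rmsd(model_set: PoseModelSet, pose_table: pd.DataFrame) -> pd.DataFrame:
    """Pose table keys plus a ``predicted_rmsd`` column."""
    out = pose_table[KEY_COLUMNS].copy()
    out["predicted_rmsd"] = model_set.predict(pose_table).to_numpy()
    return out


def select_top_pose(
    predictions: pd.DataFrame,
    group_by="ligand_id",
    value_col: str = "predicted_rmsd",
) -> pd.DataFrame:
    """Per group, the candidate with minimal predicted RMSD.

    Ties break lexicographically on
    (structure_id, conformer_id, run_id, pose_id).  Raises on empty
    groups (absent groups cannot occur: grouping is over present rows).
    """
    if isinstance(group_by, str):
        group_by = [group_by]
    if predictions.empty:
        raise ValueError("no candidates to select from")
    tie_cols = [c for c in ("structure_id", "conformer_id", "run_id", "pose_id")
                if c in predictions.columns and c not in group_by]
    ordered = predictions.sort_values(
        list(group_by) + [value_col] + tie_cols, kind="stable")
    return (ordered.drop_duplicates(subset=list(group_by), keep="first")
            .reset_index(drop=True))


def cross_structure_r2_matrix(
    model_set: PoseModelSet, pose_table: pd.DataFrame
) -> pd.DataFrame:
    """r2 of model (row) applied to each structure's labeled poses (column).

    The diagonal is native performance; markedly lower off-diagonal
    values indicate that pose models do not transfer across protein
    structures.
    """
    sids = model_set.structure_ids
    mat = pd.DataFrame(index=sids, columns=sids, dtype=float)
    for s_col in sids:
        sub = pose_table[pose_table["structure_id"] == s_col]
        if sub[RMSD_COLUMN].isna().any():
            raise ValueError(f"unlabeled poses for structure {s_col}")
        y = sub[RMSD_COLUMN].to_numpy(dtype=float)
        for s_row in sids:
            pred = np.clip(model_set.artifacts[s_row].predict_frame(sub), 0, None)
            sy = y - y.mean()
            sp = pred - pred.mean()
            denom = np.sqrt((sy**2).sum() * (sp**2).sum())
            mat.loc[s_row, s_col] = (
                float(((sy * sp).sum() / denom) ** 2) if denom > 0 else 0.0)
    return mat


def train_pose_model_set(pose_table, grid=None, seed: int = 0,
                         folds: int = 10, min_poses: int = 10) -> PoseModelSet:
    """Functional wrapper over :meth:`PoseModelSet.train`."""
    return PoseModelSet.train(pose_table, grid=grid, seed=seed, folds=folds,
                              min_poses=min_poses)
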