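"""Tables, file formats and model artifacts.

Docked-pose candidates, per-ligand molecular descriptors and per-ligand
binding affinities are carried as plain pandas DataFrames with validated
schemas:

* pose table — one row per candidate pose, keyed by
  ``(ligand_id, structure_id, conformer_id, run_id, pose_id)``, remaining
  numeric columns are scoring-term features, optional ``observed_rmsd``
  in angstrom;
* descriptor table — one row per ligand (``ligand_id`` + named numeric
  descriptor columns, empty cells = missing);
* affinity table — ``ligand_id`` plus ``pki`` (or a ``ki`` column in molar
  or nanomolar, converted on read), optional ``bound_flag`` and
  ``set_label``.

Fitted models are persisted as versioned JSON artifacts holding the RBF
support-vector expansion explicitly, so a saved model predicts
bit-identically after reload.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


KEY_COLUMNS = ["ligand_id", "structure_id", "conformer_id", "run_id", "pose_id"]
RMSD_COLUMN = "observed_rmsd"
ARTIFACT_FORMAT_VERSION = "docksel-artifact-1"


class SchemaError(ValueError):
    """A required column is missing or mistyped."""


class IntegrityError(ValueError):
    """Table content violates an invariant (e.g. duplicate keys)."""


# ---------------------------------------------------------------------------
# pose tables


def feature_columns(pose_table: pd.DataFrame) -> list[str]:
    """Scoring-term columns of a pose table, in stored order."""
    return [c for c in pose_table.columns if c not in KEY_COLUMNS + [RMSD_COLUMN]]


def validate_pose_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in KEY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"pose table missing key column(s): {missing}")
    feats = feature_columns(df)
    if not feats:
        raise SchemaError("pose table needs at least one feature column")
    dup = df.duplicated(subset=KEY_COLUMNS)
    if dup.any():
        first = df.loc[dup, KEY_COLUMNS].iloc[0].tolist()
        raise IntegrityError(f"duplicate pose key, e.g. {first}")
    for col in ("conformer_id", "run_id", "pose_id"):
        vals = pd.to_numeric(df[col], errors="raise")
        if (vals < 1).any():
            raise IntegrityError(f"{col} must be a positive integer")
        df[col] = vals.astype(int)
    for col in feats + ([RMSD_COLUMN] if RMSD_COLUMN in df.columns else []):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"non-numeric value in column {col!r}: {exc}") from exc
    if RMSD_COLUMN in df.columns:
        rmsd = df[RMSD_COLUMN]
        if (rmsd.dropna() < 0).any():
            raise IntegrityError("observed_rmsd must be >= 0")
    return df


def read_pose_table(path: str | Path, dialect: str = "auto") -> pd.DataFrame:
    """Read and validate a pose table from CSV or TSV.

    ``dialect`` is ``csv``, ``tsv`` or ``auto`` (by file extension,
    defaulting to TSV).  Empty fields are missing values.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep=sep, dtype={"ligand_id": str, "structure_id": str})
    return validate_pose_table(df)


def write_pose_table(table: pd.DataFrame, path: str | Path, dialect: str = "auto") -> None:
    path = Path(path)
    if dialect == "auto":
        dialect = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    validate_pose_table(table.copy())
    table.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# descriptor tables


def read_descriptor_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"ligand_id": str})
    if "ligand_id" not in df.columns:
        raise SchemaError("descriptor table requires a ligand_id column")
    if df["ligand_id"].duplicated().any():
        raise IntegrityError("duplicate ligand_id in descriptor table")
    if df.columns.duplicated().any():
        raise IntegrityError("duplicate descriptor column names")
    return df


def write_descriptor_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# affinity tables


def read_affinity_table(path: str | Path, ki_units: str = "M") -> pd.DataFrame:
    """Read per-ligand affinities, converting Ki to pKi if needed.

    ``ki_units`` is ``M``, ``nM`` or ``pKi``.  pKi = -log10(Ki in molar).
    """
    df = pd.read_csv(path, dtype={"ligand_id": str})
    if "ligand_id" not in df.columns:
        raise SchemaError("affinity table requires a ligand_id column")
    if df["ligand_id"].duplicated().any():
        raise IntegrityError("duplicate ligand_id in affinity table")
    df = affinity_to_pki(df, ki_units)
    if "bound_flag" not in df.columns:
        df["bound_flag"] = False
    else:
        df["bound_flag"] = df["bound_flag"].astype(bool)
    if "set_label" not in df.columns:
        df["set_label"] = "unassigned"
    return df[["ligand_id", "pki", "bound_flag", "set_label"]]


def affinity_to_pki(df: pd.DataFrame, ki_units: str = "M") -> pd.DataFrame:
    df = df.copy()
    if ki_units == "pKi":
        source = "pki" if "pki" in df.columns else "ki"
        df["pki"] = pd.to_numeric(df[source], errors="raise")
    elif ki_units in ("M", "nM"):
        if "ki" not in df.columns:
            raise SchemaError("affinity table requires a ki column for Ki units")
        ki = pd.to_numeric(df["ki"], errors="raise")
        if (ki <= 0).any():
            bad = df.loc[ki <= 0, "ligand_id"].tolist()
            raise ValueError(f"Ki must be positive; offending ligands: {bad}")
        molar = ki * (1e-9 if ki_units == "nM" else 1.0)
        df["pki"] = -np.log10(molar)
    else:
        raise ValueError(f"unknown ki_units {ki_units!r}; use M, nM or pKi")
    if not np.isfinite(df["pki"]).all():
        raise ValueError("non-finite pKi after conversion")
    return df


def write_affinity_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# geometry


def compute_pose_rmsd(coords_a, coords_b) -> float:
    """RMSD between two poses with atom correspondence by position.

    Computed in the fixed protein frame: no re-superposition, heavy-atom
    lists as given, sqrt(mean ||a_i - b_i||^2) in angstrom.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty coordinate set")
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"coordinate shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def read_sdf_coordinates(path: str | Path) -> dict[str, np.ndarray]:
    """Heavy-atom 3-D coordinates per molecule from an SDF file.

    Returns a mapping molecule title -> (N, 3) array in angstrom,
    hydrogens excluded, atom order as stored.
    """
    from rdkit import Chem

    out: dict[str, np.ndarray] = {}
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    for i, mol in enumerate(supplier):
        if mol is None:
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol_{i}"
        conf = mol.GetConformer()
        coords = [
            list(conf.GetAtomPosition(a.GetIdx()))
            for a in mol.GetAtoms() if a.GetAtomicNum() != 1
        ]
        out[name] = np.asarray(coords, dtype=float)
    return out


# ---------------------------------------------------------------------------
# model artifacts


@dataclass
class ModelArtifact:
    """A fitted RBF support-vector regressor, fully serialized.

    Predicts yhat(x) = sum_j dual_coef[j] * exp(-gamma * ||z - sv_j||^2)
    + intercept, where z is x standardized with the stored per-feature
    training mean and sample standard deviation.  ``kind`` is ``"pose"``
    (RMSD regressor for one protein structure) or ``"score"`` (pKi
    regressor).
    """

    kind: str
    feature_names: list[str]
    norm_mean: np.ndarray
    norm_sd: np.ndarray
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gamma: float
    hyperparams: dict = field(default_factory=dict)
    structure_id: str | None = None
    metadata: dict = field(default_factory=dict)
    version: str = ARTIFACT_FORMAT_VERSION

    def __post_init__(self) -> None:
        self.norm_mean = np.asarray(self.norm_mean, dtype=float)
        self.norm_sd = np.asarray(self.norm_sd, dtype=float)
        self.support_vectors = np.asarray(self.support_vectors, dtype=float)
        self.dual_coef = np.asarray(self.dual_coef, dtype=float).ravel()
        if self.kind not in ("pose", "score"):
            raise ValueError(f"unknown artifact kind {self.kind!r}")

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}")
        Z = (X - self.norm_mean) / self.norm_sd
        d2 = ((Z[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-self.gamma * d2) @ self.dual_coef + self.intercept

    def predict_frame(self, df: pd.DataFrame) -> np.ndarray:
        """Predict from a DataFrame, selecting columns by feature name."""
        missing = [c for c in self.feature_names if c not in df.columns]
        if missing:
            raise ValueError(f"missing feature column(s): {missing}")
        return self.predict(df[self.feature_names].to_numpy(dtype=float))


def save_model(artifact: ModelArtifact, path: str | Path) -> None:
    doc = {
        "version": artifact.version,
        "kind": artifact.kind,
        "structure_id": artifact.structure_id,
        "feature_names": artifact.feature_names,
        "norm_mean": artifact.norm_mean.tolist(),
        "norm_sd": artifact.norm_sd.tolist(),
        "support_vectors": artifact.support_vectors.tolist(),
        "dual_coef": artifact.dual_coef.tolist(),
        "intercept": artifact.intercept,
        "gamma": artifact.gamma,
        "hyperparams": artifact.hyperparams,
        "metadata": artifact.metadata,
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path: str | Path, expected_kind: str | None = None) -> ModelArtifact:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupted model artifact {path}: {exc}") from exc
    version = doc.get("version")
    if version != ARTIFACT_FORMAT_VERSION:
        raise ValueError(
            f"incompatible artifact version {version!r}; "
            f"expected {ARTIFACT_FORMAT_VERSION!r}")
    art = ModelArtifact(
        kind=doc["kind"],
        structure_id=doc.get("structure_id"),
        feature_names=doc["feature_names"],
        norm_mean=doc["norm_mean"],
        norm_sd=doc["norm_sd"],
        support_vectors=doc["support_vectors"],
        dual_coef=doc["dual_coef"],
        intercept=doc["intercept"],
        gamma=doc["gamma"],
        hyperparams=doc.get("hyperparams", {}),
        metadata=doc.get("metadata", {}),
    )
    if expected_kind is not None and art.kind != expected_kind:
        raise ValueError(f"artifact kind {art.kind!r}, expected {expected_kind!r}")
    return art
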