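"""Reproducible end-to-end runs: configuration, seed fan-out, manifest.

A :class:`RunConfig` fully determines a run.  The global seed fans out
to per-stage seeds through a stable hash of the stage name, so stages
can be re-run independently yet reproducibly; every output file is
recorded in a JSON manifest together with the configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import (read_affinity_table, read_descriptor_table, read_pose_table,
                 write_pose_table)
from .pose import PoseModelSet, predict_pose_rmsd, select_top_pose
from .prep import (clean_descriptors, filter_intercorrelated,
                   kennard_stone_split, rfe_select)
from .score import (ScoreFeatureConfig, build_score_features, predict_pki,
                    train_score_model)
from .svr import build_grid, fast_grid, full_grid, tiny_grid
from .synth import SyntheticConfig, generate_benchmark


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a stable per-stage seed below 2^31."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Parameters of a full pipeline run (all stages).

    When ``simulate`` is true the input tables come from the synthetic
    generator (``synthetic`` holds its configuration); otherwise
    ``pose_table`` / ``descriptor_table`` / ``affinity_table`` are file
    paths.
    """

    out_dir: str = "runs/out"
    seed: int = 0
    simulate: bool = True
    synthetic: dict = field(default_factory=dict)
    pose_table: str | None = None
    descriptor_table: str | None = None
    affinity_table: str | None = None
    ki_units: str = "M"
    grid: str = "fast"              # tiny | fast | full
    folds: int = 10
    split_ratio: tuple[int, int] = (2, 1)
    r2_threshold: float = 0.64
    n_descriptors_keep: int = 8
    n_score_terms: int = 2
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**d)
        if not cfg.simulate:
            missing = [k for k in ("pose_table", "descriptor_table",
                                   "affinity_table")
                       if getattr(cfg, k) is None]
            if missing:
                raise ValueError(
                    f"simulate=false requires input path(s): {missing}")
        if cfg.grid not in ("tiny", "fast", "full"):
            raise ValueError(f"unknown grid preset {cfg.grid!r}")
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _grid_from_config(cfg: RunConfig):
    return {"tiny": tiny_grid, "fast": fast_grid, "full": full_grid}[cfg.grid]()


def _write_csv(df: pd.DataFrame, path: Path, manifest: list, role: str) -> None:
    df.to_csv(path, index=False)
    manifest.append({"role": role, "file": path.name})


def run_end_to_end(cfg: RunConfig) -> dict:
    """Execute simulate -> prep -> pose -> score -> report and write
    artifacts plus a manifest under ``cfg.out_dir``.

    Returns a dict with the in-memory results (report DataFrame, split,
    selected descriptors, model metadata).  Deterministic for a fixed
    configuration and seed.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_files: list[dict] = []

    if cfg.simulate:
        syn = SyntheticConfig(**{**cfg.synthetic,
                                 "seed": stage_seed(cfg.seed, "simulate")})
        pose_table, descriptors, affinities, truth = generate_benchmark(syn)
        write_pose_table(pose_table, out / "pose_table.tsv")
        manifest_files.append({"role": "pose_table", "file": "pose_table.tsv"})
        _write_csv(descriptors, out / "descriptors.csv", manifest_files,
                   "descriptor_table")
        _write_csv(affinities, out / "affinities.csv", manifest_files,
                   "affinity_table")
        term_directions = truth.term_directions
    else:
        for key in ("pose_table", "descriptor_table", "affinity_table"):
            p = getattr(cfg, key)
            if not Path(p).exists():
                raise FileNotFoundError(f"config key {key}: no such file {p!r}")
        pose_table = read_pose_table(cfg.pose_table)
        descriptors = read_descriptor_table(cfg.descriptor_table)
        affinities = read_affinity_table(cfg.affinity_table, cfg.ki_units)
        term_directions = None

    grid = _grid_from_config(cfg)

    # --- descriptor preparation ------------------------------------------
    pki = affinities.set_index("ligand_id")["pki"]
    cleaned = clean_descriptors(descriptors)
    y_all = cleaned["ligand_id"].map(pki).to_numpy(dtype=float)
    filtered = filter_intercorrelated(cleaned, cfg.r2_threshold, target=y_all)
    cols = [c for c in filtered.columns if c != "ligand_id"]
    X = filtered[cols].to_numpy(dtype=float)
    Xz = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    split = kennard_stone_split(Xz, ids=filtered["ligand_id"].tolist(),
                                ratio=tuple(cfg.split_ratio))
    _write_csv(split.to_frame(), out / "split.csv", manifest_files, "split")

    tr_mask = filtered["ligand_id"].isin(set(split.train_ids)).to_numpy()
    n_keep = min(cfg.n_descriptors_keep, len(cols))
    kept, _ = rfe_select(Xz[tr_mask], y_all[tr_mask], n_keep=n_keep,
                         feature_names=cols)

    # --- pose models and selection ---------------------------------------
    model_set = PoseModelSet.train(pose_table, grid=grid,
                                   seed=stage_seed(cfg.seed, "pose"),
                                   folds=cfg.folds)
    model_set.save(out / "pose_models")
    manifest_files.append({"role": "pose_models", "file": "pose_models"})
    predictions = predict_pose_rmsd(model_set, pose_table)
    selected = select_top_pose(predictions, group_by="ligand_id")
    _write_csv(selected, out / "selected_poses.csv", manifest_files,
               "selected_poses")

    # --- affinity model ---------------------------------------------------
    from .io import feature_columns
    terms = feature_columns(pose_table)
    feature_config = ScoreFeatureConfig(
        scoring_terms=terms[:cfg.n_score_terms], descriptors=kept)
    features = build_score_features(selected, pose_table, filtered,
                                    feature_config)
    score_model = train_score_model(features, affinities, split.train_ids,
                                    grid=grid,
                                    seed=stage_seed(cfg.seed, "score"),
                                    folds=cfg.folds)
    from .io import save_model
    save_model(score_model.artifact_, out / "score_model.json")
    manifest_files.append({"role": "score_model", "file": "score_model.json"})

    report = selected.merge(predict_pki(score_model, features), on="ligand_id")
    report["set_label"] = report["ligand_id"].map(
        split.to_frame().set_index("ligand_id")["set_label"])
    report["observed_pki"] = report["ligand_id"].map(pki)
    report = report.sort_values("ligand_id").reset_index(drop=True)
    _write_csv(report, out / "report.csv", manifest_files, "report")

    manifest = {
        "tool": "docksel",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "stage_seeds": {s: stage_seed(cfg.seed, s)
                        for s in ("simulate", "pose", "score")},
        "outputs": manifest_files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return {
        "report": report,
        "split": split,
        "selected_descriptors": kept,
        "pose_metadata": model_set.metadata_frame(),
        "term_directions": term_directions,
        "manifest": manifest,
    }
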