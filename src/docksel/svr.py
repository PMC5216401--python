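"""Shared support-vector-regression machinery.

Both the pose-RMSD regressors and the affinity regressor are RBF-kernel
SVRs whose mode (epsilon- vs nu-regression), cost C, kernel width gamma
and tube parameter are chosen by maximizing 10-fold cross-validated q2
(1 - PRESS/SS) over a hyperparameter lattice.  Inputs are z-normalized
with training statistics inside the estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.svm import SVR, NuSVR

from .io import ModelArtifact
from .prep import Normalizer


@dataclass(frozen=True)
class SvrHyperParams:
    """One point of the SVR hyperparameter lattice.

    ``mode`` is ``"eps"`` or ``"nu"``; exactly one of ``eps``/``nu`` is
    active for the corresponding mode.
    """

    mode: str
    C: float
    gamma: float
    eps: float | None = None
    nu: float | None = None

    def __post_init__(self):
        if self.mode not in ("eps", "nu"):
            raise ValueError(f"unknown SVR mode {self.mode!r}")
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if self.mode == "eps" and (self.eps is None or self.eps < 0):
            raise ValueError("eps-mode requires eps >= 0")
        if self.mode == "nu" and not (self.nu is not None and 0 < self.nu <= 1):
            raise ValueError("nu-mode requires nu in (0, 1]")

    def make_estimator(self):
        if self.mode == "eps":
            return SVR(kernel="rbf", C=self.C, gamma=self.gamma, epsilon=self.eps)
        return NuSVR(kernel="rbf", C=self.C, gamma=self.gamma, nu=self.nu)

    def to_dict(self) -> dict:
        return {"mode": self.mode, "C": self.C, "gamma": self.gamma,
                "eps": self.eps, "nu": self.nu}

    @classmethod
    def from_dict(cls, d: dict) -> "SvrHyperParams":
        return cls(mode=d["mode"], C=d["C"], gamma=d["gamma"],
                   eps=d.get("eps"), nu=d.get("nu"))


def build_grid(
    C_values, gamma_values, eps_values=(), nu_values=()
) -> list[SvrHyperParams]:
    grid = [SvrHyperParams("eps", C, g, eps=e)
            for C, g, e in product(C_values, gamma_values, eps_values)]
    grid += [SvrHyperParams("nu", C, g, nu=v)
             for C, g, v in product(C_values, gamma_values, nu_values)]
    return grid


def full_grid() -> list[SvrHyperParams]:
    """The default exhaustive lattice: C in 2^-5..2^15, gamma in 2^-15..2^3,
    five eps and five nu values, both regression modes."""
    return build_grid(
        C_values=[2.0**k for k in range(-5, 17, 2)],
        gamma_values=[2.0**k for k in range(-15, 5, 2)],
        eps_values=[0.01, 0.05, 0.1, 0.2, 0.5],
        nu_values=[0.2, 0.4, 0.5, 0.6, 0.8],
    )


def fast_grid() -> list[SvrHyperParams]:
    """A coarser lattice for benchmarking and smoke runs (96 points)."""
    return build_grid(
        C_values=[2.0**k for k in (-1, 2, 5, 8, 11, 14)],
        gamma_values=[2.0**k for k in (-7, -4, -2, 0)],
        eps_values=[0.05, 0.2],
        nu_values=[0.3, 0.6],
    )


def tiny_grid() -> list[SvrHyperParams]:
    """A minimal lattice for smoke tests and determinism checks (12 points)."""
    return build_grid(
        C_values=[1.0, 2.0**5],
        gamma_values=[2.0**-3, 2.0**-1],
        eps_values=[0.1],
        nu_values=[0.5],
    )


def _grid_sort_key(hp: SvrHyperParams):
    # tie-break at equal q2cv: smaller C, then larger tube (flatter model)
    return (hp.C, -(hp.eps if hp.mode == "eps" else 0.0),
            hp.nu if hp.mode == "nu" else 0.0, hp.mode, hp.gamma)


def grid_scan_svr(
    X,
    y,
    grid: list[SvrHyperParams] | None = None,
    folds: int = 10,
    seed: int = 0,
) -> tuple[SvrHyperParams, float, pd.DataFrame]:
    """Scan the lattice, scoring each point by 10-fold cross-validated q2.

    Fold assignment is a seeded random permutation dealt round-robin and
    shared by every grid point, so scan results are independent of
    execution order (embarrassingly parallelizable).  Returns the best
    point (ties: smaller C, then flatter tube), its q2cv, and the full
    scan table.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if grid is None:
        grid = full_grid()
    if not grid:
        raise ValueError("empty hyperparameter grid")
    n = y.size
    if n < folds:
        raise ValueError(f"n={n} smaller than folds={folds}")
    rng = np.random.default_rng(seed)
    assign = rng.permutation(n) % folds
    ss = float(((y - y.mean()) ** 2).sum())
    fold_masks = [(assign == f) for f in range(folds)]

    rows = []
    best_hp, best_q2 = None, -np.inf
    for hp in grid:
        preds = np.empty(n)
        ok = True
        for mask in fold_masks:
            try:
                model = hp.make_estimator().fit(X[~mask], y[~mask])
            except Exception:
                ok = False
                break
            preds[mask] = model.predict(X[mask])
        if not ok:
            q2 = -np.inf
        else:
            q2 = 1.0 - float(((y - preds) ** 2).sum()) / ss
        rows.append({**hp.to_dict(), "q2cv": q2})
        if q2 > best_q2 or (
            q2 == best_q2 and best_hp is not None
            and _grid_sort_key(hp) < _grid_sort_key(best_hp)
        ):
            best_hp, best_q2 = hp, q2
    return best_hp, best_q2, pd.DataFrame(rows)


def fit_svr_artifact(
    X,
    y,
    feature_names: list[str],
    kind: str,
    grid: list[SvrHyperParams] | None = None,
    folds: int = 10,
    seed: int = 0,
    structure_id: str | None = None,
    metadata: dict | None = None,
) -> ModelArtifact:
    """Grid-scan, refit on all rows, and package as a ModelArtifact."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    norm = Normalizer().fit(X)
    Z = norm.transform(X)
    best_hp, q2cv, _ = grid_scan_svr(Z, y, grid=grid, folds=folds, seed=seed)
    model = best_hp.make_estimator().fit(Z, y)
    art = ModelArtifact(
        kind=kind,
        structure_id=structure_id,
        feature_names=list(feature_names),
        norm_mean=norm.mean_,
        norm_sd=norm.sd_,
        support_vectors=model.support_vectors_,
        dual_coef=model.dual_coef_,
        intercept=float(model.intercept_[0]),
        gamma=float(best_hp.gamma),
        hyperparams=best_hp.to_dict(),
        metadata=dict(metadata or {}),
    )
    fitted = art.predict(X)
    sy = y - y.mean()
    sp = fitted - fitted.mean()
    denom = np.sqrt((sy**2).sum() * (sp**2).sum())
    train_r2 = float(((sy * sp).sum() / denom) ** 2) if denom > 0 else 0.0
    art.metadata.update({"n_train": int(y.size), "q2cv": float(q2cv),
                         "train_r2": train_r2})
    return art
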