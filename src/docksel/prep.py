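"""Descriptor preprocessing, feature selection and train/test splitting.

The preprocessing chain mirrors standard QSAR practice: drop descriptors
with missing values or (near-)constant columns, discard one member of
every descriptor pair with squared Pearson intercorrelation above a
threshold (default r2 >= 0.64), z-normalize with training-set statistics
only, pre-select descriptor subsets with a genetic algorithm, prune with
recursive feature elimination, and split compounds into representative
training and test sets with the Kennard-Stone maximin algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import RFE
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold
from scipy.spatial.distance import cdist


__all__ = [
    "clean_descriptors",
    "filter_intercorrelated",
    "IntercorrelationFilter",
    "Normalizer",
    "gfa_select",
    "rfe_select",
    "kennard_stone_split",
    "SplitResult",
    "split_diagnostics",
]


def _descriptor_matrix(table: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in table.columns if c != "ligand_id"]
    return table[cols]


def clean_descriptors(table: pd.DataFrame, min_sd: float = 1e-8) -> pd.DataFrame:
    """Drop descriptors missing for any compound or with no discrimination.

    A column is removed when it contains any missing value, when its
    sample standard deviation is below ``min_sd``, or when it has at most
    one distinct value.  Rows are never touched.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 compounds to assess discrimination")
    X = _descriptor_matrix(table)
    keep = []
    for col in X.columns:
        vals = pd.to_numeric(X[col], errors="coerce")
        if vals.isna().any():
            continue
        if vals.nunique() <= 1:
            continue
        if vals.std(ddof=1) < min_sd:
            continue
        keep.append(col)
    if not keep:
        raise ValueError("cleaning removed every descriptor column")
    out = table[(["ligand_id"] if "ligand_id" in table.columns else []) + keep].copy()
    for col in keep:
        out[col] = pd.to_numeric(out[col])
    return out


class IntercorrelationFilter(BaseEstimator, TransformerMixin):
    """Remove one column of every pair with squared correlation >= threshold.

    Greedy by column order: each candidate column is kept only if its r2
    against every already-kept column is below ``r2_threshold``.  When a
    target ``y`` is supplied to :meth:`fit`, columns are examined in
    decreasing |correlation with y|, so the member of an offending pair
    more relevant to the response survives; ties and the no-target case
    fall back to original column order.

    Attributes
    ----------
    selected_ : list of kept column names (original order).
    dropped_ : list of removed column names.
    """

    def __init__(self, r2_threshold: float = 0.64):
        self.r2_threshold = r2_threshold

    def fit(self, X: pd.DataFrame, y=None):
        X = _descriptor_matrix(X) if "ligand_id" in getattr(X, "columns", []) else X
        cols = list(X.columns)
        mat = X.to_numpy(dtype=float)
        if y is not None:
            y = np.asarray(y, dtype=float).ravel()
            rel = np.abs(np.array([_safe_corr(mat[:, j], y) for j in range(len(cols))]))
            # stable sort: ties keep original order
            order = np.argsort(-rel, kind="stable")
        else:
            order = np.arange(len(cols))
        corr = np.corrcoef(mat, rowvar=False)
        if corr.ndim == 0:
            corr = np.array([[1.0]])
        r2 = np.nan_to_num(corr**2, nan=0.0)
        kept_idx: list[int] = []
        for j in order:
            if all(r2[j, k] < self.r2_threshold for k in kept_idx):
                kept_idx.append(int(j))
        kept = sorted(kept_idx)
        self.selected_ = [cols[j] for j in kept]
        self.dropped_ = [c for c in cols if c not in self.selected_]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        lead = ["ligand_id"] if "ligand_id" in X.columns else []
        return X[lead + self.selected_]


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def filter_intercorrelated(
    table: pd.DataFrame, r2_threshold: float = 0.64, target=None
) -> pd.DataFrame:
    """Functional wrapper over :class:`IntercorrelationFilter`."""
    f = IntercorrelationFilter(r2_threshold=r2_threshold)
    return f.fit(table, target).transform(table)


class Normalizer(BaseEstimator, TransformerMixin):
    """Column-wise z-normalization with sample (ddof=1) statistics.

    Fit strictly on training rows; applying the fitted transform to its
    own fit data yields column means 0 and sample standard deviations 1.
    Held-out rows are transformed with the training statistics.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0, ddof=1)
        if np.any(self.sd_ <= 0) or np.any(~np.isfinite(self.sd_)):
            bad = np.where(~(self.sd_ > 0))[0].tolist()
            raise ValueError(
                f"zero-variance feature(s) at column index {bad}; "
                "run clean_descriptors first")
        return self

    def transform(self, X):
        return (np.asarray(X, dtype=float) - self.mean_) / self.sd_

    def inverse_transform(self, Z):
        return np.asarray(Z, dtype=float) * self.sd_ + self.mean_


def fit_normalizer(table: pd.DataFrame, train_ids) -> tuple[Normalizer, list[str]]:
    """Fit a :class:`Normalizer` on the training rows of a descriptor table."""
    cols = [c for c in table.columns if c != "ligand_id"]
    rows = table[table["ligand_id"].isin(set(train_ids))]
    norm = Normalizer().fit(rows[cols].to_numpy(dtype=float))
    return norm, cols


def apply_normalizer(norm: Normalizer, table: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    out = table.copy()
    out[cols] = norm.transform(table[cols].to_numpy(dtype=float))
    return out


# ---------------------------------------------------------------------------
# feature selection


def _cv_mse_fitness(X: np.ndarray, y: np.ndarray, subset: np.ndarray,
                    folds: int, alpha: float, seed: int) -> float:
    """Negated 5-fold CV MSE of a ridge fit on the subset (higher = fitter)."""
    cols = np.flatnonzero(subset)
    if cols.size == 0:
        return -np.inf
    Xs = X[:, cols]
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    err = 0.0
    for tr, te in kf.split(Xs):
        model = Ridge(alpha=alpha).fit(Xs[tr], y[tr])
        err += float(((model.predict(Xs[te]) - y[te]) ** 2).sum())
    return -err / len(y)


def gfa_select(
    X,
    y,
    population: int = 100,
    generations: int = 50,
    subset_size_range: tuple[int, int] = (2, 12),
    seed: int = 0,
    mutation_rate: float = 0.05,
    crossover_rate: float = 0.8,
    cv_folds: int = 5,
    ridge_alpha: float = 1.0,
    feature_names: list[str] | None = None,
) -> list:
    """Genetic-algorithm descriptor subset search.

    Individuals are descriptor bitmasks with cardinality inside
    ``subset_size_range``; fitness is the negated 5-fold cross-validated
    mean squared error of a ridge-penalized linear fit on the subset.
    Elitist generational replacement with uniform crossover and per-bit
    mutation; the best-so-far fitness is non-decreasing over generations.
    Deterministic given ``seed``.

    Returns the selected descriptor names (or column indices when
    ``feature_names`` is None).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n_feat = X.shape[1]
    lo, hi = subset_size_range
    if hi > n_feat:
        raise ValueError(f"subset_size_range {subset_size_range} exceeds "
                         f"column count {n_feat}")
    lo = max(1, lo)
    rng = np.random.default_rng(seed)

    def repair(mask: np.ndarray) -> np.ndarray:
        k = mask.sum()
        if k < lo:
            off = np.flatnonzero(~mask)
            mask[rng.choice(off, lo - k, replace=False)] = True
        elif k > hi:
            on = np.flatnonzero(mask)
            mask[rng.choice(on, k - hi, replace=False)] = False
        return mask

    pop = np.zeros((population, n_feat), dtype=bool)
    for i in range(population):
        k = int(rng.integers(lo, hi + 1))
        pop[i, rng.choice(n_feat, k, replace=False)] = True

    def fitness(mask: np.ndarray) -> float:
        return _cv_mse_fitness(X, y, mask, cv_folds, ridge_alpha, seed)

    fits = np.array([fitness(m) for m in pop])
    best_mask, best_fit = pop[fits.argmax()].copy(), fits.max()

    for _ in range(generations):
        # tournament selection (size 2)
        idx_a = rng.integers(0, population, population)
        idx_b = rng.integers(0, population, population)
        parents = np.where((fits[idx_a] >= fits[idx_b])[:, None],
                           pop[idx_a], pop[idx_b])
        children = parents.copy()
        for i in range(0, population - 1, 2):
            if rng.random() < crossover_rate:
                swap = rng.random(n_feat) < 0.5
                a, b = children[i].copy(), children[i + 1].copy()
                children[i, swap], children[i + 1, swap] = b[swap], a[swap]
        flip = rng.random(children.shape) < mutation_rate
        children ^= flip
        children = np.array([repair(c) for c in children])
        fits = np.array([fitness(c) for c in children])
        # elitism: best-so-far replaces the worst child
        worst = fits.argmin()
        children[worst], fits[worst] = best_mask, best_fit
        pop = children
        if fits.max() > best_fit:
            best_fit = fits.max()
            best_mask = pop[fits.argmax()].copy()

    cols = np.flatnonzero(best_mask).tolist()
    if feature_names is not None:
        return [feature_names[j] for j in cols]
    return cols


def rfe_select(
    X,
    y,
    trainer=None,
    n_keep: int = 8,
    feature_names: list[str] | None = None,
) -> tuple[list, list]:
    """Recursive feature elimination down to ``n_keep`` descriptors.

    ``trainer`` is any sklearn estimator exposing ``coef_`` or
    ``feature_importances_`` after fit (default: ridge regression).
    Returns ``(selected, elimination_order)`` where elimination_order
    lists the dropped features from first- to last-removed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if n_keep > X.shape[1]:
        raise ValueError(f"n_keep={n_keep} exceeds column count {X.shape[1]}")
    est = trainer if trainer is not None else Ridge(alpha=1.0)
    rfe = RFE(estimator=est, n_features_to_select=n_keep, step=1)
    try:
        rfe.fit(X, y)
    except Exception as exc:
        raise RuntimeError(f"RFE trainer failed: {exc}") from exc
    names = feature_names if feature_names is not None else list(range(X.shape[1]))
    selected = [names[j] for j in range(X.shape[1]) if rfe.support_[j]]
    # ranking_: 1 = kept; larger = eliminated earlier
    order = sorted(
        (j for j in range(X.shape[1]) if not rfe.support_[j]),
        key=lambda j: -rfe.ranking_[j],
    )
    eliminated = [names[j] for j in order]
    return selected, eliminated


# ---------------------------------------------------------------------------
# Kennard-Stone splitting


@dataclass
class SplitResult:
    train_ids: list
    test_ids: list
    ratio: tuple[int, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "ligand_id": list(self.train_ids) + list(self.test_ids),
            "set_label": ["train"] * len(self.train_ids) + ["test"] * len(self.test_ids),
        })


def kennard_stone_split(
    X,
    ids=None,
    ratio: tuple[int, int] = (2, 1),
    n_train: int | None = None,
) -> SplitResult:
    """Classical Kennard-Stone maximin training-set selection.

    The two points realizing the maximum pairwise Euclidean distance seed
    the training set; points are then added one at a time by maximal
    minimum distance to the already-selected set, until the training set
    holds ``floor(n * r / (r + 1))`` points for ratio ``r:1`` (or
    ``n_train`` when given).  Ties break toward the lowest row index, so
    the split is deterministic given input order.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 2:
        raise ValueError("Kennard-Stone needs at least 2 rows")
    if np.isnan(X).any():
        raise ValueError("Kennard-Stone input must have no missing values")
    if ids is None:
        ids = list(range(n))
    ids = list(ids)
    if n_train is None:
        r_tr, r_te = ratio
        n_train = int(np.floor(n * r_tr / (r_tr + r_te)))
    n_train = max(1, min(n_train, n - 1))

    d = cdist(X, X)
    # seed pair: max distance, ties to lowest (i, j)
    iu = np.triu_indices(n, k=1)
    flat = d[iu]
    best = int(np.argmax(flat))
    i0, j0 = int(iu[0][best]), int(iu[1][best])
    selected = [i0, j0][:n_train]
    if n_train >= 2:
        min_d = np.minimum(d[i0], d[j0])
    else:
        min_d = d[i0]
    min_d[selected] = -np.inf
    while len(selected) < n_train:
        nxt = int(np.argmax(min_d))  # argmax returns lowest index on ties
        selected.append(nxt)
        min_d = np.minimum(min_d, d[nxt])
        min_d[nxt] = -np.inf
    sel_set = set(selected)
    test = [i for i in range(n) if i not in sel_set]
    return SplitResult(
        train_ids=[ids[i] for i in selected],
        test_ids=[ids[i] for i in test],
        ratio=tuple(ratio),
    )


def split_diagnostics(
    descriptors: pd.DataFrame,
    affinities: pd.DataFrame,
    split: SplitResult,
    n_components: int = 3,
    plot_path=None,
) -> dict:
    """Descriptive comparison of training and test sets after splitting.

    Reports per-set pKi summaries, per-descriptor mean/sd by set, and the
    fraction of descriptor variance explained by the leading principal
    components.  Optionally writes a pKi histogram figure.
    """
    from sklearn.decomposition import PCA

    cols = [c for c in descriptors.columns if c != "ligand_id"]
    merged = descriptors.merge(affinities[["ligand_id", "pki"]], on="ligand_id")
    labels = split.to_frame()
    merged = merged.merge(labels, on="ligand_id")

    X = merged[cols].to_numpy(dtype=float)
    Xc = (X - X.mean(axis=0))
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    pca = PCA(n_components=min(n_components, *Xc.shape)).fit(Xc / sd)

    summary = {
        "pki_summary": {
            lab: {
                "n": int((merged["set_label"] == lab).sum()),
                "mean": float(merged.loc[merged["set_label"] == lab, "pki"].mean()),
                "sd": float(merged.loc[merged["set_label"] == lab, "pki"].std(ddof=1)),
                "min": float(merged.loc[merged["set_label"] == lab, "pki"].min()),
                "max": float(merged.loc[merged["set_label"] == lab, "pki"].max()),
            }
            for lab in ("train", "test")
        },
        "pc_variance_explained": pca.explained_variance_ratio_.tolist(),
        "pc_variance_cumulative": float(pca.explained_variance_ratio_.sum()),
    }
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.5))
        for lab in ("train", "test"):
            ax.hist(merged.loc[merged["set_label"] == lab, "pki"],
                    bins=12, alpha=0.5, label=lab, density=True)
        ax.set_xlabel("pKi")
        ax.set_ylabel("density")
        ax.legend()
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return summary
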