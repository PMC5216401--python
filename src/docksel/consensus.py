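"""Baseline pose-ranking schemes: single scoring terms and consensus.

Three classical consensus schemes are provided for benchmarking against
the learned pose selector: rank-by-number (average of direction-aligned,
optionally z-standardized scores), rank-by-rank (average of per-term
within-group ranks) and rank-by-vote (each term votes for its top
fraction of candidates).  Every term carries a direction annotation
(higher-better or lower-better); consensus arithmetic first aligns all
terms to higher-better.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import KEY_COLUMNS


HIGHER = "higher"
LOWER = "lower"

_TIE_COLS = ["structure_id", "conformer_id", "run_id", "pose_id"]


def _check_direction(direction: str) -> str:
    if direction not in (HIGHER, LOWER):
        raise ValueError(f"direction must be '{HIGHER}' or '{LOWER}'")
    return direction


def _final_ranks(df: pd.DataFrame, group_cols: list[str], score: pd.Series) -> pd.DataFrame:
    """Order by score descending within group; ties by candidate key.

    Returns the frame with a ``rank`` column (1 = best, a permutation of
    1..m per group) and a ``tie_broken`` flag marking candidates whose
    rank needed the key tie-break.
    """
    out = df[[c for c in df.columns if c in KEY_COLUMNS]].copy()
    out["_score"] = np.asarray(score, dtype=float)
    tie_cols = [c for c in _TIE_COLS if c in out.columns and c not in group_cols]
    out = out.sort_values(group_cols + ["_score"] + tie_cols,
                          ascending=[True] * len(group_cols) + [False] + [True] * len(tie_cols),
                          kind="stable")
    out["rank"] = out.groupby(group_cols, sort=False).cumcount() + 1
    ties = out.groupby(group_cols, sort=False)["_score"].transform(
        lambda s: s.duplicated(keep=False))
    out["tie_broken"] = ties
    return out.sort_index()


def single_function_ranking(
    pose_table: pd.DataFrame,
    term: str,
    direction: str = HIGHER,
    group_cols="ligand_id",
) -> pd.DataFrame:
    """Rank candidates within each group by one scoring term."""
    _check_direction(direction)
    if term not in pose_table.columns:
        raise KeyError(f"unknown scoring term {term!r}")
    if isinstance(group_cols, str):
        group_cols = [group_cols]
    score = pose_table[term].astype(float)
    if direction == LOWER:
        score = -score
    out = _final_ranks(pose_table, list(group_cols), score)
    out.attrs["method"] = f"single:{term}"
    return out


def _aligned_scores(pose_table, terms: dict[str, str]) -> pd.DataFrame:
    if len(terms) < 2:
        raise ValueError("consensus needs at least 2 terms")
    missing = [t for t in terms if t not in pose_table.columns]
    if missing:
        raise KeyError(f"unknown scoring term(s): {missing}")
    aligned = {}
    for term, direction in terms.items():
        _check_direction(direction)
        v = pose_table[term].astype(float)
        aligned[term] = -v if direction == LOWER else v
    return pd.DataFrame(aligned, index=pose_table.index)


def rank_by_number(
    pose_table: pd.DataFrame,
    terms: dict[str, str],
    standardize: bool = True,
    group_cols="ligand_id",
) -> pd.DataFrame:
    """Consensus by averaging (optionally z-standardized) aligned scores.

    Standardization uses the pooled mean and sample sd of each term over
    the whole table, guarding against the different numeric spans of
    different scoring functions; it is on by default and makes the scheme
    sensitive to monotone transforms of individual terms (unlike the
    rank-based schemes).
    """
    if isinstance(group_cols, str):
        group_cols = [group_cols]
    A = _aligned_scores(pose_table, terms)
    if standardize:
        sd = A.std(ddof=1)
        flat = sd[sd == 0].index.tolist()
        if flat:
            raise ValueError(f"cannot standardize zero-variance term(s): {flat}")
        A = (A - A.mean()) / sd
    out = _final_ranks(pose_table, list(group_cols), A.mean(axis=1))
    out.attrs["method"] = "rank_by_number"
    return out


def rank_by_rank(
    pose_table: pd.DataFrame,
    terms: dict[str, str],
    group_cols="ligand_id",
) -> pd.DataFrame:
    """Consensus by averaging per-term within-group ranks (1 = best);
    tied scores share their average rank before averaging across terms."""
    if isinstance(group_cols, str):
        group_cols = [group_cols]
    A = _aligned_scores(pose_table, terms)
    mean_rank = pd.Series(0.0, index=pose_table.index)
    keys = [pose_table[c] for c in group_cols]
    for term in A.columns:
        # rank descending on aligned score, average ties
        r = A.groupby(keys, sort=False)[term].transform(
            lambda s: rankdata(-s, method="average"))
        mean_rank += r
    mean_rank /= len(A.columns)
    out = _final_ranks(pose_table, list(group_cols), -mean_rank)
    out.attrs["method"] = "rank_by_rank"
    return out


def rank_by_vote(
    pose_table: pd.DataFrame,
    terms: dict[str, str],
    top_fraction: float = 1 / 3,
    group_cols="ligand_id",
) -> pd.DataFrame:
    """Consensus by counting each term's votes for its top candidates.

    Each term votes for its top ``ceil(top_fraction * m)`` candidates per
    group (by aligned score; score ties at the cutoff are admitted by
    within-group order after key tie-break).  Candidates are ordered by
    vote count; ties by mean per-term rank, then candidate key.
    """
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    if isinstance(group_cols, str):
        group_cols = [group_cols]
    A = _aligned_scores(pose_table, terms)
    votes = pd.Series(0.0, index=pose_table.index)
    mean_rank = pd.Series(0.0, index=pose_table.index)
    keys = [pose_table[c] for c in group_cols]
    for term in A.columns:
        r = A.groupby(keys, sort=False)[term].transform(
            lambda s: rankdata(-s, method="average"))
        mean_rank += r
        sizes = A.groupby(keys, sort=False)[term].transform("size")
        cutoff = np.ceil(top_fraction * sizes)
        # strict-rank within group (ties resolved by key) for vote admission
        strict = A.groupby(keys, sort=False)[term].transform(
            lambda s: rankdata(-s, method="ordinal"))
        votes += (strict <= cutoff).astype(float)
    mean_rank /= len(A.columns)
    # order: more votes first, then lower mean rank, then key
    composite = votes - mean_rank / (mean_rank.max() + 1.0)
    out = _final_ranks(pose_table, list(group_cols), composite)
    out["votes"] = votes.astype(int)
    out.attrs["method"] = "rank_by_vote"
    return out


def top_candidates(ranking: pd.DataFrame) -> pd.DataFrame:
    """The rank-1 candidate of every group."""
    return ranking[ranking["rank"] == 1].drop(
        columns=[c for c in ("_score", "tie_broken", "votes") if c in ranking.columns]
    ).reset_index(drop=True)
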