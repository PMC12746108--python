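"""Gabriel-style block bicrossvalidation for NMF rank selection.

The input matrix is shuffled (rows and columns independently) and tiled
into an m x n grid of blocks.  Each block A is held out once; the
remaining blocks provide B (same rows as A), C (same columns as A) and
the training block D.  D is factorized at the candidate rank, the fixed
factors are projected onto B and C, and the holdout is estimated as
A' = W_B @ H_C.  Cosine similarity and R-squared between A and A'
measure how well the candidate rank predicts unseen blocks; medians
over folds and shuffles form the rank-selection curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .nmf import FitSettings, fit_fixed_h, fit_fixed_w, nmf_decompose
from .utils import spawn_seeds

__all__ = [
    "BicvSplit",
    "BicvFold",
    "RankSelectionResult",
    "make_split",
    "extract_fold",
    "estimate_holdout",
    "cosine_flat",
    "r_squared",
    "rank_selection",
]


def _block_bounds(total: int, parts: int) -> np.ndarray:
    """Boundaries splitting ``total`` into ``parts`` near-equal pieces,
    remainder going to the earliest blocks.  Returns parts+1 offsets."""
    base, rem = divmod(total, parts)
    sizes = [base + 1 if i < rem else base for i in range(parts)]
    return np.concatenate([[0], np.cumsum(sizes)])


@dataclass(frozen=True)
class BicvSplit:
    """A shuffled matrix partitioned into an m x n block grid."""

    X: np.ndarray  # shuffled matrix
    row_breaks: np.ndarray  # m+1 offsets
    col_breaks: np.ndarray  # n+1 offsets
    row_perm: np.ndarray
    col_perm: np.ndarray
    shuffle_seed: int

    @property
    def m(self) -> int:
        return len(self.row_breaks) - 1

    @property
    def n(self) -> int:
        return len(self.col_breaks) - 1

    @property
    def n_folds(self) -> int:
        return self.m * self.n


@dataclass(frozen=True)
class BicvFold:
    """One Gabriel holdout: A heldout, B shares A's rows, C shares A's
    columns, D is the training complement."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray


def make_split(X: np.ndarray, m: int, n: int, shuffle_seed: int) -> BicvSplit:
    """Shuffle rows and columns independently and fix the block grid."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < m or X.shape[1] < n:
        raise ValueError(f"matrix {X.shape} too small for a {m} x {n} design")
    if m < 1 or n < 1:
        raise ValueError("m and n must be positive")
    rng = np.random.default_rng(shuffle_seed)
    row_perm = rng.permutation(X.shape[0])
    col_perm = rng.permutation(X.shape[1])
    shuffled = X[np.ix_(row_perm, col_perm)]
    return BicvSplit(
        X=shuffled,
        row_breaks=_block_bounds(X.shape[0], m),
        col_breaks=_block_bounds(X.shape[1], n),
        row_perm=row_perm,
        col_perm=col_perm,
        shuffle_seed=shuffle_seed,
    )


def extract_fold(split: BicvSplit, fold_index: int) -> BicvFold:
    """Fold ``fold_index`` (row-major over the block grid) as A/B/C/D."""
    if not 0 <= fold_index < split.n_folds:
        raise IndexError(f"fold index {fold_index} out of range 0..{split.n_folds - 1}")
    i, j = divmod(fold_index, split.n)
    rb, cb = split.row_breaks, split.col_breaks
    rows_a = np.arange(rb[i], rb[i + 1])
    cols_a = np.arange(cb[j], cb[j + 1])
    rows_d = np.concatenate([np.arange(0, rb[i]), np.arange(rb[i + 1], rb[-1])])
    cols_d = np.concatenate([np.arange(0, cb[j]), np.arange(cb[j + 1], cb[-1])])
    X = split.X
    return BicvFold(
        A=X[np.ix_(rows_a, cols_a)],
        B=X[np.ix_(rows_a, cols_d)],
        C=X[np.ix_(rows_d, cols_a)],
        D=X[np.ix_(rows_d, cols_d)],
    )


def estimate_holdout(
    fold: BicvFold, k: int, settings: FitSettings | None = None, seed: int = 0
) -> np.ndarray:
    """Estimate the heldout block A from B, C and D.

    D -> (W_D, H_D); W_B fit on B with H_D fixed; H_C fit on C with W_D
    fixed; A' = W_B @ H_C.
    """
    if k > min(fold.D.shape):
        raise ValueError(f"rank {k} too large for training block of shape {fold.D.shape}")
    dec = nmf_decompose(fold.D, k, settings, seed=seed)
    W_B = fit_fixed_h(fold.B, dec.H, settings, seed=seed)
    H_C = fit_fixed_w(fold.C, dec.W, settings, seed=seed)
    return W_B @ H_C


def cosine_flat(A: np.ndarray, A_est: np.ndarray) -> float:
    """Cosine similarity between the flattened matrices; 0 if either is zero."""
    A = np.asarray(A, dtype=float)
    A_est = np.asarray(A_est, dtype=float)
    if A.shape != A_est.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {A_est.shape}")
    na = np.linalg.norm(A)
    nb = np.linalg.norm(A_est)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(A.ravel(), A_est.ravel()) / (na * nb))


def r_squared(A: np.ndarray, A_est: np.ndarray, center: str = "estimate") -> float:
    """R-squared between the heldout block and its estimate.

    ``center="estimate"`` (default) centers the denominator on the grand
    mean of the estimate A'; ``center="holdout"`` uses the conventional
    mean of A.  Returns NaN when the denominator is zero (degenerate
    fold, excluded from medians).
    """
    A = np.asarray(A, dtype=float)
    A_est = np.asarray(A_est, dtype=float)
    if A.shape != A_est.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {A_est.shape}")
    if center not in ("estimate", "holdout"):
        raise ValueError(f"unknown center: {center!r}")
    mean = A_est.mean() if center == "estimate" else A.mean()
    denom = float(np.sum((A - mean) ** 2))
    if denom == 0.0:
        return float("nan")
    return 1.0 - float(np.sum((A - A_est) ** 2)) / denom


@dataclass
class RankSelectionResult:
    """Long-format bicrossvalidation records plus per-rank medians.

    ``records`` columns: rank, shuffle, fold, metric, value with metric
    in {"cosine", "r_squared"}.
    """

    records: pd.DataFrame
    m: int
    n: int
    num_shuffles: int

    def medians(self) -> pd.DataFrame:
        """Per-rank median of each metric (wide: rank x metric)."""
        med = (
            self.records.dropna(subset=["value"])
            .groupby(["rank", "metric"])["value"]
            .median()
            .unstack("metric")
        )
        med.columns.name = None
        return med

    def curve(self, metric: str) -> tuple[np.ndarray, np.ndarray]:
        med = self.medians()
        if metric not in med.columns:
            raise KeyError(f"no records for metric {metric!r}")
        series = med[metric].dropna()
        return series.index.to_numpy(), series.to_numpy()


def rank_selection(
    X: np.ndarray,
    ranks: Sequence[int],
    num_shuffles: int = 100,
    m: int = 3,
    n: int = 3,
    settings: FitSettings | None = None,
    master_seed: int = 0,
    r2_center: str = "estimate",
) -> RankSelectionResult:
    """Bicrossvalidate every candidate rank over shuffled block splits.

    Each shuffle uses a fresh row/column permutation drawn from a seed
    stream derived from ``master_seed``, so any shuffle is independently
    reproducible; within a shuffle each (fold, rank) fit gets its own
    derived seed.
    """
    ranks = sorted(set(int(k) for k in ranks))
    if not ranks:
        raise ValueError("empty rank list")
    X = np.asarray(X, dtype=float)
    # worst-case training block is the complement of the largest band
    min_d_rows = X.shape[0] - (X.shape[0] // m + (1 if X.shape[0] % m else 0))
    min_d_cols = X.shape[1] - (X.shape[1] // n + (1 if X.shape[1] % n else 0))
    if ranks[-1] > min(min_d_rows, min_d_cols):
        raise ValueError(
            f"rank {ranks[-1]} exceeds the training-block capacity "
            f"({min_d_rows} x {min_d_cols}) of a {m} x {n} design on {X.shape}"
        )
    shuffle_seeds = spawn_seeds(master_seed, num_shuffles, "bicv-shuffle")
    rows = []
    for s_idx in range(num_shuffles):
        split = make_split(X, m, n, int(shuffle_seeds[s_idx]))
        fit_seeds = spawn_seeds(int(shuffle_seeds[s_idx]), split.n_folds * len(ranks), "bicv-fit")
        for f_idx in range(split.n_folds):
            fold = extract_fold(split, f_idx)
            for r_idx, k in enumerate(ranks):
                seed = int(fit_seeds[f_idx * len(ranks) + r_idx])
                A_est = estimate_holdout(fold, k, settings, seed=seed)
                rows.append((k, s_idx, f_idx, "cosine", cosine_flat(fold.A, A_est)))
                rows.append((k, s_idx, f_idx, "r_squared", r_squared(fold.A, A_est, center=r2_center)))
    records = pd.DataFrame(rows, columns=["rank", "shuffle", "fold", "metric", "value"])
    return RankSelectionResult(records=records, m=m, n=n, num_shuffles=num_shuffles)
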