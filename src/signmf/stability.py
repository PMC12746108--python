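"""Decomposition-stability measures across random restarts.

Three measures of how reproducible a rank-k decomposition is across
random initializations:

* **signature similarity** — mean cosine between signatures of the best
  restart (lowest reconstruction error) and their Hungarian-matched
  counterparts in every other restart;
* **cophenetic correlation** — agreement between consensus-derived
  sample distances and the cophenetic distances of their average-linkage
  hierarchical clustering;
* **dispersion** — mean of 4*(C_ij - 1/2)^2 over the consensus matrix C.

All three are computed from the same set of restarts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

from .nmf import Decomposition, best_of

__all__ = [
    "SignatureMatching",
    "SignatureSimilarityResult",
    "signature_cosine_matrix",
    "match_signatures",
    "signature_similarity",
    "connectivity_matrix",
    "consensus_matrix",
    "dispersion",
    "cophenetic_correlation",
]


@dataclass(frozen=True)
class SignatureMatching:
    """Optimal pairing of signatures between two decompositions."""

    pairing: tuple[int, ...]  # pairing[i] = column of other matched to column i of best
    pair_cosines: tuple[float, ...]
    total_cost: float


@dataclass
class SignatureSimilarityResult:
    """Per-signature cosine distributions and their overall mean."""

    per_signature: np.ndarray  # k x (n-1): cosines per best-signature per comparison
    score: float
    best_index: int


def _unit_columns(W: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(W, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    U = W / safe
    U[:, norms == 0] = 0.0  # zero-norm signature: cosine defined as 0
    return U


def signature_cosine_matrix(W_a: np.ndarray, W_b: np.ndarray) -> np.ndarray:
    """Pairwise cosine between signature columns of two loading matrices."""
    if W_a.shape != W_b.shape:
        raise ValueError(f"shape mismatch: {W_a.shape} vs {W_b.shape}")
    return _unit_columns(np.asarray(W_a, float)).T @ _unit_columns(np.asarray(W_b, float))


def match_signatures(W_best: np.ndarray, W_other: np.ndarray) -> SignatureMatching:
    """Hungarian matching of signature columns maximizing total cosine."""
    cos = signature_cosine_matrix(W_best, W_other)
    row, col = linear_sum_assignment(cos, maximize=True)
    pairing = np.empty(cos.shape[0], dtype=int)
    pairing[row] = col
    pair_cosines = cos[np.arange(cos.shape[0]), pairing]
    return SignatureMatching(
        pairing=tuple(int(c) for c in pairing),
        pair_cosines=tuple(float(c) for c in pair_cosines),
        total_cost=float(pair_cosines.sum()),
    )


def signature_similarity(
    decomps: Sequence[Decomposition], criterion: str = "recon_error"
) -> SignatureSimilarityResult:
    """Mean matched cosine between the best restart and all others.

    The best decomposition is the one minimizing ``criterion``; each of
    the remaining n-1 is matched to it signature-by-signature with the
    Hungarian algorithm and the mean of all matched cosines is the
    stability score for this rank.
    """
    decomps = list(decomps)
    if len(decomps) < 2:
        raise ValueError("need at least 2 decompositions")
    best = best_of(decomps, criterion)
    best_index = next(i for i, d in enumerate(decomps) if d is best)
    others = [d for i, d in enumerate(decomps) if i != best_index]
    k = best.rank
    per_sig = np.empty((k, len(others)))
    for j, other in enumerate(others):
        per_sig[:, j] = match_signatures(best.W, other.W).pair_cosines
    return SignatureSimilarityResult(per_signature=per_sig, score=float(per_sig.mean()), best_index=best_index)


def connectivity_matrix(H: np.ndarray) -> np.ndarray:
    """Binary sample co-assignment matrix: each sample is assigned to its
    argmax signature (ties to the lowest index)."""
    H = np.asarray(H, dtype=float)
    if np.any(H < 0):
        raise ValueError("H must be non-negative")
    assign = np.argmax(H, axis=0)
    return (assign[:, None] == assign[None, :]).astype(float)


def consensus_matrix(decomps: Sequence[Decomposition]) -> np.ndarray:
    """Mean connectivity over restarts: co-assignment frequencies in [0, 1]."""
    decomps = list(decomps)
    if len(decomps) < 2:
        raise ValueError("need at least 2 decompositions")
    n_samples = {d.H.shape[1] for d in decomps}
    if len(n_samples) != 1:
        raise ValueError("decompositions cover different sample sets")
    C = np.mean([connectivity_matrix(d.H) for d in decomps], axis=0)
    return C


def dispersion(C: np.ndarray) -> float:
    """Dispersion coefficient: 1 for a binary consensus, 0 when all 1/2."""
    C = np.asarray(C, dtype=float)
    p = C.shape[0]
    return float(np.sum(4.0 * (C - 0.5) ** 2) / (p * p))


def cophenetic_correlation(C: np.ndarray) -> float:
    """Cophenetic correlation of the consensus matrix.

    Pearson correlation between the condensed distances d = 1 - C and
    the cophenetic distances of their average-linkage dendrogram.
    Returns NaN when the distances are constant (undefined).
    """
    C = np.asarray(C, dtype=float)
    if C.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    d = squareform(1.0 - C, checks=False)
    if np.ptp(d) == 0.0:
        return float("nan")
    Z = linkage(d, method="average")
    coph = cophenet(Z)
    if np.ptp(coph) == 0.0:
        return float("nan")
    return float(pearsonr(d, coph)[0])
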