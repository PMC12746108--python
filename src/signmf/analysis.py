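"""Sample-level interpretation of a decomposition.

Given (W, H) for a cohort, each sample gets: its relative signature
weights, its primary signature (highest weight), its representative
signature set (smallest set covering >= 90% of total signature weight),
a single-signature-dominance (SSD) flag, and a per-sample model fit
(cosine between the sample and its reconstruction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SampleSignatureProfile",
    "relative_weights",
    "representative_signatures",
    "primary_signature",
    "model_fit",
    "profile_samples",
]


@dataclass(frozen=True)
class SampleSignatureProfile:
    sample_id: str
    relative_weights: tuple[float, ...]
    primary: str
    representative_set: tuple[str, ...]
    is_ssd: bool
    model_fit: float


def relative_weights(H: np.ndarray) -> np.ndarray:
    """Normalize each sample column of H to proportions summing to 1."""
    H = np.asarray(H, dtype=float)
    if np.any(H < 0):
        raise ValueError("H must be non-negative")
    sums = H.sum(axis=0)
    if np.any(sums <= 0):
        raise ValueError(f"zero-weight sample column(s): {np.flatnonzero(sums <= 0).tolist()}")
    return H / sums


def _rep_indices(rel: np.ndarray, threshold: float) -> list[int]:
    # descending by weight, ties to the lower signature index
    order = np.lexsort((np.arange(len(rel)), -rel))
    cum = 0.0
    chosen: list[int] = []
    for idx in order:
        chosen.append(int(idx))
        cum += rel[idx]
        if cum >= threshold - 1e-12:
            break
    return chosen


def representative_signatures(rel: np.ndarray, threshold: float = 0.9) -> list[int]:
    """Smallest prefix of signatures (sorted by descending weight) whose
    cumulative proportion reaches ``threshold``; returns signature indices."""
    rel = np.asarray(rel, dtype=float)
    if abs(rel.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    return _rep_indices(rel, threshold)


def primary_signature(rel: np.ndarray) -> int:
    """Index of the highest-weight signature (ties to the lowest index)."""
    rel = np.asarray(rel, dtype=float)
    return int(np.argmax(rel))


def model_fit(X: np.ndarray, W: np.ndarray, H: np.ndarray, method: str = "cosine") -> np.ndarray:
    """Per-sample agreement between X and its reconstruction W @ H.

    ``method="cosine"`` (default): cosine between each sample column and
    its reconstruction, invariant to positive rescaling of the sample;
    ``method="r_squared"``: per-column R2 of the reconstruction.
    """
    X = np.asarray(X, dtype=float)
    recon = np.asarray(W, dtype=float) @ np.asarray(H, dtype=float)
    if recon.shape != X.shape:
        raise ValueError(f"shape mismatch: X {X.shape} vs WH {recon.shape}")
    if method == "cosine":
        nx = np.linalg.norm(X, axis=0)
        nr = np.linalg.norm(recon, axis=0)
        denom = nx * nr
        fits = np.zeros(X.shape[1])
        ok = denom > 0
        fits[ok] = np.einsum("ij,ij->j", X, recon)[ok] / denom[ok]
        return fits
    if method == "r_squared":
        ss_res = np.sum((X - recon) ** 2, axis=0)
        ss_tot = np.sum((X - X.mean(axis=0)) ** 2, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, np.nan)
    raise ValueError(f"unknown method: {method!r}")


def profile_samples(
    X: np.ndarray,
    W: np.ndarray,
    H: np.ndarray,
    sample_ids: list[str] | None = None,
    signature_ids: list[str] | None = None,
    threshold: float = 0.9,
) -> pd.DataFrame:
    """Per-sample profile table: primary signature, representative-set
    size, SSD flag, model fit, and one proportion column per signature."""
    H = np.asarray(H, dtype=float)
    k, n_samp = H.shape
    sample_ids = sample_ids or [f"sample{j + 1}" for j in range(n_samp)]
    signature_ids = signature_ids or [f"S{i + 1}" for i in range(k)]
    rel = relative_weights(H)
    fits = model_fit(X, W, H)
    rows = []
    for j in range(n_samp):
        reps = representative_signatures(rel[:, j], threshold)
        rows.append(
            {
                "sample": sample_ids[j],
                "primary": signature_ids[primary_signature(rel[:, j])],
                "n_representative": len(reps),
                "is_ssd": len(reps) == 1,
                "model_fit": fits[j],
                **{signature_ids[i]: rel[i, j] for i in range(k)},
            }
        )
    return pd.DataFrame(rows).set_index("sample")
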