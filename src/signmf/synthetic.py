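"""Synthetic benchmark matrices of known rank.

The generator builds a ground-truth factor pair and a noisy product:

* ``W_true`` (nk x k): signature i owns n dedicated feature rows whose
  loadings in column i are lognormal(mu=0, sigma=1); to make signatures
  overlap, ``floor(p * (kn - n))`` rows owned by other signatures also
  receive a lognormal loading in column i.
* ``H_true`` (k x kn, or k x n_samples): uniform(0, 1) weights with
  ``floor(s * k * n)`` randomly chosen entries zeroed.
* ``X = W_true @ H_true + Normal(0, sigma^2)``, negatives clipped to 0.

This emulates compositional community data where taxa are shared across
guilds and samples mix several guilds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .utils import spawn_seeds

__all__ = ["SyntheticDataset", "synthetic_dense", "benchmark_suite"]


@dataclass
class SyntheticDataset:
    """A generated matrix with its ground truth and parameters."""

    X: np.ndarray
    W_true: np.ndarray
    H_true: np.ndarray
    true_rank: int
    params: dict = field(default_factory=dict)


def synthetic_dense(
    k: int,
    n: int = 20,
    p: float = 0.25,
    s: float = 0.25,
    noise_var: float = 0.25,
    seed: int = 0,
    n_samples: int | None = None,
    sparsity_mode: str = "count",
) -> SyntheticDataset:
    """Generate a rank-``k`` benchmark matrix with overlapping signatures.

    Parameters
    ----------
    k : number of signatures (>= 2).
    n : dedicated features per signature; X has n*k rows.
    p : overlap fraction — each signature cross-loads floor(p*(kn - n))
        features owned by other signatures.
    s : sparsity of H; by default ("count" mode) floor(s*k*n) entries of
        H are zeroed, matching the published construction; "fraction"
        mode zeroes fraction s of all k*n_samples entries instead.
    noise_var : variance of the additive Gaussian noise on W @ H.
    n_samples : number of sample columns; defaults to k*n.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if not 0 <= s < 1:
        raise ValueError("s must be in [0, 1)")
    if noise_var < 0:
        raise ValueError("noise_var must be >= 0")
    if sparsity_mode not in ("count", "fraction"):
        raise ValueError(f"unknown sparsity_mode: {sparsity_mode!r}")
    n_feat = n * k
    n_samp = n * k if n_samples is None else int(n_samples)
    if n_samp < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)

    W = np.zeros((n_feat, k))
    for i in range(k):
        own = np.arange(i * n, (i + 1) * n)
        W[own, i] = rng.lognormal(mean=0.0, sigma=1.0, size=n)
        n_cross = int(np.floor(p * (n_feat - n)))
        if n_cross:
            others = np.concatenate([np.arange(0, i * n), np.arange((i + 1) * n, n_feat)])
            chosen = rng.choice(others, size=n_cross, replace=False)
            W[chosen, i] = rng.lognormal(mean=0.0, sigma=1.0, size=n_cross)

    H = rng.uniform(0.0, 1.0, size=(k, n_samp))
    n_zero = int(np.floor(s * k * n)) if sparsity_mode == "count" else int(np.floor(s * H.size))
    if n_zero:
        flat = rng.choice(H.size, size=min(n_zero, H.size), replace=False)
        H.ravel()[flat] = 0.0

    X = W @ H
    if noise_var > 0:
        X = X + rng.normal(loc=0.0, scale=np.sqrt(noise_var), size=X.shape)
    X = np.clip(X, 0.0, None)
    params = dict(
        k=k, n=n, p=p, s=s, noise_var=noise_var, seed=seed,
        n_samples=n_samp, sparsity_mode=sparsity_mode,
    )
    return SyntheticDataset(X=X, W_true=W, H_true=H, true_rank=k, params=params)


def benchmark_suite(
    true_ranks: Sequence[int],
    replicates: int = 20,
    params: dict | None = None,
    master_seed: int = 0,
) -> list[SyntheticDataset]:
    """One dataset per (true rank, replicate), seeded from a master stream."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    params = dict(params or {})
    ranks = [int(k) for k in true_ranks]
    seeds = spawn_seeds(master_seed, len(ranks) * replicates, "benchmark-suite")
    suite = []
    for i, k in enumerate(ranks):
        for r in range(replicates):
            seed = int(seeds[i * replicates + r])
            suite.append(synthetic_dense(k=k, seed=seed, **params))
    return suite
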