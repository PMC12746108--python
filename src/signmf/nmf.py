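"""KL-divergence NMF by multiplicative updates.

The solver minimizes the generalized Kullback-Leibler divergence

    D(X || WH) = sum_ij [ X_ij * log(X_ij / (WH)_ij) - X_ij + (WH)_ij ]

with the convention ``0 * log 0 = 0``.  It supports fits in which one
factor is held fixed (needed by the Gabriel-holdout bicrossvalidation
steps) and multi-start selection by reconstruction error.  All fits are
bitwise reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FitSettings",
    "Decomposition",
    "kl_divergence",
    "nmf_decompose",
    "fit_fixed_h",
    "fit_fixed_w",
    "best_of",
]


@dataclass(frozen=True)
class FitSettings:
    """Solver settings.

    max_iter : hard cap on multiplicative-update iterations.
    tol : relative KL improvement below which iteration stops; checked
        every ``check_every`` iterations.
    eps : guard constant added to denominators and to WH inside logs.
    """

    max_iter: int = 500
    tol: float = 1e-4
    eps: float = 1e-10
    check_every: int = 10
    init: str = "random"
    beta_loss: str = "kullback-leibler"

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.init != "random":
            raise ValueError(f"unsupported init: {self.init!r}")
        if self.beta_loss != "kullback-leibler":
            raise ValueError(f"unsupported beta_loss: {self.beta_loss!r}")


@dataclass(eq=False)
class Decomposition:
    """A (W, H) factor pair at a given rank with its provenance."""

    W: np.ndarray  # features x k
    H: np.ndarray  # k x samples
    rank: int
    recon_error: float
    seed: int
    iterations: int
    trace: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.W.ndim != 2 or self.H.ndim != 2:
            raise ValueError("W and H must be 2-D")
        if self.W.shape[1] != self.rank or self.H.shape[0] != self.rank:
            raise ValueError("rank must equal the inner dimension of W and H")
        if np.any(self.W < 0) or np.any(self.H < 0):
            raise ValueError("factors must be non-negative")
        if not np.isfinite(self.recon_error):
            raise ValueError("recon_error must be finite")

    @property
    def reconstruction(self) -> np.ndarray:
        return self.W @ self.H


def kl_divergence(X: np.ndarray, W: np.ndarray, H: np.ndarray, eps: float = 1e-10) -> float:
    """Generalized KL divergence D(X || WH), zero iff X == WH elementwise."""
    X = np.asarray(X, dtype=float)
    WH = np.asarray(W, dtype=float) @ np.asarray(H, dtype=float)
    if WH.shape != X.shape:
        raise ValueError(f"shape mismatch: X {X.shape} vs WH {WH.shape}")
    pos = X > 0
    div = float(np.sum(X[pos] * np.log(X[pos] / (WH[pos] + eps)))) + float(np.sum(WH - X))
    return div


def _init_factors(
    X: np.ndarray, k: int, rng: np.random.Generator, init_w: bool, init_h: bool
) -> tuple[np.ndarray | None, np.ndarray | None]:
    # uniform(0,1) scaled so that E[(WH)_ij] is on the order of mean(X)
    scale = np.sqrt(max(X.mean(), np.finfo(float).tiny) / k)
    W = scale * rng.uniform(size=(X.shape[0], k)) if init_w else None
    H = scale * rng.uniform(size=(k, X.shape[1])) if init_h else None
    return W, H


def _mu_solve(
    X: np.ndarray,
    W: np.ndarray,
    H: np.ndarray,
    settings: FitSettings,
    update_w: bool,
    update_h: bool,
) -> tuple[np.ndarray, np.ndarray, float, int, list[float]]:
    """Run multiplicative updates; returns (W, H, error, n_iter, trace).

    The KL objective is evaluated from the running WH product using the
    identity D(X||WH) = sum_pos[x log x] - sum(X) - sum_pos[x log WH] + sum(WH),
    so convergence checks cost one log pass, not a full re-factorization.
    """
    eps = settings.eps
    W = W.copy()
    H = H.copy()
    pos = X > 0
    xp = X[pos]
    kl_const = float(np.sum(xp * np.log(xp))) - float(X.sum())

    def kl_from(WH: np.ndarray) -> float:
        return kl_const - float(np.sum(xp * np.log(WH[pos] + eps))) + float(WH.sum())

    WH = W @ H
    prev = kl_from(WH)
    trace = [prev]
    n_iter = 0
    for it in range(1, settings.max_iter + 1):
        ratio = X / (WH + eps)
        if update_w:
            W *= (ratio @ H.T) / (H.sum(axis=1)[None, :] + eps)
            WH = W @ H
            if update_h:
                ratio = X / (WH + eps)
        if update_h:
            H *= (W.T @ ratio) / (W.sum(axis=0)[:, None] + eps)
            WH = W @ H
        n_iter = it
        if it % settings.check_every == 0 or it == settings.max_iter:
            err = kl_from(WH)
            trace.append(err)
            if prev - err < settings.tol * max(prev, eps):
                break
            prev = err
    return W, H, trace[-1], n_iter, trace


def nmf_decompose(
    X: np.ndarray, k: int, settings: FitSettings | None = None, seed: int = 0
) -> Decomposition:
    """Factor a non-negative matrix into rank-``k`` non-negative W, H."""
    settings = settings or FitSettings()
    X = np.ascontiguousarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("X must be non-negative")
    if not (1 <= k <= min(X.shape)):
        raise ValueError(f"rank {k} out of range for matrix of shape {X.shape}")
    if not np.any(X > 0):
        raise ValueError("X is all-zero")
    rng = np.random.default_rng(seed)
    W, H = _init_factors(X, k, rng, init_w=True, init_h=True)
    W, H, err, n_iter, trace = _mu_solve(X, W, H, settings, True, True)
    return Decomposition(W=W, H=H, rank=k, recon_error=err, seed=seed, iterations=n_iter, trace=trace)


def fit_fixed_h(
    X: np.ndarray, H_fixed: np.ndarray, settings: FitSettings | None = None, seed: int = 0
) -> np.ndarray:
    """Fit W by KL multiplicative updates with H held fixed."""
    settings = settings or FitSettings()
    X = np.ascontiguousarray(X, dtype=float)
    H_fixed = np.ascontiguousarray(H_fixed, dtype=float)
    if H_fixed.ndim != 2 or H_fixed.shape[1] != X.shape[1]:
        raise ValueError(f"H_fixed shape {H_fixed.shape} does not conform to X {X.shape}")
    rng = np.random.default_rng(seed)
    k = H_fixed.shape[0]
    W, _ = _init_factors(X, k, rng, init_w=True, init_h=False)
    W, _, _, _, _ = _mu_solve(X, W, H_fixed, settings, update_w=True, update_h=False)
    return W


def fit_fixed_w(
    X: np.ndarray, W_fixed: np.ndarray, settings: FitSettings | None = None, seed: int = 0
) -> np.ndarray:
    """Fit H by KL multiplicative updates with W held fixed."""
    settings = settings or FitSettings()
    X = np.ascontiguousarray(X, dtype=float)
    W_fixed = np.ascontiguousarray(W_fixed, dtype=float)
    if W_fixed.ndim != 2 or W_fixed.shape[0] != X.shape[0]:
        raise ValueError(f"W_fixed shape {W_fixed.shape} does not conform to X {X.shape}")
    rng = np.random.default_rng(seed)
    k = W_fixed.shape[1]
    _, H = _init_factors(X, k, rng, init_w=False, init_h=True)
    _, H, _, _, _ = _mu_solve(X, W_fixed, H, settings, update_w=False, update_h=True)
    return H


def best_of(decomps: Sequence[Decomposition], criterion: str = "recon_error") -> Decomposition:
    """Pick the decomposition minimizing ``criterion``; ties go to the lowest index."""
    if criterion != "recon_error":
        raise ValueError(f"unknown criterion: {criterion!r}")
    decomps = list(decomps)
    if not decomps:
        raise ValueError("empty decomposition list")
    ranks = {d.rank for d in decomps}
    if len(ranks) != 1:
        raise ValueError(f"mixed ranks: {sorted(ranks)}")
    best = min(range(len(decomps)), key=lambda i: decomps[i].recon_error)
    return decomps[best]
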