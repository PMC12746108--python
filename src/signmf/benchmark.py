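"""Rank-recovery benchmark comparing the five selection criteria.

For each synthetic dataset of known rank, all five criteria scan the
same candidate ranks: the two bicrossvalidation metrics (median cosine
and R2, elbow-suggested) run on their own shuffle set, and the three
stability coefficients (signature similarity, cophenetic correlation,
dispersion, peak-suggested) share one multi-restart decomposition set
per rank.  A criterion is correct on a dataset when its suggested rank
equals the true rank.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .bicv import rank_selection
from .nmf import FitSettings, nmf_decompose
from .rank_suggest import RankCurve, suggest_rank_elbow, suggest_rank_stability
from .stability import consensus_matrix, cophenetic_correlation, dispersion, signature_similarity
from .synthetic import SyntheticDataset
from .utils import spawn_seeds

__all__ = ["BenchmarkOutcome", "stability_curves", "run_benchmark", "CRITERIA"]

CRITERIA = ("bicv_cosine", "bicv_r2", "signature_similarity", "cophenetic", "dispersion")


@dataclass
class BenchmarkOutcome:
    """Per-dataset suggestions and correctness for every criterion.

    ``results`` columns: criterion, true_rank, replicate, suggested
    (nullable), correct.
    """

    results: pd.DataFrame
    candidate_ranks: tuple[int, ...]

    def percent_correct(self) -> pd.Series:
        """Overall percent of correctly identified ranks per criterion."""
        return 100.0 * self.results.groupby("criterion")["correct"].mean()

    def percent_correct_by_rank(self) -> pd.DataFrame:
        """Percent correct per criterion per true rank (criterion x rank)."""
        return 100.0 * (
            self.results.groupby(["criterion", "true_rank"])["correct"].mean().unstack("true_rank")
        )


def stability_curves(
    X: np.ndarray,
    candidate_ranks: Sequence[int],
    num_restarts: int,
    settings: FitSettings | None,
    master_seed: int,
) -> dict[str, RankCurve]:
    """Signature-similarity, cophenetic and dispersion curves over ranks,
    all computed from the same multi-restart decomposition set."""
    ranks = sorted(set(int(k) for k in candidate_ranks))
    seeds = spawn_seeds(master_seed, len(ranks) * num_restarts, "stability-restarts")
    sim, coph, disp = [], [], []
    for i, k in enumerate(ranks):
        decomps = [
            nmf_decompose(X, k, settings, seed=int(seeds[i * num_restarts + r]))
            for r in range(num_restarts)
        ]
        sim.append(signature_similarity(decomps).score)
        C = consensus_matrix(decomps)
        coph.append(cophenetic_correlation(C))
        disp.append(dispersion(C))
    curves = {}
    for name, vals in (("signature_similarity", sim), ("cophenetic", coph), ("dispersion", disp)):
        pairs = [(r, v) for r, v in zip(ranks, vals) if np.isfinite(v)]
        curves[name] = RankCurve(tuple(r for r, _ in pairs), tuple(v for _, v in pairs))
    return curves


def run_benchmark(
    suite: Sequence[SyntheticDataset],
    candidate_ranks: Sequence[int],
    num_shuffles: int = 10,
    num_restarts: int = 20,
    settings: FitSettings | None = None,
    master_seed: int = 0,
    m: int = 3,
    n: int = 3,
    stability_t: float = 0.02,
) -> BenchmarkOutcome:
    """Run all five criteria on every dataset of the suite."""
    candidate_ranks = sorted(set(int(k) for k in candidate_ranks))
    true_ranks = {d.true_rank for d in suite}
    missing = true_ranks - set(candidate_ranks)
    if missing:
        raise ValueError(f"candidate ranks exclude true rank(s) {sorted(missing)}")
    dataset_seeds = spawn_seeds(master_seed, 2 * len(suite), "benchmark-run")
    rows = []
    replicate_counter: dict[int, int] = {}
    for idx, ds in enumerate(suite):
        replicate = replicate_counter.get(ds.true_rank, 0)
        replicate_counter[ds.true_rank] = replicate + 1
        bicv_seed, stab_seed = int(dataset_seeds[2 * idx]), int(dataset_seeds[2 * idx + 1])

        sel = rank_selection(
            ds.X, candidate_ranks, num_shuffles=num_shuffles, m=m, n=n,
            settings=settings, master_seed=bicv_seed,
        )
        suggestions: dict[str, int | None] = {}
        for crit, metric in (("bicv_cosine", "cosine"), ("bicv_r2", "r_squared")):
            ranks_arr, vals = sel.curve(metric)
            suggestions[crit] = (
                suggest_rank_elbow(RankCurve(tuple(ranks_arr), tuple(vals)), online=True)
                if len(ranks_arr) >= 3
                else None
            )

        curves = stability_curves(ds.X, candidate_ranks, num_restarts, settings, stab_seed)
        for crit, curve in curves.items():
            suggestions[crit] = (
                suggest_rank_stability(curve, t=stability_t) if len(curve.ranks) else None
            )

        for crit in CRITERIA:
            sug = suggestions.get(crit)
            rows.append(
                {
                    "criterion": crit,
                    "true_rank": ds.true_rank,
                    "replicate": replicate,
                    "suggested": sug,
                    "correct": sug == ds.true_rank,
                }
            )
    results = pd.DataFrame(rows)
    return BenchmarkOutcome(results=results, candidate_ranks=tuple(candidate_ranks))
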