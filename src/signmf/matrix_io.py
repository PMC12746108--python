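"""Reading, validation, scaling and writing of abundance tables.

Tables are tab-separated with a header row of sample IDs and a leading
column of feature IDs.  The canonical in-memory orientation is features
in rows, samples in columns — the same orientation as the W (features x
signatures) and H (signatures x samples) factors.
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["AbundanceMatrix", "read_table", "write_table", "drop_features", "total_sum_scale"]


@dataclass(frozen=True)
class AbundanceMatrix:
    """Non-negative feature x sample table with ordered, unique labels."""

    values: np.ndarray
    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if values.shape[0] < 2 or values.shape[1] < 2:
            raise ValueError("matrix must have at least 2 rows and 2 columns")
        if not np.all(np.isfinite(values)):
            raise ValueError("matrix contains non-finite values")
        if np.any(values < 0):
            raise ValueError("matrix contains negative values")
        for name, labels in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            if len(set(labels)) != len(labels):
                raise ValueError(f"duplicate {name} labels")
            if any(lab == "" for lab in labels):
                raise ValueError(f"empty {name} label")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.feature_ids), columns=list(self.sample_ids))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AbundanceMatrix":
        return cls(frame.to_numpy(dtype=float), tuple(map(str, frame.index)), tuple(map(str, frame.columns)))


def read_table(path: str | PathLike, orient: str = "features_in_rows") -> AbundanceMatrix:
    """Read a TSV abundance table into canonical features x samples form.

    ``orient="samples_in_rows"`` transposes after reading, so the result
    is always features x samples.
    """
    if orient not in ("features_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orient: {orient!r}")
    frame = pd.read_csv(path, sep="\t", index_col=0, header=0)
    try:
        frame = frame.astype(float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if orient == "samples_in_rows":
        frame = frame.T
    return AbundanceMatrix.from_frame(frame)


def write_table(m: AbundanceMatrix | pd.DataFrame, path: str | PathLike) -> None:
    """Write a labelled matrix as TSV, round-trippable through read_table."""
    frame = m.to_frame() if isinstance(m, AbundanceMatrix) else m
    if any(str(lab) == "" for lab in frame.index) or any(str(lab) == "" for lab in frame.columns):
        raise ValueError("empty labels cannot be written")
    frame.to_csv(path, sep="\t", float_format="%.15g")


def drop_features(m: AbundanceMatrix, labels: Iterable[str]) -> AbundanceMatrix:
    """Remove named feature rows (absent labels are ignored), keeping order.

    Used e.g. to drop the unknown-taxon row ("?") before total-sum scaling.
    """
    drop = {str(lab) for lab in labels}
    keep = [i for i, f in enumerate(m.feature_ids) if f not in drop]
    if len(keep) < 2:
        raise ValueError("dropping these features would leave fewer than 2 rows")
    if len(keep) == len(m.feature_ids):
        return m
    return AbundanceMatrix(m.values[keep, :], tuple(m.feature_ids[i] for i in keep), m.sample_ids)


def total_sum_scale(m: AbundanceMatrix) -> AbundanceMatrix:
    """Divide each sample column by its sum (relative abundances)."""
    sums = m.values.sum(axis=0)
    zero = np.flatnonzero(sums <= 0)
    if zero.size:
        raise ValueError(f"zero-sum sample column(s): {[m.sample_ids[i] for i in zero]}")
    return AbundanceMatrix(m.values / sums, m.feature_ids, m.sample_ids)
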