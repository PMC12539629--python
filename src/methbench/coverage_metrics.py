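"""Coverage breadth and depth-retention statistics.

The central quantity is the depth-versus-coverage dependency curve: for each
integer depth threshold t the fraction of the CpG universe covered by at
least t reads.  Its area under the curve over thresholds 1..200, divided by
200, is the normalized coverage-retention score in [0, 1] — a run whose
every CpG has >= 200 reads scores exactly 1, a run with no coverage scores 0.
Sites absent from a run count as depth 0: the universe is fixed a priori
(the "total genomic CpGs" of the study design), so dropping sites hurts the
score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .io_calls import MethylationCallSet

DEFAULT_T_MAX = 200


@dataclass
class RetentionCurve:
    """Fraction of the universe retained at each depth threshold 1..t_max."""

    thresholds: np.ndarray
    retained_fraction: np.ndarray

    def __post_init__(self) -> None:
        if len(self.thresholds) != len(self.retained_fraction):
            raise ValueError("thresholds and fractions differ in length")
        f = np.asarray(self.retained_fraction, dtype=float)
        if np.any(f < -1e-12) or np.any(f > 1 + 1e-12):
            raise ValueError("retained fractions outside [0, 1]")
        if np.any(np.diff(f) > 1e-12):
            raise ValueError("retention curve must be non-increasing")

    @property
    def t_max(self) -> int:
        return int(self.thresholds[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(threshold=self.thresholds, fraction=self.retained_fraction)
        )


def depth_over_universe(
    calls: MethylationCallSet, universe: pd.MultiIndex | Iterable[tuple[str, int]]
) -> np.ndarray:
    """Per-universe-site read depth for one run; absent sites are depth 0."""
    if not isinstance(universe, pd.MultiIndex):
        universe = pd.MultiIndex.from_tuples(list(universe), names=["chrom", "pos"])
    if len(universe) == 0:
        raise ValueError("empty CpG universe")
    s = calls.df.set_index(["chrom", "pos"])["depth"]
    return s.reindex(universe).fillna(0.0).to_numpy()


def covered_fraction(
    calls: MethylationCallSet,
    universe: pd.MultiIndex | Iterable[tuple[str, int]],
    min_depth: int = 1,
) -> float:
    """Fraction of universe CpGs covered by at least ``min_depth`` reads."""
    depth = depth_over_universe(calls, universe)
    return float(np.mean(depth >= min_depth))


def retention_curve(
    calls: MethylationCallSet,
    universe: pd.MultiIndex | Iterable[tuple[str, int]],
    t_max: int = DEFAULT_T_MAX,
) -> RetentionCurve:
    """Depth-versus-coverage curve over integer thresholds 1..t_max."""
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    depth = depth_over_universe(calls, universe)
    return retention_curve_from_depth(depth, t_max)


def retention_curve_from_depth(depth: np.ndarray, t_max: int = DEFAULT_T_MAX) -> RetentionCurve:
    """Vector form of :func:`retention_curve` for a precomputed depth vector."""
    depth = np.asarray(depth)
    n = depth.size
    if n == 0:
        raise ValueError("empty depth vector")
    capped = np.minimum(depth, t_max).astype(np.int64)
    capped = np.maximum(capped, 0)
    counts = np.bincount(capped, minlength=t_max + 1)
    # survivors(t) = number of sites with depth >= t
    survivors = n - np.cumsum(counts)[: t_max]  # index t-1 -> depth >= t
    thresholds = np.arange(1, t_max + 1)
    return RetentionCurve(thresholds=thresholds, retained_fraction=survivors / n)


def coverage_auc(curve: RetentionCurve, require_t_max: int | None = DEFAULT_T_MAX) -> float:
    """Normalized area under the retention curve: mean retained fraction over
    thresholds 1..200 (discrete sum divided by 200)."""
    if require_t_max is not None and curve.t_max != require_t_max:
        raise ValueError(
            f"curve spans 1..{curve.t_max}, expected 1..{require_t_max}; "
            "pass require_t_max=None to override"
        )
    return float(np.mean(curve.retained_fraction))


def mean_depth(
    calls: MethylationCallSet, universe: pd.MultiIndex | Iterable[tuple[str, int]]
) -> float:
    """Arithmetic mean read depth over the universe (absent sites count 0)."""
    return float(np.mean(depth_over_universe(calls, universe)))
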