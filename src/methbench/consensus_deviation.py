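"""Consensus corridors and deviation statistics.

A consensus corridor is a closed beta-value interval taken as the plausible
true methylation at a locus, built from multiple independent measurements:

* data-driven corridors (per CpG): the smallest interval containing at least
  ``min_per_protocol`` measurements from *each* high-coverage protocol;
* gold-standard corridors (per reference locus): the narrowest interval
  containing measurements from at least ``min_technologies`` distinct
  technologies, widened by a flank of 0.05 beta units on each side.

The deviation of a measurement m from a corridor [l, u] is 0 inside the
closed interval and min(|m - l|, |m - u|) outside — the distance to the
nearest corridor border.  Corridor endpoints are restricted to observed
measurement values: any optimal interval can be shrunk onto observed values
without losing members, which makes an exact O(n^2) search (and a brute-force
test oracle) possible.  Ties on width are broken by the smallest lower
bound, so the construction is deterministic.

A locus where the corridor cannot be built (too few measurements or
technologies) is *corridor-undefined*: deviations there propagate as missing
and reduce aggregation denominators; they never silently count as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_calls import MethylationCallSet

DEFAULT_MIN_PER_PROTOCOL = 5
DEFAULT_MIN_TECHNOLOGIES = 3
DEFAULT_FLANK = 0.05


@dataclass(frozen=True)
class Corridor:
    """Closed interval [lower, upper] of consensus methylation."""

    lower: float
    upper: float
    source: str  # "data_driven" | "gold_standard"
    support: int  # measurements (data-driven) or technologies (gold-standard)

    def __post_init__(self) -> None:
        if not 0.0 <= self.lower <= self.upper <= 1.0:
            raise ValueError(f"invalid corridor [{self.lower}, {self.upper}]")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, m: float) -> bool:
        return self.lower <= m <= self.upper


def build_data_corridor(
    measurements_by_protocol: Mapping[str, Sequence[float]],
    min_per_protocol: int = DEFAULT_MIN_PER_PROTOCOL,
) -> Corridor | None:
    """Smallest interval holding >= ``min_per_protocol`` measurements from
    each protocol; ``None`` (corridor-undefined) when any protocol is short.

    Sliding-window search over the pooled sorted values: for each right edge
    the left edge is advanced as far as validity allows, so every minimal
    window is visited once.
    """
    if not measurements_by_protocol:
        raise ValueError("no protocols supplied")
    groups = {
        k: np.asarray([v for v in vals if not np.isnan(v)], dtype=float)
        for k, vals in measurements_by_protocol.items()
    }
    if any(len(v) < min_per_protocol for v in groups.values()):
        return None
    names = list(groups)
    values = np.concatenate([groups[k] for k in names])
    labels = np.concatenate(
        [np.full(len(groups[k]), i) for i, k in enumerate(names)]
    )
    order = np.argsort(values, kind="stable")
    values, labels = values[order], labels[order]
    n = len(values)
    n_groups = len(names)

    counts = np.zeros(n_groups, dtype=np.int64)
    short = n_groups  # groups currently below min_per_protocol
    best: tuple[float, float, float, int] | None = None  # width, lower, upper, size
    left = 0
    for right in range(n):
        g = labels[right]
        counts[g] += 1
        if counts[g] == min_per_protocol:
            short -= 1
        while short == 0:
            width = values[right] - values[left]
            cand = (width, values[left], values[right], right - left + 1)
            if best is None or (cand[0], cand[1]) < (best[0], best[1]):
                best = cand
            lg = labels[left]
            counts[lg] -= 1
            if counts[lg] == min_per_protocol - 1:
                short += 1
            left += 1
    assert best is not None  # short == 0 reached at least once: all groups full
    return Corridor(lower=best[1], upper=best[2], source="data_driven",
                    support=int(best[3]))


def build_gs_corridor(
    measurements_by_technology: Mapping[str, float | Sequence[float]],
    min_technologies: int = DEFAULT_MIN_TECHNOLOGIES,
    flank: float = DEFAULT_FLANK,
) -> Corridor | None:
    """Narrowest interval with measurements from >= ``min_technologies``
    distinct technologies, widened by ``flank`` beta units per side and
    clipped to [0, 1].  ``None`` when too few technologies report."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    pairs: list[tuple[float, int]] = []
    tech_ids: dict[str, int] = {}
    for tech, vals in measurements_by_technology.items():
        seq = [vals] if np.isscalar(vals) else list(vals)
        seq = [float(v) for v in seq if not np.isnan(v)]
        if not seq:
            continue
        tid = tech_ids.setdefault(tech, len(tech_ids))
        pairs.extend((v, tid) for v in seq)
    if len(tech_ids) < min_technologies:
        return None
    pairs.sort()
    values = np.array([p[0] for p in pairs])
    labels = np.array([p[1] for p in pairs])
    n = len(values)
    counts = np.zeros(len(tech_ids), dtype=np.int64)
    distinct = 0
    best: tuple[float, float, float] | None = None
    left = 0
    for right in range(n):
        if counts[labels[right]] == 0:
            distinct += 1
        counts[labels[right]] += 1
        while distinct >= min_technologies:
            cand = (values[right] - values[left], values[left], values[right])
            if best is None or cand[:2] < best[:2]:
                best = cand
            counts[labels[left]] -= 1
            if counts[labels[left]] == 0:
                distinct -= 1
            left += 1
    assert best is not None
    return Corridor(
        lower=max(0.0, best[1] - flank),
        upper=min(1.0, best[2] + flank),
        source="gold_standard",
        support=int(min_technologies),
    )


def deviation(m: float, corridor: Corridor | None) -> float:
    """Distance from a measurement to the nearest corridor border; 0 inside
    the closed corridor; NaN when the measurement or corridor is undefined."""
    if corridor is None or m is None or np.isnan(m):
        return float("nan")
    if corridor.lower <= m <= corridor.upper:
        return 0.0
    return float(min(abs(m - corridor.lower), abs(m - corridor.upper)))


def deviations(ms: np.ndarray, corridor: Corridor | None) -> np.ndarray:
    """Vectorized :func:`deviation` over one corridor."""
    ms = np.asarray(ms, dtype=float)
    if corridor is None:
        return np.full(ms.shape, np.nan)
    out = np.minimum(np.abs(ms - corridor.lower), np.abs(ms - corridor.upper))
    out[(ms >= corridor.lower) & (ms <= corridor.upper)] = 0.0
    out[np.isnan(ms)] = np.nan
    return out


def mean_absolute_deviation(
    records: pd.DataFrame | Sequence[float],
    n_samples: int | None = None,
    n_regions: int | None = None,
) -> float:
    """Mean deviation over a samples x regions grid.

    ``records`` is either a frame with a ``d`` column or a flat sequence of
    deviations.  Missing (NaN) entries — undefined corridors or measurements
    — are excluded with the denominator reduced accordingly.
    """
    if isinstance(records, pd.DataFrame):
        d = records["d"].to_numpy(dtype=float)
    else:
        d = np.asarray(list(records), dtype=float)
    if d.size == 0:
        raise ValueError("empty deviation grid")
    if n_samples is not None and n_regions is not None:
        expected = n_samples * n_regions
        if d.size > expected:
            raise ValueError(f"{d.size} records exceed the {expected}-cell grid")
    valid = d[~np.isnan(d)]
    if valid.size == 0:
        raise ValueError("no defined deviations in the grid")
    return float(valid.mean())


def inside_fraction(
    betas: Sequence[float] | np.ndarray | MethylationCallSet,
    corridors: Sequence[Corridor | None],
) -> float:
    """Fraction of measurements falling within their per-site corridor,
    among sites where both the beta and the corridor are defined."""
    if isinstance(betas, MethylationCallSet):
        betas = betas.df["beta"].to_numpy()
    betas = np.asarray(betas, dtype=float)
    if len(betas) != len(corridors):
        raise ValueError("betas and corridors differ in length")
    n_eval = 0
    n_inside = 0
    for m, c in zip(betas, corridors):
        if c is None or np.isnan(m):
            continue
        n_eval += 1
        if c.lower <= m <= c.upper:
            n_inside += 1
    if n_eval == 0:
        raise ValueError("no site has both a defined beta and a defined corridor")
    return n_inside / n_eval


def discrepancy_score(
    a: MethylationCallSet | pd.Series, b: MethylationCallSet | pd.Series
) -> float:
    """100 x mean absolute beta difference over sites defined in both runs."""
    sa = a.df.set_index(["chrom", "pos"])["beta"] if isinstance(a, MethylationCallSet) else a
    sb = b.df.set_index(["chrom", "pos"])["beta"] if isinstance(b, MethylationCallSet) else b
    joined = pd.concat([sa, sb], axis=1, join="inner", keys=["a", "b"]).dropna()
    if joined.empty:
        raise ValueError("no common defined CpGs between the two call sets")
    return float(100.0 * np.mean(np.abs(joined["a"] - joined["b"])))


def filter_gold_standard_regions(
    table: pd.DataFrame, min_measurements: int = 4
) -> pd.DataFrame:
    """Drop reference regions with too few data points to support a corridor
    (fewer than ``min_measurements``, i.e. <= 3 under the default)."""
    counts = table.groupby("region")["beta"].count()
    keep = counts.index[counts >= min_measurements]
    return table[table["region"].isin(keep)].reset_index(drop=True)


def corridors_to_table(
    corridors: Mapping[str, Corridor | None]
) -> pd.DataFrame:
    """Export corridors keyed by locus id as a flat table (undefined loci get
    NaN bounds)."""
    rows = []
    for key, c in corridors.items():
        rows.append(
            dict(
                locus=key,
                lower=np.nan if c is None else c.lower,
                upper=np.nan if c is None else c.upper,
                source="" if c is None else c.source,
                support=0 if c is None else c.support,
            )
        )
    return pd.DataFrame(rows, columns=["locus", "lower", "upper", "source", "support"])
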