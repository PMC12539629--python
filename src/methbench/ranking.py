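"""Decathlon-style rank aggregation of the benchmark metrics.

Every metric is ranked within each (protocol, metric) cell across workflows
(1 = best, ties averaged so the rank sum n(n+1)/2 is preserved).  A
workflow's summary score S_w is the mean of its ranks over all available
cells — workflow-protocol combinations absent from the design are excluded
with the denominator reduced, rather than imputed.  Exact ties in S_w are
broken by the mean per-cell z-score, computed with the population standard
deviation and sign-flipped so that lower is always better.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

Orientation = Literal["lower_better", "higher_better"]


class MetricTable:
    """(workflow x protocol) grid of named metric values.

    Stored long-format; every metric must declare whether lower or higher
    values are better before ranks can be computed.
    """

    def __init__(self, orientations: Mapping[str, Orientation] | None = None):
        self._rows: list[dict] = []
        self.orientations: dict[str, Orientation] = dict(orientations or {})

    def declare(self, metric: str, orientation: Orientation) -> None:
        if orientation not in ("lower_better", "higher_better"):
            raise ValueError(f"unknown orientation {orientation!r}")
        existing = self.orientations.get(metric)
        if existing is not None and existing != orientation:
            raise ValueError(f"conflicting orientation for metric {metric!r}")
        self.orientations[metric] = orientation

    def add(self, workflow: str, protocol: str, metric: str, value: float) -> None:
        if metric not in self.orientations:
            raise ValueError(f"metric {metric!r} has no declared orientation")
        self._rows.append(
            dict(workflow=workflow, protocol=protocol, metric=metric,
                 value=float(value))
        )

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self._rows, columns=["workflow", "protocol", "metric", "value"])
        if df.duplicated(["workflow", "protocol", "metric"]).any():
            raise ValueError("duplicate (workflow, protocol, metric) entries")
        return df

    def __len__(self) -> int:
        return len(self._rows)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame().to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, orientations: Mapping[str, Orientation]
    ) -> "MetricTable":
        t = cls(orientations)
        for row in df.itertuples(index=False):
            t.add(row.workflow, row.protocol, row.metric, row.value)
        return t

    @classmethod
    def from_tsv(
        cls, path: str | Path, orientations: Mapping[str, Orientation]
    ) -> "MetricTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"), orientations)


@dataclass
class RankResult:
    """Per-cell ranks plus the aggregated workflow ordering."""

    ranks: pd.DataFrame        # workflow, protocol, metric, rank
    s_w: pd.Series             # per-workflow mean rank over available cells
    z_mean: pd.Series          # per-workflow mean direction-normalized z-score
    order: list[str]           # workflows, best first

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame({"S_w": self.s_w, "z_mean": self.z_mean})
        df = df.loc[self.order]
        df.insert(0, "final_rank", np.arange(1, len(df) + 1))
        df.index.name = "workflow"
        return df

    def wide_ranks(self) -> pd.DataFrame:
        """Fig-style wide table: workflows x (protocol, metric) rank cells."""
        return self.ranks.pivot_table(
            index="workflow", columns=["protocol", "metric"], values="rank"
        ).loc[self.order]


def rank_metric(values: pd.Series, orientation: Orientation) -> pd.Series:
    """Rank one metric across workflows: best value gets rank 1, ties get the
    average of the covered ranks, missing values receive no rank."""
    if orientation not in ("lower_better", "higher_better"):
        raise ValueError(f"unknown orientation {orientation!r}")
    present = values.dropna()
    if len(present) < 2:
        raise ValueError("need at least 2 non-missing values to rank")
    ascending = orientation == "lower_better"
    return present.rank(ascending=ascending, method="average")


def _direction_normalized_z(values: pd.Series, orientation: Orientation) -> pd.Series:
    """Population-sd z-scores, sign-flipped so lower z means better."""
    present = values.dropna()
    sd = float(present.std(ddof=0))
    if sd == 0.0:
        return pd.Series(0.0, index=present.index)
    z = (present - present.mean()) / sd
    if orientation == "higher_better":
        z = -z
    return z


def aggregate_ranks(
    table: MetricTable,
    missing: Literal["exclude", "worst"] = "exclude",
) -> RankResult:
    """Aggregate a metric grid into the final workflow ordering.

    ``missing="exclude"`` (default) drops absent cells from each workflow's
    average; ``"worst"`` imputes the worst rank (n) of the cell instead.
    """
    df = table.frame()
    if df.empty:
        raise ValueError("empty metric table")
    workflows = sorted(df["workflow"].unique())
    n = len(workflows)
    rank_rows = []
    z_rows = []
    for (protocol, metric), cell in df.groupby(["protocol", "metric"]):
        orientation = table.orientations[metric]
        values = cell.set_index("workflow")["value"]
        ranks = rank_metric(values, orientation)
        zs = _direction_normalized_z(values, orientation)
        for w in workflows:
            if w in ranks.index:
                rank_rows.append(dict(workflow=w, protocol=protocol,
                                      metric=metric, rank=float(ranks[w])))
                z_rows.append(dict(workflow=w, value=float(zs[w])))
            elif missing == "worst":
                rank_rows.append(dict(workflow=w, protocol=protocol,
                                      metric=metric, rank=float(n)))
    ranks_df = pd.DataFrame(rank_rows, columns=["workflow", "protocol", "metric", "rank"])
    s_w = ranks_df.groupby("workflow")["rank"].mean()
    z_df = pd.DataFrame(z_rows, columns=["workflow", "value"])
    z_mean = z_df.groupby("workflow")["value"].mean().reindex(s_w.index).fillna(0.0)
    order = sorted(s_w.index, key=lambda w: (s_w[w], z_mean[w], w))
    return RankResult(ranks=ranks_df, s_w=s_w, z_mean=z_mean, order=order)
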