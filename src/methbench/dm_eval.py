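"""Differential-methylation scoring against a reference label set.

Each workflow's tumor-normal comparison is reduced to a per-site table of
delta beta (tumor minus normal) and a confidence score, and evaluated
against reference labels ({hyper, hypo, null}) in two ways:

* an event-weighted ROC AUC: hyper and hypo events are scored separately
  (each one-vs-null) and combined weighted by event counts;
* the Pearson correlation between the workflow's delta beta and the
  reference delta beta, averaged across sample pairs after Fisher
  z-transform.

The two metrics are merged by rank averaging into one composite DM score
per workflow (lower composite = better).  The differential model fits that
produce real reference labels (array-based moderated-t, sequencing-based
beta-binomial tests) are out of scope: this module consumes score/label
tables; for synthetic runs the score is |delta beta| * sqrt(pooled depth),
a simple signal-to-noise surrogate.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .io_calls import MethylationCallSet
from .synthetic_data import TrueMethylome

LABELS = ("hyper", "hypo", "null")


def roc_auc(labels: Sequence[bool] | np.ndarray, scores: Sequence[float]) -> float:
    """Probability that a random positive outranks a random negative, ties
    counted one half (rank-sum formulation)."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.all() or not labels.any():
        raise ValueError("ROC AUC needs both a positive and a negative class")
    return float(roc_auc_score(labels, scores))


def weighted_dm_auc(
    auc_hyper: float | None, n_hyper: int, auc_hypo: float | None, n_hypo: int
) -> float:
    """Event-count-weighted combination of the hyper and hypo AUCs."""
    if n_hyper < 0 or n_hypo < 0:
        raise ValueError("event counts must be non-negative")
    if n_hyper + n_hypo == 0:
        raise ValueError("no differential events to weight")
    if (n_hyper == 0 or auc_hyper is None) and (n_hypo == 0 or auc_hypo is None):
        raise ValueError("neither event class has a defined AUC")
    if n_hyper == 0 or auc_hyper is None:
        return float(auc_hypo)
    if n_hypo == 0 or auc_hypo is None:
        return float(auc_hyper)
    return float((n_hyper * auc_hyper + n_hypo * auc_hypo) / (n_hyper + n_hypo))


def delta_correlation(
    seq_delta: Sequence[float] | pd.Series, ref_delta: Sequence[float] | pd.Series
) -> float:
    """Pearson correlation of sequencing vs reference delta beta over their
    common defined support."""
    a = pd.Series(seq_delta)
    b = pd.Series(ref_delta)
    joined = pd.concat([a, b], axis=1, join="inner", keys=["seq", "ref"]).dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 common defined sites")
    x = joined["seq"].to_numpy()
    y = joined["ref"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in delta values")
    return float(stats.pearsonr(x, y).statistic)


def fisher_mean_correlation(rs: Sequence[float]) -> float:
    """Average correlations across sample pairs on the Fisher z scale."""
    rs = np.asarray(list(rs), dtype=float)
    if rs.size == 0:
        raise ValueError("no correlations to average")
    z = np.arctanh(np.clip(rs, -0.999999, 0.999999))
    return float(np.tanh(z.mean()))


def dm_composite(metrics: pd.DataFrame) -> pd.Series:
    """Average the per-metric ranks of (weighted_auc, correlation).

    ``metrics`` is indexed by workflow with columns ``weighted_auc`` and
    ``correlation``; both are higher-is-better.  Ties receive the average of
    the covered ranks.  Returns the composite rank (1 = best).
    """
    if len(metrics) < 2:
        raise ValueError("need at least 2 workflows to rank")
    r_auc = metrics["weighted_auc"].rank(ascending=False, method="average")
    r_cor = metrics["correlation"].rank(ascending=False, method="average")
    return ((r_auc + r_cor) / 2.0).rename("dm_composite")


# ---------------------------------------------------------------------------
# Building differential tables


def make_differential_table(
    tumor: MethylationCallSet, normal: MethylationCallSet
) -> pd.DataFrame:
    """Per-site delta beta and confidence score for one tumor-normal pair.

    score = |delta beta| * sqrt(depth_tumor + depth_normal): effect size
    scaled by the precision the pooled coverage affords.
    """
    t = tumor.df.set_index(["chrom", "pos"])[["beta", "depth"]]
    n = normal.df.set_index(["chrom", "pos"])[["beta", "depth"]]
    j = t.join(n, how="inner", lsuffix="_t", rsuffix="_n").dropna(
        subset=["beta_t", "beta_n"]
    )
    delta = j["beta_t"] - j["beta_n"]
    pooled = j["depth_t"].fillna(0) + j["depth_n"].fillna(0)
    out = pd.DataFrame(
        dict(delta_beta=delta, score=np.abs(delta) * np.sqrt(pooled))
    )
    return out.reset_index()


def reference_labels_from_truth(truth: TrueMethylome) -> pd.DataFrame:
    """Reference label table (chrom, pos, delta_beta, label) from a synthetic
    ground truth."""
    df = truth.df
    return pd.DataFrame(
        dict(
            chrom=df["chrom"],
            pos=df["pos"],
            delta_beta=df["beta_tumor"] - df["beta_normal"],
            label=df["dml_label"],
        )
    )


def evaluate_dm(
    table: pd.DataFrame, reference: pd.DataFrame
) -> dict[str, float]:
    """Score one differential table against the reference labels.

    Hyper and hypo AUCs are one-vs-null (events of the class as positives,
    null sites as negatives), combined by event count; the correlation is
    taken between the table's and the reference's delta beta.
    """
    merged = table.merge(reference, on=["chrom", "pos"], suffixes=("", "_ref"))
    if merged.empty:
        raise ValueError("no common sites between table and reference")
    out: dict[str, float] = {}
    aucs: dict[str, float | None] = {}
    counts: dict[str, int] = {}
    for event in ("hyper", "hypo"):
        sub = merged[merged["label"].isin([event, "null"])]
        pos = sub["label"] == event
        counts[event] = int(pos.sum())
        if counts[event] == 0 or pos.all():
            aucs[event] = None
            continue
        aucs[event] = roc_auc(pos.to_numpy(), sub["score"].to_numpy())
    out["auc_hyper"] = np.nan if aucs["hyper"] is None else aucs["hyper"]
    out["auc_hypo"] = np.nan if aucs["hypo"] is None else aucs["hypo"]
    out["n_hyper"] = counts["hyper"]
    out["n_hypo"] = counts["hypo"]
    out["weighted_auc"] = weighted_dm_auc(
        aucs["hyper"], counts["hyper"], aucs["hypo"], counts["hypo"]
    )
    out["correlation"] = delta_correlation(
        merged.set_index(["chrom", "pos"])["delta_beta"],
        merged.set_index(["chrom", "pos"])["delta_beta_ref"],
    )
    return out
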