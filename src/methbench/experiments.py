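"""Replicated recovery experiments on synthetic data.

These are the package's calibration studies: they check that the benchmark
metrics actually detect the distortions the generator injects.

* Bias recovery — a workflow with an additive beta bias must show a larger
  mean gold-standard corridor deviation than an unbiased workflow simulated
  under the same seed family.
* Noise-ordering recovery — workflows differing only in call noise must come
  out of the final rank aggregation in noise order.

Both return the fraction of replicates in which the expected relation holds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import consensus_deviation as cons
from . import coverage_metrics as cov
from . import dm_eval
from .ranking import MetricTable, aggregate_ranks
from .synthetic_data import (
    GoldStandardLocus,
    ProtocolProfile,
    TrueMethylome,
    WorkflowProfile,
    _substream,
    generate_gold_standard,
    generate_truth,
    simulate_calls,
)


def _locus_beta(calls, loci: list[GoldStandardLocus], truth: TrueMethylome) -> np.ndarray:
    """Depth-weighted mean beta of a call set over each locus span."""
    df = calls.df.dropna(subset=["beta"])
    pos = df["pos"].to_numpy()
    beta = df["beta"].to_numpy()
    depth = df["depth"].to_numpy()
    out = np.full(len(loci), np.nan)
    for i, loc in enumerate(loci):
        lo = np.searchsorted(pos, loc.start, side="left")
        hi = np.searchsorted(pos, loc.end, side="right")
        if hi > lo and depth[lo:hi].sum() > 0:
            out[i] = np.average(beta[lo:hi], weights=depth[lo:hi])
    return out


def gold_standard_deviation(
    calls, loci: list[GoldStandardLocus], truth: TrueMethylome, flank: float = 0.05
) -> float:
    """Mean deviation of a run's locus-level betas from the per-locus
    gold-standard corridors."""
    betas = _locus_beta(calls, loci, truth)
    ds = []
    for b, loc in zip(betas, loci):
        corridor = cons.build_gs_corridor(loc.measurements, flank=flank)
        ds.append(cons.deviation(b, corridor))
    return cons.mean_absolute_deviation(ds)


def bias_recovery_experiment(
    n_replicates: int = 100,
    seed: int = 0,
    bias: float = 0.1,
    n_loci: int = 46,
    mean_depth: float = 30.0,
    n_sites: int = 1200,
) -> float:
    """Fraction of replicates in which the biased workflow shows a strictly
    larger mean gold-standard deviation than the unbiased one."""
    protocol = ProtocolProfile("sim", mean_depth=mean_depth, depth_dispersion=5.0)
    unbiased = WorkflowProfile("unbiased")
    biased = WorkflowProfile("biased", bias=bias)
    wins = 0
    for rep in range(n_replicates):
        rep_seed = int(_substream(seed, f"bias-rep-{rep}").integers(2**31))
        truth = generate_truth(n_sites, 0, 0.3, seed=rep_seed)
        loci = generate_gold_standard(truth, n_loci, 5, 0.04, seed=rep_seed)
        d = {}
        for wf in (unbiased, biased):
            calls = simulate_calls(truth, "normal", protocol, wf, seed=rep_seed)
            d[wf.name] = gold_standard_deviation(calls, loci, truth)
        wins += d["biased"] > d["unbiased"]
    return wins / n_replicates


def noise_ordering_experiment(
    n_replicates: int = 50,
    seed: int = 0,
    noise_levels: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3),
    n_sites: int = 20_000,
    n_loci: int = 46,
    mean_depth: float = 30.0,
    n_dml: int = 2000,
    effect: float = 0.3,
) -> float:
    """Fraction of replicates in which the aggregated final ranking recovers
    the injected noise ordering exactly.

    Workflows differ only in noise_sd; per replicate the metric grid holds
    coverage AUC, gold-standard deviation and the two DM metrics, and the
    ranking module aggregates it.
    """
    protocol = ProtocolProfile("sim", mean_depth=mean_depth, depth_dispersion=5.0)
    workflows = [
        WorkflowProfile(f"wf-noise-{i}", noise_sd=s) for i, s in enumerate(noise_levels)
    ]
    expected = [w.name for w in workflows]
    universe_frac_threshold = 200
    hits = 0
    for rep in range(n_replicates):
        rep_seed = int(_substream(seed, f"noise-rep-{rep}").integers(2**31))
        truth = generate_truth(n_sites, n_dml, effect, seed=rep_seed)
        loci = generate_gold_standard(truth, n_loci, 5, 0.04, seed=rep_seed)
        reference = dm_eval.reference_labels_from_truth(truth)
        universe = pd.MultiIndex.from_frame(truth.df[["chrom", "pos"]])
        table = MetricTable(
            {
                "coverage": "higher_better",
                "gs_deviation": "lower_better",
                "dm_auc": "higher_better",
                "dm_corr": "higher_better",
            }
        )
        for wf in workflows:
            normal = simulate_calls(truth, "normal", protocol, wf, seed=rep_seed)
            tumor = simulate_calls(truth, "tumor", protocol, wf, seed=rep_seed)
            curve = cov.retention_curve(normal, universe, t_max=universe_frac_threshold)
            table.add(wf.name, "sim", "coverage",
                      cov.coverage_auc(curve, require_t_max=universe_frac_threshold))
            table.add(wf.name, "sim", "gs_deviation",
                      gold_standard_deviation(normal, loci, truth))
            scores = dm_eval.evaluate_dm(
                dm_eval.make_differential_table(tumor, normal), reference
            )
            table.add(wf.name, "sim", "dm_auc", scores["weighted_auc"])
            table.add(wf.name, "sim", "dm_corr", scores["correlation"])
        order = aggregate_ranks(table).order
        hits += order == expected
    return hits / n_replicates
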