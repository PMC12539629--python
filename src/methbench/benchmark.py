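"""End-to-end benchmark orchestration: manifest -> metrics -> ranking -> report.

``run_benchmark`` consumes a run manifest (real or simulated call files) and
produces the full metric grid and the aggregated workflow ranking:

* ``coverage``      — normalized depth-vs-coverage AUC, higher is better;
* ``wg_deviation``  — mean deviation from per-CpG data-driven consensus
                      corridors built from the high-coverage protocols,
                      lower is better (plus the inside-corridor fraction as
                      a reported side statistic);
* ``gs_deviation``  — mean absolute deviation from gold-standard locus
                      corridors over the samples x regions grid, lower is
                      better;
* ``dm_calling``    — composite rank of event-weighted DM AUC and delta-beta
                      correlation against a reference label table, lower is
                      better.

Externally measured metrics (e.g. runtime, peak memory) can be merged into
the grid through the same long-format table before ranking.

``run_synthetic_scenario`` generates a full simulated study from a scenario
YAML, writes the call files through the ordinary writers, and then runs the
benchmark on them exactly as it would on real data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import consensus_deviation as cons
from . import coverage_metrics as cov
from . import dm_eval
from .io_calls import (
    MethylationCallSet,
    MethylationMatrix,
    RunMeta,
    assemble_matrix,
    filter_by_depth,
    read_call_file,
    read_manifest,
    write_call_file,
    write_manifest,
    collapse_strands,
)
from .ranking import MetricTable, RankResult, aggregate_ranks
from .synthetic_data import (
    Scenario,
    generate_gold_standard,
    generate_truth,
    load_scenario,
    locus_table,
    simulate_calls,
)

logger = logging.getLogger(__name__)

KNOWN_METRICS = ("coverage", "wg_deviation", "gs_deviation", "dm_calling")

ORIENTATIONS = {
    "coverage": "higher_better",
    "wg_deviation": "lower_better",
    "gs_deviation": "lower_better",
    "dm_calling": "lower_better",
    "inside_fraction": "higher_better",
    "run_time": "lower_better",
    "max_mem": "lower_better",
}


@dataclass
class BenchmarkConfig:
    """Everything one benchmark invocation depends on."""

    manifest_path: Path
    out_dir: Path
    seed: int = 0
    min_depth: int = 10
    t_max: int = 200
    min_per_protocol: int = 5
    flank: float = 0.05
    high_coverage_protocols: tuple[str, ...] = ("WGBS", "Swift", "EM-seq")
    gold_standard_measurements: Path | None = None  # long (region, technology, beta)
    gold_standard_loci: Path | None = None  # (region, chrom, start, end)
    reference_dm: Path | None = None  # (chrom, pos, delta_beta, label)
    metrics: tuple[str, ...] = KNOWN_METRICS
    external_metrics: Path | None = None  # long metric table merged before ranking
    collapse_mode: str = "merge"

    def validate(self) -> None:
        unknown = [m for m in self.metrics if m not in KNOWN_METRICS]
        if unknown:
            raise ValueError(f"unknown metric(s) {unknown}; known: {KNOWN_METRICS}")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not Path(self.manifest_path).exists():
            raise FileNotFoundError(self.manifest_path)


@dataclass
class BenchmarkResult:
    metric_table: MetricTable
    rank_result: RankResult
    side_stats: pd.DataFrame  # extra reported quantities (inside fraction, ...)
    out_dir: Path


def _load_call_sets(config: BenchmarkConfig) -> list[MethylationCallSet]:
    manifest = read_manifest(config.manifest_path)
    base = Path(config.manifest_path).parent
    call_sets = []
    for row in manifest.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        meta = RunMeta(row.workflow, row.protocol, row.sample,
                       None if pd.isna(row.condition) else row.condition)
        try:
            cs = read_call_file(p, row.dialect, meta=meta)
        except (OSError, ValueError) as exc:
            logger.warning("excluding run %s: %s", meta.run_id, exc)
            continue
        call_sets.append(collapse_strands(cs, mode=config.collapse_mode))
    if len({cs.meta.workflow for cs in call_sets}) < 2:
        raise ValueError("benchmark needs at least 2 workflows with readable runs")
    return call_sets


def _coverage_metrics(matrix: MethylationMatrix, table: MetricTable, t_max: int) -> None:
    per_run = {}
    for rid in matrix.manifest.index:
        depth = matrix.depth[rid].to_numpy()
        curve = cov.retention_curve_from_depth(depth, t_max=t_max)
        per_run[rid] = cov.coverage_auc(curve, require_t_max=t_max)
    m = matrix.manifest.assign(auc=pd.Series(per_run))
    for (w, p), grp in m.groupby(["workflow", "protocol"]):
        table.add(w, p, "coverage", grp["auc"].mean())


def _site_corridors_for_sample(
    beta: pd.DataFrame,
    manifest: pd.DataFrame,
    sample: str,
    protocols: Sequence[str],
    min_per_protocol: int,
) -> list[cons.Corridor | None]:
    """Per-CpG data-driven corridor for one sample from the high-coverage
    protocols' workflow measurements."""
    group_cols = {}
    for p in protocols:
        ids = manifest.index[(manifest["protocol"] == p) & (manifest["sample"] == sample)]
        group_cols[p] = beta[list(ids)].to_numpy()
    n_sites = beta.shape[0]
    corridors: list[cons.Corridor | None] = []
    for i in range(n_sites):
        per_protocol = {}
        ok = True
        for p, arr in group_cols.items():
            vals = arr[i]
            vals = vals[~np.isnan(vals)]
            if len(vals) < min_per_protocol:
                ok = False
                break
            per_protocol[p] = vals
        corridors.append(
            cons.build_data_corridor(per_protocol, min_per_protocol) if ok else None
        )
    return corridors


def _wg_deviation_metrics(
    matrix: MethylationMatrix, table: MetricTable, config: BenchmarkConfig
) -> pd.DataFrame:
    """Genome-wide consensus deviation and inside fraction per run."""
    manifest = matrix.manifest
    samples = sorted(manifest["sample"].unique())
    protocols = [p for p in config.high_coverage_protocols
                 if p in set(manifest["protocol"])]
    if not protocols:
        raise ValueError("no high-coverage protocol present in the manifest")
    rows = []
    for sample in samples:
        corridors = _site_corridors_for_sample(
            matrix.beta, manifest, sample, protocols, config.min_per_protocol
        )
        lower = np.array([np.nan if c is None else c.lower for c in corridors])
        upper = np.array([np.nan if c is None else c.upper for c in corridors])
        for rid in manifest.index[manifest["sample"] == sample]:
            m = matrix.beta[rid].to_numpy()
            with np.errstate(invalid="ignore"):
                d = np.minimum(np.abs(m - lower), np.abs(m - upper))
                d[(m >= lower) & (m <= upper)] = 0.0
            valid = ~np.isnan(d)
            if valid.sum() == 0:
                continue
            rows.append(
                dict(
                    run=rid,
                    workflow=manifest.loc[rid, "workflow"],
                    protocol=manifest.loc[rid, "protocol"],
                    sample=sample,
                    wg_deviation=float(d[valid].mean()),
                    inside_fraction=float((d[valid] == 0).mean()),
                    n_sites=int(valid.sum()),
                )
            )
    per_run = pd.DataFrame(rows)
    if per_run.empty:
        raise ValueError("no CpG had a defined data-driven corridor")
    for (w, p), grp in per_run.groupby(["workflow", "protocol"]):
        table.add(w, p, "wg_deviation", grp["wg_deviation"].mean())
    return per_run


def _locus_measurements(
    call_sets: Sequence[MethylationCallSet], loci: pd.DataFrame
) -> pd.DataFrame:
    """Depth-weighted mean beta per (run, region)."""
    rows = []
    for cs in call_sets:
        df = cs.df.dropna(subset=["beta"])
        by_chrom = {
            c: (g["pos"].to_numpy(), g["beta"].to_numpy(), g["depth"].to_numpy())
            for c, g in df.groupby("chrom", sort=False)
        }
        for loc in loci.itertuples(index=False):
            if loc.chrom not in by_chrom:
                continue
            pos, beta_arr, depth_arr = by_chrom[loc.chrom]
            lo = np.searchsorted(pos, loc.start, side="left")
            hi = np.searchsorted(pos, loc.end, side="right")
            if hi <= lo:
                continue
            b = beta_arr[lo:hi]
            w = depth_arr[lo:hi]
            beta = float(np.average(b, weights=w)) if np.nansum(w) > 0 else float(b.mean())
            rows.append(
                dict(workflow=cs.meta.workflow, protocol=cs.meta.protocol,
                     sample=cs.meta.sample, region=loc.region, beta=beta)
            )
    return pd.DataFrame(rows, columns=["workflow", "protocol", "sample", "region", "beta"])


def _gs_deviation_metrics(
    call_sets: Sequence[MethylationCallSet],
    table: MetricTable,
    config: BenchmarkConfig,
) -> pd.DataFrame:
    measurements = pd.read_csv(config.gold_standard_measurements, sep="\t")
    measurements = cons.filter_gold_standard_regions(measurements)
    loci = pd.read_csv(config.gold_standard_loci, sep="\t")
    loci = loci[loci["region"].isin(measurements["region"].unique())]
    corridors = {
        region: cons.build_gs_corridor(
            grp.groupby("technology")["beta"].apply(list).to_dict(),
            flank=config.flank,
        )
        for region, grp in measurements.groupby("region")
    }
    per_locus = _locus_measurements(call_sets, loci)
    per_locus["d"] = [
        cons.deviation(row.beta, corridors.get(row.region))
        for row in per_locus.itertuples(index=False)
    ]
    for (w, p), grp in per_locus.groupby(["workflow", "protocol"]):
        n_samples = grp["sample"].nunique()
        n_regions = grp["region"].nunique()
        table.add(w, p, "gs_deviation",
                  cons.mean_absolute_deviation(grp, n_samples, n_regions))
    return per_locus


def _infer_pairs(manifest: pd.DataFrame) -> list[tuple[str, str]]:
    """Pair tumor and normal samples sharing a patient prefix."""
    tumors = manifest.loc[manifest["condition"] == "tumor", "sample"].unique()
    normals = set(manifest.loc[manifest["condition"] == "normal", "sample"].unique())
    pairs = []
    for t in sorted(tumors):
        stem = t.rstrip("T").rstrip("_-")
        match = [n for n in normals if n.rstrip("N").rstrip("_-") == stem]
        if match:
            pairs.append((t, sorted(match)[0]))
    return pairs


def _dm_metrics(
    call_sets: Sequence[MethylationCallSet],
    table: MetricTable,
    config: BenchmarkConfig,
) -> pd.DataFrame:
    # keep_default_na: the label token "null" must survive the round trip
    reference = pd.read_csv(config.reference_dm, sep="\t",
                            keep_default_na=False, na_values=[""])
    by_run = {cs.meta.run_id: cs for cs in call_sets}
    manifest = pd.DataFrame(
        [dict(run=cs.meta.run_id, workflow=cs.meta.workflow,
              protocol=cs.meta.protocol, sample=cs.meta.sample,
              condition=cs.meta.condition) for cs in call_sets]
    )
    pairs = _infer_pairs(manifest)
    if not pairs:
        raise ValueError("no tumor-normal sample pairs found for DM evaluation")
    rows = []
    for (w, p), grp in manifest.groupby(["workflow", "protocol"]):
        by_sample = {r.sample: r.run for r in grp.itertuples(index=False)}
        aucs, cors = [], []
        for t_sample, n_sample in pairs:
            if t_sample not in by_sample or n_sample not in by_sample:
                continue
            dt = dm_eval.make_differential_table(
                by_run[by_sample[t_sample]], by_run[by_sample[n_sample]]
            )
            try:
                scores = dm_eval.evaluate_dm(dt, reference)
            except ValueError as exc:
                logger.warning("DM evaluation skipped for %s/%s pair %s: %s",
                               w, p, t_sample, exc)
                continue
            aucs.append(scores["weighted_auc"])
            cors.append(scores["correlation"])
        if aucs:
            rows.append(dict(workflow=w, protocol=p,
                             weighted_auc=float(np.mean(aucs)),
                             correlation=dm_eval.fisher_mean_correlation(cors)))
    per_wf = pd.DataFrame(rows, columns=["workflow", "protocol", "weighted_auc", "correlation"])
    for p, grp in per_wf.groupby("protocol"):
        if len(grp) < 2:
            continue
        composite = dm_eval.dm_composite(grp.set_index("workflow"))
        for w, v in composite.items():
            table.add(w, p, "dm_calling", v)
    return per_wf


def run_benchmark(config: BenchmarkConfig) -> BenchmarkResult:
    """Execute every enabled metric and the final ranking; write the results
    bundle (metrics, ranks, summary, report) under ``config.out_dir``."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    call_sets = _load_call_sets(config)
    matrix = assemble_matrix(call_sets, "union")
    filtered = filter_by_depth(matrix, config.min_depth)

    table = MetricTable(ORIENTATIONS)
    side_frames = {}
    if "coverage" in config.metrics:
        _coverage_metrics(matrix, table, config.t_max)
    if "wg_deviation" in config.metrics:
        side_frames["wg_per_run"] = _wg_deviation_metrics(filtered, table, config)
    if "gs_deviation" in config.metrics:
        if config.gold_standard_measurements is None or config.gold_standard_loci is None:
            raise ValueError("gs_deviation metric needs gold-standard tables")
        side_frames["gs_per_locus"] = _gs_deviation_metrics(call_sets, table, config)
    if "dm_calling" in config.metrics:
        if config.reference_dm is None:
            raise ValueError("dm_calling metric needs a reference label table")
        side_frames["dm_per_workflow"] = _dm_metrics(call_sets, table, config)
    if config.external_metrics is not None:
        ext = pd.read_csv(config.external_metrics, sep="\t")
        for row in ext.itertuples(index=False):
            if row.metric not in table.orientations:
                raise ValueError(f"external metric {row.metric!r} has no orientation")
            table.add(row.workflow, row.protocol, row.metric, row.value)

    rank_result = aggregate_ranks(table)

    table.to_tsv(out_dir / "metrics.tsv")
    rank_result.ranks.to_csv(out_dir / "ranks_long.tsv", sep="\t", index=False)
    rank_result.summary().to_csv(out_dir / "ranking_summary.tsv", sep="\t")
    side = pd.concat(
        [df.assign(block=name) for name, df in side_frames.items()],
        ignore_index=True,
    ) if side_frames else pd.DataFrame()
    if not side.empty:
        side.to_csv(out_dir / "side_stats.tsv", sep="\t", index=False)
    _write_report(out_dir / "report.txt", table, rank_result, config)
    return BenchmarkResult(metric_table=table, rank_result=rank_result,
                           side_stats=side, out_dir=out_dir)


def _write_report(path: Path, table: MetricTable, ranks: RankResult,
                  config: BenchmarkConfig) -> None:
    lines = ["Methylation workflow benchmark report", "=" * 38, ""]
    lines.append(f"manifest: {config.manifest_path}")
    lines.append(f"min_depth: {config.min_depth}  t_max: {config.t_max}  "
                 f"min_per_protocol: {config.min_per_protocol}  flank: {config.flank}")
    lines.append(f"high-coverage protocols: {', '.join(config.high_coverage_protocols)}")
    lines.append(f"seed: {config.seed}")
    lines.append("")
    lines.append("Final ranking (1 = best; S_w = mean rank over available cells;")
    lines.append("ties broken by mean direction-normalized z-score):")
    lines.append("")
    lines.append(ranks.summary().to_string())
    lines.append("")
    lines.append("Per-cell ranks (workflow x protocol/metric):")
    lines.append("")
    lines.append(ranks.wide_ranks().round(1).to_string())
    lines.append("")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Synthetic-scenario runner


def generate_scenario_dataset(scenario: Scenario, data_dir: str | Path) -> Path:
    """Simulate every planned run of a scenario and write the call files,
    manifest, gold-standard tables, reference labels and truth sidecar.
    Returns the manifest path."""
    data_dir = Path(data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)
    truth = generate_truth(scenario.n_sites, scenario.n_dml, scenario.effect,
                           scenario.seed)
    cond_of = {s["id"]: s["condition"] for s in scenario.samples}
    wf = {w.name: w for w in scenario.workflows}
    prot = {p.name: p for p in scenario.protocols}
    manifest_rows = []
    for w_name, p_name, s_id in scenario.planned_runs:
        cs = simulate_calls(truth, cond_of[s_id], prot[p_name], wf[w_name],
                            seed=scenario.seed, sample=s_id)
        fname = f"{w_name}__{p_name}__{s_id}.cov"
        write_call_file(cs, data_dir / fname, "bismark_cov")
        manifest_rows.append(
            dict(path=fname, dialect="bismark_cov", workflow=w_name,
                 protocol=p_name, sample=s_id, condition=cond_of[s_id])
        )
    manifest = pd.DataFrame(manifest_rows)
    manifest_path = write_manifest(manifest, data_dir / "manifest.tsv")

    gs = scenario.gold_standard
    if gs:
        loci = generate_gold_standard(
            truth,
            n_loci=int(gs.get("n_loci", 46)),
            n_technologies=int(gs.get("n_technologies", 5)),
            tech_noise_sd=float(gs.get("tech_noise_sd", 0.04)),
            seed=scenario.seed,
            sites_per_locus=int(gs.get("sites_per_locus", 5)),
        )
        locus_table(loci).to_csv(data_dir / "gold_standard_measurements.tsv",
                                 sep="\t", index=False)
        pd.DataFrame(
            [dict(region=l.region_id, chrom=l.chrom, start=l.start, end=l.end)
             for l in loci]
        ).to_csv(data_dir / "gold_standard_loci.tsv", sep="\t", index=False)
    dm_eval.reference_labels_from_truth(truth).to_csv(
        data_dir / "reference_dm.tsv", sep="\t", index=False
    )
    truth.df.to_csv(data_dir / "truth.tsv", sep="\t", index=False)
    return manifest_path


def run_synthetic_scenario(
    scenario_path: str | Path,
    out_dir: str | Path,
    seed: int | None = None,
    n_sites: int | None = None,
    metrics: tuple[str, ...] = KNOWN_METRICS,
    min_per_protocol: int | None = None,
) -> BenchmarkResult:
    """Generate a scenario's dataset, then benchmark it end to end."""
    scenario = load_scenario(scenario_path, seed=seed, n_sites=n_sites)
    out_dir = Path(out_dir)
    data_dir = out_dir / "data"
    manifest_path = generate_scenario_dataset(scenario, data_dir)
    config = BenchmarkConfig(
        manifest_path=manifest_path,
        out_dir=out_dir / "results",
        seed=scenario.seed,
        gold_standard_measurements=data_dir / "gold_standard_measurements.tsv",
        gold_standard_loci=data_dir / "gold_standard_loci.tsv",
        reference_dm=data_dir / "reference_dm.tsv",
        metrics=metrics,
    )
    if min_per_protocol is not None:
        config.min_per_protocol = min_per_protocol
    return run_benchmark(config)
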