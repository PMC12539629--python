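"""Synthetic multi-workflow methylomes with known ground truth.

The generator emulates, at the level of per-CpG calls, the statistical
structure a methylation-calling benchmark has to cope with:

* a bimodal true beta distribution (a sharp unmethylated mode near 0 and a
  broad methylated mode around 0.8), with tumor/normal differences injected
  at declared differentially methylated loci (DMLs);
* protocol-specific coverage: negative-binomial read depth whose mean is
  modulated by a per-site GC-context score (PBAT-like protocols are shallow
  and skewed toward GC-rich sites) plus a bisulfite/enzymatic conversion
  error rate;
* workflow-specific artefacts expressed as call-level effects: loss of sites
  (retention < 1), additive beta bias (an under- or over-estimating caller),
  extra call noise, double counting of CpG calls from overlapping read mates
  (depth inflation x2 on a fraction of sites) and missing duplicate removal
  (depth inflation by a constant factor).

Read-level phenomena (chimeric reads, M-bias, alignment) are deliberately
not simulated; only their downstream consequences on calls are modelled,
because the benchmark evaluates call files, not reads.

One root seed deterministically spawns an independent substream per
(workflow, protocol, sample, condition), so adding a run never perturbs
existing runs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io_calls import CALL_COLUMNS, MethylationCallSet, RunMeta

__all__ = [
    "ProtocolProfile",
    "WorkflowProfile",
    "TrueMethylome",
    "GoldStandardLocus",
    "generate_truth",
    "simulate_calls",
    "generate_gold_standard",
    "blueprint_like_locus_table",
    "Scenario",
    "load_scenario",
    "bundled_scenario_path",
]


@dataclass(frozen=True)
class ProtocolProfile:
    """Coverage characteristics of a sequencing protocol.

    mean_depth      expected reads per CpG (e.g. ~43 for a deep WGBS run,
                    <13 for low-input protocols)
    depth_dispersion  negative-binomial size parameter; small values give the
                    overdispersed, skewed depth histograms of low-input data
    gc_skew         log-scale coverage modulation per unit GC score
                    (0 = uniform; positive = preference for GC-rich sites)
    conversion_error  probability that a methylated call is lost to
                    incomplete conversion (scales beta down)
    """

    name: str
    mean_depth: float
    depth_dispersion: float = 5.0
    gc_skew: float = 0.0
    conversion_error: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be positive")
        if not 0.0 <= self.conversion_error <= 1.0:
            raise ValueError("conversion_error must be in [0, 1]")


@dataclass(frozen=True)
class WorkflowProfile:
    """Call-level distortions characteristic of one processing workflow."""

    name: str
    retention: float = 1.0          # probability a covered site survives processing
    bias: float = 0.0               # additive shift of the called beta, in [-1, 1]
    noise_sd: float = 0.0           # sd of extra per-site gaussian call noise
    double_count: bool = False      # double CpG counts from overlapping mates
    double_count_fraction: float = 0.5  # fraction of sites affected when double_count
    dedup: bool = True              # when False, depth inflated by duplicate_factor
    duplicate_factor: float = 1.2

    def __post_init__(self) -> None:
        if not 0.0 < self.retention <= 1.0:
            raise ValueError("retention must be in (0, 1]")
        if not -1.0 <= self.bias <= 1.0:
            raise ValueError("bias must be in [-1, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.double_count_fraction <= 1.0:
            raise ValueError("double_count_fraction must be in [0, 1]")
        if self.duplicate_factor < 1.0:
            raise ValueError("duplicate_factor must be >= 1")


@dataclass
class TrueMethylome:
    """Ground-truth methylome shared by all simulated runs.

    ``df`` columns: chrom, pos, gc (GC-context score in [0,1]), beta_normal,
    beta_tumor, dml_label in {hyper, hypo, null}.
    """

    df: pd.DataFrame
    effect: float

    def beta(self, condition: str) -> np.ndarray:
        if condition not in ("tumor", "normal"):
            raise ValueError(f"unknown condition {condition!r}")
        return self.df[f"beta_{condition}"].to_numpy()

    @property
    def n_sites(self) -> int:
        return len(self.df)


@dataclass
class GoldStandardLocus:
    """One reference locus measured by several independent technologies."""

    region_id: str
    chrom: str
    start: int  # 0-based position of first CpG in the span
    end: int    # position of last CpG (inclusive)
    site_index: np.ndarray  # row indices into the truth frame
    measurements: dict[str, float]  # technology -> beta
    true_beta: float


def _substream(seed: int, *keys: str) -> np.random.Generator:
    """Independent, reproducible RNG stream keyed by strings under one root
    seed.  Keyed via CRC32 so streams do not depend on generation order."""
    key = zlib.crc32("|".join(keys).encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def generate_truth(
    n_sites: int,
    n_dml: int,
    effect: float,
    seed: int,
    chrom: str = "chr1",
    unmethylated_weight: float = 0.25,
) -> TrueMethylome:
    """Draw a ground-truth methylome with a bimodal beta mixture.

    beta_normal is a two-component Beta mixture: an unmethylated component
    Beta(1.5, 15) (sharp near 0) with weight ``unmethylated_weight`` and a
    methylated component Beta(8, 2) (broad mode near 0.8).  Tumor equals
    normal except at ``n_dml`` DML sites, split evenly between hyper- and
    hypomethylation with the exact additive ``effect`` applied (eligible
    sites only, so the shifted value stays in [0, 1]).
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    if n_dml > n_sites:
        raise ValueError("n_dml cannot exceed n_sites")
    if not 0.0 < effect <= 1.0:
        raise ValueError("effect must be in (0, 1]")
    rng = _substream(seed, "truth")
    gaps = rng.integers(2, 150, size=n_sites)
    pos = np.cumsum(gaps) + 100
    gc = rng.beta(2.0, 2.0, size=n_sites)
    is_meth = rng.random(n_sites) >= unmethylated_weight
    beta_normal = np.where(
        is_meth, rng.beta(8.0, 2.0, size=n_sites), rng.beta(1.5, 15.0, size=n_sites)
    )
    beta_tumor = beta_normal.copy()
    labels = np.full(n_sites, "null", dtype=object)
    if n_dml > 0:
        n_hyper = n_dml // 2
        n_hypo = n_dml - n_hyper
        can_hyper = np.flatnonzero(beta_normal <= 1.0 - effect)
        can_hypo = np.flatnonzero(beta_normal >= effect)
        if len(can_hyper) < n_hyper or len(can_hypo) < n_hypo:
            raise ValueError("not enough eligible sites for the requested DML count")
        hyper = rng.choice(can_hyper, size=n_hyper, replace=False)
        remaining = np.setdiff1d(can_hypo, hyper, assume_unique=False)
        if len(remaining) < n_hypo:
            raise ValueError("not enough eligible sites for the requested DML count")
        hypo = rng.choice(remaining, size=n_hypo, replace=False)
        beta_tumor[hyper] += effect
        beta_tumor[hypo] -= effect
        labels[hyper] = "hyper"
        labels[hypo] = "hypo"
    df = pd.DataFrame(
        dict(
            chrom=chrom,
            pos=pos.astype(np.int64),
            gc=gc,
            beta_normal=beta_normal,
            beta_tumor=beta_tumor,
            dml_label=labels,
        )
    )
    return TrueMethylome(df=df, effect=effect)


def simulate_calls(
    truth: TrueMethylome,
    condition: Literal["tumor", "normal"],
    protocol: ProtocolProfile,
    workflow: WorkflowProfile,
    seed: int,
    sample: str = "S1",
) -> MethylationCallSet:
    """Simulate one run's call set from the truth and the two profiles.

    Per retained site: depth ~ NegBin(mean_depth * exp(gc_skew*(gc-0.5)),
    dispersion); the observed methylated count is Binomial(depth, p) with
    p = clip(true_beta*(1-conversion_error) + bias + N(0, noise_sd), 0, 1);
    effects apply in that fixed order.  Count-inflation artefacts
    (double counting, missing dedup) scale both counts, leaving beta intact.
    Sites lost to retention are absent from the output; zero-depth sites are
    kept with missing beta.
    """
    # sequencing-level randomness (read depth) is shared by every workflow
    # processing the same library, so it is keyed by (protocol, sample,
    # condition) only; workflow-level distortions get their own substream
    lib_rng = _substream(seed, "library", protocol.name, sample, condition)
    rng = _substream(seed, workflow.name, protocol.name, sample, condition)
    true_beta = truth.beta(condition)
    gc = truth.df["gc"].to_numpy()
    n = truth.n_sites

    mu = protocol.mean_depth * np.exp(protocol.gc_skew * (gc - 0.5))
    size = protocol.depth_dispersion
    depth = lib_rng.negative_binomial(size, size / (size + mu), size=n)

    keep = rng.random(n) < workflow.retention

    p = true_beta * (1.0 - protocol.conversion_error) + workflow.bias
    if workflow.noise_sd > 0:
        p = p + rng.normal(0.0, workflow.noise_sd, size=n)
    p = np.clip(p, 0.0, 1.0)
    m = rng.binomial(depth, p)
    u = depth - m

    if workflow.double_count:
        doubled = rng.random(n) < workflow.double_count_fraction
        m = np.where(doubled, m * 2, m)
        u = np.where(doubled, u * 2, u)
    if not workflow.dedup:
        m = np.round(m * workflow.duplicate_factor).astype(np.int64)
        u = np.round(u * workflow.duplicate_factor).astype(np.int64)

    m = m[keep].astype(float)
    u = u[keep].astype(float)
    total = m + u
    with np.errstate(invalid="ignore"):
        beta = np.where(total > 0, m / np.maximum(total, 1), np.nan)
    df = pd.DataFrame(
        dict(
            chrom=truth.df["chrom"].to_numpy()[keep],
            pos=truth.df["pos"].to_numpy()[keep],
            beta=beta,
            depth=total,
            count_m=m,
            count_u=u,
        )
    )[CALL_COLUMNS]
    meta = RunMeta(workflow.name, protocol.name, sample, condition)
    return MethylationCallSet(df.reset_index(drop=True), meta=meta)


def generate_gold_standard(
    truth: TrueMethylome,
    n_loci: int,
    n_technologies: int,
    tech_noise_sd: float,
    seed: int,
    sites_per_locus: int = 5,
) -> list[GoldStandardLocus]:
    """Pick reference loci and attach noisy per-technology beta measurements.

    Loci are non-overlapping windows of ``sites_per_locus`` consecutive CpGs
    that contain no DML (so the locus has a single condition-independent true
    beta, the mean truth beta over the window).  Each of the
    ``n_technologies`` technologies reports true_beta + N(0, tech_noise_sd),
    clipped to [0, 1].
    """
    if n_technologies < 3:
        raise ValueError("at least 3 technologies are required")
    if tech_noise_sd < 0:
        raise ValueError("tech_noise_sd must be >= 0")
    rng = _substream(seed, "gold_standard")
    labels = truth.df["dml_label"].to_numpy()
    n = truth.n_sites
    # candidate window starts: all sites in the window are null
    ok = labels == "null"
    window_ok = np.ones(n - sites_per_locus + 1, dtype=bool)
    for k in range(sites_per_locus):
        window_ok &= ok[k : n - sites_per_locus + 1 + k]
    starts = np.flatnonzero(window_ok)
    chosen: list[int] = []
    taken = np.zeros(n, dtype=bool)
    for s in rng.permutation(starts):
        if not taken[s : s + sites_per_locus].any():
            chosen.append(int(s))
            taken[s : s + sites_per_locus] = True
            if len(chosen) == n_loci:
                break
    if len(chosen) < n_loci:
        raise ValueError(
            f"could not place {n_loci} non-overlapping DML-free loci "
            f"(found {len(chosen)}); increase n_sites or reduce n_loci"
        )
    chosen.sort()
    techs = [f"tech{k + 1}" for k in range(n_technologies)]
    loci = []
    beta_normal = truth.df["beta_normal"].to_numpy()
    pos = truth.df["pos"].to_numpy()
    chroms = truth.df["chrom"].to_numpy()
    for i, s in enumerate(chosen):
        idx = np.arange(s, s + sites_per_locus)
        tb = float(beta_normal[idx].mean())
        meas = np.clip(tb + rng.normal(0.0, tech_noise_sd, size=n_technologies), 0, 1)
        loci.append(
            GoldStandardLocus(
                region_id=f"L{i + 1:02d}",
                chrom=str(chroms[s]),
                start=int(pos[s]),
                end=int(pos[s + sites_per_locus - 1]),
                site_index=idx,
                measurements=dict(zip(techs, meas.tolist())),
                true_beta=tb,
            )
        )
    return loci


def locus_table(loci: Sequence[GoldStandardLocus]) -> pd.DataFrame:
    """Long-format (region, technology, beta) table for a locus list."""
    rows = [
        dict(region=loc.region_id, technology=t, beta=b)
        for loc in loci
        for t, b in loc.measurements.items()
    ]
    return pd.DataFrame(rows, columns=["region", "technology", "beta"])


def blueprint_like_locus_table(
    seed: int, n_technologies: int = 5, tech_noise_sd: float = 0.03
) -> pd.DataFrame:
    """A 48-region reference table emulating a multi-center locus panel:
    16 mandatory regions (m1..m16) and 32 recommended ones (r1..r32), where
    regions r29 and r30 carry only 3 data points each (too sparse to build a
    corridor from) and every other region carries ``n_technologies``
    measurements.  Returns a long (region, technology, beta) table.
    """
    rng = _substream(seed, "blueprint_panel")
    regions = [f"m{i}" for i in range(1, 17)] + [f"r{i}" for i in range(1, 33)]
    sparse = {"r29", "r30"}
    rows = []
    for region in regions:
        true = float(rng.beta(1.2, 1.2))
        k = 3 if region in sparse else n_technologies
        for t in range(k):
            b = float(np.clip(true + rng.normal(0.0, tech_noise_sd), 0, 1))
            rows.append(dict(region=region, technology=f"tech{t + 1}", beta=b))
    return pd.DataFrame(rows, columns=["region", "technology", "beta"])


# ---------------------------------------------------------------------------
# Scenario files


@dataclass
class Scenario:
    """A full simulated study design loaded from YAML."""

    name: str
    seed: int
    n_sites: int
    n_dml: int
    effect: float
    samples: list[dict]  # id, patient, condition
    protocols: list[ProtocolProfile]
    workflows: list[WorkflowProfile]
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (workflow, protocol)
    gold_standard: dict = field(default_factory=dict)

    @property
    def planned_runs(self) -> list[tuple[str, str, str]]:
        """(workflow, protocol, sample) triples after exclusions."""
        excluded = {(w, p) for w, p in self.excluded}
        return [
            (w.name, p.name, s["id"])
            for w in self.workflows
            for p in self.protocols
            for s in self.samples
            if (w.name, p.name) not in excluded
        ]


def load_scenario(path: str | Path, seed: int | None = None,
                  n_sites: int | None = None) -> Scenario:
    """Load a scenario YAML; ``seed``/``n_sites`` override the file values."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if seed is None and "seed" not in raw:
        raise ValueError("scenario must declare a seed (reproducibility required)")
    protocols = [ProtocolProfile(**p) for p in raw["protocols"]]
    workflows = [WorkflowProfile(**w) for w in raw["workflows"]]
    return Scenario(
        name=raw.get("name", Path(path).stem),
        seed=int(seed if seed is not None else raw["seed"]),
        n_sites=int(n_sites if n_sites is not None else raw["n_sites"]),
        n_dml=int(raw.get("n_dml", 0)),
        effect=float(raw.get("effect", 0.3)),
        samples=list(raw["samples"]),
        protocols=protocols,
        workflows=workflows,
        excluded=[tuple(x) for x in raw.get("excluded", [])],
        gold_standard=dict(raw.get("gold_standard", {})),
    )


def bundled_scenario_path(name: str = "study_design") -> Path:
    """Path of a scenario YAML shipped with the package."""
    return Path(__file__).parent / "scenarios" / f"{name}.yaml"
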