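# Methods

This note documents the statistical models, the parameter choices and the
deliberately open design decisions behind `methbench`.

## Call-file handling

Two dialects are read and written: the six-column coverage format
(1-based inclusive coordinates, methylation %, methylated count,
unmethylated count) and bedGraph (0-based half-open, four or six columns).
Internally every record is a 0-based plus-strand cytosine position. When
counts are present, beta is recomputed as count-M / (count-M + count-U)
rather than trusting the printed percentage: counts are exact integers while
percentages are rounded. Missing beta is an explicit NaN state — a beta of 0
is a real unmethylated call and never stands in for "no data". Zero-depth
sites are represented by absence from the file, matching how real callers
emit coverage files.

Strand collapsing merges the two symmetric cytosines of a CpG dyad
(positions p, p+1) by summing counts; runs of consecutive positions are
paired greedily left to right, which is deterministic and conserves total
counts. Merging is the default because per-strand depth at a CpG is roughly
halved and most consumers work per dyad; `plus_only` remains available for
callers that already report per-dyad values on the plus strand.

Depth filtering retains sites with depth ≥ `min_depth` (default 10, i.e.
"below 10 reads" excluded). The filter only hides betas and preserves depth
values, which makes it idempotent and monotone in the threshold.

Chromosomes sort naturally (chr2 before chr10).

## Consensus corridors

Corridor endpoints are restricted to observed measurement values: any
optimal interval can be shrunk onto observed values without losing members,
so the restriction is lossless and admits both an exact sliding-window
search (implementation) and an exhaustive O(n²) candidate enumeration (the
independent test oracle). Intervals are closed; boundary membership is the
convention under which the deviation function is continuous (1-Lipschitz)
in the measurement. Width ties break toward the smaller lower bound, so the
construction is deterministic.

* Data-driven corridor (per CpG, per sample): smallest interval with at
  least `min_per_protocol` = 5 measurements from each high-coverage
  protocol. The high-coverage set defaults to WGBS-, Swift- and EM-seq-like
  protocols (configurable); shallow protocols contribute measurements to be
  *scored*, not to define the corridor. Corridors are built per sample by
  default — methylation differs between samples, so pooling samples would
  widen corridors with real biology rather than technical spread — with
  pooling available as an option.
* Gold-standard corridor (per reference locus): narrowest interval
  containing measurements from at least 3 distinct technologies, widened by
  a flank of 0.05 on each side and clipped to [0, 1]. The flank is read as
  5 percentage points of methylation (absolute beta units), not 5% of the
  corridor width: a relative flank would collapse to zero exactly when the
  technologies agree perfectly, which is when mild widening is most clearly
  intended.

A locus whose corridor cannot be built (a protocol short of 5 measurements,
fewer than 3 technologies) is *corridor-undefined*. Deviations there are
missing values: they are excluded from aggregation and shrink the
denominator. They are never counted as zero — silently treating "cannot
evaluate" as "perfect" would reward data loss.

Aggregation over the study grid is the mean of defined deviations over
samples × regions. With no missing cells this equals the textbook
Σ d / (M × P); with missing cells the mean (reduced denominator) is used,
since a sum would penalise a workflow for having been evaluable at more
loci.

## Coverage retention

The retention curve is the fraction of a fixed CpG universe with depth ≥ t
for integer thresholds t = 1..200; the score is the discrete mean of the
curve (sum / 200). Orientation: higher is better — a workflow that retains
reads scores higher. The discrete sum (rather than trapezoidal integration)
makes the saturated case exactly 1.0. Threshold 0 is excluded: it would be
identically 1 for every run and only dilute the score. Sites absent from a
run count as depth 0, so the universe must be fixed a priori (in the
synthetic setting, the truth's site list; on real data, the union of sites
or an external CpG annotation).

## Differential methylation

The package consumes per-site score/label tables; it does not fit the
underlying differential models (array moderated-t or sequencing
beta-binomial fits), which need replicate structure that is out of scope
here. For synthetic runs the per-site score is |Δβ|·√(pooled depth) — a
monotone signal-to-noise surrogate for a test statistic. Hyper- and
hypomethylation AUCs are computed one-vs-null (events of one class as
positives, null sites as negatives) and combined weighted by event counts.
Correlations across multiple tumor–normal pairs are averaged on the Fisher
z scale, the standard way to average correlation coefficients. The DM
composite is the average of the two metric ranks within a protocol.

## Rank aggregation

Within each (protocol, metric) cell workflows are ranked 1..n (1 = best,
ties averaged — averaging is the convention that preserves the rank sum
n(n+1)/2). S_w is the *mean* rank over available cells. Mean was chosen over
sum deliberately: with design holes (a workflow unsupported on one
protocol) a sum would conflate "bad" with "absent", while the mean stays
comparable; with a complete grid the two order identically. Missing cells
are excluded by default (worst-rank imputation available behind a flag).
Exact S_w ties are broken by the mean z-score, computed with the population
standard deviation within each cell and sign-flipped so that lower is
always better; any remaining tie falls back to workflow name for
determinism. Externally measured metrics (runtime, peak memory) can be
merged into the grid through the same long-format table; the package does
not measure them.

## Synthetic data generator

The generator emulates the call-level statistical structure the benchmark
must cope with; it is a first-class, tested module, not a fixture.

* True methylome: betas drawn from a two-component mixture — Beta(1.5, 15)
  (sharp unmethylated mode near 0, weight 0.25) and Beta(8, 2) (broad
  methylated mode near 0.8, weight 0.75) — reproducing the characteristic
  bimodal beta histogram of real methylomes. Differential loci get an exact
  additive effect (default 0.3), split evenly between hyper and hypo, on
  sites where the shifted value stays in [0, 1].
* Protocols: per-site depth is negative binomial with mean
  `mean_depth · exp(gc_skew · (gc − 0.5))` and dispersion `depth_dispersion`.
  The bundled profiles use mean depth 43 for the deep standard protocol,
  30 for the two intermediate ones and 12/8 for the low-input ones; the
  PBAT-like profile combines low mean, low dispersion (heavy skew) and a
  strong positive GC preference. A conversion-error rate scales beta down
  slightly.
* Workflows are call-level distortion bundles: site retention < 1, additive
  beta bias, extra gaussian call noise, double counting of overlapping-mate
  calls (counts ×2 on a fraction of sites, default 0.5 — roughly the
  fraction of fragments short enough to overlap), and missing duplicate
  removal (counts × 1.2). Effects apply in fixed order: conversion error →
  bias → noise → clip to [0, 1] → binomial sampling of methylated counts;
  count-inflation artefacts act on counts afterwards and leave beta intact.
  Profile magnitudes are package choices (no quantitative per-tool values
  exist to copy) and are named by archetype, not after real tools.
* Seeding: one root seed spawns independent substreams via hashed spawn
  keys. Read-depth randomness is keyed by (protocol, sample, condition)
  only — every workflow processes the same sequencing library, so their
  depths are identical where retention allows — while workflow distortions
  get per-run substreams. Adding a run never changes existing runs.
* Gold-standard loci are non-overlapping windows of 5 consecutive CpGs
  chosen to contain no differential site (so one condition-independent true
  beta per locus), with per-technology measurements true ± N(0, sd),
  clipped. A separate 48-region panel generator emulates a multi-center
  reference table in which two recommended regions carry only 3 data points
  and are dropped by the ≥ 4-measurement filter, leaving 46.

What the generator does **not** model: read-level phenomena (chimeric
reads, M-bias, alignment errors, PCR duplicates as reads). Only their
call-level consequences (retention loss, bias, noise, count inflation) are
simulated. Passing tests therefore show that the *evaluation machinery*
detects call-level distortions of known size and direction; they do not
certify behaviour on artefacts whose call-level signature differs from
these, nor calibrate absolute metric values for real data.

## Problem sizes and numerical choices

The bundled study scenario runs at 2 000 CpGs (192 call files), chosen so a
full simulate-and-benchmark cycle stays interactive on one CPU; the
acceptance script uses 1 000–1 500 CpGs and the replicated experiments use
1 200 CpGs (bias study, 100 replicates) and 20 000 CpGs (noise-ordering
study, 50 replicates). These sizes are statistical choices: large enough
that the expected metric differences dominate sampling noise, small enough
to rerun casually. Corridor searches are exact, not heuristic, at any size.
Degenerate inputs fail loudly: empty universes, single-class ROC labels,
zero-variance correlations and all-missing grids raise errors rather than
returning conventional values.

## Known limitations

* The data-driven corridor is degenerate when the number of workflows per
  protocol equals `min_per_protocol` (the corridor then spans all
  measurements and every deviation is 0); it becomes informative with more
  workflows than the minimum, as in the bundled 10-workflow design.
* Locus-level workflow measurements are depth-weighted mean betas over the
  locus span; real targeted assays aggregate differently per technology.
* The DM score surrogate ranks sites well for binomial-like noise but is
  not a calibrated test statistic; AUC values on synthetic data should be
  compared between workflows, not interpreted absolutely.
* Runtime and memory metrics are accepted as external inputs only.
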