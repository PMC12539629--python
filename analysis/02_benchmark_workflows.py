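"""Benchmark the simulated runs and rank the workflows.

Reads the manifest written by 01_simulate_study.py, computes the four metric
families (coverage AUC, genome-wide consensus deviation, gold-standard
deviation, differential-methylation composite) and aggregates them into the
final decathlon-style ranking under results/study/results/.
"""

from pathlib import Path

from methbench.benchmark import BenchmarkConfig, run_benchmark

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    data = ROOT / "scratch" / "study" / "data"
    if not (data / "manifest.tsv").exists():
        raise SystemExit("run analysis/01_simulate_study.py first")
    config = BenchmarkConfig(
        manifest_path=data / "manifest.tsv",
        out_dir=ROOT / "results" / "study",
        gold_standard_measurements=data / "gold_standard_measurements.tsv",
        gold_standard_loci=data / "gold_standard_loci.tsv",
        reference_dm=data / "reference_dm.tsv",
    )
    result = run_benchmark(config)
    print(result.rank_result.summary().to_string())
    print(f"\nresults bundle: {result.out_dir}")


if __name__ == "__main__":
    main()
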