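"""Generate the simulated study dataset.

Emits the full bundled design — 10 workflows x 5 protocols x 4 samples minus
the two unsupported workflow-protocol combinations, i.e. 192 call files —
plus the gold-standard locus tables and the differential-methylation
reference, under results/study/data/.
"""

import glob
from pathlib import Path

from methbench.benchmark import generate_scenario_dataset
from methbench.synthetic_data import bundled_scenario_path, load_scenario

# bulk output (192 call files) goes under scratch/; small result tables
# produced by the later steps live under results/
OUT = Path(__file__).resolve().parents[1] / "scratch" / "study" / "data"


def main() -> None:
    scenario = load_scenario(bundled_scenario_path())
    manifest = generate_scenario_dataset(scenario, OUT)
    n = len(glob.glob(str(OUT / "*.cov")))
    print(f"scenario: {scenario.name} (seed {scenario.seed}, "
          f"{scenario.n_sites} CpGs, {scenario.n_dml} DMLs)")
    print(f"wrote {n} call files (planned: {len(scenario.planned_runs)})")
    print(f"manifest: {manifest}")


if __name__ == "__main__":
    main()
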