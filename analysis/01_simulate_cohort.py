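#!/usr/bin/env python
"""Generate the synthetic 37-sample breath-GC/MS cohort.

Writes one chromatogram CSV per sample under scratch/cohort/ (bulky,
regenerable) and the ground truth — class labels, per-sample compound
placements, synthetic clinical covariates, the scenario itself — under
results/.
"""
import argparse
from pathlib import Path

import breathmap as bm
import breathmap.chromatogram_io as cio

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=20221228)
    args = parser.parse_args()

    scenario = bm.default_scenario(seed=args.seed)
    chromatograms, labels, compounds = bm.generate_cohort(scenario)
    covariates = bm.generate_covariates(scenario)

    cohort_dir = ROOT / "scratch" / "cohort"
    cohort_dir.mkdir(parents=True, exist_ok=True)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    for chrom in chromatograms:
        cio.write_chromatogram(chrom, cohort_dir / f"{chrom.sample_id}.csv")
    cio.write_labels(
        [c.sample_id for c in chromatograms], labels, results / "labels_true.tsv"
    )
    cio.write_compounds(compounds, results / "compounds.tsv")
    cio.write_covariates(covariates, results / "covariates.tsv")
    (results / "scenario.json").write_text(scenario.to_json())

    sizes = scenario.class_sizes
    print(
        f"simulated {scenario.n_samples} samples in {len(sizes)} classes "
        f"{sizes} on a {scenario.rt_start}-{scenario.rt_end} min axis"
    )
    print(f"chromatograms -> {cohort_dir}")
    print(f"ground truth  -> {results}/labels_true.tsv, compounds.tsv, covariates.tsv")


if __name__ == "__main__":
    main()
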