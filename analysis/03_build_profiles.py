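#!/usr/bin/env python
"""Condense each sample's peak table into its 10-feature profile.

Reads results/peaks.tsv, writes the unscaled profile matrix to
results/profiles.tsv (standardization happens at the clustering stage).
"""
import json
from pathlib import Path

import breathmap as bm
import breathmap.chromatogram_io as cio

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    results = ROOT / "results"
    tables = cio.read_peak_table(results / "peaks.tsv")
    scenario = json.loads((results / "scenario.json").read_text())
    rt_range = (scenario["rt_start"], scenario["rt_end"])
    matrix = bm.profile_cohort(tables, rt_range, standardized=False)
    cio.write_profiles(matrix, results / "profiles.tsv")
    print(
        f"profile matrix: {matrix.n_samples} samples x 10 features "
        f"-> {results}/profiles.tsv"
    )


if __name__ == "__main__":
    main()
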