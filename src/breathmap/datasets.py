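"""Bundled reference data.

The package ships one small table: per-cluster lists of volatile and
semivolatile compound names reported as characteristic (non-recurrent
between clusters) in a 37-patient pulmonary-arterial-hypertension breath
GC/MS cohort.  The synthetic-cohort generator draws its compound labels
from these lists, and the characterization tests use them as a known
pairwise-disjoint set system.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["reference_compound_clusters"]


def reference_compound_clusters() -> dict[int, list[str]]:
    """Per-cluster compound-name lists, keyed by cluster number (1-4).

    Lists preserve file order; names within a cluster are unique and the
    four lists are pairwise disjoint.
    """
    ref = resources.files("breathmap.data").joinpath("voc_clusters.tsv")
    with resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t", dtype={"cluster": int, "compound": str})
    return {
        int(cluster): group["compound"].tolist()
        for cluster, group in table.groupby("cluster", sort=True)
    }
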