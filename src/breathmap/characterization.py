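"""Post-clustering reporting: compound sets and covariate summaries.

Given a clustering of the cohort, this module builds Table-style
reports: per-cluster compound inventories, the compounds unique to each
cluster (present in at least one of its samples and in no sample of any
other cluster), and per-cluster clinical covariate summaries
(n / mean / SD / median / min / max for numeric covariates, level counts
for categorical ones).
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CovariateSummary",
    "cluster_compound_sets",
    "unique_compounds",
    "summarize_covariates",
]


def _labels_as_mapping(labels) -> Mapping[str, int]:
    if isinstance(labels, pd.Series):
        return labels.to_dict()
    if isinstance(labels, Mapping):
        return labels
    raise TypeError("labels must be a mapping sample_id -> cluster label")


def cluster_compound_sets(
    compound_table: pd.DataFrame,
    labels,
    min_support: int = 1,
) -> dict[int, set[str]]:
    """Union of compound names over the samples of each cluster.

    ``labels`` maps sample_id to cluster label; every sample appearing
    in the table must be labelled.  With ``min_support`` > 1 a compound
    must occur in at least that many distinct samples of the cluster to
    enter its set (a guard against single-sample artifacts; the default
    of 1 is the all-inclusive reading).
    """
    label_map = _labels_as_mapping(labels)
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    unlabeled = set(compound_table["sample_id"]) - set(label_map)
    if unlabeled:
        raise ValueError(f"unlabeled samples in compound table: {sorted(unlabeled)}")
    sets: dict[int, set[str]] = {int(c): set() for c in label_map.values() if c >= 0}
    support: dict[int, Counter] = {c: Counter() for c in sets}
    deduped = compound_table.drop_duplicates(subset=["sample_id", "compound"])
    for sample_id, compound in zip(deduped["sample_id"], deduped["compound"]):
        cluster = int(label_map[sample_id])
        if cluster >= 0:  # DBSCAN noise samples contribute to no cluster
            support[cluster][compound] += 1
    for cluster, counter in support.items():
        sets[cluster] = {c for c, k in counter.items() if k >= min_support}
    return sets


def unique_compounds(
    cluster_sets: Mapping[int, set[str]]
) -> dict[int, list[str]]:
    """Per-cluster compounds found in no other cluster, sorted.

    unique(c) = set(c) minus the union of all other clusters' sets; the
    outputs are pairwise disjoint by construction and idempotent (running
    the operation on its own output returns it unchanged).
    """
    if len(cluster_sets) < 2:
        raise ValueError("need at least two clusters")
    result: dict[int, list[str]] = {}
    for cluster, compounds in cluster_sets.items():
        others: set[str] = set()
        for other, other_compounds in cluster_sets.items():
            if other != cluster:
                others |= other_compounds
        result[cluster] = sorted(compounds - others)
    return result


@dataclass
class CovariateSummary:
    """Numeric and categorical per-cluster covariate summaries."""

    numeric: pd.DataFrame  # cluster, covariate, n, mean, sd, median, min, max
    categorical: pd.DataFrame  # cluster, covariate, level, count


def summarize_covariates(covariate_table: pd.DataFrame, labels) -> CovariateSummary:
    """Table-2-style per-cluster summaries of a long-format covariate table.

    A covariate is treated as numeric when every non-missing value is
    numeric; missing values are excluded per covariate with the
    remaining n reported.  Sample SD (n-1) is used; a single-member
    group reports SD as NaN.
    """
    label_map = _labels_as_mapping(labels)
    unlabeled = set(covariate_table["sample_id"]) - set(label_map)
    if unlabeled:
        raise ValueError(f"unlabeled samples in covariate table: {sorted(unlabeled)}")
    table = covariate_table.copy()
    table["cluster"] = [int(label_map[s]) for s in table["sample_id"]]
    numeric_rows, categorical_rows = [], []
    for covariate, group in table.groupby("covariate", sort=True):
        values = group["value"]
        present = values[~pd.isna(values)]
        is_numeric = all(isinstance(v, (int, float)) for v in present)
        for cluster, sub in group.groupby("cluster", sort=True):
            sub_present = sub["value"][~pd.isna(sub["value"])]
            if is_numeric:
                v = np.asarray(sub_present, dtype=np.float64)
                numeric_rows.append(
                    {
                        "cluster": cluster,
                        "covariate": covariate,
                        "n": v.size,
                        "mean": v.mean() if v.size else np.nan,
                        "sd": v.std(ddof=1) if v.size > 1 else np.nan,
                        "median": float(np.median(v)) if v.size else np.nan,
                        "min": v.min() if v.size else np.nan,
                        "max": v.max() if v.size else np.nan,
                    }
                )
            else:
                for level, count in sorted(Counter(sub_present).items()):
                    categorical_rows.append(
                        {
                            "cluster": cluster,
                            "covariate": covariate,
                            "level": level,
                            "count": count,
                        }
                    )
    return CovariateSummary(
        numeric=pd.DataFrame(
            numeric_rows,
            columns=["cluster", "covariate", "n", "mean", "sd", "median", "min", "max"],
        ),
        categorical=pd.DataFrame(
            categorical_rows, columns=["cluster", "covariate", "level", "count"]
        ),
    )
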