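#!/usr/bin/env python
"""Stage 2: elbow-based k selection and four-algorithm cluster analysis.

Standardizes the profile matrix, computes the k-means inertia curve
(k = 1..10), selects k by the second-difference elbow rule, partitions
the cohort with spectral, k-means, DBSCAN and Ward agglomerative
clustering, and compares every partition against the generator's ground
truth with the adjusted Rand index.
"""
import argparse
from pathlib import Path

import numpy as np

import breathmap as bm
import breathmap.chromatogram_io as cio
from breathmap.clustering import median_knn_eps
from breathmap.plotting import plot_cluster_map, plot_elbow, plot_parallel_coordinates

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--kmax", type=int, default=10)
    args = parser.parse_args()

    results = ROOT / "results"
    matrix = bm.standardize(cio.read_profiles(results / "profiles.tsv"))
    truth_map = cio.read_labels(results / "labels_true.tsv")
    truth = np.array([truth_map[s] for s in matrix.sample_ids])

    curve = bm.inertia_curve(matrix, k_max=args.kmax, seed=args.seed)
    k = bm.select_k_elbow(curve)
    print(f"elbow criterion over k = 1..{args.kmax}: selected k = {k}")
    with (results / "elbow.tsv").open("w") as fh:
        fh.write("k\tinertia\n")
        for kk, inertia in zip(curve.k_values, curve.inertias):
            fh.write(f"{int(kk)}\t{inertia!r}\n")

    partitions = {
        "spectral": bm.spectral(matrix, k, seed=args.seed),
        "kmeans": bm.kmeans(matrix, k, seed=args.seed)[0],
        "agglomerative": bm.agglomerative(matrix, k),
        "dbscan": bm.dbscan(
            matrix, eps=median_knn_eps(matrix, k=3), min_samples=3
        ),
    }
    for name, result in partitions.items():
        sizes, n_noise = bm.cluster_sizes(result)
        ari = bm.adjusted_rand_index(result.labels, truth)
        noise = f" (+{n_noise} noise)" if n_noise else ""
        print(f"  {name:14s} sizes {sorted(sizes.tolist())}{noise}  ARI vs truth {ari:.3f}")

    spectral_result = partitions["spectral"]
    cio.write_labels(matrix.sample_ids, spectral_result.labels, results / "labels_pred.tsv")

    figures = results / "figures"
    figures.mkdir(exist_ok=True)
    plot_elbow(curve, k, figures / "elbow.svg")
    plot_parallel_coordinates(matrix, spectral_result.labels, figures / "parallel_coordinates.svg")
    plot_cluster_map(matrix.sample_ids, spectral_result.labels, figures / "cluster_map.svg")
    print(f"spectral labels -> {results}/labels_pred.tsv; figures -> {figures}")


if __name__ == "__main__":
    main()
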