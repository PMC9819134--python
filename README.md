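# breathmap

Breath GC/MS chromatogram profiling and cluster mapping.

Exhaled air carries volatile and semivolatile metabolites that can be
captured on a sorbent and separated by gas chromatography / mass
spectrometry.  For cohorts of patients with a rare disease such as
pulmonary arterial hypertension, a natural question is whether the
resulting chromatograms fall into homogeneous subgroups — metabolome
"fingerprint" classes — without any labels.  `breathmap` implements a
two-stage answer as a reusable, tested pipeline:

1. **Peak detection.**  For each sample, find the local maxima of the
   intensity trace, keep peaks whose topographic prominence reaches a
   significance threshold (default 10,000 detector units), integrate
   each peak between its two neighbouring local minima (trapezoidal
   area, ratio = area/prominence), and confirm peaks against the
   level-1 and level-2 approximations of a discrete wavelet transform
   (reverse-biorthogonal `rbio2.2`): a genuine peak survives the
   lowpass, a sub-filter-width spike does not.
2. **Profiling and clustering.**  Condense each sample into a
   10-feature profile (count, mean/max height, mean prominence, mean
   width, total area, mean area/intensity ratio, tallest-peak retention
   time, retention-time SD, first-half fraction), z-score the cohort
   matrix, pick the number of clusters k* by the elbow criterion

   &nbsp;&nbsp;&nbsp;&nbsp;k\* = argmax₂≤k≤kmax−1 [ I(k−1) − 2 I(k) + I(k+1) ]

   over the k-means inertia curve I(k), and partition the cohort with
   normalized spectral clustering (plus k-means, DBSCAN and Ward
   agglomerative for comparison).  Partitions are scored against ground
   truth with the adjusted Rand index (ARI).

Because no public raw data exist for such cohorts, the package ships a
synthetic-cohort generator (`bnp37`): 37 samples in four planted classes
of sizes 10/8/11/8, with shared and class-unique Gaussian compound
peaks, baseline drift and detector noise on a 0.5–52.75 min retention
axis.  The generator is first-class, tested code — it is the ground
truth against which every recovery property is verified.  See
`docs/methods.md` for the model, the parameter choices and what the
synthetic cohort does and does not emulate.

## Worked example

The `analysis/` scripts run the whole pipeline on the synthetic cohort
(chromatograms land in `scratch/`, tables in `results/`):

```sh
python analysis/01_simulate_cohort.py      # 37 samples, 4 classes
python analysis/02_detect_peaks.py         # stage 1
python analysis/03_build_profiles.py       # 10-feature profiles
python analysis/04_cluster_analysis.py     # elbow + 4 algorithms
python analysis/05_characterize_clusters.py
```

which prints:

```
simulated 37 samples in 4 classes (10, 8, 11, 8) on a 0.5-52.75 min axis
detected 583 significant peaks across 37 samples (15-17 per sample); 583/583 confirmed by DWT levels 1-2
profile matrix: 37 samples x 10 features -> results/profiles.tsv
elbow criterion over k = 1..10: selected k = 4
  spectral       sizes [8, 8, 10, 11]  ARI vs truth 1.000
  kmeans         sizes [8, 8, 10, 11]  ARI vs truth 1.000
  agglomerative  sizes [8, 8, 10, 11]  ARI vs truth 1.000
  dbscan         sizes [3, 3, 3, 4, 4, 4, 4, 5] (+7 noise)  ARI vs truth 0.337
cluster 0: 18 compounds observed, 6 unique to this cluster
...
```

Reading: each sample's 18 true peaks yield 15–17 detected ones (the
shared peaks nearest the 10,000 threshold drop out sample-by-sample);
all detected peaks are wavelet-confirmed; the elbow rule recovers the
planted class count (k = 4); spectral, k-means and Ward clustering all
reproduce the planted 10/8/11/8 partition exactly (ARI 1.0), while
density-based DBSCAN — included for comparison — fragments clusters of
this size and dimensionality.  The characterization stage then recovers
each class's six unique compounds and summarises the (signal-free)
clinical covariates per cluster.

The same pipeline is available as a CLI (`breathmap simulate / detect /
profile / cluster / characterize`) for running on external chromatogram
CSVs (`rt,intensity` per sample).

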