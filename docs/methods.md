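# Methods

`breathmap` re-implements, as a tested pipeline, a two-stage analysis of
exhaled-air GC/MS chromatograms from a pulmonary-arterial-hypertension
(PAH) cohort: per-sample peak detection with wavelet-based confirmation,
condensation of each sample into a fixed-length feature profile, and
cluster analysis of the cohort with elbow-based selection of the number
of clusters.  Because the underlying patient data are not public, the
pipeline is exercised end-to-end on a synthetic cohort with planted
class structure; every recovery claim in the test suite is therefore a
statement about parameter recovery under known ground truth, not about
real breath data.

## Stage 1 — peak detection

A chromatogram is a uniformly sampled trace of detector intensity
(arbitrary units) against retention time (minutes).  The detector:

1. finds all interior local maxima (a plateau of equal values flanked by
   strictly lower values counts once, at its leftmost index);
2. measures each maximum's **topographic prominence** — height minus the
   higher of the two minimal valleys separating it from nearer higher
   terrain, or from the signal edge;
3. keeps peaks whose *intensity* reaches `min_intensity` (default
   10,000 detector units).  "Intensity" is deliberately configurable:
   the default basis is prominence, which is invariant to baseline
   offsets (adding a constant to the trace changes every height but no
   prominence); `intensity_basis="height"` gives the literal raw-height
   reading.  Both quantities are recorded per peak;
4. finds each peak's **integration range** — the nearest interior local
   minimum on each side (an equal-value minimum run is treated as one
   minimum and the range extends over the whole run; a monotone edge
   falls back to the trace boundary) — and integrates the trace between
   the bounds with the trapezoidal rule, with **no baseline
   subtraction**;
5. records the **area / intensity ratio** (units: minutes), the width at
   half prominence (linear interpolation on both flanks), and sorts
   peaks by retention time.

### DWT confirmation

The trace is additionally decomposed with a multilevel discrete wavelet
transform (reverse-biorthogonal mother wavelet, default `rbio2.2`,
symmetric boundary extension).  Zeroing the detail bands and
reconstructing gives the *approximation* of the trace at levels 1 and 2.
A detected peak is **confirmed** when, at every requested level, the
approximation has a local maximum within `confirm_rt_tol` (default
0.1 min) of the peak *whose own prominence retains at least half*
(`confirm_min_retention = 0.5`) of the peak's prominence.

The retention factor is the operative part of the rule.  Pure
co-location is insufficient: the lowpass reconstruction of a one-sample
impulse still shows ringing local maxima at the impulse position, so a
position-only rule confirms everything.  What distinguishes a genuine
chromatographic peak from a sub-filter-width spike is amplitude
survival — an isolated Gaussian peak of width comparable to or larger
than the filter support passes the level-2 lowpass nearly unattenuated,
while an impulse retains only ~19% of its prominence there (~75% at
level 1, so an impulse is confirmed at level 1 alone but not at
level 2).  The threshold of 0.5 sits well between those regimes and is
not sensitive in practice: on the default synthetic cohort every true
peak retains > 0.9.  Unconfirmed peaks are *flagged, not dropped*, by
default (`drop_unconfirmed` inverts this), since flagging preserves
information and the choice is reversible downstream.

## Stage 2 — profiles and clustering

Each sample's peak table is condensed into ten features: peak count,
mean height, max height, mean prominence, mean width, total area, mean
area/intensity ratio, retention time of the tallest peak, SD of peak
retention times, and the fraction of peaks in the first half of the
retention axis.  The set spans count, magnitude, shape, area and
position, and every entry is computable from stage-1 outputs alone.  A
sample with no detected peaks maps to the all-zero profile so degenerate
samples remain clusterable.

Profiles are stacked into an n x 10 matrix and z-scored per column
(population SD; constant columns map to zeros) before any distance
computation — the raw features differ by orders of magnitude (counts
vs. areas), so unscaled Euclidean distances would be dominated by a
single column.  `--no-standardize` disables this.

Four partitioning algorithms are implemented from first principles (the
test suite cross-checks each against scikit-learn on fixtures):

- **k-means** — Lloyd iterations from k-means++ seeds, best of 10
  restarts, stop when assignments stabilise or after 300 iterations;
  empty clusters are re-seeded with the point farthest from its center.
- **spectral** — RBF affinity `exp(-gamma d^2)` with the median
  heuristic `gamma = 1/(2 median(d^2))`; symmetric normalized Laplacian
  `I - D^{-1/2} A D^{-1/2}`; the k eigenvectors of smallest eigenvalue
  are row-normalized and clustered with the k-means above.
- **DBSCAN** — textbook density reachability; core points need
  `min_samples` neighbours within `eps` (self included); border points
  join the first core cluster that discovers them; iteration follows
  row order so results are deterministic.  Default `eps` is the median
  3-NN distance.  DBSCAN is exploratory here: with ~10-sample clusters
  and 10 dimensions it fragments the cohort at any reasonable `eps`,
  and it never drives a headline number.
- **agglomerative** — bottom-up Ward merging (pair minimising
  `|A||B|/(|A|+|B|) ||c_A - c_B||^2`), ties broken on the smallest pair
  of cluster indices.

**Elbow rule.**  The number of clusters is chosen from the k-means
inertia curve I(k), k = 1..k_max (default 10).  Each k is additionally
warm-started from the previous k's best centers plus the worst-fit
point, which guarantees a non-increasing curve.  The elbow is formalised
as the maximal second forward difference,
`k* = argmax_{2<=k<=kmax-1} I(k-1) - 2 I(k) + I(k+1)`, ties toward
smaller k.  This is the sharpest-bend reading of "the point where the
curve becomes flat".  Its known failure mode matters for the generator
design below: if successive drops decay gradually (as they do when the
class centroids are nearly collinear), the rule prefers k = 2.

The adjusted Rand index (pair-counting, chance-corrected) compares
partitions against the generator's ground truth.

## The synthetic cohort (`bnp37`)

The built-in scenario emulates the study conditions: 37 samples in four
latent classes of sizes 10/8/11/8, a 0.5–52.75 min retention axis at 120
points/min (mirroring a ~53-minute GC temperature program), a linear
baseline (500 units, +15 units/min drift) and Gaussian detector noise
(SD 150).  Every sample carries 12 shared compound peaks; each class
adds 6 unique peaks whose names are drawn from the bundled per-cluster
compound lists, so class-unique name sets are disjoint by construction.
Peaks are Gaussian in shape — the simplest model with analytic mode and
area; no peak-shape information beyond "peak" is available to constrain
anything richer — with per-sample retention jitter (SD 0.02 min) and
height noise (CV 0.10, truncated at 0.1x the mean; intensities clipped
at 0).

Two deliberate calibrations:

- **Threshold exercise.** Shared-peak mean heights straddle the
  10,000-unit filter (8.5k–30k): in expectation ~2.8 of the 18 true
  peaks per sample (~15%) fall below it, so the significance filter does
  real work and per-sample peak counts fluctuate the way a hard
  threshold on noisy heights makes them fluctuate.
- **Simplex class geometry.** The class signal is laid out as three
  balanced sign contrasts over decorrelated feature blocks: peak
  magnitude high for classes {0, 2}; unique peaks early on the rt axis
  for {0, 1}; peaks wide for {0, 3} (widths 0.042–0.066 min; each class
  also has a distinct dominant-peak retention time).  The four class
  centroids in the standardized feature space then form a near-regular
  simplex.  This is not cosmetic: a monotone layout (one class "low" on
  everything, one "high") makes the centroids nearly collinear, the
  inertia drops decay smoothly, and the second-difference elbow
  prefers k = 2 regardless of separation.  With the simplex layout the
  drops stay comparable up to k = 4 and collapse after it.

All randomness flows through `numpy.random.Generator`; per-sample
substreams are seeded `(scenario.seed, sample_index)`, so cohorts are
bit-reproducible and independent of generation order.

**What the generator does not emulate:** mass spectra (no m/z
dimension), co-elution and deconvolution, retention-index drift between
samples or batches, heteroscedastic detector noise, and any real
biological covariance between compounds.  The synthetic covariate table
(age, sex, six-minute-walk distance) has PAH-cohort-shaped marginals but
carries *no* class signal by design — per-cluster covariate summaries
are expected to show no differences.  Passing recovery tests therefore
demonstrate that the pipeline's operators compose correctly and recover
planted structure at realistic signal-to-noise; they do not validate the
clinical meaning of clusters in real breath data.

## Numerical choices and degenerate inputs

- Plateau maxima and minimum runs resolve to deterministic indices
  (leftmost; integration ranges span whole minimum runs).
- Peak width uses scipy's linear flank interpolation at half prominence.
- z-scoring uses population SD; re-standardizing a standardized matrix
  is an error rather than a silent no-op.
- k-means and spectral take explicit integer seeds and are deterministic
  given them; agglomerative and DBSCAN are deterministic outright.
- Spectral clustering rejects an all-identical matrix (degenerate
  affinity); duplicate points short of that are handled by falling back
  to the median of positive squared distances.
- ARI returns 1.0 when both partitions are trivial (the
  max-index = expected-index degeneracy).
- Single-member clusters report SD as NaN (sample SD, n-1) in covariate
  summaries; missing covariate values are excluded per covariate with n
  reported.

## Problem sizes used in tests

The suite runs the full 37-sample cohort end-to-end (seconds), brute
force oracles on 100 random 200-point traces, exhaustive-partition
k-means checks up to 8 points, and 100-replicate elbow-recovery sweeps
for K in {2, 3, 4, 5} blobs at 6-SD separation (~1 minute).  These sizes
were chosen to keep the whole suite under a few minutes on one CPU while
still exercising every operator at the cohort's real scale.

## Known limitations

- The ten profile features are one defensible choice among many; the
  pipeline fixes them rather than learning them, and no feature
  importance is computed beyond the parallel-coordinates view.
- The elbow rule inherits the second-difference formalisation's bias
  toward k = 2 on elongated cluster geometries; the inertia-curve TSV is
  always written so a flat-curve pathology is visible on inspection.
- Compound "presence" is binary per sample; abundance is not used in
  cluster characterization.
- No alignment across samples: retention jitter is assumed small
  relative to peak spacing (true for the generator; real GC data may
  need retention-index alignment first).
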