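# Methods

This note documents the models, algorithms, defaults and numerical choices
behind `msistream`, and what the synthetic-data tests do and do not
demonstrate about real MSI data.

## Data model and out-of-core contract

A *sample* is one tissue section's centroided peak data: an m/z feature
vector (strictly increasing, positive, in Da), an `(n_pixels, n_features)`
intensity matrix (non-negative until variance stabilization), 0-based pixel
coordinates stored row-major by (y, x), and an optional boolean tissue
mask.  All samples live in one HDF5 workspace
(`/samples/<id>/{mz,intensities,coords,tissue_mask}`, `/common_mz`,
`/metadata/<k>`), with floats at 64-bit so that content digests (SHA-256
over raw bytes plus shape) are bit-exact across write/read cycles.

Every pipeline stage iterates samples one at a time and writes results
back; the workspace counts the number of simultaneously materialized sample
objects (a weak-reference set updated at load time) and the streaming
stages keep that count at 1.  The only super-sample memory objects are the
`p × p` cross-product matrix of the filter stage and the m/z histogram;
both are independent of pixel and sample count.  Consequently stage cost is
`a + b·N` in the number of samples N, which the test suite asserts as a
linear fit with R² ≥ 0.95 over N ∈ {2, 4, 8, 16} — a shape claim only;
absolute times are hardware-dependent.

Every mutating stage appends one metadata record: step name, complete
parameter map, ISO-8601 timestamp, and digests of the workspace state
before and after.  The parameter maps are sufficient to replay a stage from
the same input digest and reproduce the output digest exactly; a test
replays alignment, normalization, filtering and VST this way.

## m/z alignment

Histogram bins are uniform in log(m/z), so a "5 ppm" bin (the default,
user-adjustable) is 5 ppm wide at every mass — a constant-Da bin cannot be.
Each pooled sample feature increments exactly one bin (occurrence counts,
not intensity-weighted; intensity weighting would let one bright channel
dominate the axis).  The smoother is a hand-rolled local-linear loess with
tricube weights evaluated on a 1 ppm refined grid; the window spans 7
coarse bins by default (exposed as `span_bins`).  Smoothing is evaluated
only near occupied bins — elsewhere the histogram is identically zero and
can hold no centroid.  Centroids sit where the first difference of the
smoothed curve changes sign from positive to negative; plateau ties break
to the lowest index; endpoints never qualify; sign changes with
non-positive smoothed value are discarded as numerical ripple.

Two numerical facts shape the defaults:

- The histogram quantizes feature positions to the 5 ppm bin; a cluster
  confined to one bin therefore cannot be located more precisely than the
  bin centre, whatever the refined-grid spacing.  `align_workspace` fixes
  this by refining each detected centroid to the mean of the sample
  features assigned to it (group means stay inside their nearest-neighbour
  cells, so ordering is preserved), which also makes alignment idempotent:
  exactly coincident features reproduce their axis bit-for-bit, so aligning
  an already-aligned workspace changes nothing.
- A reference-free method can only remove *relative* drift: a shift common
  to every sample is invisible to it, so the best achievable residual
  against absolute truth equals the central tendency of the per-sample
  drifts (≈ mean/√(3N)·range for uniform drifts over N samples).
  `align_workspace` therefore runs a wide-window first pass (window
  covering twice the drift window) that collapses each drift-spread feature
  into one provisional centroid, estimates each sample's drift as the
  median of its matched drifts, recalibrates, and re-detects at the
  standard window.  Recalibration is skipped when the drift estimates have
  no spread (nothing relative to remove).  Matching is nearest-neighbour
  within the 100 ppm default window; features mapping to one centroid are
  summed per pixel (conserves total signal, order-independent); unmatched
  features are dropped and counted in the ledger, keeping the common axis
  identical across samples as the downstream stages require.

Internal lock-mass correction estimates a sample's drift as the median of
(observed − theoretical) shifts over reference ions matched within the
window, removed additively in Da or multiplicatively in ppm (both offered:
the drift of orthogonal-acceleration TOF instruments is often relative).

## Normalization

Intra-sample factors per spectrum: `mean` uses all features including zeros
(total ion current up to a constant); `median` uses positive entries only —
centroided matrices are sparse and a zero median is degenerate; `mfc` is
the median of ratios to a reference over features positive in both, with
the reference defaulting to that sample's element-wise median spectrum (a
workspace-wide reference can be passed instead).  Units with no positive
signal, or fewer than `min_shared = 10` shared positive features for mfc,
receive factor 1 and a degeneracy flag rather than an exception — one bad
pixel must not abort a 200-sample run; a median over fewer than ~10 ratios
is too unstable to trust.  Inter-sample factors are derived the same three
ways from homogenized profiles (mean over masked pixels, following the
"average tissue profile" convention), with the mfc reference the
element-wise median across sample profiles.

The mfc estimator's tolerance of asymmetric biological change has a sharp
boundary: with increases only, it is exact while *fewer than half* of the
features change, and at exactly half the median of ratios falls between the
clean and the changed group (for fold 3: double the true factor — the
classical breakdown point of the median under one-sided bounded
contamination).  With unbiased directions (increases and decreases), it
remains exact well past half.  Mean normalization is biased by roughly
`1 + (fold−1)·f` at perturbed fraction f and already exceeds 5% error below
f = 0.05.  All of this is computed, not assumed, by
`synthetic.mfc_recovery_study` and asserted in the tests; the acceptance
script reports the largest robust fraction on a 0.05 grid.

## Variance stabilization

Noise model: `x = (μ + ε_a)·exp(ε_m)` with additive `ε_a ~ N(0, σ_a²)` and
multiplicative `ε_m ~ N(0, σ_m²)`.  The started log `ln(x + c)` maps zeros
to `ln c` (re-centred to 0 by default so sparse matrices stay
sparse-friendly; the choice is recorded in the ledger) and for
`μ ≫ σ_a/σ_m` gives per-feature standard deviation → σ_m.  The log is
natural; the base only rescales downstream statistics.  The default offset
is 50 counts; the automatic mode takes the lower 5% quantile of all
positive intensities, computed out-of-core in two passes (1024 log-spaced
histogram bins locate the order statistic's bin; a second pass resolves it
exactly — the result equals full sorting, verified against it).  A ledger
guard refuses a second transformation.

The flatness diagnostic ranks features by mean over (masked) pixels,
follows the running median of the per-feature std in a sliding window
(default 51 ranks, centred, median-of-available at the edges), and reports
the least-squares slope of that curve as a scalar score.  The test
threshold — slope shrinking at least 10-fold after the transform — is a
property-test choice; no numeric flatness threshold exists in the
literature this implements.

## Solvent/matrix filtering

One global Pearson correlation matrix is computed over the pooled pixels of
all samples (per-sample matrices averaged afterwards would weight samples
by pixel count in an unspecified way and is less stable), accumulated from
per-sample moments; `n` here is the pooled pixel count.  Zero-variance
features (variance ≤ 1e-12 of the mean square) get zero rows and are
assigned to the background cluster by convention — a constant channel
carries no spatial tissue signal.  Feature representations are the rows of
the correlation matrix; k-means (k = 2, 10 restarts, seeded) is the
default, a full-covariance 2-component Gaussian mixture the alternative
(reduced to 10 principal directions when p > 500).  Labels are
deterministic given the seed, canonicalized so the first non-degenerate
feature's cluster is "A".

Which cluster is tissue is decided automatically (large studies cannot be
inspected visually): a manual override wins; otherwise, with any usable
tissue mask, the cluster with the higher mean on/off-mask intensity ratio;
otherwise the cluster with the higher mean within-cluster correlation.
The decision path and both clusters' m/z lists go into the ledger.
Delocalized tissue channels — present at reduced intensity across the whole
image — still correlate more with tissue than with background and stay in
the tissue cluster; a dedicated synthetic case asserts this.  By default
the pipeline filters after normalization and before VST (the stage order of
the method listing); the stages are independent functions, so other orders
are possible.

## Synthetic data

The generator plants, per sample: a global drift (uniform in ±50 ppm by
default) plus ~0.5 ppm per-feature jitter; a sample scale factor (uniform
in [0.5, 2]); per-pixel log-normal scales (σ = 0.3); an elliptical tissue
mask (~35% semi-axes, jittered) on a 40×40 default grid; log-normal base
intensities spanning ~3 decades (median 1000 counts) to exercise
heteroscedasticity; multiplicative noise σ_m = 0.2 and additive noise
σ_a = 10 counts, clipped at zero; tissue channels high on-mask (off-mask
floor 2%), background channels the reverse, optional delocalized channels
with a 40% off-mask floor.  Defaults were chosen once as representative of
centroided DESI/MALDI tissue data at these count scales.  Regeneration from
the same parameters and seed is bit-identical, and all recovery tests read
ground truth exclusively from the returned truth object.

What the synthetic model omits — isotope patterns, adducts, chemical noise
correlated across m/z, instrument line shapes, spatial structure beyond an
elliptical mask, batch drift over acquisition time — bounds what passing
tests show: they establish that each algorithm recovers exactly the
distortion class it targets under the stated noise model, not that real
tissue data satisfies that model.

## Problem sizes and determinism

Test and acceptance runs use desk-scale sizes chosen to make the measured
statistics stable: the robustness sweep uses 100 spectra × 2000 features ×
20 seeds per fraction; drift recovery uses 100 samples × 30 features (so
the unidentifiable common-drift component, ~2.9 ppm standard deviation,
sits inside the 5 ppm pass band); filter recovery uses 20 generator seeds
of 30-feature workspaces; the scaling check uses 36×36-pixel, 150-feature
samples.  All randomness flows through seeded `numpy` generators; k-means
and the Gaussian mixture receive explicit seeds; pipeline outputs are
bit-reproducible given identical inputs, parameters and seeds.

## Known limitations

- The common-axis model drops unmatched features rather than growing the
  axis; rare sample-specific channels outside the drift window are lost
  (counted in the ledger).
- Correlation moments are accumulated in raw (not centred) form; with
  extreme means-to-variance ratios (≫ 1e6) catastrophic cancellation could
  degrade the 1e-9 agreement with direct Pearson that holds at realistic
  count scales.
- The filter's two-cluster assumption mixes chemically distinct background
  sources into one cluster; more than two clusters would need manual
  merging.
- No quantile normalization, RUV-style batch correction, glog/arcsinh
  transforms, or profile-mode (non-centroided) spectra.
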