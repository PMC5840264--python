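# msistream

Out-of-core preprocessing for large-scale mass spectrometry imaging (MSI)
studies: DESI/MALDI experiments that acquire a centroided mass spectrum at
every pixel of a tissue section, across hundreds of tissue specimens.  Raw
peak matrices from such studies cannot be compared directly — m/z axes drift
between samples, overall intensity varies pixel-to-pixel and
sample-to-sample, technical variance grows with signal intensity, and
solvent/matrix ion channels carry no tissue chemistry.  `msistream` removes
each of these effects while streaming one sample at a time from a single
HDF5 workspace, so memory use is bounded by one sample regardless of study
size, and every step is recorded in a provenance ledger inside the
workspace file.

It is written for computational MSI/metabolomics researchers who want a
scriptable Python library (with a thin `msistream` CLI for batch use) rather
than an interactive viewer.

## Methods at a glance

Given per-sample peak matrices $X^{(s)} \in \mathbb{R}^{n_{pix} \times p_s}$
with m/z axes $m^{(s)}$:

- **m/z alignment (kernel clustering).**  All sample features are pooled into
  a histogram with bins uniform in $\log m/z$ (bin width 5 ppm by default), a
  loess smoother (local-linear, tricube weights) evaluates the occurrence
  frequency on a 1 ppm refined grid, and cluster centroids are placed where
  the first difference of the smoothed curve changes sign from + to −.  Each
  sample feature is matched to its nearest centroid within a drift window
  (100 ppm default).  A wide-window first pass and per-sample recalibration
  by the median matched drift handle tens-of-ppm per-sample drift without
  any reference masses; an internal lock-mass mode
  ($\hat d = \mathrm{median}_r (m_{obs,r} - m_{ref,r})$) is available when
  reference ions are known.
- **Normalization.**  Intra-sample: each spectrum $x_i$ is divided by a
  factor — its mean, the median of its positive intensities, or the median
  fold change $\mathrm{median}_j (x_{ij}/\mathrm{ref}_j)$ against the median
  spectrum.  Inter-sample: one uniform factor per sample, derived the same
  three ways from homogenized (masked-mean) sample profiles.  The median
  fold change tolerates large asymmetric biological changes in up to half of
  the features.
- **Solvent/matrix filtering.**  The feature–feature Pearson correlation
  matrix is accumulated from streaming sufficient statistics (sums, squared
  sums, cross-products) over all pixels of all samples; its rows are split
  into two clusters (k-means default, Gaussian mixture optional).
  Background channels anti-correlate spatially with tissue channels and form
  the second cluster, identified automatically from the on/off-mask
  intensity ratio (or within-cluster correlation when no masks exist).
- **Variance stabilization.**  The started log $\ln(x + c)$, with offset
  $c = 50$ counts by default or the lower 5% quantile of positive
  intensities (computed in two streaming passes).  Under
  $x = (\mu + \varepsilon_a)\,e^{\varepsilon_m}$ the transformed standard
  deviation converges to $\sigma_m$ for strong signals, removing the
  intensity–variance dependence that otherwise dominates PCA-style analysis.

A synthetic-data generator plants all of these distortions (drift, scale
factors, heteroscedastic noise, tissue masks, background channels) with
retrievable ground truth, so the whole pipeline is testable without any
external data.

## Worked example

```sh
python examples/01_full_pipeline.py
```

```
workspace: 4 samples, 120 features each
common m/z axis: 120 consolidated features
filter kept 78 tissue features, removed 42 background features
started log applied with offset 50 counts

provenance ledger:
  ...  init
  ...  mzalign
  ...  normalize-intra
  ...  normalize-inter
  ...  filter
  ...  vst
```

The 4 synthetic samples, each drifted and scaled differently, collapse onto
one 120-feature common axis (one centroid per planted feature); filtering
removes the 25 planted background channels plus weak-signal channels that
carry no spatial tissue information; the ledger lists every mutating stage
with parameters and content digests.  `examples/02_mz_alignment.py` prints
per-sample drift estimates next to the planted values (typically within a
fraction of a ppm of each other), `03` tabulates median-fold-change versus
mean normalization error as biological perturbation grows, `04` shows the
variance-rank curve flattening ~40,000-fold under the started log with the
multiplicative noise level recovered (0.199 vs 0.2 planted), and `05`
demonstrates background-channel recovery at 98% label accuracy.

The same stages are available from the shell:

```sh
msistream synth --out study.h5 --samples 6 --pixels 40x40 --features 200 --seed 17
msistream run --config pipeline.cfg     # ordered stages from a key=value file
msistream export --workspace study.h5 --outdir matrices/
```

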