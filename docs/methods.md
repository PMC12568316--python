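# Methods

## The representation problem

An LC-MS run records, at each chromatographic retention time (RT), a
spectrum of mass-to-charge (m/z) values with ion intensities.  Rasterized
onto a fixed m/z grid, a run becomes a large, sparse, non-negative matrix
`M` of shape (scans × m/z-bins) — effectively a grayscale image whose
bright regions are eluting analytes.  Feeding the whole matrix to an image
classifier is impractical (10⁷–10⁸ pixels per run), and cutting it into
fixed grid tiles splits signal peaks across tile borders, destroying
exactly the local texture a convolutional model would exploit.

msimg instead selects a small set of *patch centers anchored on signal
density*: patches are placed where the data is, not where a grid happens to
fall.  The output per sample is a tensor of `num_patches` patches of size
`patch_height × patch_width` — a multi-channel image a standard CNN can
consume.  This package implements the representation pipeline and a linear
separability probe; training CNNs on the tensors is downstream of the
package and out of its scope.

## Pipeline

1. **Binning.** Ion at m/z `x` lands in bin `i = floor((x − mz_min)/bin_size)`;
   intensities sharing a bin are summed.  Ions outside `[mz_min, mz_max)` are
   dropped (the grid is undefined there) and counted in the log.  Rows are
   ordered by retention time.
2. **Normalization.** Intensities are divided by the 99.9th percentile of the
   *non-zero* values and clipped to [0, 1].  The percentile is the lower
   empirical order statistic (`np.percentile(..., method="lower")`) — an
   actually observed intensity — so that after normalization the 99.9th
   percentile of the non-zero values equals 1 exactly, independent of how
   densely the upper tail is sampled.  An interpolated percentile would sit
   between two order statistics and, after clipping, the recomputed
   percentile would fall short of 1 by the local order-statistic spacing.
3. **Signal mask.** Pixels with normalized intensity strictly above
   `tau_intensity` are signal; the rest background.
4. **Density map.** Each pixel's value is the count of mask ones inside the
   `w × w` box window centered on it, computed exactly with an integer
   summed-area table; windows are clipped at the borders (equivalent to
   zero-padding), keeping the map the same shape as the matrix.
5. **NMS peak extraction (per sample).** Repeatedly take the global density
   maximum (ties: smallest row, then column — the row-major argmax), record
   it if its density ≥ `tau_density`, and zero a patch-sized rectangle
   around it on a working copy.  The rectangle spans
   `[c − s//2, c + s − s//2 − 1]` on each axis (for odd `s` this is the
   centered window).  Stop at `max_peaks` or when no pixel reaches the
   threshold.
6. **DAPS (across samples).** Pool every sample's peaks; a patch covers the
   circle of radius `r = sqrt((h/2)² + (w/2)²)` (center to diagonal corner)
   around its center.  Greedily select the available point covering the most
   available points (boundary counts as inside; ties: smallest row, then
   column), retire everything it covers, and stop when the best coverage
   score drops below `tau_min_peaks`.  Selected centers are therefore
   pairwise more than `r` apart.  Radius queries use a k-d tree; since the
   radius is fixed, neighbor lists are precomputed and coverage counts
   updated incrementally, which is exactly equivalent to re-scoring each
   round (verified against an all-pairs oracle in the tests).
7. **Entropy ranking.** For each candidate center, extract the patch from
   every training sample (cells beyond the borders filled with `pad_value`,
   and those fill cells participate in the histogram), quantize to 256
   levels (`k = round(v·255)`, NumPy round-half-to-even, clamped) and
   compute Shannon entropy in bits; average over the training set.  The
   `num_patches` locations with the highest mean entropy are the golden
   locations; ties keep DAPS selection order.
8. **Image assembly.** Any sample — training or held-out — is represented by
   its patches at the golden locations stacked in rank order:
   `(num_patches, patch_height, patch_width)`.  The fitted model (JSON
   artifact: binning, thresholds, locations, entropies) is all that
   transform needs; held-out processing never re-runs selection.

The grid baseline (`candidate_strategy="grid"`) replaces steps 3–6 with
sliding-window centers at a fixed stride (default: the patch size, i.e.
disjoint tiles) and shares the entropy ranking, isolating the effect of
density-aware placement.

## Parameters

| name | default | meaning |
|---|---|---|
| `bin_size` | 0.1 Da | m/z grid resolution; no standard value, instrument-dependent |
| normalization percentile | 99.9 | upper-tail anchor mapped to 1 |
| `tau_intensity` | 0.01 | signal-mask threshold on [0,1] intensity |
| `w` (`density_window`) | 9 px | box window for the density map; odd |
| `tau_density` | 5 | minimum window count for an NMS peak |
| `max_peaks_per_sample` | 100 | per-sample NMS budget |
| `patch_height × patch_width` | 224 × 224 | patch size; matches standard CNN inputs and defines both the NMS suppression rectangle and the DAPS radius |
| `tau_min_peaks` | 2 | DAPS stop: a center must cover at least one point besides itself |
| `num_patches` | 64 | channels in the output tensor |
| `pad_value` | 0.0 | fill beyond matrix borders |

Patch size 224 and 64 channels are the defaults because performance
saturates near there and they match mainstream CNN input conventions; the
mask/density thresholds have no standard values and should be tuned to the
instrument's noise floor.  `tau_min_peaks = 2` encodes the weakest
meaningful clustering requirement — an isolated candidate never seen to
cluster with anything is rejected.

## Synthetic data

`msimg.synthetic` generates sparse matrices as sums of 2-D Gaussian blobs
(amplitude × exp(−Δrow²/2σ_RT² − Δcol²/2σ_mz²)) plus sparse uniform "salt"
noise, clipped to [0, 1].  Defaults: 256 × 256 grid, 12 blobs with σ = 2 px
and amplitudes U(0.15, 0.35), pairwise separation ≥ 40 px, salt density
10⁻³ with amplitude ≤ 0.05.  The separation keeps each blob an isolated
hotspot (the regime the density/NMS stage targets); the amplitude range
leaves headroom so a 2.5× class effect stays below the intensity clip.  A
two-class corpus shares one blob layout (real cohorts share the
chromatographic landscape), jitters each peak's amplitude by U(0.8, 1.2)
per sample, and multiplies a designated third of the peaks by
`class_effect` in the positive class.  All randomness flows through
`numpy.random.default_rng` (PCG64), so a seed fixes the corpus bit for bit
across platforms.

What the generator does *not* emulate: isotope envelopes, adducts,
chromatographic drift and tailing, heteroscedastic detector noise,
batch effects, or class signal expressed as RT shifts rather than
abundance changes.  Passing tests therefore demonstrate the algorithmic
contracts (oracle equivalence, recovery, hygiene, monotone information
advantage) — not clinical-grade classification performance on real
cohorts.

The synthetic mzML writer emits the minimal standard profile (one MS1
centroid spectrum per matrix row, 64-bit little-endian floats, base64, no
compression); each non-zero cell becomes an ion at its bin's center m/z,
which by construction rebins to the same cell, making round-trips exact.

## Numerical and design notes

- Density maps use integer arithmetic throughout; oracle agreement is exact,
  not approximate.
- All argmax tie-breaks are lexicographic (row, then column), making every
  stage deterministic for a fixed input.
- The entropy quantizer uses NumPy's round-half-to-even; any consistent
  rounding rule would do, but this one is stated so results are
  bit-comparable.
- The separability probe is an unscaled L2 logistic regression on flattened
  tensors under stratified k-fold CV.  Features are deliberately not
  standardized: pixels already share the [0, 1] scale, and per-feature
  standardization turns near-constant background pixels into huge z-scores
  that swamp the informative ones.  Cross-validated null accuracy is known
  to fluctuate at-or-below chance (fold-wise anti-learning of noise), so
  "no class signal" is checked one-sided against an upper bound.
- Channel diagnostics treat (sample, pixel) pairs as observations and
  channels as variables, bounding the PCA answer by the channel count.  On
  synthetic blob data channels share the same radial profile, so measured
  inter-channel correlation is high and one component dominates — an honest
  property of the generator, not of the method on real runs, where channel
  content differs structurally.
- Degenerate inputs: an all-zero matrix normalizes to itself with a warning;
  NMS on a sub-threshold map returns an empty list; DAPS may return no
  centers if the first best score is below `tau_min_peaks`; a constant
  channel's undefined correlation is reported as 0 with a warning.

## Problem sizes used in the shipped checks

Tests and the acceptance script run on 128–256 px square matrices, patch
32 × 32, 8 channels, corpora of 16–120 samples — sizes chosen so the whole
verification cycle completes in seconds on one CPU while exercising every
code path at realistic sparsity.  The defaults above (224 px, 64 channels)
remain the recommended settings for real runs.

## Known limitations

- No RT alignment across runs is performed (by design — patch placement is
  shared, not warped); severe retention drift between cohorts would smear
  hotspots in the pooled candidate set.
- Golden locations are global for a training set; per-fold refitting is the
  caller's responsibility in nested CV designs.
- The mzML reader covers the common encodings (32/64-bit float, zlib or
  none); exotic compressions (numpress) are not supported.
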