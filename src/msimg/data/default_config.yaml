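# msimg default configuration.
# Values marked "no published default" are heuristics with no standard value
# in the literature; tune them to your instrument and chromatography.

binning:
  mz_min: 100.0        # Da; no published default — must match your acquisition range
  mz_max: 1100.0       # Da; no published default
  bin_size: 0.1        # Da; no published default

normalization:
  percentile: 99.9     # percentile of non-zero intensities mapped to 1.0

density:
  tau_intensity: 0.01  # signal-mask threshold on normalized intensity; no published default
  window: 9            # odd box-window side w for the density map; no published default
  tau_density: 5       # minimum density for an NMS candidate peak; no published default
  max_peaks: 100       # per-sample NMS peak budget; no published default

daps:
  tau_min_peaks: 2     # stop when the best coverage score drops below this; no published default

patch:
  height: 224          # patch size matching standard CNN inputs
  width: 224
  pad_value: 0.0       # fill for patch cells beyond the matrix borders
  num_patches: 64      # channels in the output tensor
  grid_stride: null    # grid baseline stride; null = patch size (disjoint tiles)
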