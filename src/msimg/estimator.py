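"""Scikit-learn style transformer tying the pipeline stages together.

``MsimgTransformer.fit`` learns the golden patch locations from a training
set of normalized mass-spec matrices (binarize → density map → NMS per
sample, pool, DAPS greedy coverage — or the fixed-grid baseline — then mean-
entropy ranking).  ``transform`` turns any sample, training or held-out,
into its ``(num_patches, patch_height, patch_width)`` tensor using only the
fitted locations; nothing is re-selected at transform time.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import daps as _daps
from . import density as _density
from . import patches as _patches
from .spectra_io import BinningSpec, MassSpecMatrix, normalize_matrix

logger = logging.getLogger(__name__)

__all__ = ["MsimgTransformer"]


def _as_matrix(x: MassSpecMatrix | np.ndarray, percentile: float) -> MassSpecMatrix:
    """Accept a MassSpecMatrix or a bare 2-D array; normalize if needed."""
    if isinstance(x, MassSpecMatrix):
        return x if x.normalized else normalize_matrix(x, percentile)
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("each sample must be a 2-D matrix")
    nominal = BinningSpec(mz_min=0.0, mz_max=float(arr.shape[1]), bin_size=1.0)
    m = MassSpecMatrix(values=arr, binning=nominal, normalized=bool(arr.size == 0 or arr.max() <= 1.0))
    return m if m.normalized else normalize_matrix(m, percentile)


class MsimgTransformer(TransformerMixin, BaseEstimator):
    """Learn density-aware patch locations; emit multi-channel image tensors.

    Parameters
    ----------
    tau_intensity : float, default 0.01
        Signal-mask threshold on normalized intensity (strict ``>``).
    density_window : int, default 9
        Odd box-window side ``w`` for the density map.
    tau_density : int, default 5
        Minimum density for an NMS peak to count as a candidate.
    max_peaks_per_sample : int, default 100
        Per-sample NMS peak budget.
    patch_height, patch_width : int, default 224
        Patch size; also the NMS suppression rectangle, and (via the
        center-to-corner distance) the DAPS coverage radius.
    pad_value : float, default 0.0
        Fill value for patch cells beyond the matrix borders.
    tau_min_peaks : int, default 2
        DAPS stopping threshold: selection stops once the best coverage
        score drops below this.
    num_patches : int, default 64
        Channels in the output tensor (top entropy-ranked locations).
    candidate_strategy : {"daps", "grid"}, default "daps"
        "grid" replaces DAPS with the fixed-grid sliding-window baseline;
        the entropy ranking is shared by both.
    grid_stride : int or None, default None
        Grid baseline stride; None means the patch size (disjoint tiles).
    normalization_percentile : float, default 99.9
        Percentile used when an unnormalized matrix is passed in.

    Attributes
    ----------
    golden_locations_ : list of (row, col)
        Selected patch centers, entropy rank order.
    mean_entropies_ : list of float
        Mean training-set patch entropy (bits) per golden location.
    candidate_centers_ : list of (row, col)
        All candidate centers before entropy ranking (DAPS or grid order).
    candidate_scores_ : list of int or None
        DAPS coverage score per candidate (None for the grid baseline).
    n_pooled_peaks_ : int
        Size of the pooled per-sample NMS peak set.
    radius_ : float
        DAPS coverage radius derived from the patch size.
    matrix_shape_ : tuple of int
        Training matrix shape; transform inputs must match.
    binning_ : BinningSpec or None
        Binning metadata of the training matrices, when available.
    """

    def __init__(
        self,
        tau_intensity: float = _density.DEFAULT_TAU_INTENSITY,
        density_window: int = _density.DEFAULT_WINDOW,
        tau_density: int = _density.DEFAULT_TAU_DENSITY,
        max_peaks_per_sample: int = _density.DEFAULT_MAX_PEAKS,
        patch_height: int = 224,
        patch_width: int = 224,
        pad_value: float = 0.0,
        tau_min_peaks: int = 2,
        num_patches: int = 64,
        candidate_strategy: str = "daps",
        grid_stride: int | None = None,
        normalization_percentile: float = 99.9,
    ):
        self.tau_intensity = tau_intensity
        self.density_window = density_window
        self.tau_density = tau_density
        self.max_peaks_per_sample = max_peaks_per_sample
        self.patch_height = patch_height
        self.patch_width = patch_width
        self.pad_value = pad_value
        self.tau_min_peaks = tau_min_peaks
        self.num_patches = num_patches
        self.candidate_strategy = candidate_strategy
        self.grid_stride = grid_stride
        self.normalization_percentile = normalization_percentile

    # -- helpers ----------------------------------------------------------

    def _patch_spec(self) -> _patches.PatchSpec:
        return _patches.PatchSpec(
            patch_height=self.patch_height, patch_width=self.patch_width, pad_value=self.pad_value
        )

    def _coerce_all(self, X: Sequence[MassSpecMatrix | np.ndarray]) -> list[MassSpecMatrix]:
        mats = [_as_matrix(x, self.normalization_percentile) for x in X]
        if not mats:
            raise ValueError("need at least one sample")
        shapes = {m.shape for m in mats}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent matrix shapes: {sorted(shapes)}")
        return mats

    # -- estimator API ----------------------------------------------------

    def fit(self, X: Sequence[MassSpecMatrix | np.ndarray], y=None) -> "MsimgTransformer":
        """Learn golden patch locations from training matrices. ``y`` is ignored
        (location selection is label-free)."""
        if self.candidate_strategy not in ("daps", "grid"):
            raise ValueError("candidate_strategy must be 'daps' or 'grid'")
        mats = self._coerce_all(X)
        shape = mats[0].shape
        self.matrix_shape_ = shape
        self.binning_ = mats[0].binning if isinstance(mats[0], MassSpecMatrix) else None
        self.radius_ = _daps.coverage_radius(self.patch_height, self.patch_width)

        if self.candidate_strategy == "daps":
            per_sample = []
            for m in mats:
                mask = _density.binarize(m, self.tau_intensity)
                dmap = _density.density_map(mask, self.density_window)
                peaks = _density.nms_extract_peaks(
                    dmap,
                    tau_density=self.tau_density,
                    max_peaks=self.max_peaks_per_sample,
                    suppress_h=self.patch_height,
                    suppress_w=self.patch_width,
                    sample_id=m.sample_id,
                )
                logger.info("sample %s: %d candidate peaks", m.sample_id or "?", len(peaks))
                per_sample.append(peaks)
            pool = _daps.pool_from_samples(per_sample)
            self.n_pooled_peaks_ = len(pool)
            selected = _daps.daps_select(
                pool,
                _daps.DapsConfig(
                    patch_height=self.patch_height,
                    patch_width=self.patch_width,
                    tau_min_peaks=self.tau_min_peaks,
                ),
            )
            candidates = selected.centers
            self.candidate_scores_ = list(selected.scores)
        else:
            candidates = _patches.grid_candidate_locations(
                shape[0], shape[1], self._patch_spec(), stride=self.grid_stride
            )
            self.n_pooled_peaks_ = 0
            self.candidate_scores_ = None

        logger.info(
            "pooled %d peaks -> %d candidate centers (%s)",
            self.n_pooled_peaks_, len(candidates), self.candidate_strategy,
        )
        if self.num_patches > len(candidates):
            raise ValueError(
                f"num_patches={self.num_patches} exceeds the {len(candidates)} candidate "
                f"locations this training set supports; the achievable maximum is {len(candidates)}"
            )
        self.candidate_centers_ = list(candidates)
        golden = _patches.rank_golden_locations(mats, candidates, self._patch_spec(), self.num_patches)
        self.golden_locations_ = list(golden.locations)
        self.mean_entropies_ = list(golden.mean_entropies)
        return self

    def transform(self, X: Sequence[MassSpecMatrix | np.ndarray]) -> np.ndarray:
        """Map samples to tensors of shape (n_samples, num_patches, h, w)."""
        self._check_fitted()
        mats = self._coerce_all(X)
        golden = self.golden_locations()
        out = []
        for m in mats:
            if m.shape != tuple(self.matrix_shape_):
                raise ValueError(
                    f"sample shape {m.shape} does not match the fitted shape "
                    f"{tuple(self.matrix_shape_)}: binning provenance mismatch"
                )
            if self.binning_ is not None and m.binning != self.binning_ and m.binning.bin_size != 1.0:
                raise ValueError("sample binning does not match the fitted binning")
            out.append(_patches.build_multichannel_image(m, golden, self._patch_spec()).tensor)
        return np.stack(out)

    def transform_images(
        self, X: Sequence[MassSpecMatrix | np.ndarray]
    ) -> list[_patches.MultiChannelImage]:
        """Like :meth:`transform` but keeps sample ids / labels / provenance."""
        self._check_fitted()
        mats = self._coerce_all(X)
        golden = self.golden_locations()
        return [_patches.build_multichannel_image(m, golden, self._patch_spec()) for m in mats]

    def golden_locations(self) -> _patches.GoldenLocations:
        self._check_fitted()
        return _patches.GoldenLocations(
            locations=list(self.golden_locations_), mean_entropies=list(self.mean_entropies_)
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "golden_locations_"):
            raise ValueError("this MsimgTransformer instance is not fitted yet")
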