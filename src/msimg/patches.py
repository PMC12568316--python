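"""Patch extraction, entropy ranking, multi-channel image assembly, diagnostics.

Given the candidate patch centers chosen by DAPS (or by the fixed-grid
baseline), every training sample contributes one patch per candidate
location.  Locations are scored by the mean Shannon entropy (in bits, after
quantizing intensities to 256 levels) of their patches across the training
set; the ``num_patches`` highest-scoring locations become the "golden
locations".  Each sample — train or held-out — is then represented by the
tensor of its patches at those locations, stacked along the channel axis:
shape ``(num_patches, patch_height, patch_width)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from .daps import SelectedCenters
from .spectra_io import MassSpecMatrix

__all__ = [
    "PatchSpec",
    "GoldenLocations",
    "MultiChannelImage",
    "extract_patch",
    "patch_entropy",
    "rank_golden_locations",
    "build_multichannel_image",
    "grid_candidate_locations",
    "inter_channel_correlation",
    "pca_components_for_variance",
]


@dataclass(frozen=True)
class PatchSpec:
    """Patch geometry and the fill value used beyond the matrix borders."""

    patch_height: int = 224
    patch_width: int = 224
    pad_value: float = 0.0

    def __post_init__(self) -> None:
        if self.patch_height < 1 or self.patch_width < 1:
            raise ValueError("patch dimensions must be >= 1")
        if not (0.0 <= self.pad_value <= 1.0):
            raise ValueError("pad_value must lie in [0, 1]")


@dataclass
class GoldenLocations:
    """Training-derived patch centers ordered by mean entropy, non-increasing."""

    locations: list[tuple[int, int]]
    mean_entropies: list[float]

    @property
    def num_patches(self) -> int:
        return len(self.locations)


@dataclass
class MultiChannelImage:
    """Per-sample tensor (num_patches, patch_height, patch_width); channel c is
    the sample's patch at golden location c."""

    tensor: np.ndarray
    sample_id: str = ""
    label: str | None = None
    locations: list[tuple[int, int]] = field(default_factory=list)


def _values(matrix: MassSpecMatrix | np.ndarray) -> np.ndarray:
    return matrix.values if isinstance(matrix, MassSpecMatrix) else np.asarray(matrix, dtype=np.float64)


def extract_patch(
    matrix: MassSpecMatrix | np.ndarray, center: tuple[int, int], spec: PatchSpec
) -> np.ndarray:
    """Cut the (h, w) patch centered at ``center``; out-of-bounds cells are padded.

    The center lands on patch cell ``(h//2, w//2)``; for even sizes the
    footprint is ``[center - s//2, center + s - s//2 - 1]`` on each axis.
    """
    vals = _values(matrix)
    n_rows, n_cols = vals.shape
    r, c = center
    if not (0 <= r < n_rows and 0 <= c < n_cols):
        raise ValueError(f"center {center} outside matrix of shape {vals.shape}")
    h, w = spec.patch_height, spec.patch_width
    r0, c0 = r - h // 2, c - w // 2
    patch = np.full((h, w), spec.pad_value, dtype=np.float64)
    sr0, sc0 = max(r0, 0), max(c0, 0)
    sr1, sc1 = min(r0 + h, n_rows), min(c0 + w, n_cols)
    patch[sr0 - r0 : sr1 - r0, sc0 - c0 : sc1 - c0] = vals[sr0:sr1, sc0:sc1]
    return patch


def patch_entropy(patch: np.ndarray) -> float:
    """Shannon entropy (bits) of the patch after quantization to 256 levels.

    Intensities in [0, 1] map to ``k = round(v * 255)`` (NumPy round-half-to-
    even, clamped to [0, 255]); H = −Σ p_k log2 p_k over occupied levels, so
    0 ≤ H ≤ 8, with 0 iff the quantized patch is constant.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.size == 0:
        raise ValueError("empty patch")
    if patch.min() < 0.0 or patch.max() > 1.0:
        raise ValueError("patch values must lie in [0, 1]")
    levels = np.clip(np.rint(patch * 255.0), 0, 255).astype(np.intp)
    counts = np.bincount(levels.ravel(), minlength=256)
    p = counts[counts > 0] / patch.size
    return float(-(p * np.log2(p)).sum())


def rank_golden_locations(
    train_matrices: Sequence[MassSpecMatrix | np.ndarray],
    candidates: SelectedCenters | Sequence[tuple[int, int]],
    spec: PatchSpec,
    num_patches: int,
) -> GoldenLocations:
    """Rank candidate centers by mean patch entropy over the training set.

    Every training sample contributes one entropy value per candidate
    location; locations are sorted by the mean, descending, and the top
    ``num_patches`` are returned.  Ties keep the candidate (DAPS selection)
    order, making the ranking deterministic.
    """
    centers = list(candidates.centers) if isinstance(candidates, SelectedCenters) else list(candidates)
    if not train_matrices:
        raise ValueError("training set must not be empty")
    if num_patches > len(centers):
        raise ValueError(
            f"num_patches={num_patches} exceeds the {len(centers)} available candidate "
            f"locations; the achievable maximum is {len(centers)}"
        )
    means = np.array(
        [
            np.mean([patch_entropy(extract_patch(m, ctr, spec)) for m in train_matrices])
            for ctr in centers
        ]
    )
    order = np.argsort(-means, kind="stable")[:num_patches]
    return GoldenLocations(
        locations=[centers[i] for i in order],
        mean_entropies=[float(means[i]) for i in order],
    )


def build_multichannel_image(
    matrix: MassSpecMatrix | np.ndarray, golden: GoldenLocations, spec: PatchSpec
) -> MultiChannelImage:
    """Stack the sample's patches at the golden locations along the channel axis.

    Applies to any sample, training or held-out, using the same training-
    derived locations; nothing is re-selected here.
    """
    if golden.num_patches == 0:
        raise ValueError("no golden locations to extract")
    vals = _values(matrix)
    for r, c in golden.locations:
        if not (0 <= r < vals.shape[0] and 0 <= c < vals.shape[1]):
            raise ValueError(
                f"golden location ({r}, {c}) outside matrix of shape {vals.shape}; "
                "the sample's binning does not match the model's provenance"
            )
    tensor = np.stack([extract_patch(vals, ctr, spec) for ctr in golden.locations])
    sample_id = matrix.sample_id if isinstance(matrix, MassSpecMatrix) else ""
    label = matrix.label if isinstance(matrix, MassSpecMatrix) else None
    return MultiChannelImage(tensor=tensor, sample_id=sample_id, label=label, locations=list(golden.locations))


def grid_candidate_locations(
    n_rows: int, n_cols: int, spec: PatchSpec, stride: int | None = None
) -> list[tuple[int, int]]:
    """Fixed-grid sliding-window candidate centers (the grid-partition baseline).

    Windows of the patch size are placed at the given stride (default: the
    patch size, i.e. non-overlapping tiles), scanning row-major from the
    top-left; only windows fully inside the matrix are kept.  The resulting
    centers feed the same entropy ranking as the density-aware candidates.
    """
    stride = spec.patch_height if stride is None else stride
    if stride < 1:
        raise ValueError("stride must be >= 1")
    h, w = spec.patch_height, spec.patch_width
    if h > n_rows or w > n_cols:
        warnings.warn("patch larger than matrix: no grid locations", RuntimeWarning, stacklevel=2)
        return []
    return [
        (top + h // 2, left + w // 2)
        for top in range(0, n_rows - h + 1, stride)
        for left in range(0, n_cols - w + 1, stride)
    ]


def _tensor_stack(images: Sequence[MultiChannelImage | np.ndarray]) -> np.ndarray:
    arrs = [im.tensor if isinstance(im, MultiChannelImage) else np.asarray(im) for im in images]
    return np.stack(arrs)  # (n_samples, channels, h, w)


def inter_channel_correlation(images: Sequence[MultiChannelImage | np.ndarray]) -> np.ndarray:
    """Pearson correlation between channels, pooling all samples' pixels.

    Channel c is flattened into one vector over every sample and pixel; the
    result is a symmetric (channels × channels) matrix with unit diagonal.
    A constant channel has no defined correlation; its entries are reported
    as 0 with a warning.
    """
    stacked = _tensor_stack(images)
    if stacked.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    n, c = stacked.shape[:2]
    flat = stacked.transpose(1, 0, 2, 3).reshape(c, -1)
    sd = flat.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn("constant channel(s): correlation undefined, reported as 0", RuntimeWarning, stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(flat)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def pca_components_for_variance(
    images: Sequence[MultiChannelImage | np.ndarray], variance_fraction: float = 0.95
) -> int:
    """Smallest number of principal components explaining the given variance.

    Observations are (sample, pixel) pairs and variables are the channels, so
    the answer is bounded by the channel count; a small answer relative to
    that bound signals redundant channels, a large one non-redundant ones.
    """
    if not (0.0 < variance_fraction < 1.0):
        raise ValueError("variance_fraction must lie in (0, 1)")
    stacked = _tensor_stack(images)
    if stacked.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    c = stacked.shape[1]
    X = stacked.transpose(0, 2, 3, 1).reshape(-1, c)
    pca = PCA(n_components=min(c, X.shape[0])).fit(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    # guard the float edge where cum[-1] rounds to just below the target
    return int(min(np.searchsorted(cum, variance_fraction), len(cum) - 1) + 1)
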