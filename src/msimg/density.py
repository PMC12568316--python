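"""Signal-density estimation and non-maximum suppression peak extraction.

The normalized matrix is thresholded into a binary signal mask (intensity
strictly greater than ``tau_intensity`` counts as signal).  A w×w box window
summed over the mask gives a density map whose value at each pixel is the
number of signal pixels in the surrounding window (windows are clipped at
the matrix borders, equivalently the mask is zero-padded).  Candidate peaks
are then pulled off the density map greedily: take the global maximum,
suppress a patch-sized rectangle around it, repeat until the maximum falls
below ``tau_density`` or the peak budget is exhausted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra_io import MassSpecMatrix

__all__ = ["SignalMask", "DensityMap", "PeakPoint", "binarize", "density_map", "nms_extract_peaks"]

#: spec-level defaults; none of these has a published value
DEFAULT_TAU_INTENSITY = 0.01
DEFAULT_TAU_DENSITY = 5
DEFAULT_WINDOW = 9
DEFAULT_MAX_PEAKS = 100


@dataclass
class SignalMask:
    """Binary mask: 1 where the source intensity exceeds ``tau_intensity``."""

    mask: np.ndarray
    tau_intensity: float


@dataclass
class DensityMap:
    """Integer count of mask ones inside the w×w window centered at each pixel."""

    density: np.ndarray
    window_w: int


@dataclass(frozen=True)
class PeakPoint:
    """A candidate peak: its position and the density value at extraction time."""

    row: int
    col: int
    density_value: int
    sample_id: str = ""


def binarize(matrix: MassSpecMatrix, tau_intensity: float = DEFAULT_TAU_INTENSITY) -> SignalMask:
    """Threshold a normalized matrix into a binary signal mask (strict ``>``)."""
    if not matrix.normalized:
        raise ValueError("binarize requires a normalized matrix")
    if not (0.0 <= tau_intensity < 1.0):
        raise ValueError("tau_intensity must lie in [0, 1)")
    return SignalMask(mask=(matrix.values > tau_intensity).astype(np.uint8), tau_intensity=tau_intensity)


def density_map(mask: SignalMask, w: int = DEFAULT_WINDOW) -> DensityMap:
    """Box-window count of signal pixels, computed exactly via an integral image.

    ``w`` must be odd so the window is centered; windows are truncated at the
    borders, keeping the map the same shape as the matrix.
    """
    if w < 1 or w % 2 == 0:
        raise ValueError("window size w must be a positive odd integer")
    m = np.asarray(mask.mask, dtype=np.int64)
    n_rows, n_cols = m.shape
    half = w // 2
    # summed-area table with a zero border; integer arithmetic keeps it exact
    sat = np.zeros((n_rows + 1, n_cols + 1), dtype=np.int64)
    sat[1:, 1:] = m.cumsum(axis=0).cumsum(axis=1)
    r0 = np.clip(np.arange(n_rows) - half, 0, n_rows)
    r1 = np.clip(np.arange(n_rows) + half + 1, 0, n_rows)
    c0 = np.clip(np.arange(n_cols) - half, 0, n_cols)
    c1 = np.clip(np.arange(n_cols) + half + 1, 0, n_cols)
    d = sat[np.ix_(r1, c1)] - sat[np.ix_(r0, c1)] - sat[np.ix_(r1, c0)] + sat[np.ix_(r0, c0)]
    return DensityMap(density=d, window_w=w)


def nms_extract_peaks(
    dmap: DensityMap,
    tau_density: int = DEFAULT_TAU_DENSITY,
    max_peaks: int = DEFAULT_MAX_PEAKS,
    suppress_h: int = 224,
    suppress_w: int = 224,
    sample_id: str = "",
) -> list[PeakPoint]:
    """Iterative non-maximum suppression on the density map.

    Each round locates the global density maximum (ties broken toward the
    smallest row, then smallest column — the row-major argmax), records it if
    its density is at least ``tau_density``, and zeroes the suppression
    rectangle around it on a working copy.  The rectangle spans rows
    ``[r - suppress_h//2, r + suppress_h - suppress_h//2 - 1]`` (and likewise
    for columns), clipped at the borders; for the usual case this is the
    patch footprint centered on the peak.  Stops after ``max_peaks`` peaks or
    when no pixel reaches the threshold.  The input map is left untouched.
    """
    if tau_density < 1:
        raise ValueError("tau_density must be >= 1")
    if max_peaks < 1:
        raise ValueError("max_peaks must be >= 1")
    work = dmap.density.copy()
    n_rows, n_cols = work.shape
    up, left = suppress_h // 2, suppress_w // 2
    down, right = suppress_h - up - 1, suppress_w - left - 1
    peaks: list[PeakPoint] = []
    while len(peaks) < max_peaks:
        flat = int(np.argmax(work))
        r, c = divmod(flat, n_cols)
        val = int(work[r, c])
        if val < tau_density:
            break
        peaks.append(PeakPoint(row=r, col=c, density_value=val, sample_id=sample_id))
        work[max(r - up, 0) : r + down + 1, max(c - left, 0) : c + right + 1] = 0
    return peaks
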