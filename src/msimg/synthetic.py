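"""Synthetic LC-MS matrices with planted 2-D peaks, for testing every stage.

A sample is a sparse non-negative (scans × m/z-bins) matrix built as a sum
of isotropic-ish Gaussian blobs (separate RT and m/z widths) plus sparse
uniform "salt" noise, clipped to [0, 1] and flagged normalized.  Peak
centers are drawn by rejection sampling under a minimum pairwise separation,
so each blob is an isolated signal hotspot — the regime the density-map /
NMS stage is designed for.  A two-class dataset shares one peak layout
across samples (real cohorts share the chromatographic landscape) with
per-sample amplitude jitter; a designated subset of peaks is scaled by
``class_effect`` in the positive class, giving a tunable, localized class
signal.  All randomness flows through ``numpy.random.default_rng`` (PCG64),
so a fixed seed reproduces a sample bit for bit on any platform.

Gaussian blobs, not isotope envelopes or chromatographic drift: the goal is
to exercise the algorithms, not to imitate instrument physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .spectra_io import BinningSpec, MassSpecMatrix

__all__ = ["SyntheticConfig", "GroundTruth", "generate_sample", "generate_dataset", "write_mzml_fixture"]

POSITIVE_LABEL = "case"
NEGATIVE_LABEL = "control"


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults give well-separated hotspots on a 256×256 grid."""

    n_scans: int = 256
    n_bins: int = 256
    n_peaks: int = 12
    peak_amplitude_range: tuple[float, float] = (0.15, 0.35)
    peak_sigma_rt: float = 2.0
    peak_sigma_mz: float = 2.0
    min_separation: float = 40.0
    noise_density: float = 1e-3
    noise_amplitude: float = 0.05
    class_effect: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.peak_amplitude_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("peak_amplitude_range must be within [0, 1]")
        if not (0.0 <= self.noise_amplitude <= 1.0):
            raise ValueError("noise_amplitude must be within [0, 1]")
        if self.class_effect <= 0:
            raise ValueError("class_effect must be positive")

    def binning(self) -> BinningSpec:
        # nominal axis: 0.1 Da bins starting at 100 Da
        return BinningSpec(mz_min=100.0, mz_max=100.0 + 0.1 * self.n_bins, bin_size=0.1)


@dataclass
class GroundTruth:
    """Planted peak layout of one sample: centers, amplitudes, class-modulated ids."""

    peak_centers: list[tuple[int, int]]
    amplitudes: list[float]
    modulated_ids: list[int]
    label: str = NEGATIVE_LABEL


@dataclass
class _Layout:
    centers: np.ndarray  # (n_peaks, 2) int
    base_amplitudes: np.ndarray
    modulated_ids: np.ndarray


def _draw_layout(config: SyntheticConfig, rng: np.random.Generator) -> _Layout:
    """Rejection-sample peak centers with pairwise separation >= min_separation."""
    if config.n_peaks == 0:
        return _Layout(
            centers=np.empty((0, 2), dtype=int),
            base_amplitudes=np.empty(0),
            modulated_ids=np.empty(0, dtype=int),
        )
    margin = int(math.ceil(3 * max(config.peak_sigma_rt, config.peak_sigma_mz)))
    if config.n_scans - 2 * margin <= 0 or config.n_bins - 2 * margin <= 0:
        raise ValueError("matrix too small for the requested peak width")
    centers: list[tuple[int, int]] = []
    attempts = 0
    max_attempts = 1000 * max(config.n_peaks, 1)
    while len(centers) < config.n_peaks:
        if attempts >= max_attempts:
            raise ValueError(
                f"could not place {config.n_peaks} peaks with min_separation="
                f"{config.min_separation} on a {config.n_scans}x{config.n_bins} grid"
            )
        attempts += 1
        r = int(rng.integers(margin, config.n_scans - margin))
        c = int(rng.integers(margin, config.n_bins - margin))
        if all(math.hypot(r - r0, c - c0) >= config.min_separation for r0, c0 in centers):
            centers.append((r, c))
    lo, hi = config.peak_amplitude_range
    amps = rng.uniform(lo, hi, size=config.n_peaks)
    n_mod = max(1, config.n_peaks // 3) if config.n_peaks else 0
    mod = rng.choice(config.n_peaks, size=n_mod, replace=False) if n_mod else np.array([], dtype=int)
    return _Layout(
        centers=np.array(centers, dtype=int).reshape(-1, 2),
        base_amplitudes=amps,
        modulated_ids=np.sort(mod),
    )


def _render(
    config: SyntheticConfig,
    layout: _Layout,
    amplitudes: np.ndarray,
    label: str,
    rng: np.random.Generator,
    sample_id: str,
) -> tuple[MassSpecMatrix, GroundTruth]:
    values = np.zeros((config.n_scans, config.n_bins), dtype=np.float64)
    reach_r = int(math.ceil(4 * config.peak_sigma_rt))
    reach_c = int(math.ceil(4 * config.peak_sigma_mz))
    for (r, c), amp in zip(layout.centers, amplitudes):
        r0, r1 = max(r - reach_r, 0), min(r + reach_r + 1, config.n_scans)
        c0, c1 = max(c - reach_c, 0), min(c + reach_c + 1, config.n_bins)
        dr = (np.arange(r0, r1) - r)[:, None]
        dc = (np.arange(c0, c1) - c)[None, :]
        values[r0:r1, c0:c1] += amp * np.exp(
            -(dr**2) / (2 * config.peak_sigma_rt**2) - (dc**2) / (2 * config.peak_sigma_mz**2)
        )
    if config.noise_density > 0 and config.noise_amplitude > 0:
        n_noise = rng.binomial(values.size, config.noise_density)
        if n_noise:
            flat = rng.choice(values.size, size=n_noise, replace=False)
            values.ravel()[flat] += rng.uniform(0, config.noise_amplitude, size=n_noise)
    np.clip(values, 0.0, 1.0, out=values)
    matrix = MassSpecMatrix(
        values=values,
        binning=config.binning(),
        rt_axis=np.arange(config.n_scans, dtype=np.float64),
        normalized=True,
        sample_id=sample_id,
        label=label,
    )
    truth = GroundTruth(
        peak_centers=[(int(r), int(c)) for r, c in layout.centers],
        amplitudes=[float(a) for a in amplitudes],
        modulated_ids=[int(i) for i in layout.modulated_ids],
        label=label,
    )
    return matrix, truth


def _effective_amplitudes(config: SyntheticConfig, layout: _Layout, label: str) -> np.ndarray:
    amps = layout.base_amplitudes.copy()
    if label == POSITIVE_LABEL and len(layout.modulated_ids):
        amps[layout.modulated_ids] *= config.class_effect
    return amps


def generate_sample(
    config: SyntheticConfig, label: str = NEGATIVE_LABEL, seed: int | None = None
) -> tuple[MassSpecMatrix, GroundTruth]:
    """Generate one matrix and its ground truth; identical seed → identical bytes."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    layout = _draw_layout(config, rng)
    amps = _effective_amplitudes(config, layout, label)
    return _render(config, layout, amps, label, rng, sample_id=f"synthetic-{label}")


def generate_dataset(
    config: SyntheticConfig, n_per_class: int, seed: int | None = None
) -> list[tuple[MassSpecMatrix, GroundTruth]]:
    """Balanced two-class corpus sharing one peak layout.

    The layout (centers, base amplitudes, modulated peak ids) is drawn once;
    each sample applies its own uniform(0.8, 1.2) per-peak amplitude jitter
    and fresh noise.  Positive-class samples additionally scale the modulated
    peaks by ``class_effect``.  Samples alternate control/case so slicing a
    prefix stays balanced.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    layout = _draw_layout(config, rng)
    samples: list[tuple[MassSpecMatrix, GroundTruth]] = []
    for k in range(n_per_class):
        for label in (NEGATIVE_LABEL, POSITIVE_LABEL):
            jitter = rng.uniform(0.8, 1.2, size=config.n_peaks)
            amps = _effective_amplitudes(config, layout, label) * jitter
            matrix, truth = _render(config, layout, amps, label, rng, sample_id=f"{label}_{k:03d}")
            samples.append((matrix, truth))
    return samples


# -- mzML fixture writing ---------------------------------------------------

_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0" id="{run_id}">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="http://ontologies.berkeleybop.org/uo.obo"/>
  </cvList>
  <run id="{run_id}">
    <spectrumList count="{n}">
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _binary_array(data: np.ndarray, accession: str, name: str) -> str:
    import base64

    raw = np.asarray(data, dtype="<f8").tobytes()
    b64 = base64.b64encode(raw).decode("ascii")
    return (
        f'          <binaryDataArray encodedLength="{len(b64)}">\n'
        f'            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
        f'            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
        f'            <cvParam cvRef="MS" accession="{accession}" name="{name}" value=""/>\n'
        f"            <binary>{b64}</binary>\n"
        f"          </binaryDataArray>\n"
    )


def write_mzml_fixture(matrix: MassSpecMatrix, path: str | Path) -> None:
    """Serialize a matrix as a minimal centroid mzML file.

    One MS1 spectrum per matrix row; every non-zero cell becomes an ion at
    the bin's center m/z with the cell value as intensity.  Rebinning the
    file with the same grid reproduces the matrix (each center falls back
    into its own bin).  Arrays are little-endian 64-bit floats, base64,
    uncompressed — the simplest profile any mzML reader accepts.
    """
    path = Path(path)
    binning = matrix.binning
    parts: list[str] = [_MZML_HEADER.format(run_id=matrix.sample_id or "synthetic", n=matrix.shape[0])]
    for row in range(matrix.shape[0]):
        cols = np.flatnonzero(matrix.values[row])
        mz = binning.bin_center(cols).astype(np.float64)
        inten = matrix.values[row, cols]
        rt = float(matrix.rt_axis[row])
        parts.append(
            f'      <spectrum index="{row}" id="scan={row + 1}" defaultArrayLength="{len(cols)}">\n'
            f'        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>\n'
            f'        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>\n'
            f'        <scanList count="1">\n'
            f"          <scan>\n"
            f'            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt!r}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>\n'
            f"          </scan>\n"
            f"        </scanList>\n"
            f'        <binaryDataArrayList count="2">\n'
            + _binary_array(mz, "MS:1000514", "m/z array")
            + _binary_array(inten, "MS:1000515", "intensity array")
            + "        </binaryDataArrayList>\n"
            "      </spectrum>\n"
        )
    parts.append(_MZML_FOOTER)
    path.write_text("".join(parts), encoding="utf-8")
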