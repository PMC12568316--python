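"""Read LC-MS runs and convert them into normalized 2-D mass-spec matrices.

An LC-MS run is a sequence of scans; each scan carries a retention time and
two parallel arrays (m/z values, ion intensities).  The run is rasterized
onto a fixed m/z grid: ion *j* of a scan lands in bin

    i = floor((mz_j - mz_min) / bin_size)

and intensities falling into the same bin are summed.  Stacking the binned
scans row by row yields a matrix of shape ``(n_scans, n_bins)`` — the raw
"mass-spec image".  Intensities are then rescaled so that the 99.9th
percentile of the non-zero values maps to 1, and clipped to [0, 1].
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import h5py
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Scan",
    "SpectrumList",
    "BinningSpec",
    "MassSpecMatrix",
    "mz_bin_index",
    "build_mass_spec_matrix",
    "normalize_matrix",
    "read_mzml",
    "save_matrix",
    "load_matrix",
]


class Scan(NamedTuple):
    """One spectrum: retention time (seconds) plus parallel m/z / intensity arrays."""

    retention_time: float
    mz_values: np.ndarray
    intensities: np.ndarray


@dataclass
class SpectrumList:
    """Ordered scans of a single LC-MS run.

    Invariants: retention times strictly increasing, parallel arrays of equal
    length per scan, non-negative intensities.  ``validate()`` enforces them.
    """

    scans: list[Scan]
    source_id: str = ""

    def validate(self) -> "SpectrumList":
        rts = [s.retention_time for s in self.scans]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("retention times must be strictly increasing")
        for s in self.scans:
            if len(s.mz_values) != len(s.intensities):
                raise ValueError("mz_values and intensities must have equal length")
            if np.any(np.asarray(s.intensities) < 0):
                raise ValueError("intensities must be non-negative")
        return self

    def __len__(self) -> int:
        return len(self.scans)


@dataclass(frozen=True)
class BinningSpec:
    """m/z grid: half-open range [mz_min, mz_max) divided into bins of bin_size Da."""

    mz_min: float
    mz_max: float
    bin_size: float

    def __post_init__(self) -> None:
        if self.mz_max <= self.mz_min:
            raise ValueError("mz_max must exceed mz_min")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")

    @property
    def n_bins(self) -> int:
        # tolerance guards the ceiling against float noise when the range is
        # an exact multiple of the bin size (e.g. (106.4-100)/0.1 -> 64.00000000000006)
        return math.ceil((self.mz_max - self.mz_min) / self.bin_size - 1e-9)

    def bin_center(self, i: int | np.ndarray) -> float | np.ndarray:
        return self.mz_min + (np.asarray(i) + 0.5) * self.bin_size


@dataclass
class MassSpecMatrix:
    """2-D intensity grid: rows = scans (retention time order), cols = m/z bins."""

    values: np.ndarray
    binning: BinningSpec
    rt_axis: np.ndarray = field(default=None)  # type: ignore[assignment]
    normalized: bool = False
    sample_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (n_scans, n_bins)")
        if np.any(self.values < 0):
            raise ValueError("intensities must be non-negative")
        if self.rt_axis is None:
            self.rt_axis = np.arange(self.values.shape[0], dtype=np.float64)
        self.rt_axis = np.asarray(self.rt_axis, dtype=np.float64)
        if self.rt_axis.shape != (self.values.shape[0],):
            raise ValueError("rt_axis length must equal the number of scans")
        if self.normalized and self.values.size and self.values.max() > 1.0:
            raise ValueError("normalized matrix must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


def mz_bin_index(mz: float, spec: BinningSpec) -> int:
    """Map an m/z value to its bin index ``floor((mz - mz_min)/bin_size)``.

    Raises ``ValueError`` for m/z outside ``[mz_min, mz_max)``; the grid is
    undefined there and callers normally drop such ions.
    """
    if not (spec.mz_min <= mz < spec.mz_max):
        raise ValueError(f"m/z {mz} outside binning range [{spec.mz_min}, {spec.mz_max})")
    return int(math.floor((mz - spec.mz_min) / spec.bin_size))


def build_mass_spec_matrix(
    spectra: SpectrumList, spec: BinningSpec, *, sample_id: str | None = None
) -> MassSpecMatrix:
    """Rasterize a run onto the m/z grid; same-bin intensities are summed.

    Rows follow retention-time order (scans re-sorted if the source was
    unsorted; ties keep file order).  Ions outside the m/z range are dropped
    and counted in a log message.  Scans with no ions yield all-zero rows so
    the row index always equals the scan index.
    """
    if not spectra.scans:
        raise ValueError("cannot build a matrix from an empty scan list")
    order = sorted(range(len(spectra.scans)), key=lambda k: spectra.scans[k].retention_time)
    n_bins = spec.n_bins
    values = np.zeros((len(spectra.scans), n_bins), dtype=np.float64)
    rt_axis = np.empty(len(spectra.scans), dtype=np.float64)
    n_dropped = 0
    for row, k in enumerate(order):
        scan = spectra.scans[k]
        rt_axis[row] = scan.retention_time
        mz = np.asarray(scan.mz_values, dtype=np.float64)
        inten = np.asarray(scan.intensities, dtype=np.float64)
        if mz.size == 0:
            continue
        in_range = (mz >= spec.mz_min) & (mz < spec.mz_max)
        n_dropped += int(mz.size - in_range.sum())
        idx = np.floor((mz[in_range] - spec.mz_min) / spec.bin_size).astype(np.intp)
        np.add.at(values[row], idx, inten[in_range])
    if n_dropped:
        logger.info("dropped %d ions outside m/z range [%g, %g)", n_dropped, spec.mz_min, spec.mz_max)
    return MassSpecMatrix(
        values=values,
        binning=spec,
        rt_axis=rt_axis,
        normalized=False,
        sample_id=sample_id if sample_id is not None else spectra.source_id,
    )


def normalize_matrix(matrix: MassSpecMatrix, percentile: float = 99.9) -> MassSpecMatrix:
    """Scale intensities so the given percentile of non-zero values maps to 1.

    The scale is the *lower* empirical order statistic at the requested
    percentile of the non-zero values (``np.percentile(..., method="lower")``),
    i.e. an actually observed intensity.  Values are divided by it and clipped
    to [0, 1]; zeros stay exactly zero.  Anchoring the scale at an observed
    value makes the contract "the chosen percentile of the normalized non-zero
    values equals 1" hold exactly, independent of how densely the upper tail
    is sampled.
    """
    if matrix.normalized:
        raise ValueError("matrix is already normalized")
    nz = matrix.values[matrix.values > 0]
    if nz.size == 0:
        warnings.warn("all-zero matrix: normalization is a no-op", RuntimeWarning, stacklevel=2)
        return replace(matrix, values=matrix.values.copy(), normalized=True)
    scale = float(np.percentile(nz, percentile, method="lower"))
    out = np.clip(matrix.values / scale, 0.0, 1.0)
    return replace(matrix, values=out, normalized=True)


# -- mzML reading -----------------------------------------------------------
#
# mzML is plain XML; the parts this pipeline needs (per-spectrum cvParams and
# base64-encoded binary arrays) are parsed directly with the stdlib streaming
# parser.  Accession-driven, namespace-agnostic; handles 32/64-bit floats,
# zlib or no compression, and minute/second retention-time units.

_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_START = "MS:1000016"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(bda_elem) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (array kind accession, float64 data)."""
    import base64
    import zlib

    dtype, compressed, kind, text = "<f8", False, None, ""
    for child in bda_elem.iter():
        name = _localname(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == _ACC_F32:
                dtype = "<f4"
            elif acc == _ACC_F64:
                dtype = "<f8"
            elif acc == _ACC_ZLIB:
                compressed = True
            elif acc in (_ACC_MZ_ARRAY, _ACC_INTENSITY_ARRAY):
                kind = acc
        elif name == "binary":
            text = child.text or ""
    raw = base64.b64decode(text)
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(np.float64)


def _parse_spectrum(elem) -> tuple[int, Scan]:
    """Extract (ms_level, Scan) from one <spectrum> element."""
    ms_level, rt = 1, 0.0
    mz = inten = np.empty(0)
    for child in elem.iter():
        name = _localname(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == _ACC_MS_LEVEL:
                ms_level = int(child.get("value", 1))
            elif acc == _ACC_SCAN_START:
                rt = float(child.get("value", 0.0))
                unit = (child.get("unitName") or "").lower()
                if "minute" in unit:
                    rt *= 60.0
        elif name == "binaryDataArray":
            kind, data = _decode_binary_array(child)
            if kind == _ACC_MZ_ARRAY:
                mz = data
            elif kind == _ACC_INTENSITY_ARRAY:
                inten = data
    return ms_level, Scan(retention_time=rt, mz_values=mz, intensities=inten)


def read_mzml(path: str | Path, *, ms_level: int | None = 1) -> SpectrumList:
    """Load an mzML file into a :class:`SpectrumList`.

    Only MS1 scans are kept by default (``ms_level=None`` keeps every level).
    Scans are re-sorted by retention time; retention times are reported in
    seconds regardless of the unit used in the file.
    """
    from xml.etree.ElementTree import iterparse

    scans: list[Scan] = []
    for _event, elem in iterparse(str(path), events=("end",)):
        if _localname(elem.tag) != "spectrum":
            continue
        level, scan = _parse_spectrum(elem)
        if ms_level is None or level == ms_level:
            scans.append(scan)
        elem.clear()
    scans.sort(key=lambda s: s.retention_time)
    return SpectrumList(scans=scans, source_id=Path(path).stem)


# -- HDF5 persistence -------------------------------------------------------

def save_matrix(matrix: MassSpecMatrix, path: str | Path) -> None:
    """Write a matrix plus its binning metadata to an HDF5 file."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("matrix", data=matrix.values, compression="gzip")
        f.create_dataset("rt_axis", data=matrix.rt_axis)
        d.attrs["mz_min"] = matrix.binning.mz_min
        d.attrs["mz_max"] = matrix.binning.mz_max
        d.attrs["bin_size"] = matrix.binning.bin_size
        d.attrs["normalized"] = bool(matrix.normalized)
        d.attrs["sample_id"] = matrix.sample_id
        if matrix.label is not None:
            d.attrs["label"] = matrix.label


def load_matrix(path: str | Path) -> MassSpecMatrix:
    """Read a matrix written by :func:`save_matrix`."""
    with h5py.File(path, "r") as f:
        d = f["matrix"]
        binning = BinningSpec(
            mz_min=float(d.attrs["mz_min"]),
            mz_max=float(d.attrs["mz_max"]),
            bin_size=float(d.attrs["bin_size"]),
        )
        label = d.attrs.get("label")
        return MassSpecMatrix(
            values=d[()],
            binning=binning,
            rt_axis=f["rt_axis"][()] if "rt_axis" in f else None,
            normalized=bool(d.attrs.get("normalized", False)),
            sample_id=str(d.attrs.get("sample_id", Path(path).stem)),
            label=str(label) if label is not None else None,
        )
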