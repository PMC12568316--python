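"""Serialize a fitted transformer as a diffable JSON model artifact.

The artifact freezes everything transform needs — binning, thresholds,
patch geometry, the golden locations with their mean entropies — so a model
file alone suffices to image new runs; no training data is touched at
transform time.  The timestamp is the only field excluded from the config
hash, keeping re-runs byte-comparable.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

from .estimator import MsimgTransformer
from .spectra_io import BinningSpec

__all__ = ["model_to_dict", "model_from_dict", "save_model", "load_model"]


def _tool_version() -> str:
    try:
        return version("msimg")
    except PackageNotFoundError:
        return "unknown"


def model_to_dict(est: MsimgTransformer, *, timestamp: str | None = None) -> dict:
    """Freeze a fitted transformer into a plain dict (JSON-ready)."""
    est._check_fitted()
    payload = {
        "params": est.get_params(),
        "binning": (
            None
            if est.binning_ is None
            else {
                "mz_min": est.binning_.mz_min,
                "mz_max": est.binning_.mz_max,
                "bin_size": est.binning_.bin_size,
            }
        ),
        "matrix_shape": list(est.matrix_shape_),
        "radius_r": est.radius_,
        "n_pooled_peaks": est.n_pooled_peaks_,
        "candidate_centers": [list(c) for c in est.candidate_centers_],
        "candidate_scores": est.candidate_scores_,
        "golden_locations": [list(c) for c in est.golden_locations_],
        "mean_entropies": est.mean_entropies_,
        "tool_version": _tool_version(),
    }
    payload["config_hash"] = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]
    payload["created"] = timestamp or _dt.datetime.now(_dt.timezone.utc).isoformat()
    return payload


def model_from_dict(payload: dict) -> MsimgTransformer:
    """Rebuild a fitted transformer from a model dict."""
    est = MsimgTransformer(**payload["params"])
    b = payload.get("binning")
    est.binning_ = None if b is None else BinningSpec(**b)
    est.matrix_shape_ = tuple(payload["matrix_shape"])
    est.radius_ = float(payload["radius_r"])
    est.n_pooled_peaks_ = int(payload["n_pooled_peaks"])
    est.candidate_centers_ = [tuple(c) for c in payload["candidate_centers"]]
    est.candidate_scores_ = payload.get("candidate_scores")
    est.golden_locations_ = [tuple(c) for c in payload["golden_locations"]]
    est.mean_entropies_ = [float(e) for e in payload["mean_entropies"]]
    return est


def save_model(est: MsimgTransformer, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(est), indent=2, sort_keys=True))


def load_model(path: str | Path) -> MsimgTransformer:
    return model_from_dict(json.loads(Path(path).read_text()))
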