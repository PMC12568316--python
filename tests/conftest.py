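import numpy as np
import pytest

from msimg import BinningSpec, MassSpecMatrix, SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20250929)


@pytest.fixture
def binning():
    return BinningSpec(mz_min=100.0, mz_max=200.0, bin_size=0.1)


def make_normalized(values, **kw):
    """Wrap a [0,1] array as a normalized MassSpecMatrix with a nominal grid."""
    values = np.asarray(values, dtype=np.float64)
    spec = BinningSpec(mz_min=0.0, mz_max=float(values.shape[1]), bin_size=1.0)
    return MassSpecMatrix(values=values, binning=spec, normalized=True, **kw)


@pytest.fixture(scope="session")
def small_corpus():
    """Two-class corpus small enough for unit tests (8+8 samples, 128x128)."""
    cfg = SyntheticConfig(
        n_scans=128, n_bins=128, n_peaks=6, min_separation=36.0, class_effect=2.5, seed=5
    )
    return generate_dataset(cfg, 8, seed=5)
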