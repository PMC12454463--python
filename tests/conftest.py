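import numpy as np
import pytest

from pancdwi import (
    DwiDataset,
    GradientScheme,
    PhantomSpec,
    TissueTruth,
    simulate_dataset,
)
from pancdwi.phantom import make_direction_set


def scheme_two_shell(n_dirs: int = 6, shells=(200.0, 1000.0)) -> GradientScheme:
    """Directional two-shell scheme without b=0 (perfusion-suppressed range)."""
    dirs = make_direction_set(n_dirs)
    bvals = np.repeat(shells, n_dirs)
    bvecs = np.tile(dirs, (len(shells), 1))
    return GradientScheme(bvals, bvecs, np.ones(len(bvals), dtype=int))


def tensor_signals(scheme: GradientScheme, D: np.ndarray, s0: float = 1000.0,
                   shape=(2, 2, 1)) -> DwiDataset:
    """Noiseless tensor-model signals replicated over a small grid."""
    dapp = np.einsum("ni,ij,nj->n", scheme.bvecs, D, scheme.bvecs)
    series = s0 * np.exp(-scheme.bvals * dapp)
    sig = np.broadcast_to(series, shape + series.shape).copy()
    return DwiDataset(signal=sig, scheme=scheme)


@pytest.fixture(scope="session")
def noiseless_spec() -> PhantomSpec:
    """Noise-free, kurtosis-free, perfusion-free phantom: the exactness regime."""
    return PhantomSpec(
        grid=(32, 32, 6),
        snr=np.inf,
        pancreas=TissueTruth(ad=1.3e-3, rd=0.85e-3, mk=0.0, s0=100.0),
        body=TissueTruth(ad=1.2e-3, rd=1.05e-3, mk=0.0, s0=80.0),
    )


@pytest.fixture(scope="session")
def noiseless_acquisition(noiseless_spec):
    return simulate_dataset(noiseless_spec, subject=0, repeat=0)
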