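import numpy as np
import pytest

import pcadenoise as pcd


@pytest.fixture(scope="session")
def protocol():
    return pcd.make_protocol(seed=0)


@pytest.fixture(scope="session")
def clean_phantom(protocol):
    """Noise-free 12x12 phantom under the default study protocol (N=110)."""
    return pcd.build_phantom(protocol=protocol)


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)


def spectrum_from(lam, M):
    """EigenSpectrum wrapper for a hand-specified ascending eigenvalue list."""
    lam = np.asarray(lam, dtype=float)
    return pcd.EigenSpectrum(eigenvalues=lam, eigenvectors=np.eye(len(lam)),
                             M=M, N=len(lam))
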