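import numpy as np
import pytest

from rotaphot.conformers import Conformer
from rotaphot.synthetic import gen_conformer_ensemble, gen_dpbf_trace, gen_tcspc


@pytest.fixture
def noise_free_trace():
    """Exact exponential: phi=0.72, c=1e-3, k_bg=1e-4 -> rate 8.2e-4 s^-1."""
    return gen_dpbf_trace(0.72, phi_ref_rate_constant=1e-3, k_background=1e-4,
                          n_points=30, dt=30.0, noise_level=0.0)


@pytest.fixture
def biexp_histogram():
    """Seeded Poisson histogram with truth (1.76 ns, 19%) + (0.50 ns, 81%)."""
    return gen_tcspc([(1.76, 0.19), (0.50, 0.81)], seed=42, peak_counts=1e4)


@pytest.fixture
def labelled_ensemble():
    return gen_conformer_ensemble((10, 10, 10), seed=1, kind="protonated")


@pytest.fixture
def toy_porphyrin():
    """Minimal Zn porphyrin core: Zn at origin, four pyrrole N, empty axial site."""
    elements = ["Zn", "N", "N", "N", "N"]
    coords = np.array([
        [0.0, 0.0, 0.0],
        [2.05, 0.0, 0.0], [-2.05, 0.0, 0.0], [0.0, 2.05, 0.0], [0.0, -2.05, 0.0],
    ])
    return Conformer(elements, coords, label="core")
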