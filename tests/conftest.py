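import numpy as np
import pytest

import protqa as pq


@pytest.fixture(scope="session")
def ideal_helix():
    """30-residue poly-ALA alpha helix at (phi, psi) = (-57, -47)."""
    return pq.build_chain("A" * 30, (-57.0, -47.0), structure_id="helix")


@pytest.fixture(scope="session")
def mixed_native():
    """A synthetic native with mixed helix/strand/coil topology."""
    return pq.make_native(70, seed=11, structure_id="native70")


@pytest.fixture(scope="session")
def small_tables():
    """Preference tables learned from a small synthetic reference set."""
    refs = [pq.make_native(60, seed=100 + s, structure_id=f"ref{s}")
            for s in range(6)]
    return pq.build_preference_tables(refs)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A uniform random proper rotation matrix (QR-based)."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
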