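import numpy as np
import pytest

from tmdkit.energy import LipophilicityTable
from tmdkit.geometry import CrickParams, HelixBundle, build_symmetric_bundle


@pytest.fixture(scope="session")
def lipo_table():
    return LipophilicityTable.default()


@pytest.fixture(scope="session")
def dimer_bundle():
    """A tightly packed poly-Leu C2 bundle."""
    params = CrickParams(n_chains=2, superhelical_radius=5.0, tilt=15.0)
    return build_symmetric_bundle(params, "L" * 24)


@pytest.fixture(scope="session")
def trimer_bundle():
    params = CrickParams(n_chains=3, superhelical_radius=5.5, tilt=15.0)
    return build_symmetric_bundle(params, "L" * 24)


@pytest.fixture
def far_apart_dimer():
    """Two poly-Leu helices separated by 100 Angstrom (no contacts)."""
    mono = build_symmetric_bundle(
        CrickParams(n_chains=1, tilt=0.0), "L" * 24
    )
    chain = mono.coords[0]
    coords = np.stack([chain, chain + np.array([100.0, 0.0, 0.0])])
    return HelixBundle(coords, ["L" * 24] * 2, 2)


def toy_bundle(chain_coords, sequences):
    """Bundle straight from coordinate arrays (no geometry constraints)."""
    return HelixBundle(np.asarray(chain_coords, dtype=float), sequences, len(sequences))
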