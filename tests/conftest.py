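import os

import numpy as np
import pytest

from qdma.io_formats import Geometry, GaussianShell, WavefunctionData

FIXTURE_DIR = os.path.join(os.path.dirname(__file__), "..", "src", "qdma",
                           "data", "fchk")


def fixture_path(prefix: str) -> str:
    """Bundled fchk fixture whose filename starts with `prefix`."""
    names = sorted(n for n in os.listdir(FIXTURE_DIR)
                   if n.startswith(prefix) and n.endswith(".fchk"))
    if not names:
        raise FileNotFoundError(f"no bundled fixture matching {prefix}*")
    return os.path.join(FIXTURE_DIR, names[0])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def small_wfn(rng):
    """Two-center synthetic wavefunction with s, p (cart) and d (pure)
    shells and a random symmetric 'density'; exercises every integral
    path without needing an SCF."""
    geo = Geometry.from_arrays(["O", "H"], [[0.0, 0.0, 0.1], [0.0, 0.7, -0.4]])
    shells = [
        GaussianShell(0, 0, [(130.7, 0.15), (23.8, 0.54), (6.44, 0.44)]),
        GaussianShell(0, 1, [(5.03, 0.16), (1.17, 0.61), (0.38, 0.39)],
                      pure=False),
        GaussianShell(0, 2, [(0.9, 1.0)], pure=True),
        GaussianShell(1, 0, [(3.43, 0.15), (0.62, 0.53), (0.17, 0.44)]),
        GaussianShell(1, 1, [(0.8, 1.0)], pure=False),
    ]
    nao = 1 + 3 + 5 + 1 + 3
    a = rng.normal(size=(nao, nao))
    dm = (a + a.T) / 6.0
    return WavefunctionData(geo, shells, dm, "SCF")


@pytest.fixture(scope="session")
def benzene_sto3g():
    """Bundled benzene SCF/STO-3G wavefunction."""
    from qdma.io_formats import read_fchk
    return read_fchk(fixture_path("benzene_scf"), density_choice="SCF")
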