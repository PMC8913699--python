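"""Shared fixtures: toy complexes, simulated profiles, tiny PDB text."""

import numpy as np
import pytest

from contrast_screen import (ContrastSpec, NoiseSpec, ToySpec,
                             make_toy_complex, simulate_experiment)
from contrast_screen.structures_io import BeadModel
from contrast_screen.synthetic_data import DEFAULT_CONTRAST


def make_beads(xyz, resname="ALA", component="A", domain="", chain="A",
               mass=None, deuteration=0.0):
    """Minimal bead model around a coordinate array."""
    xyz = np.asarray(xyz, float).reshape(-1, 3)
    n = len(xyz)
    return BeadModel(xyz, np.full(n, resname, object), np.arange(1, n + 1),
                     np.full(n, chain, object),
                     np.full(n, 71.08 if mass is None else mass, float),
                     np.full(n, component, object),
                     np.full(n, domain, object),
                     np.full(n, deuteration, float))


@pytest.fixture(scope="session")
def toy():
    """Default ground-truth toy complex: (truth, core, templates)."""
    return make_toy_complex(ToySpec())


@pytest.fixture(scope="session")
def small_toy():
    """Down-scaled toy (~310 beads) for trajectory-heavy tests."""
    spec = ToySpec(core_beads=10, b_beads=6, ca_beads=5, n_beads=8, seed=11)
    return make_toy_complex(spec)


@pytest.fixture(scope="session")
def toy_profiles(toy):
    """Simulated SAXS and iCM-SANS experiments of the default truth."""
    truth, _, _ = toy
    saxs = simulate_experiment(truth, "xray", noise=NoiseSpec(seed=101))
    sans = simulate_experiment(truth, "sans", contrast=DEFAULT_CONTRAST,
                               noise=NoiseSpec(seed=102))
    return saxs, sans


@pytest.fixture(scope="session")
def contrast_icm():
    return DEFAULT_CONTRAST


THREE_RES_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.450   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.300   2.400   0.000  1.00  0.00           O
ATOM      5  N   TRP A   2       3.300   1.500   0.000  1.00  0.00           N
ATOM      6  CA  TRP A   2       4.000   2.800   0.000  1.00  0.00           C
ATOM      7  C   TRP A   2       5.500   2.600   0.000  1.00  0.00           C
ATOM      8  O   TRP A   2       6.000   1.500   0.000  1.00  0.00           O
ATOM      9  N   ALA A   3       6.200   3.700   0.000  1.00  0.00           N
ATOM     10  CA  ALA A   3       7.650   3.700   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def three_res_pdb():
    return THREE_RES_PDB
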