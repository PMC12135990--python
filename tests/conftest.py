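"""Shared fixtures: toy structures and a cached Monte Carlo pool.

Everything is generated programmatically; the Monte Carlo pool is
session-scoped because sampling a few hundred conformers is the expensive
step shared by the sampler, pool-reduction and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from flexsaxs import (
    FlexibleRegion,
    MCConfig,
    ToySpec,
    build_toy_chain,
    detect_flexible_regions,
    run_mc,
)
from flexsaxs.elements import atomic_mass, electrons
from flexsaxs.structure import Atom, Structure

# a minimal hand-written two-residue PDB (confidence 91.50 on residue 1)
TWO_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 91.50           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 91.50           C
ATOM      3  C   ALA A   1       2.004   1.420   0.000  1.00 91.50           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00 91.50           O
ATOM      5  N   GLY A   2       3.332   1.536   0.000  1.00 45.20           N
ATOM      6  CA  GLY A   2       3.953   2.850   0.000  1.00 45.20           C
ATOM      7  C   GLY A   2       5.470   2.750   0.000  1.00 45.20           C
ATOM      8  O   GLY A   2       6.090   1.690   0.000  1.00 45.20           O
END
"""


def make_atoms(coords, element="C", names=None, residue_index=None):
    """Quick synthetic structure from bare coordinates."""
    coords = np.asarray(coords, dtype=float)
    atoms = []
    for i, xyz in enumerate(coords):
        el = element if isinstance(element, str) else element[i]
        atoms.append(
            Atom(
                name=names[i] if names else f"X{i + 1}",
                element=el,
                electrons=electrons(el),
                mass=atomic_mass(el),
                residue_index=residue_index[i] if residue_index else i + 1,
                residue_name="UNK",
                coords=xyz,
            )
        )
    return Structure(atoms)


@pytest.fixture(scope="session")
def toy_spec():
    return ToySpec()


@pytest.fixture(scope="session")
def toy_chain(toy_spec):
    return build_toy_chain(toy_spec)


@pytest.fixture(scope="session")
def toy_regions(toy_chain):
    return detect_flexible_regions(toy_chain.residue_confidence(), threshold=60)


@pytest.fixture(scope="session")
def align_range():
    return FlexibleRegion(1, 20)


@pytest.fixture(scope="session")
def mc_config(align_range):
    return MCConfig(trial_attempts=800, align_range=align_range, seed=7)


@pytest.fixture(scope="session")
def mc_pool(toy_chain, toy_regions, mc_config):
    """~700 accepted conformers of the toy chain; shared across tests."""
    return run_mc(toy_chain, toy_regions, mc_config)


@pytest.fixture
def two_residue_pdb(tmp_path):
    path = tmp_path / "two_res.pdb"
    path.write_text(TWO_RESIDUE_PDB)
    return path
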