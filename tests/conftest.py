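"""Shared fixtures: the synthetic toy complex and small helpers."""

import numpy as np
import pytest

from airdock import build_topology, make_toy_dimer
from airdock.build import EXTENDED, build_peptide


@pytest.fixture(scope="session")
def toy():
    """The seed-0 toy receptor-ligand complex (built once per session)."""
    return make_toy_dimer(0)


@pytest.fixture(scope="session")
def toy_topology(toy):
    return build_topology(toy.reference)


@pytest.fixture(scope="session")
def tripeptide():
    """A 3-residue extended peptide (GLY-ALA-SER)."""
    return build_peptide(["GLY", "ALA", "SER"], conformation=EXTENDED)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
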