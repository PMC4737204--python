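import numpy as np
import pytest

from capsidkit.energetics import SolvationParams
from capsidkit.ensemble_synth import (ToyCapsidParams, generate_toy_capsid,
                                      reference_toy_capsid)
from capsidkit.structure_io import Atom, Chain, Residue, StructureModel


@pytest.fixture(scope="session")
def toy_params():
    return ToyCapsidParams()


@pytest.fixture(scope="session")
def toy_asu(toy_params):
    """Asymmetric unit: one C5-symmetric pentamer with I23 cell metadata."""
    return generate_toy_capsid(toy_params)


@pytest.fixture(scope="session")
def toy_capsid(toy_params):
    """One complete 12-pentamer capsid from the icosahedral orbit."""
    return reference_toy_capsid(toy_params)


@pytest.fixture(scope="session")
def sparams():
    return SolvationParams()


@pytest.fixture(scope="session")
def fast_params():
    """Reduced sphere sampling for tests that only need the model's logic."""
    return SolvationParams(n_sphere_points=240)


def make_residue(name, number, atom_specs, serial_start=1):
    """Residue from (atom_name, element, xyz) triples."""
    atoms = [Atom(serial_start + i, an, el, np.array(xyz, dtype=float))
             for i, (an, el, xyz) in enumerate(atom_specs)]
    return Residue(name, number, atoms)


def make_structure(chain_specs, **kwargs):
    """StructureModel from {chain_id: [residues]}."""
    chains = [Chain(cid, residues) for cid, residues in chain_specs.items()]
    return StructureModel(chains, **kwargs)
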