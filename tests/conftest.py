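import numpy as np
import pytest

from powderdyn import (HydropathyTable, Topology, TRPCAGE_SEQUENCE,
                       make_topology)
from powderdyn.core_model import ATOMIC_MASSES, AtomRecord


@pytest.fixture(scope="session")
def trpcage_topology() -> Topology:
    """Two Trp-cage units built from the bundled residue templates."""
    return make_topology(TRPCAGE_SEQUENCE, n_proteins=2)


@pytest.fixture(scope="session")
def hydropathy() -> HydropathyTable:
    return HydropathyTable.eisenberg()


@pytest.fixture
def tiny_topology() -> Topology:
    """Five heavy atoms in one alanine-like residue; for brute-force oracles."""
    names = ["N", "CA", "C", "O", "CB"]
    elements = ["N", "C", "C", "O", "C"]
    atoms = [AtomRecord(atom_id=i + 1, name=n, element=e,
                        mass=ATOMIC_MASSES[e], residue_index=1,
                        residue_name="ALA", protein_index=0,
                        is_heavy=True, is_methyl_hydrogen=False)
             for i, (n, e) in enumerate(zip(names, elements))]
    return Topology(atoms, n_proteins=1, sequence="A")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
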