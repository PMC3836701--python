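import numpy as np
import pytest

from idpgo.structure import load_complex
from idpgo.synthetic import (ChainSpec, ToyComplexSpec, default_binding_toy,
                             make_toy_complex)
from idpgo.topology import (FlavoringScheme, GoTopology, build_topology)


@pytest.fixture(scope="session")
def toy_charged():
    """Charged two-helix binding toy: (pdb_text, ground_truth)."""
    return make_toy_complex(default_binding_toy(charged=True))


@pytest.fixture(scope="session")
def toy_structure(toy_charged):
    pdb_text, _ = toy_charged
    return load_complex(pdb_text)


@pytest.fixture(scope="session")
def toy_topology(toy_charged, toy_structure):
    """Uniform-flavored explicit-charge topology of the binding toy."""
    _, truth = toy_charged
    return build_topology(
        toy_structure, cutoff=truth["contact_cutoff"],
        min_seq_sep=truth["min_seq_sep"], contact_mode="ca",
        flavoring=FlavoringScheme.uniform(), base_epsilon=1.5,
        charge_mode="explicit")


@pytest.fixture(scope="session")
def helix_chain_topology():
    """Isolated 12-residue helix (single chain), used for calibration and
    helicity tests."""
    pdb_text, _ = make_toy_complex(
        ToyComplexSpec(chains=(ChainSpec("A", "H" * 12, "0" * 12),),
                       contact_cutoff=7.5))
    return build_topology(
        load_complex(pdb_text), cutoff=7.5, contact_mode="ca",
        flavoring=FlavoringScheme.uniform(), base_epsilon=1.0)


def make_pair_topology(eps: float = 4.0, r_native: float = 6.0,
                       bonded: bool = False) -> GoTopology:
    """Two particles joined by a single 12-10 contact (optionally by a
    rigid bond instead); no angles, dihedrals or charges."""
    from idpgo.topology import ContactRecord
    coords = np.array([[30.0, 30.0, 30.0], [30.0, 30.0, 30.0 + r_native]])
    if bonded:
        bonds = np.array([[0, 1]])
        blen = np.array([r_native])
        contacts = []
    else:
        bonds = np.zeros((0, 2), dtype=np.int64)
        blen = np.zeros(0)
        contacts = [ContactRecord(0, 1, r_native, eps, "intra:A")]
    return GoTopology(
        res_names=["ALA", "ALA"], masses=np.full(2, 110.0),
        charges=np.zeros(2), chain_index=np.zeros(2, dtype=np.int64),
        chain_ids=["A"], native_coords=coords,
        bonds=bonds, bond_lengths=blen,
        angles=np.zeros((0, 3), dtype=np.int64), angle_values=np.zeros(0),
        dihedrals=np.zeros((0, 4), dtype=np.int64),
        dihedral_values=np.zeros(0), contacts=contacts, eps_rep=0.0)
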