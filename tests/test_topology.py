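"""Go-topology construction: contacts, flavoring, charges, scaling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from idpgo.structure import load_complex
from idpgo.synthetic import ChainSpec, ToyComplexSpec, make_toy_complex
from idpgo.topology import (FlavoringScheme, GoTopology, assign_charges,
                            build_topology, flavor_contacts,
                            identify_native_contacts, scale_topology)


def test_contacts_match_brute_force_enumeration(toy_charged, toy_structure):
    """Contact identification equals the generator's independent O(n^2)
    all-pairs scan."""
    _, truth = toy_charged
    contacts = identify_native_contacts(
        toy_structure, cutoff=truth["contact_cutoff"],
        min_seq_sep=truth["min_seq_sep"], mode="ca")
    got = {(c.i, c.j): (c.kind, c.r_native) for c in contacts}
    chain_ids = truth["chain_ids"]
    expected = {}
    for rec in truth["contacts"]:
        kind = rec["kind"]
        expected[(rec["i"], rec["j"])] = (kind, rec["r_native"])
    assert set(got) == set(expected)
    for key in got:
        assert got[key][0] == expected[key][0]
        assert got[key][1] == pytest.approx(expected[key][1], abs=5e-3)


def test_contact_classes_partition_and_uniqueness(toy_topology):
    pairs = [(c.i, c.j) for c in toy_topology.contacts]
    assert len(pairs) == len(set(pairs))
    kinds = {c.kind for c in toy_topology.contacts}
    assert kinds <= {"inter", "intra:A", "intra:B"}
    assert len(toy_topology.intra_contacts) + len(toy_topology.inter_contacts) \
        == len(toy_topology.contacts)


def test_contact_set_symmetric_under_chain_order(toy_charged):
    """Swapping chain order permutes indices but preserves the contact set."""
    pdb_text, truth = toy_charged
    s_ab = load_complex(pdb_text, ["A", "B"])
    s_ba = load_complex(pdb_text, ["B", "A"])
    cut, sep = truth["contact_cutoff"], truth["min_seq_sep"]
    c_ab = identify_native_contacts(s_ab, cut, sep, "ca")
    c_ba = identify_native_contacts(s_ba, cut, sep, "ca")
    n_a, n_b = truth["chain_lengths"]

    def to_ab(i):
        return i - n_b if i >= n_b else i + n_a

    remapped = {tuple(sorted((to_ab(c.i), to_ab(c.j)))) for c in c_ba}
    assert remapped == {(c.i, c.j) for c in c_ab}


def test_distant_residues_never_contact():
    pdb_text, _ = make_toy_complex(ToyComplexSpec(chains=(
        ChainSpec("A", "HHHHH", "00000"),
        ChainSpec("B", "HHHHH", "00000", offset=(50.0, 0.0, 0.0)))))
    contacts = identify_native_contacts(load_complex(pdb_text), 7.5, 3, "ca")
    assert all(c.kind != "inter" for c in contacts)


@pytest.mark.parametrize("scheme", ["uniform", "default"])
def test_flavoring_mean_equals_base_epsilon(toy_structure, scheme):
    """Under mean normalization the average assigned depth is exactly the
    base depth (direct-averaging oracle)."""
    contacts = identify_native_contacts(toy_structure, 7.5, 3, "ca")
    flavoring = (FlavoringScheme.uniform() if scheme == "uniform"
                 else FlavoringScheme.default())
    res_names = toy_structure.res_names
    out = flavor_contacts(contacts, flavoring, 1.3, res_names)
    eps = np.array([c.epsilon for c in out])
    assert eps.mean() == pytest.approx(1.3, abs=1e-9)
    if scheme == "uniform":
        np.testing.assert_allclose(eps, 1.3)
    assert np.all(eps > 0)


def test_flavoring_zero_base(toy_structure):
    contacts = identify_native_contacts(toy_structure, 7.5, 3, "ca")
    out = flavor_contacts(contacts, FlavoringScheme.uniform(), 0.0,
                          toy_structure.res_names)
    assert all(c.epsilon == 0.0 for c in out)


def test_charge_assignment_kr_de_peptide():
    """K-R-D-E pattern gives (+1, +1, -1, -1), net zero."""
    pdb_text, _ = make_toy_complex(ToyComplexSpec(chains=(
        ChainSpec("A", "H" * 8, "0++--000"),)))
    top = build_topology(load_complex(pdb_text), cutoff=7.5,
                         contact_mode="ca",
                         flavoring=FlavoringScheme.uniform(),
                         charge_mode="explicit")
    np.testing.assert_array_equal(top.charges,
                                  [0, 1, 1, -1, -1, 0, 0, 0])
    assert top.net_charge() == 0


def test_uncharged_modes_and_balanced_nets(toy_charged, toy_topology):
    """Explicit charges match the designed pattern; 'none' zeroes all; a
    complex with equal +/- counts has zero net charge."""
    _, truth = toy_charged
    np.testing.assert_array_equal(toy_topology.charges, truth["charges"])
    assert toy_topology.net_charge() == sum(truth["net_charge_per_chain"])
    neutral = assign_charges(toy_topology, "none")
    assert np.all(neutral.charges == 0)
    # glycine-free uncharged fixture
    pdb_text, _ = make_toy_complex(ToyComplexSpec(chains=(
        ChainSpec("A", "HHHHHH", "000000"),)))
    top = build_topology(load_complex(pdb_text), cutoff=7.5,
                         contact_mode="ca",
                         flavoring=FlavoringScheme.uniform(),
                         charge_mode="explicit")
    assert np.all(top.charges == 0)


def test_scaling_identity_and_composition(toy_topology):
    eps0 = np.array([c.epsilon for c in toy_topology.contacts])
    same = scale_topology(toy_topology, 1.0, 1.0)
    np.testing.assert_array_equal(
        [c.epsilon for c in same.contacts], eps0)
    twice = scale_topology(scale_topology(toy_topology, 0.5, 1.0), 0.5, 1.0)
    intra = [k for k, c in enumerate(toy_topology.contacts) if not c.is_inter]
    np.testing.assert_allclose(
        np.array([c.epsilon for c in twice.contacts])[intra],
        0.25 * eps0[intra])


@settings(deadline=None, max_examples=25)
@given(li=st.floats(0.2, 4.0), le=st.floats(0.2, 4.0))
def test_scaling_inverts_exactly(toy_topology, li, le):
    """Applying (a, b) then (1/a, 1/b) restores every depth."""
    back = scale_topology(scale_topology(toy_topology, li, le),
                          1.0 / li, 1.0 / le)
    np.testing.assert_allclose(
        [c.epsilon for c in back.contacts],
        [c.epsilon for c in toy_topology.contacts], rtol=1e-12)


def test_scaling_rejects_nonpositive(toy_topology):
    with pytest.raises(ValueError):
        scale_topology(toy_topology, 0.0, 1.0)


def test_bonds_connect_consecutive_residues_only(toy_topology):
    chain = toy_topology.chain_index
    for (i, j) in toy_topology.bonds:
        assert j == i + 1 and chain[i] == chain[j]


def test_topology_json_roundtrip(tmp_path, toy_topology):
    path = tmp_path / "model.json"
    toy_topology.save(path)
    back = GoTopology.load(path)
    np.testing.assert_allclose(back.native_coords, toy_topology.native_coords)
    np.testing.assert_array_equal(back.charges, toy_topology.charges)
    assert [(c.i, c.j, c.kind) for c in back.contacts] == \
        [(c.i, c.j, c.kind) for c in toy_topology.contacts]
    assert back.lambda_inter == toy_topology.lambda_inter
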