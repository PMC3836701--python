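"""Reaction coordinates: contact fractions, counts, RMSD, separations."""

import numpy as np
import pytest

from idpgo.observables import (binding_rmsd, center_separation,
                               contact_formed, contact_probability_map,
                               fraction_native, native_contact_count,
                               nonspecific_contacts, pair_distances)

BOX = 60.0


@pytest.mark.parametrize("r, formed", [(7.9, True), (8.1, False),
                                       (5.9, False), (7.0, True)])
def test_contact_formation_tolerance(r, formed):
    """A native contact (r_native = 7.0) is formed iff within 1.0 A."""
    assert contact_formed(r, 7.0) is formed


def _toy_arrays(toy_topology):
    pairs, rnat, _ = toy_topology.contact_arrays("all")
    return pairs, rnat


def test_q_is_one_at_native_and_zero_when_separated(toy_topology):
    pairs, rnat = _toy_arrays(toy_topology)
    native = toy_topology.native_coords + 20.0
    assert fraction_native(native, pairs, rnat, BOX)[0] == 1.0
    ipairs, irnat, _ = toy_topology.contact_arrays("inter")
    far = native.copy()
    chain_b = toy_topology.chain_index == 1
    # displace chain B by (box/2, box/2, box/2): beyond any native distance
    far[chain_b] += 29.0
    assert fraction_native(far, ipairs, irnat, BOX)[0] == 0.0


def test_q_and_counts_match_brute_force(toy_topology):
    """Vectorized Q / N_inter equal a per-contact loop on random frames."""
    pairs, rnat = _toy_arrays(toy_topology)
    rng = np.random.default_rng(3)
    frames = (toy_topology.native_coords + 20.0
              + rng.normal(0, 1.5, (5, toy_topology.n_particles, 3)))
    q = fraction_native(frames, pairs, rnat, BOX)
    n = native_contact_count(frames, pairs, rnat, BOX)
    for f in range(5):
        formed = 0
        for (i, j), r0 in zip(pairs, rnat):
            d = frames[f, i] - frames[f, j]
            d -= BOX * np.rint(d / BOX)
            if abs(np.linalg.norm(d) - r0) <= 1.0:
                formed += 1
        assert n[f] == formed
        assert q[f] == pytest.approx(formed / len(pairs))


def test_q_non_increasing_when_tolerance_tightens(toy_topology):
    pairs, rnat = _toy_arrays(toy_topology)
    rng = np.random.default_rng(4)
    frames = (toy_topology.native_coords + 20.0
              + rng.normal(0, 1.0, (10, toy_topology.n_particles, 3)))
    q_loose = fraction_native(frames, pairs, rnat, BOX, tolerance=1.0)
    q_tight = fraction_native(frames, pairs, rnat, BOX, tolerance=0.5)
    assert np.all(q_tight <= q_loose)


def test_nonspecific_count_cutoff_and_brute_force():
    """Pairs at 9.9 A count, at 10.1 A do not; random frames match an
    all-pairs scan."""
    coords = np.zeros((1, 4, 3))
    coords[0, 1] = [3.8, 0, 0]
    coords[0, 2] = [3.8 + 9.9, 0, 0]        # 9.9 A from particle 1
    coords[0, 3] = [3.8 + 9.9, 3.8, 0]
    ga, gb = [0, 1], [2, 3]
    n = nonspecific_contacts(coords + 20.0, ga, gb, BOX)
    d12 = 9.9
    assert n[0] == 1 + (1 if np.hypot(d12, 3.8) <= 10 else 0)
    coords[0, 2, 0] = 3.8 + 10.1
    coords[0, 3, 0] = 3.8 + 10.1
    assert nonspecific_contacts(coords + 20.0, ga, [2], BOX)[0] == 0

    rng = np.random.default_rng(5)
    frames = rng.uniform(10, 40, (4, 12, 3))
    ga, gb = np.arange(6), np.arange(6, 12)
    got = nonspecific_contacts(frames, ga, gb, BOX)
    for f in range(4):
        cnt = 0
        for i in ga:
            for j in gb:
                d = frames[f, i] - frames[f, j]
                d -= BOX * np.rint(d / BOX)
                cnt += np.linalg.norm(d) <= 10.0
        assert got[f] == cnt


def test_nonspecific_excludes_native_pairs_on_request(toy_topology):
    ga = np.nonzero(toy_topology.chain_index == 0)[0]
    gb = np.nonzero(toy_topology.chain_index == 1)[0]
    ipairs, _, _ = toy_topology.contact_arrays("inter")
    native = toy_topology.native_coords[None] + 20.0
    with_native = nonspecific_contacts(native, ga, gb, BOX)
    without = nonspecific_contacts(native, ga, gb, BOX, exclude_pairs=ipairs)
    assert with_native[0] - without[0] == len(ipairs)


def test_binding_rmsd_zero_at_native_and_translation_oracle(toy_topology):
    native = toy_topology.native_coords
    ga = np.nonzero(toy_topology.chain_index == 0)[0]
    gb = np.nonzero(toy_topology.chain_index == 1)[0]
    assert binding_rmsd(native, native, ga, gb)[0] == pytest.approx(0, abs=1e-9)
    # rigid 5 A displacement of the IDP after perfect substrate alignment
    moved = native.copy()
    moved[gb] += [3.0, 4.0, 0.0]
    assert binding_rmsd(moved, native, ga, gb)[0] == pytest.approx(5.0, abs=1e-9)


def test_binding_rmsd_invariant_under_rigid_complex_transform(toy_topology):
    native = toy_topology.native_coords
    ga = np.nonzero(toy_topology.chain_index == 0)[0]
    gb = np.nonzero(toy_topology.chain_index == 1)[0]
    rng = np.random.default_rng(6)
    frame = native + rng.normal(0, 0.8, native.shape)
    base = binding_rmsd(frame, native, ga, gb)[0]
    theta = 0.9
    rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                    [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
    moved = frame @ rot.T + np.array([5.0, -3.0, 11.0])
    assert binding_rmsd(moved, native, ga, gb)[0] == pytest.approx(base, abs=1e-9)


def test_center_separation_arithmetic_and_pbc_bound():
    coords = np.zeros((1, 4, 3))
    coords[0, 0] = [10, 10, 10]
    coords[0, 1] = [12, 10, 10]
    coords[0, 2] = [36, 10, 10]
    coords[0, 3] = [38, 10, 10]
    r = center_separation(coords, [0, 1], [2, 3], BOX)
    assert r[0] == pytest.approx(26.0)
    assert center_separation(coords, [0, 1], [0, 1], BOX)[0] == 0.0
    rng = np.random.default_rng(7)
    frames = rng.uniform(0, BOX, (50, 6, 3))
    r = center_separation(frames, [0, 1, 2], [3, 4, 5], BOX)
    assert np.all(r <= BOX * np.sqrt(3) / 2 + 1e-9)


def test_observables_invariant_under_periodic_wrapping(toy_topology):
    """Wrapping input coordinates into the box changes nothing."""
    pairs, rnat = _toy_arrays(toy_topology)
    rng = np.random.default_rng(8)
    frames = (toy_topology.native_coords + 200.0
              + rng.normal(0, 1.0, (5, toy_topology.n_particles, 3)))
    wrapped = frames - BOX * np.floor(frames / BOX)
    ga = np.nonzero(toy_topology.chain_index == 0)[0]
    gb = np.nonzero(toy_topology.chain_index == 1)[0]
    np.testing.assert_allclose(
        fraction_native(frames, pairs, rnat, BOX),
        fraction_native(wrapped, pairs, rnat, BOX))
    np.testing.assert_allclose(
        nonspecific_contacts(frames, ga, gb, BOX),
        nonspecific_contacts(wrapped, ga, gb, BOX))
    np.testing.assert_allclose(
        center_separation(frames, ga, gb, BOX),
        center_separation(wrapped, ga, gb, BOX), atol=1e-9)
    np.testing.assert_allclose(
        binding_rmsd(frames, toy_topology.native_coords, ga, gb, BOX),
        binding_rmsd(wrapped, toy_topology.native_coords, ga, gb, BOX),
        atol=1e-9)


def test_segment_q_size_weighted_mean(toy_topology):
    """Q over the union of per-segment subsets equals the size-weighted
    mean of per-segment Q's."""
    ipairs, irnat, _ = toy_topology.contact_arrays("inter")
    rng = np.random.default_rng(9)
    frames = (toy_topology.native_coords + 20.0
              + rng.normal(0, 1.2, (8, toy_topology.n_particles, 3)))
    half = len(ipairs) // 2
    subsets = [(ipairs[:half], irnat[:half]), (ipairs[half:], irnat[half:])]
    q_union = fraction_native(frames, ipairs, irnat, BOX)
    weighted = sum(
        len(p) * fraction_native(frames, p, r, BOX) for p, r in subsets
    ) / len(ipairs)
    np.testing.assert_allclose(q_union, weighted, atol=1e-12)


def test_contact_probability_map_planted_frequencies():
    """An ensemble with contacts planted at known residues recovers the
    planted per-residue frequencies exactly."""
    n_frames = 10
    coords = np.zeros((n_frames, 6, 3))
    coords[:, 0] = [10, 10, 10]
    coords[:, 1] = [22, 10, 10]
    coords[:, 2] = [34, 10, 10]
    coords[:, 3:] = 45.0
    # residue 3 (group B) contacts residue 0 in the first 4 frames only
    for f in range(4):
        coords[f, 3] = [10, 18, 10]    # 8 A from residue 0
    prob = contact_probability_map(coords, [0, 1, 2], [3, 4, 5], BOX)
    assert prob[0] == pytest.approx(0.4)
    assert prob[3] == pytest.approx(0.4)
    assert prob[1] == prob[2] == prob[4] == prob[5] == 0.0
    single = contact_probability_map(coords[:1], [0, 1, 2], [3, 4, 5], BOX)
    assert set(np.unique(single)) <= {0.0, 1.0}


def test_empty_subset_and_group_errors(toy_topology):
    with pytest.raises(ValueError):
        fraction_native(toy_topology.native_coords, np.zeros((0, 2)), [], BOX)
    with pytest.raises(ValueError):
        center_separation(toy_topology.native_coords, [], [0], BOX)
    with pytest.raises(ValueError):
        binding_rmsd(toy_topology.native_coords, toy_topology.native_coords,
                     [0, 1], [2])


def test_segment_table_yaml_roundtrip(tmp_path, toy_topology):
    """Per-segment Q's come from a YAML segment table, not hard-coded
    ranges; inclusive ranges become half-open internally."""
    from idpgo.observables import compute_observables, load_segment_table
    from idpgo.dynamics import Trajectory
    path = tmp_path / "segments.yaml"
    path.write_text("substrate_helix: [0, 15]\nidp_helix: [16, 27]\n")
    segments = load_segment_table(path)
    assert segments == {"substrate_helix": (0, 16), "idp_helix": (16, 28)}
    frames = np.repeat(toy_topology.native_coords[None] + 20.0, 3, axis=0)
    traj = Trajectory(times=np.arange(1.0, 4.0), coords=frames, box=BOX,
                      temperature=300.0, seed=0)
    obs = compute_observables(traj, toy_topology, segments=segments)
    for name in ("Q_inter_substrate_helix", "Q_inter_idp_helix"):
        assert name in obs
        np.testing.assert_allclose(obs[name], 1.0)
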