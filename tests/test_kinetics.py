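"""State assignment, transition statistics and rate definitions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from idpgo.kinetics import (B, CC, U, StateThresholds, StateTrajectory,
                            assign_states, branching_fraction,
                            capture_rate_from_mfpt, evolution_fraction,
                            smooth_series, transition_stats)
from idpgo.synthetic import MarkovSpec, make_markov_trajectory


# ---------------------------------------------------------------- smoothing

def test_smoothing_identity_cases():
    x = np.array([1.0, 4.0, 2.0, 8.0])
    np.testing.assert_array_equal(smooth_series(x, 0.0, 1.0), x)
    const = np.full(50, 3.3)
    np.testing.assert_allclose(smooth_series(const, 15.0, 1.0), const)


def test_smoothing_step_series_hand_oracle():
    """3-frame centered average of a step series, hand-computed."""
    x = np.array([0.0, 0.0, 0.0, 3.0, 3.0, 3.0])
    got = smooth_series(x, 3.0, 1.0)      # window of 3 frames
    expected = np.array([0.0, 0.0, 1.0, 2.0, 3.0, 3.0])
    np.testing.assert_allclose(got, expected)


@settings(deadline=None, max_examples=30)
@given(st.lists(st.floats(0, 50), min_size=3, max_size=60),
       st.floats(0.5, 30.0))
def test_smoothing_preserves_mean_bounds(values, window):
    """The running average stays within the data range."""
    x = np.asarray(values)
    s = smooth_series(x, window, 1.0)
    assert s.min() >= x.min() - 1e-9 and s.max() <= x.max() + 1e-9


# ----------------------------------------------------------- state labeling

THRESH = StateThresholds(n_inter_min=11, smoothing_window_ps=0.0)


@pytest.mark.parametrize("n_inter, n_nonspec, expected", [
    (0, 0, U),       # no specific or nonspecific contacts
    (0, 3, CC),      # nonspecific only
    (11, 5, B),      # at/above the bound threshold
    (14, 0, B),
])
def test_state_definitions(n_inter, n_nonspec, expected):
    st_ = assign_states([float(n_inter)], [float(n_nonspec)], THRESH)
    assert st_.labels[0] == expected


def test_intermediate_frames_inherit_previous_label():
    """0.5 <= N_inter < threshold is not a fourth state: it keeps the last
    unambiguous label (CC at trajectory start)."""
    n_inter = np.array([3.0, 3.0, 11.0, 5.0, 0.0, 2.0])
    n_nonspec = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 9.0])
    st_ = assign_states(n_inter, n_nonspec, THRESH)
    # frames 0-1 ambiguous at start -> CC; frame 3 ambiguous -> keeps B;
    # frame 5 ambiguous (N_inter = 2) -> keeps U despite the nonspecifics
    np.testing.assert_array_equal(st_.labels, [CC, CC, B, B, U, U])


def test_labels_are_exhaustive_and_episodes_tile(toy_charged):
    rng = np.random.default_rng(1)
    n_inter = rng.integers(0, 14, 500).astype(float)
    n_nonspec = rng.integers(0, 6, 500).astype(float)
    st_ = assign_states(n_inter, n_nonspec, THRESH)
    assert np.isin(st_.labels, [U, CC, B]).all()
    covered = sum(e.n_frames for e in st_.episodes)
    assert covered == st_.n_frames
    for e1, e2 in zip(st_.episodes, st_.episodes[1:]):
        assert e2.start == e1.end


# ------------------------------------------------------------- rate recovery

@pytest.fixture(scope="module")
def markov_chain():
    spec = MarkovSpec(k_cap=1.0, k_esc=5.0, k_evo=0.5, k_unbind=0.5,
                      length_ns=20_000.0, frame_spacing_ps=2.0, seed=42)
    return make_markov_trajectory(spec), spec


@pytest.fixture(scope="module")
def markov_rates(markov_chain):
    data, spec = markov_chain
    st_ = assign_states(data["n_inter"], data["n_nonspec"],
                        StateThresholds(n_inter_min=spec.bound_threshold,
                                        smoothing_window_ps=0.0),
                        frame_spacing_ps=spec.frame_spacing_ps)
    return st_, transition_stats(st_), spec


def test_generator_rates_recovered(markov_rates):
    """The four effective rates match the generator's rate matrix within
    3 standard errors (SE ~ k/sqrt(N) for Poisson transition counts)."""
    st_, rates, spec = markov_rates
    for got, true, n in [
        (rates.k_cap, spec.k_cap, rates.counts["N_cap"]),
        (rates.k_esc, spec.k_esc, rates.counts["N_esc"]),
        (rates.k_evo, spec.k_evo, rates.counts["N_evo"]),
        (1.0 / rates.mfpt_conditional[(B, CC)], spec.k_unbind,
         rates.counts["N_B_to_CC"]),
    ]:
        se = true / np.sqrt(n)
        assert abs(got - true) < 3 * se + 0.02 * true, (got, true, n)


def test_labels_recovered_exactly_from_counts(markov_chain):
    data, spec = markov_chain
    st_ = assign_states(data["n_inter"], data["n_nonspec"],
                        StateThresholds(n_inter_min=spec.bound_threshold,
                                        smoothing_window_ps=0.0),
                        frame_spacing_ps=spec.frame_spacing_ps)
    np.testing.assert_array_equal(st_.labels, data["states"])


def test_kcap_mfpt_identity(markov_rates):
    """k_cap x MFPT(U->CC) = 1 identically."""
    _, rates, _ = markov_rates
    assert rates.k_cap * rates.mfpt_first_passage[U, CC] == pytest.approx(1.0)


def test_first_passage_additivity(markov_rates):
    """Markov additivity: MFPT(U->B) ~ MFPT(U->CC) + MFPT(CC->B) for
    first-passage (elapsed) times."""
    _, rates, _ = markov_rates
    lhs = rates.mfpt_first_passage[U, B]
    rhs = rates.mfpt_first_passage[U, CC] + rates.mfpt_first_passage[CC, B]
    assert lhs == pytest.approx(rhs, rel=0.1)


def test_evolution_fraction_identity_and_values(markov_rates):
    """evolution_fraction equals k_evo/(k_evo + k_esc) exactly on the same
    labeling, and approaches the generator's branching ratio."""
    st_, rates, spec = markov_rates
    ef = evolution_fraction(st_)
    assert ef == pytest.approx(
        branching_fraction(rates.k_evo, rates.k_esc), abs=1e-12)
    assert ef == pytest.approx(
        spec.k_evo / (spec.k_evo + spec.k_esc), rel=0.2)


def test_branching_and_capture_arithmetic():
    """Definitional cross-checks on reported encounter statistics: a mean
    encounter time of 0.72 ns means k_cap = 1.4 1/ns; rates (0.012, 0.020)
    1/ns give ~37% evolution probability; 16 evolutions of 2316 completed
    collisions is 0.69%."""
    # 1/0.72 = 1.389, which rounds to the two-significant-figure 1.4
    assert capture_rate_from_mfpt(0.72) == pytest.approx(1.4, abs=0.051)
    assert branching_fraction(0.012, 0.020) == pytest.approx(0.375, abs=1e-12)
    assert 16 / (16 + 2300) == pytest.approx(0.0069, abs=1e-4)


def test_evolution_fraction_edge_cases():
    # all completed CC episodes evolve
    labels = np.array([U, CC, B, B, CC, B])
    st_ = StateTrajectory(labels, 1.0)
    assert evolution_fraction(st_) == 1.0
    # trailing truncated CC episode is excluded
    labels = np.array([U, CC])
    with pytest.raises(ValueError):
        evolution_fraction(StateTrajectory(labels, 1.0))


def test_zero_count_rates_flagged_not_raised():
    labels = np.array([U] * 10 + [CC] * 10)
    rates = transition_stats(StateTrajectory(labels, 1.0))
    assert rates.k_esc == 0.0 and rates.k_evo == 0.0
    assert any("k_evo" in f for f in rates.flags)


def test_direct_u_b_transitions_split_through_cc():
    labels = np.array([U, U, B, B, U])
    st_ = StateTrajectory(labels, 1.0)
    states_seq = [e.state for e in st_.episodes]
    assert states_seq == [U, CC, B, CC, U]
    assert sum(e.n_frames for e in st_.episodes) == 5
    rates = transition_stats(st_, half_split=False)
    assert rates.counts["N_cap"] == 1
    assert rates.counts["N_evo"] == 1
    assert rates.counts["N_TS"] == 2      # U->B and B->U passages


def test_smoothing_reduces_transition_count():
    """N_TS with 15-ps smoothing never exceeds the unsmoothed count."""
    rng = np.random.default_rng(7)
    # noisy two-basin series flickering across the bound threshold
    base = np.where(np.sin(np.arange(3000) / 150.0) > 0, 12.0, 0.0)
    n_inter = np.clip(base + rng.normal(0, 4.0, 3000), 0, None)
    n_nonspec = np.clip(rng.normal(2, 2.0, 3000), 0, None)
    thr = StateThresholds(n_inter_min=11, smoothing_window_ps=15.0)
    raw = assign_states(n_inter, n_nonspec,
                        StateThresholds(n_inter_min=11,
                                        smoothing_window_ps=0.0),
                        frame_spacing_ps=1.0)
    smoothed = assign_states(n_inter, n_nonspec, thr, frame_spacing_ps=1.0,
                             presmoothed=False)
    n_raw = transition_stats(raw, half_split=False).counts["N_TS"]
    n_smooth = transition_stats(smoothed, half_split=False).counts["N_TS"]
    assert n_smooth <= n_raw
    assert n_raw > 0


def test_half_split_uncertainties_present(markov_rates):
    _, rates, _ = markov_rates
    assert set(rates.uncertainties) == {
        "k_TS_per_us", "k_cap_per_ns", "k_esc_per_ns", "k_evo_per_ns"}
    assert all(v >= 0 for v in rates.uncertainties.values())


def test_rate_summary_serializes(markov_rates):
    import json
    _, rates, _ = markov_rates
    d = rates.as_dict()
    json.dumps({k: v for k, v in d.items() if k != "mfpt_first_passage_ns"},
               default=float)
    assert d["k_cap_per_ns"] == rates.k_cap
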