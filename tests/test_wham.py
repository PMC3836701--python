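"""WHAM reweighting against analytic oracles; K_D and surfaces."""

import numpy as np
import pytest

from idpgo.constants import KB
from idpgo.synthetic import make_thermo_samples
from idpgo.wham import (dissociation_constant, effective_concentration,
                        free_energy_surface, heat_capacity,
                        melting_temperature, wham)

TEMPS = [280.0, 310.0, 340.0]


@pytest.fixture(scope="module")
def harmonic_wham():
    data = make_thermo_samples("harmonic", TEMPS, 30_000, seed=1, n_modes=4)
    return wham(data["energies"], TEMPS), data


@pytest.fixture(scope="module")
def two_level_wham():
    data = make_thermo_samples("two_level", TEMPS, 30_000, seed=2,
                               delta_e=1.2, g0=3, g1=1)
    return wham(data["energies"], TEMPS), data


def test_single_temperature_gives_uniform_weights():
    data = make_thermo_samples("harmonic", [300.0], 500, seed=3)
    wr = wham(data["energies"], [300.0])
    w = wr.weights(300.0)
    np.testing.assert_allclose(w, 1.0 / len(w), rtol=1e-12)


def test_reweighted_mean_energy_matches_equipartition(harmonic_wham):
    """Harmonic modes: <U>(T) = n_modes k_B T / 2 at an intermediate,
    non-sampled temperature (analytic oracle, 2%)."""
    wr, _ = harmonic_wham
    for t in (295.0, 300.0, 325.0):
        mean_u = wr.expectation(wr.energies, t)
        assert mean_u == pytest.approx(4 * KB * t / 2, rel=0.02)


def test_weights_reproduce_sampled_series_means(harmonic_wham):
    """At each sampled temperature the reweighted mean energy returns that
    series' empirical mean within sampling error."""
    wr, data = harmonic_wham
    for t, series in zip(TEMPS, data["energies"]):
        assert wr.expectation(wr.energies, t) == pytest.approx(
            np.mean(series), rel=0.02)


def test_two_level_occupancy_closed_form(two_level_wham):
    """P(level 1)(T) = g1 e^{-b dE} / (g0 + g1 e^{-b dE}) within 2%."""
    wr, data = two_level_wham
    level = np.concatenate(data["levels"]).astype(float)
    for t in (285.0, 310.0, 335.0):
        p1 = wr.expectation(level, t)
        w1 = 1 * np.exp(-1.2 / (KB * t))
        assert p1 == pytest.approx(w1 / (3 + w1), rel=0.02)


def test_heat_capacity_harmonic_flat(harmonic_wham):
    """C_V of 4 harmonic modes is 2 k_B, independent of T."""
    wr, _ = harmonic_wham
    cv = heat_capacity(wr, np.linspace(285.0, 335.0, 11))
    np.testing.assert_allclose(cv, 2.0 * KB, rtol=0.05)


def test_heat_capacity_schottky_peak_location():
    """Two-level C_V peaks at the analytic Schottky temperature."""
    de, g0, g1 = 1.2, 1, 1
    temps = [220.0, 260.0, 300.0, 340.0, 380.0]
    data = make_thermo_samples("two_level", temps, 40_000, seed=4,
                               delta_e=de, g0=g0, g1=g1)
    wr = wham(data["energies"], temps)
    grid = np.linspace(225.0, 375.0, 151)
    cv = heat_capacity(wr, grid)
    t_peak = grid[np.argmax(cv)]
    # analytic peak of the symmetric two-level Schottky anomaly:
    # x tanh(x/2) = 2 with x = dE/(kB T)  ->  x ~ 2.39936
    t_exact = de / (KB * 2.39936)
    assert t_peak == pytest.approx(t_exact, abs=2 * (grid[1] - grid[0]))


def test_heat_capacity_empty_grid(harmonic_wham):
    wr, _ = harmonic_wham
    assert heat_capacity(wr, []).size == 0


def test_melting_temperature_two_level_crossing():
    """With degeneracies g0 = g1, P(level 1) crosses 1/2 exactly where
    dE = T dS, i.e., never for dS = 0; with g1 > g0 the crossing is at
    T* = dE / (kB ln(g1/g0))."""
    de, g0, g1 = 1.5, 1, 8
    t_star = de / (KB * np.log(g1 / g0))      # ~363 K
    temps = [300.0, 340.0, 380.0, 420.0]
    data = make_thermo_samples("two_level", temps, 40_000, seed=5,
                               delta_e=de, g0=g0, g1=g1)
    wr = wham(data["energies"], temps)
    bound = 1.0 - np.concatenate(data["levels"]).astype(float)  # level 0
    res = melting_temperature(wr, bound, np.linspace(305.0, 415.0, 111))
    assert res.t_m == pytest.approx(t_star, rel=0.02)


def test_melting_temperature_no_crossing_is_an_error(harmonic_wham):
    wr, _ = harmonic_wham
    with pytest.raises(ValueError, match="cross"):
        melting_temperature(wr, np.ones_like(wr.energies),
                            np.linspace(285.0, 335.0, 11))


# ------------------------------------------------------------ concentrations

def test_effective_concentration_reference_boxes():
    """100 A and 105 A cubic boxes hold one pair at 1.66 mM and 1.43 mM."""
    assert effective_concentration(100.0) * 1e3 == pytest.approx(1.66, abs=0.005)
    assert effective_concentration(105.0) * 1e3 == pytest.approx(1.43, abs=0.005)


def test_effective_concentration_volume_scaling():
    assert effective_concentration(200.0) == pytest.approx(
        effective_concentration(100.0) / 8.0, rel=1e-12)


# ----------------------------------------------------------------------- K_D

def test_kd_symmetric_point():
    """P_U = 0.5 in a 100 A box: K_D = C_eff * 0.5 = 0.83 mM."""
    wr = wham([np.zeros(1000)], [300.0])
    n_inter = np.zeros(1000)
    n_inter[:500] = 11.0
    kd = dissociation_constant(wr, n_inter, 100.0)
    assert kd * 1e3 == pytest.approx(0.83, abs=0.005)


def test_kd_recovers_constructed_binding_free_energy():
    """Two-state sampler with prescribed dG_bind: the K_D estimator returns
    C_eff P_U^2 / P_B matching the closed form within sampling error."""
    de, g0, g1 = 1.0, 4, 1      # level 0 = bound (degenerate), 1 = unbound
    temps = [280.0, 300.0, 320.0]
    data = make_thermo_samples("two_level", temps, 50_000, seed=6,
                               delta_e=de, g0=g0, g1=g1)
    wr = wham(data["energies"], temps)
    level = np.concatenate(data["levels"])
    n_inter = np.where(level == 0, 11.0, 0.0)   # level 0 sampled as bound
    box = 100.0
    kd = dissociation_constant(wr, n_inter, box, t_query=300.0)
    w0 = g0 * np.exp(0.0)
    w1 = g1 * np.exp(-de / (KB * 300.0))
    p_u = w1 / (w0 + w1)        # unbound probability = level-1 occupancy
    expected = effective_concentration(box) * p_u ** 2 / (1 - p_u)
    assert kd == pytest.approx(expected, rel=0.1)


def test_kd_monotone_vanishes_with_unbound_probability():
    wr = wham([np.zeros(10_000)], [300.0])
    kds = []
    for n_unbound in (1000, 100, 10):
        n_inter = np.full(10_000, 11.0)
        n_inter[:n_unbound] = 0.0
        kds.append(dissociation_constant(wr, n_inter, 100.0))
    assert kds[0] > kds[1] > kds[2] > 0


def test_kd_degenerate_probability_is_an_error():
    wr = wham([np.zeros(100)], [300.0])
    with pytest.raises(ValueError, match="degenerate"):
        dissociation_constant(wr, np.zeros(100), 100.0)


def test_kd_complement_rule(two_level_wham):
    wr, data = two_level_wham
    level = np.concatenate(data["levels"]).astype(float)
    n_inter = np.where(level == 1, 12.0, 3.0)   # never exactly zero
    kd = dissociation_constant(wr, n_inter, 100.0, unbound_rule="complement",
                               bound_threshold=11)
    assert kd > 0


# ------------------------------------------------------------------ surfaces

def test_fes_flat_for_uniform_samples():
    rng = np.random.default_rng(7)
    wr = wham([rng.random(200_000)], [300.0])
    fes = free_energy_surface(wr, wr.energies, 300.0, bins=10,
                              range_x=(0.0, 1.0))
    assert np.nanmax(fes.free_energy) < 0.05
    assert fes.mask_empty.sum() == 0


def test_fes_gaussian_curvature():
    """Samples from a known Gaussian give a quadratic surface with the
    analytic curvature F(x) = x^2 / (2 s^2) in kT."""
    rng = np.random.default_rng(8)
    s = 0.7
    x = rng.normal(0.0, s, 400_000)
    wr = wham([np.zeros_like(x)], [300.0])
    fes = free_energy_surface(wr, x, 300.0, bins=41, range_x=(-2.0, 2.0))
    c = fes.centers_x
    expected = c ** 2 / (2 * s ** 2)
    expected -= expected.min()
    np.testing.assert_allclose(fes.free_energy, expected, atol=0.08)


def test_fes_anchored_at_zero_and_2d(toy_charged):
    rng = np.random.default_rng(9)
    x = rng.normal(0, 1, 50_000)
    y = rng.normal(0, 1, 50_000)
    wr = wham([np.zeros_like(x)], [300.0])
    fes = free_energy_surface(wr, x, 300.0, obs_y=y, bins=15)
    assert np.nanmin(fes.free_energy) == 0.0
    assert fes.free_energy.shape == (15, 15)
    table = fes.to_table()
    assert len(table.splitlines()) == 1 + 15 * 15


def test_fes_invariant_under_sample_duplication():
    rng = np.random.default_rng(10)
    x = rng.normal(0, 1, 20_000)
    wr1 = wham([np.zeros_like(x)], [300.0])
    fes1 = free_energy_surface(wr1, x, 300.0, bins=21, range_x=(-3, 3))
    x2 = np.concatenate([x, x])
    wr2 = wham([np.zeros_like(x2)], [300.0])
    fes2 = free_energy_surface(wr2, x2, 300.0, bins=21, range_x=(-3, 3))
    np.testing.assert_allclose(fes1.free_energy, fes2.free_energy, atol=1e-12)


def test_wham_input_validation():
    with pytest.raises(ValueError):
        wham([], [])
    with pytest.raises(ValueError):
        wham([np.zeros(0)], [300.0])
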