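"""Two-stage model calibration and production-run orchestration.

Topology-based models transplanted from a folded complex over-stabilize the
unbound IDP, so the workflow is: (1) uniformly scale the intramolecular
contact strengths (lambda_intra) until short unbound simulations reproduce
a target residual helicity; (2) scale the intermolecular strengths
(lambda_inter) until the dissociation constant from replica-exchange + WHAM
matches the experimental K_D to the same order of magnitude.  Charged
models are re-calibrated after charge assignment.  Production runs are then
performed at the melting temperature, where bound and unbound states are
both well sampled.

Helicity of a C-alpha-only model is operationalized per residue as: the
native (i, i+4) contact is formed AND the backbone pseudo-dihedral
C-alpha(i-1..i+2) is within a tolerance (default 40 degrees) of its native
value.

Evaluation-run lengths here default far below what converged reproduction
of experimental systems requires; they are study parameters, not fixed
constants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dynamics import SimulationConfig, Trajectory, run_langevin
from .kinetics import (StateThresholds, StateTrajectory, RateSummary,
                       assign_states, smooth_series, transition_stats)
from .observables import ObservableSeries, compute_observables, pair_distances
from .remd import run_rex
from .topology import GoTopology, dihedral_angle, scale_topology
from .wham import dissociation_constant, wham

logger = logging.getLogger(__name__)


@dataclass
class CalibrationSpec:
    """Targets and run settings for the two calibration stages."""

    target_helicity: float | None = None          # mean over the IDP chain
    target_helicity_profile: np.ndarray | None = None
    target_kd: float | None = None                # mol/L
    kd_tolerance_decades: float = 1.0             # order-of-magnitude match
    temperature: float = 300.0
    box: float = 60.0
    unbound_steps: int = 200_000
    rex_steps: int = 400_000
    rex_ladder: np.ndarray | None = None
    rex_exchange_interval: int = 1000
    save_interval: int = 100
    ionic_strength: float = 0.0
    helicity_tolerance: float = 0.05
    lambda_intra_bounds: tuple = (0.1, 1.5)
    lambda_inter_bounds: tuple = (0.2, 5.0)
    bound_threshold: int = 7
    unbound_rule: str = "no_native"


def residual_helicity(trajectory: Trajectory, topology: GoTopology,
                      dihedral_tolerance_deg: float = 40.0) -> np.ndarray:
    """Per-residue helical fraction of a single-chain trajectory.

    Residues whose (i, i+4) contact is absent from the topology (natively
    non-helical) score 0.
    """
    n = topology.n_particles
    if len(topology.chain_ids) != 1:
        raise ValueError("residual helicity is defined for a single chain")
    if n < 5:
        raise ValueError("chain shorter than 5 residues")
    frames = trajectory.coords
    box = trajectory.box
    helix_contacts = {
        c.i: c for c in topology.intra_contacts if c.j - c.i == 4
    }
    tol = np.deg2rad(dihedral_tolerance_deg)
    out = np.zeros(n)
    for i, c in helix_contacts.items():
        if i < 1 or i + 2 >= n:
            continue
        r = pair_distances(frames, [(c.i, c.j)], box)[:, 0]
        formed = np.abs(r - c.r_native) <= 1.0
        native_phi = dihedral_angle(*topology.native_coords[i - 1:i + 3])
        phis = np.array([
            dihedral_angle(*frames[f, i - 1:i + 3]) for f in range(len(frames))
        ])
        dphi = np.angle(np.exp(1j * (phis - native_phi)))
        out[i] = float(np.mean(formed & (np.abs(dphi) <= tol)))
    return out


def _mean_helicity(topology, lam, spec, seed) -> float:
    scaled = scale_topology(topology, lam / topology.lambda_intra, 1.0)
    cfg = SimulationConfig(
        temperature=spec.temperature, box=spec.box,
        n_steps=spec.unbound_steps, save_interval=spec.save_interval,
        ionic_strength=spec.ionic_strength, seed=seed)
    traj = run_langevin(scaled, scaled.native_coords, cfg)
    return float(residual_helicity(traj, scaled).mean())


def calibrate_intra(topology: GoTopology, spec: CalibrationSpec,
                    seed: int = 0) -> dict:
    """Bisection on lambda_intra to match the target mean helicity.

    Each evaluation is a fixed-length unbound Langevin run at 300 K.
    Returns the accepted lambda_intra together with the achieved helicity
    and the unscaled (lambda = 1) helicity for reference.
    """
    if spec.target_helicity is None:
        if spec.target_helicity_profile is None:
            raise ValueError("no helicity target given")
        target = float(np.mean(spec.target_helicity_profile))
    else:
        target = spec.target_helicity
    if not 0.0 < target < 1.0:
        raise ValueError("target mean helicity must be in (0, 1)")

    lo, hi = spec.lambda_intra_bounds
    h_unscaled = _mean_helicity(topology, 1.0, spec, seed)
    h_lo = _mean_helicity(topology, lo, spec, seed + 1)
    h_hi = _mean_helicity(topology, hi, spec, seed + 2)
    if not (min(h_lo, h_hi) - spec.helicity_tolerance <= target
            <= max(h_lo, h_hi) + spec.helicity_tolerance):
        raise ValueError(
            f"target helicity {target:.3f} unreachable in lambda bracket "
            f"[{lo}, {hi}]: end-point helicities {h_lo:.3f}, {h_hi:.3f}")
    k = 3
    lam, hel = 1.0, h_unscaled
    while hi - lo > 0.01:
        lam = 0.5 * (lo + hi)
        hel = _mean_helicity(topology, lam, spec, seed + k)
        k += 1
        if abs(hel - target) < spec.helicity_tolerance:
            break
        # helicity increases with lambda_intra
        if hel > target:
            hi = lam
        else:
            lo = lam
    return {
        "lambda_intra": lam,
        "achieved_helicity": hel,
        "unscaled_helicity": h_unscaled,
        "target": target,
        "evaluations": k,
    }


def _evaluate_kd(topology, spec, seed):
    ladder = spec.rex_ladder
    cfg = SimulationConfig(
        temperature=spec.temperature, box=spec.box, n_steps=spec.rex_steps,
        save_interval=spec.save_interval, ionic_strength=spec.ionic_strength,
        seed=seed)
    rex = run_rex(topology, cfg, ladder=ladder,
                  exchange_interval=spec.rex_exchange_interval, seed=seed)
    wr = wham(rex.energy_series, rex.ladder)
    ipairs, irnat, _ = topology.contact_arrays("inter")
    n_inter = np.concatenate([
        _n_inter_series(t, ipairs, irnat) for t in rex.trajectories
    ])
    if spec.unbound_rule == "no_native":
        n_unbound_events = int((n_inter == 0).sum())
        if n_unbound_events == 0 or n_unbound_events == len(n_inter):
            raise RuntimeError(
                "replica-exchange sampling shows no binding/unbinding "
                "events; run longer simulations")
    kd = dissociation_constant(
        wr, n_inter, spec.box, t_query=spec.temperature,
        unbound_rule=spec.unbound_rule, bound_threshold=spec.bound_threshold)
    return kd, rex, wr, n_inter


def _n_inter_series(trajectory, ipairs, irnat):
    from .observables import native_contact_count
    return native_contact_count(trajectory.coords, ipairs, irnat,
                                trajectory.box)


def calibrate_inter(topology: GoTopology, spec: CalibrationSpec,
                    seed: int = 0) -> dict:
    """Search on lambda_inter until the REX/WHAM dissociation constant
    matches the target K_D within the configured number of decades.

    The computed K_D is very sensitive to small changes in lambda_inter;
    bisection in log-lambda against log-K_D (K_D decreases monotonically
    with binding strength) with an order-of-magnitude acceptance window.
    """
    if spec.target_kd is None or spec.target_kd <= 0:
        raise ValueError("positive target K_D required")
    lo, hi = spec.lambda_inter_bounds
    target = np.log10(spec.target_kd)

    def miss(lam, s):
        scaled = scale_topology(topology, 1.0, lam / topology.lambda_inter)
        kd, *_ = _evaluate_kd(scaled, spec, s)
        logger.info("calibrate_inter: lambda=%.3f K_D=%.3e", lam, kd)
        return np.log10(kd) - target

    m_lo = miss(lo, seed)
    if abs(m_lo) <= spec.kd_tolerance_decades:
        return {"lambda_inter": lo, "log10_miss": m_lo, "evaluations": 1}
    m_hi = miss(hi, seed + 1)
    if abs(m_hi) <= spec.kd_tolerance_decades:
        return {"lambda_inter": hi, "log10_miss": m_hi, "evaluations": 2}
    if m_lo * m_hi > 0:
        raise ValueError(
            f"target K_D {spec.target_kd:.2e} M not bracketed by "
            f"lambda_inter in [{lo}, {hi}] "
            f"(log10 misses {m_lo:+.2f}, {m_hi:+.2f})")
    k = 2
    while k < 12:
        lam = np.sqrt(lo * hi)
        m = miss(lam, seed + k)
        k += 1
        if abs(m) <= spec.kd_tolerance_decades:
            return {"lambda_inter": lam, "log10_miss": m, "evaluations": k}
        if (m > 0) == (m_hi > 0):
            hi, m_hi = lam, m
        else:
            lo, m_lo = lam, m
    return {"lambda_inter": lam, "log10_miss": m, "evaluations": k,
            "converged": False}


def run_production(
    topology: GoTopology,
    t_m: float,
    n_steps: int,
    seed: int = 0,
    box: float = 60.0,
    save_interval: int = 20,
    ionic_strength: float = 0.0,
    thresholds: StateThresholds | None = None,
    start_coords: np.ndarray | None = None,
) -> tuple[Trajectory, ObservableSeries, StateTrajectory, RateSummary]:
    """Single-temperature production Langevin run at T_m with streamed
    observables, state assignment and rate summary.

    Warns when the bound/unbound occupancy split is worse than 80/20 - the
    melting temperature should then be adjusted.
    """
    if thresholds is None:
        thresholds = StateThresholds(n_inter_min=7)
    cfg = SimulationConfig(
        temperature=t_m, box=box, n_steps=n_steps,
        save_interval=save_interval, ionic_strength=ionic_strength, seed=seed)
    traj = run_langevin(
        topology,
        topology.native_coords if start_coords is None else start_coords,
        cfg)
    obs = compute_observables(traj, topology)
    spacing = traj.frame_spacing
    n_inter_s = smooth_series(obs["N_inter"], thresholds.smoothing_window_ps,
                              spacing)
    n_nonspec_s = smooth_series(obs["N_nonspec"],
                                thresholds.smoothing_window_ps, spacing)
    states = assign_states(n_inter_s, n_nonspec_s, thresholds, spacing)
    rates = transition_stats(states)
    bound = states.state_fraction(2)
    unbound = 1.0 - bound
    if min(bound, unbound) < 0.2:
        logger.warning(
            "bound/unbound split %.2f/%.2f is worse than 80/20; adjust the "
            "production temperature (%s K)", bound, unbound, t_m)
    return traj, obs, states, rates
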