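"""End-to-end toy studies: charged vs uncharged binding thermokinetics.

This module fixes the study conditions for the two-helix binding toy
(:func:`idpgo.synthetic.default_binding_toy`) and drives the full pipeline
over them: build topology -> replica exchange -> WHAM (T_m, K_D) ->
production Langevin at T_m -> state assignment -> rates.  The same entry
points back the analysis scripts and the acceptance checks, so every
reported number is recomputed from scratch.

Study conditions (fixed once): 60 A cubic box, C-alpha contact criterion
at 7.5 A, base well depth 1.0 kcal/mol with the default flavoring,
lambda_inter = 1.5, bound-state threshold N_inter >= 7 of 11 native
intermolecular contacts, eight replicas spanning 270-400 K, 15-ps
state-assignment smoothing.  Charged models place +4 on the substrate
helix and -4 on the IDP helix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import SimulationConfig
from .calibration import run_production
from .kinetics import StateThresholds
from .observables import native_contact_count
from .remd import default_ladder, run_rex
from .structure import load_complex
from .synthetic import default_binding_toy, make_toy_complex
from .topology import FlavoringScheme, build_topology, scale_topology
from .wham import (dissociation_constant, effective_concentration,
                   heat_capacity, melting_temperature, wham)


@dataclass
class ToyStudyConditions:
    box: float = 60.0
    contact_cutoff: float = 7.5
    base_epsilon: float = 1.0
    lambda_intra: float = 1.0
    lambda_inter: float = 1.5
    bound_threshold: int = 7
    smoothing_window_ps: float = 15.0
    ladder: np.ndarray = field(default_factory=lambda: default_ladder(8, 270.0, 400.0))
    rex_steps: int = 400_000
    rex_save_interval: int = 100
    rex_exchange_interval: int = 1000
    production_steps: int = 2_000_000
    production_save_interval: int = 20
    kd_temperature: float = 300.0


def build_toy_model(charged: bool, conditions: ToyStudyConditions | None = None,
                    ionic_strength: float = 0.0):
    """Toy topology under the study conditions.  ``ionic_strength`` only
    matters downstream (it is a simulation parameter, not a topology one)."""
    cond = conditions or ToyStudyConditions()
    pdb_text, _ = make_toy_complex(default_binding_toy(charged=charged))
    structure = load_complex(pdb_text)
    top = build_topology(
        structure, cutoff=cond.contact_cutoff, contact_mode="ca",
        flavoring=FlavoringScheme.default(), base_epsilon=cond.base_epsilon,
        charge_mode="explicit" if charged else "none",
        provenance={"source": "synthetic two-helix binding toy",
                    "charged": charged})
    return scale_topology(top, cond.lambda_intra, cond.lambda_inter)


def thermodynamics_study(topology, conditions: ToyStudyConditions,
                         seed: int, ionic_strength: float = 0.0) -> dict:
    """REX + WHAM: heat capacity, T_m and K_D of one model."""
    cond = conditions
    cfg = SimulationConfig(
        temperature=300.0, box=cond.box, n_steps=cond.rex_steps,
        save_interval=cond.rex_save_interval, ionic_strength=ionic_strength,
        seed=seed)
    rex = run_rex(topology, cfg, ladder=cond.ladder,
                  exchange_interval=cond.rex_exchange_interval, seed=seed)
    wr = wham(rex.energy_series, rex.ladder)
    ipairs, irnat, _ = topology.contact_arrays("inter")
    n_inter = np.concatenate([
        native_contact_count(t.coords, ipairs, irnat, cond.box)
        for t in rex.trajectories
    ])
    bound = (n_inter >= cond.bound_threshold).astype(float)
    t_grid = np.linspace(cond.ladder[0], cond.ladder[-1], 131)
    melting = melting_temperature(wr, bound, t_grid)
    kd = dissociation_constant(wr, n_inter, cond.box,
                               t_query=cond.kd_temperature)
    return {
        "rex": rex, "wham": wr, "n_inter": n_inter,
        "t_grid": t_grid, "heat_capacity": heat_capacity(wr, t_grid),
        "t_m": melting.t_m, "t_cv_peak": melting.t_cv_peak,
        "kd_m": kd,
        "c_eff_m": effective_concentration(cond.box),
        "acceptance_rates": rex.acceptance_rates,
    }


def fine_tune_tm(topology, t_start: float, conditions: ToyStudyConditions,
                 seed: int, ionic_strength: float = 0.0,
                 probe_steps: int = 400_000, window: tuple = (0.35, 0.65),
                 step: float = 5.0, max_iter: int = 6) -> float:
    """Fine-tune the production temperature so bound and unbound states are
    sampled with similar probabilities.

    The WHAM estimate of T_m is refined with short production probes:
    too-bound probes raise T, too-unbound probes lower it.
    """
    cond = conditions
    thresholds = StateThresholds(
        n_inter_min=cond.bound_threshold,
        smoothing_window_ps=cond.smoothing_window_ps)
    t = t_start
    for it in range(max_iter):
        _, _, states, _ = run_production(
            topology, t, probe_steps, seed=seed + 100 + it, box=cond.box,
            save_interval=cond.production_save_interval,
            ionic_strength=ionic_strength, thresholds=thresholds)
        bound = states.state_fraction(2)
        if bound > window[1]:
            t += step
        elif bound < window[0]:
            t -= step
        else:
            break
    return t


def kinetics_study(topology, t_m: float, conditions: ToyStudyConditions,
                   seed: int, ionic_strength: float = 0.0,
                   fine_tune: bool = True) -> dict:
    """Production run at (fine-tuned) T_m with the three-state rate
    decomposition."""
    cond = conditions
    thresholds = StateThresholds(
        n_inter_min=cond.bound_threshold,
        smoothing_window_ps=cond.smoothing_window_ps)
    if fine_tune:
        t_m = fine_tune_tm(topology, t_m, cond, seed,
                           ionic_strength=ionic_strength)
    traj, obs, states, rates = run_production(
        topology, t_m, cond.production_steps, seed=seed, box=cond.box,
        save_interval=cond.production_save_interval,
        ionic_strength=ionic_strength, thresholds=thresholds)
    return {"trajectory": traj, "observables": obs, "states": states,
            "rates": rates, "t_production": t_m}


def charged_vs_uncharged(seed: int,
                         conditions: ToyStudyConditions | None = None,
                         keep_heavy: bool = False) -> dict:
    """The headline toy comparison: does turning on complementary charges
    raise the capture rate, lower the escape rate and raise the evolution
    fraction at the respective melting temperatures?

    Returns a summary dict per model plus the charged/uncharged ratios.
    ``keep_heavy`` retains trajectories and WHAM objects for plotting.
    """
    cond = conditions or ToyStudyConditions()
    out: dict = {"conditions": cond}
    for label, charged in (("uncharged", False), ("charged", True)):
        top = build_toy_model(charged, cond)
        thermo = thermodynamics_study(top, cond, seed=seed + (17 if charged else 0))
        kin = kinetics_study(top, thermo["t_m"], cond,
                             seed=seed + (23 if charged else 5))
        rates = kin["rates"]
        summary = {
            "t_m": thermo["t_m"],
            "t_production": kin["t_production"],
            "t_cv_peak": thermo["t_cv_peak"],
            "kd_m": thermo["kd_m"],
            "c_eff_m": thermo["c_eff_m"],
            "k_ts_per_us": rates.k_ts,
            "k_cap_per_ns": rates.k_cap,
            "k_esc_per_ns": rates.k_esc,
            "k_evo_per_ns": rates.k_evo,
            "evolution_fraction": rates.evolution_fraction,
            "counts": dict(rates.counts),
            "state_fractions": dict(rates.state_fractions),
        }
        if keep_heavy:
            summary["thermo"] = thermo
            summary["kinetics"] = kin
        out[label] = summary
    u, c = out["uncharged"], out["charged"]
    out["ratios"] = {
        "k_cap_charged_over_uncharged":
            c["k_cap_per_ns"] / u["k_cap_per_ns"] if u["k_cap_per_ns"] else np.inf,
        "k_esc_charged_over_uncharged":
            c["k_esc_per_ns"] / u["k_esc_per_ns"] if u["k_esc_per_ns"] else np.inf,
        "evolution_fraction_charged_over_uncharged":
            c["evolution_fraction"] / u["evolution_fraction"]
            if u["evolution_fraction"] else np.inf,
    }
    return out
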