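"""Temperature replica exchange over the Langevin integrator.

Neighboring temperature pairs attempt configuration swaps every
``exchange_interval`` steps with the Metropolis criterion
min(1, exp[(beta_i - beta_j)(U_i - U_j)]); alternating even/odd pairs are
attempted on successive rounds.  Configurations travel between temperature
slots and velocities are rescaled by sqrt(T_new/T_old) on acceptance, so
each temperature slot carries a continuous canonical ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KB
from .dynamics import SimulationConfig, Trajectory, draw_velocities, run_langevin
from .forcefield import CompiledSystem, ElectrostaticParams
from .topology import GoTopology


def default_ladder(n_replicas: int = 8, t_min: float = 270.0,
                   t_max: float = 400.0) -> np.ndarray:
    """Geometric temperature ladder with fixed endpoints (K)."""
    if n_replicas < 2:
        raise ValueError("need at least 2 replicas")
    return t_min * (t_max / t_min) ** (np.arange(n_replicas) / (n_replicas - 1))


@dataclass
class RexResult:
    ladder: np.ndarray                           # (K,) ascending
    trajectories: list[Trajectory]               # one per temperature slot
    energy_series: list[np.ndarray]              # PE per slot, kcal/mol
    attempts: np.ndarray                         # (K-1,) neighbor pairs
    accepts: np.ndarray

    @property
    def acceptance_rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.attempts > 0, self.accepts / self.attempts, np.nan)


def run_rex(
    topology: GoTopology,
    config: SimulationConfig,
    ladder=None,
    exchange_interval: int = 1000,
    seed: int = 0,
    start_coords: np.ndarray | None = None,
) -> RexResult:
    """Run temperature replica exchange; ``config.n_steps`` is the total
    per-replica length.  ``config.temperature`` is ignored in favor of the
    ladder."""
    if ladder is None:
        ladder = default_ladder()
    ladder = np.asarray(ladder, dtype=float)
    if len(ladder) < 2 or np.any(np.diff(ladder) <= 0):
        raise ValueError("ladder must be ascending with >= 2 temperatures")
    if config.n_steps % exchange_interval != 0:
        raise ValueError("exchange interval must divide total steps")
    if exchange_interval % config.save_interval != 0:
        raise ValueError("save interval must divide exchange interval")

    n_rep = len(ladder)
    betas = 1.0 / (KB * ladder)
    rng = np.random.default_rng(seed)
    if start_coords is None:
        start_coords = topology.native_coords
    # one compiled system per slot (electrostatic screening length depends
    # only weakly on T through lambda_D; keep per-slot params exact)
    systems = [
        CompiledSystem(topology, ElectrostaticParams(
            eps_r=config.eps_r, ionic_strength=config.ionic_strength,
            temperature=t, cutoff=config.cutoff))
        for t in ladder
    ]
    pos = [np.array(start_coords, dtype=float) for _ in range(n_rep)]
    vel = [draw_velocities(topology.masses, t, rng) for t in ladder]

    n_rounds = config.n_steps // exchange_interval
    frames: list[list[np.ndarray]] = [[] for _ in range(n_rep)]
    energies: list[list[np.ndarray]] = [[] for _ in range(n_rep)]
    kinetic: list[list[np.ndarray]] = [[] for _ in range(n_rep)]
    attempts = np.zeros(n_rep - 1, dtype=np.int64)
    accepts = np.zeros(n_rep - 1, dtype=np.int64)
    last_pe = np.zeros(n_rep)

    for rnd in range(n_rounds):
        for k in range(n_rep):
            seg_cfg = SimulationConfig(
                temperature=float(ladder[k]), box=config.box,
                n_steps=exchange_interval, timestep_fs=config.timestep_fs,
                friction=config.friction, cutoff=config.cutoff,
                save_interval=config.save_interval,
                ionic_strength=config.ionic_strength, eps_r=config.eps_r,
                shake_tol=config.shake_tol,
                shake_max_iter=config.shake_max_iter,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            traj = run_langevin(topology, pos[k], seg_cfg,
                                velocities=vel[k], system=systems[k])
            pos[k] = traj.coords[-1].copy()
            vel[k] = traj.final_velocities
            frames[k].append(traj.coords)
            energies[k].append(traj.potential_energies)
            kinetic[k].append(traj.kinetic_energies)
            last_pe[k] = traj.potential_energies[-1]

        first = rnd % 2  # alternate even/odd neighbor pairs
        for k in range(first, n_rep - 1, 2):
            attempts[k] += 1
            delta = (betas[k] - betas[k + 1]) * (last_pe[k] - last_pe[k + 1])
            if delta >= 0 or rng.random() < np.exp(delta):
                accepts[k] += 1
                pos[k], pos[k + 1] = pos[k + 1], pos[k]
                scale_up = np.sqrt(ladder[k + 1] / ladder[k])
                vel[k], vel[k + 1] = vel[k + 1] / scale_up, vel[k] * scale_up
                last_pe[k], last_pe[k + 1] = last_pe[k + 1], last_pe[k]

    dt_frame = config.timestep_ps * config.save_interval
    trajectories, energy_series = [], []
    for k in range(n_rep):
        coords = np.concatenate(frames[k], axis=0)
        pes = np.concatenate(energies[k])
        kes = np.concatenate(kinetic[k])
        times = dt_frame * np.arange(1, len(pes) + 1)
        trajectories.append(Trajectory(
            times=times, coords=coords, box=config.box,
            temperature=float(ladder[k]), seed=seed,
            potential_energies=pes, kinetic_energies=kes,
        ))
        energy_series.append(pes)
    return RexResult(ladder, trajectories, energy_series, attempts, accepts)
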