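"""Langevin dynamics with SHAKE-constrained virtual bonds.

The integrator is a BAOAB splitting: deterministic half-kick / half-drift
steps around an exact Ornstein-Uhlenbeck velocity update, with SHAKE
position projection after every drift and RATTLE velocity projection after
the stochastic and final kick steps.  At zero friction it reduces to
velocity Verlet.  Identical topology + config + seed gives a bit-identical
trajectory.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import h5py

from . import _kernels
from .constants import COULOMB_K, KB, KCAL_TO_DA_A2_PS2
from .forcefield import CompiledSystem, ElectrostaticParams
from .topology import GoTopology


@dataclass
class SimulationConfig:
    temperature: float                 # K
    box: float                         # A, cubic edge
    n_steps: int
    timestep_fs: float = 15.0
    friction: float = 0.1              # ps^-1
    cutoff: float = 25.0               # A
    save_interval: int = 100           # steps between saved frames
    ionic_strength: float = 0.0        # mol/L
    eps_r: float = 80.0
    shake_tol: float = 1e-8            # relative bond-length tolerance
    shake_max_iter: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.timestep_fs <= 0:
            raise ValueError("timestep must be positive")
        if self.friction < 0:
            raise ValueError("friction must be non-negative")
        if self.n_steps % self.save_interval != 0:
            raise ValueError("save interval must divide total steps")

    @property
    def timestep_ps(self) -> float:
        return self.timestep_fs * 1e-3

    @property
    def electrostatics(self) -> ElectrostaticParams:
        return ElectrostaticParams(
            eps_r=self.eps_r, ionic_strength=self.ionic_strength,
            temperature=self.temperature, cutoff=self.cutoff,
        )


@dataclass
class Trajectory:
    """Time-ordered frames of unwrapped C-alpha coordinates."""

    times: np.ndarray                  # (F,) ps, strictly increasing
    coords: np.ndarray                 # (F, n, 3) A, unwrapped
    box: float
    temperature: float
    seed: int
    topology_fingerprint: str = ""
    potential_energies: np.ndarray = field(default_factory=lambda: np.zeros(0))
    kinetic_energies: np.ndarray = field(default_factory=lambda: np.zeros(0))
    final_velocities: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def frame_spacing(self) -> float:
        """Frame spacing in ps."""
        return float(self.times[1] - self.times[0]) if self.n_frames > 1 else 0.0

    @property
    def wrapped_coords(self) -> np.ndarray:
        """Coordinates wrapped into [0, box)."""
        return self.coords - self.box * np.floor(self.coords / self.box)

    def validate(self) -> None:
        dt = np.diff(self.times)
        if len(dt) and not (np.all(dt > 0) and np.allclose(dt, dt[0])):
            raise ValueError("frame times must be strictly increasing and uniform")

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("times", data=self.times)
            f.create_dataset("coords", data=self.coords.astype(np.float32))
            f.create_dataset("potential_energies", data=self.potential_energies)
            f.create_dataset("kinetic_energies", data=self.kinetic_energies)
            f.attrs["box"] = self.box
            f.attrs["temperature"] = self.temperature
            f.attrs["seed"] = self.seed
            f.attrs["topology_fingerprint"] = self.topology_fingerprint

    @classmethod
    def load(cls, path) -> "Trajectory":
        with h5py.File(path, "r") as f:
            return cls(
                times=f["times"][:],
                coords=f["coords"][:].astype(np.float64),
                box=float(f.attrs["box"]),
                temperature=float(f.attrs["temperature"]),
                seed=int(f.attrs["seed"]),
                topology_fingerprint=str(f.attrs["topology_fingerprint"]),
                potential_energies=f["potential_energies"][:],
                kinetic_energies=f["kinetic_energies"][:],
            )


def topology_fingerprint(topology: GoTopology) -> str:
    return hashlib.md5(
        json.dumps(topology.to_dict(), sort_keys=True).encode()
    ).hexdigest()


def draw_velocities(masses: np.ndarray, temperature: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Maxwell-Boltzmann velocities, A/ps."""
    sigma = np.sqrt(KB * temperature * KCAL_TO_DA_A2_PS2 / masses)
    return rng.standard_normal((len(masses), 3)) * sigma[:, None]


class ShakeError(RuntimeError):
    pass


def run_langevin(
    topology: GoTopology,
    start_coords: np.ndarray,
    config: SimulationConfig,
    velocities: np.ndarray | None = None,
    system: CompiledSystem | None = None,
) -> Trajectory:
    """Integrate Langevin dynamics; returns the saved trajectory.

    Initial velocities default to a Maxwell-Boltzmann draw at the target
    temperature (seeded from ``config.seed``).  Bonds are constrained at
    their native lengths; starting coordinates must already satisfy the
    constraints to within the SHAKE tolerance.
    """
    t = topology
    if system is None:
        system = CompiledSystem(t, config.electrostatics)
    pos = np.ascontiguousarray(start_coords, dtype=float).copy()
    if pos.shape != (t.n_particles, 3):
        raise ValueError("start coordinates do not match topology")
    rng = np.random.default_rng(config.seed)
    if velocities is None:
        velocities = draw_velocities(t.masses, config.temperature, rng)
    vel = np.ascontiguousarray(velocities, dtype=float).copy()

    n_frames = config.n_steps // config.save_interval
    out_pos = np.empty((n_frames, t.n_particles, 3))
    out_pe = np.empty(n_frames)
    out_ke = np.empty(n_frames)
    kernel_seed = int(rng.integers(0, 2**31 - 1))

    status, step = _kernels.integrate(
        pos, vel, t.masses, config.box,
        t.bonds, t.bond_lengths,
        t.angles, t.angle_values, system.k_theta,
        t.dihedrals, t.dihedral_values, system.k_dih1, system.k_dih3,
        system.cpairs, system.c_rnat, system.c_eps, system.c_inter,
        system.nn_pairs, t.sigma_rep, t.eps_rep,
        system.e_pairs, system.e_qq, system.elec.kappa,
        COULOMB_K / system.elec.eps_r, config.cutoff,
        t.zinc_restraints, t.zinc_restraint_lengths, t.zinc_restraint_k,
        config.timestep_ps, config.friction, KB * config.temperature,
        config.n_steps, config.save_interval, kernel_seed,
        config.shake_tol, config.shake_max_iter,
        out_pos, out_pe, out_ke,
    )
    if status == 1:
        raise ShakeError(f"SHAKE failed to converge at step {step}")
    if status == 2:
        raise RuntimeError(f"non-finite coordinates at step {step}")

    dt_frame = config.timestep_ps * config.save_interval
    times = dt_frame * np.arange(1, n_frames + 1)
    return Trajectory(
        times=times, coords=out_pos, box=config.box,
        temperature=config.temperature, seed=config.seed,
        topology_fingerprint=topology_fingerprint(t),
        potential_energies=out_pe, kinetic_energies=out_ke,
        final_velocities=vel,
    )
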