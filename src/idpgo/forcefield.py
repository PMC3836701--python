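"""Coarse-grained potential: bonded terms, native-contact wells, excluded
volume, Debye-Hueckel electrostatics and metal restraints, evaluated under
periodic boundary conditions with a shifted cutoff.

The potential is

    U = U_bond + U_angle + U_dihedral
        + sum_native eps_ij [5 (r0/r)^12 - 6 (r0/r)^10]
        + sum_nonnative eps_rep (sigma/r)^12
        + sum_charged k_C q_i q_j exp(-r/lambda_D) / (eps_r r)
        + sum_restraints k (r - r0)^2

with every non-bonded term shifted so it vanishes at the cutoff (default
25 A).  Virtual bonds are normally held fixed by SHAKE during dynamics, in
which case the bond term is reported as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import constants as sc

from . import _kernels
from .constants import COULOMB_K
from .topology import GoTopology

DEFAULT_CUTOFF = 25.0          # A
DEFAULT_K_THETA = 20.0         # kcal/mol/rad^2
DEFAULT_K_DIH1 = 0.4           # kcal/mol (n = 1 term)
DEFAULT_K_DIH3 = 0.2           # kcal/mol (n = 3 term)
DEFAULT_K_BOND = 100.0         # kcal/mol/A^2 (only used when SHAKE is off)


def debye_length(ionic_strength: float, temperature: float = 300.0,
                 eps_r: float = 80.0) -> float:
    """Debye screening length in Angstrom.

    lambda_D = sqrt(eps_r eps_0 k_B T / (2 N_A e^2 I)), with the ionic
    strength I in mol/L.  Returns ``inf`` for I = 0 (pure Coulomb).
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be non-negative")
    if ionic_strength == 0:
        return math.inf
    i_si = ionic_strength * 1000.0  # mol/m^3
    lam = math.sqrt(
        eps_r * sc.epsilon_0 * sc.k * temperature
        / (2.0 * sc.N_A * sc.e ** 2 * i_si)
    )
    return lam * 1e10


@dataclass(frozen=True)
class ElectrostaticParams:
    """Debye-Hueckel parameters: uniform dielectric and ionic screening."""

    eps_r: float = 80.0
    ionic_strength: float = 0.0    # mol/L
    temperature: float = 300.0     # K (enters only the screening length)
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self):
        if self.eps_r <= 0:
            raise ValueError("dielectric constant must be positive")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be non-negative")

    @property
    def lambda_debye(self) -> float:
        return debye_length(self.ionic_strength, self.temperature, self.eps_r)

    @property
    def kappa(self) -> float:
        """Inverse screening length, 1/A (0 when no salt)."""
        lam = self.lambda_debye
        return 0.0 if math.isinf(lam) else 1.0 / lam


def debye_huckel_pair(q_i: float, q_j: float, r, params: ElectrostaticParams,
                      shifted: bool = True):
    """Screened-Coulomb pair energy (kcal/mol), shifted to 0 at the cutoff."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    a = COULOMB_K * q_i * q_j / params.eps_r
    u = a * np.exp(-params.kappa * r) / r
    if shifted:
        u = np.where(
            r < params.cutoff,
            u - a * math.exp(-params.kappa * params.cutoff) / params.cutoff,
            0.0,
        )
    return u if u.shape else float(u)


def native_contact_energy(r, r_native: float, eps_ij: float):
    """12-10 native-contact well; minimum -eps_ij at r = r_native."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0) or r_native <= 0:
        raise ValueError("distances must be positive")
    x = r_native / r
    u = eps_ij * (5.0 * x ** 12 - 6.0 * x ** 10)
    return u if u.shape else float(u)


@dataclass
class EnergyBreakdown:
    bond: float
    angle: float
    dihedral: float
    contact_intra: float
    contact_inter: float
    excluded: float
    electrostatic: float
    restraint: float

    @property
    def contact(self) -> float:
        return self.contact_intra + self.contact_inter

    @property
    def total(self) -> float:
        return (self.bond + self.angle + self.dihedral + self.contact_intra
                + self.contact_inter + self.excluded + self.electrostatic
                + self.restraint)

    def as_dict(self) -> dict:
        return {
            "bond": self.bond, "angle": self.angle, "dihedral": self.dihedral,
            "contact_intra": self.contact_intra,
            "contact_inter": self.contact_inter,
            "excluded": self.excluded, "electrostatic": self.electrostatic,
            "restraint": self.restraint, "total": self.total,
        }


class CompiledSystem:
    """Topology flattened into the pair tables the kernels consume.

    Non-native pairs are every intra-chain pair with sequence separation
    >= 3 and every inter-chain pair, minus the native contacts and the
    restrained metal pairs.  Electrostatic pairs are the non-bonded pairs
    (native or not) with a non-zero charge product.
    """

    def __init__(self, topology: GoTopology,
                 elec: ElectrostaticParams | None = None,
                 k_theta: float = DEFAULT_K_THETA,
                 k_dih1: float = DEFAULT_K_DIH1,
                 k_dih3: float = DEFAULT_K_DIH3,
                 k_bond: float = DEFAULT_K_BOND):
        self.topology = topology
        self.elec = elec or ElectrostaticParams()
        self.k_theta = k_theta
        self.k_dih1 = k_dih1
        self.k_dih3 = k_dih3
        self.k_bond = k_bond

        n = topology.n_particles
        cpairs, c_rnat, c_eps = topology.contact_arrays("all")
        c_inter = np.array([c.is_inter for c in topology.contacts], dtype=np.bool_)
        contact_set = {(min(i, j), max(i, j)) for i, j in cpairs}
        zn_set = {
            (min(i, j), max(i, j)) for i, j in topology.zinc_restraints
        }
        chain = topology.chain_index
        nn, ep, qq = [], [], []
        q = topology.charges
        for i in range(n):
            for j in range(i + 1, n):
                same = chain[i] >= 0 and chain[i] == chain[j]
                if same and abs(i - j) < 3:
                    continue
                key = (i, j)
                if key in zn_set:
                    continue
                native = key in contact_set
                if not native:
                    nn.append(key)
                if q[i] * q[j] != 0.0:
                    ep.append(key)
                    qq.append(q[i] * q[j])

        self.cpairs = cpairs
        self.c_rnat = c_rnat
        self.c_eps = c_eps
        self.c_inter = c_inter
        self.nn_pairs = np.asarray(nn, dtype=np.int64).reshape(-1, 2)
        self.e_pairs = np.asarray(ep, dtype=np.int64).reshape(-1, 2)
        self.e_qq = np.asarray(qq, dtype=float)

    def energy_forces(self, coords: np.ndarray, box: float,
                      shake_active: bool = True) -> tuple[EnergyBreakdown, np.ndarray]:
        t = self.topology
        coords = np.ascontiguousarray(coords, dtype=float)
        if coords.shape != (t.n_particles, 3):
            raise ValueError(
                f"coordinate shape {coords.shape} does not match topology "
                f"({t.n_particles} particles)"
            )
        if box <= 2 * self.elec.cutoff:
            raise ValueError("box edge must exceed twice the cutoff")
        self._check_overlap(coords, box)
        forces = np.zeros_like(coords)
        comp = _kernels.energy_forces(
            coords, box,
            t.bonds, t.bond_lengths, self.k_bond, not shake_active,
            t.angles, t.angle_values, self.k_theta,
            t.dihedrals, t.dihedral_values, self.k_dih1, self.k_dih3,
            self.cpairs, self.c_rnat, self.c_eps, self.c_inter,
            self.nn_pairs, t.sigma_rep, t.eps_rep,
            self.e_pairs, self.e_qq, self.elec.kappa,
            COULOMB_K / self.elec.eps_r, self.elec.cutoff,
            t.zinc_restraints, t.zinc_restraint_lengths, t.zinc_restraint_k,
            forces,
        )
        breakdown = EnergyBreakdown(*comp)
        return breakdown, forces

    def _check_overlap(self, coords: np.ndarray, box: float) -> None:
        for pairs in (self.cpairs, self.nn_pairs):
            if len(pairs) == 0:
                continue
            d = coords[pairs[:, 0]] - coords[pairs[:, 1]]
            d -= box * np.rint(d / box)
            r = np.linalg.norm(d, axis=1)
            if np.any(r < 1e-6):
                k = int(np.argmin(r))
                raise ValueError(
                    f"overlapping particles {pairs[k, 0]} and {pairs[k, 1]}"
                )


def potential_energy(topology, coords, box: float,
                     elec: ElectrostaticParams | None = None,
                     shake_active: bool = True) -> EnergyBreakdown:
    """Energy breakdown for one frame.  ``topology`` may be a
    :class:`GoTopology` or an already-compiled :class:`CompiledSystem`."""
    system = topology if isinstance(topology, CompiledSystem) \
        else CompiledSystem(topology, elec)
    breakdown, _ = system.energy_forces(coords, box, shake_active)
    return breakdown


def forces(topology, coords, box: float,
           elec: ElectrostaticParams | None = None) -> np.ndarray:
    """Analytic forces (-gradient of the shifted potential), kcal/mol/A."""
    system = topology if isinstance(topology, CompiledSystem) \
        else CompiledSystem(topology, elec)
    _, f = system.energy_forces(coords, box)
    return f
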