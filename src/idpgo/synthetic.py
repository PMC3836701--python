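"""Synthetic inputs with machine-readable ground truth.

Three generators cover the full pipeline without any external data:

* :func:`make_toy_complex` - small two-chain complexes with ideal-geometry
  C-alpha traces (plus pseudo-C-beta atoms for SASA work), designed
  secondary structure and charge patterns, emitted as standard PDB text
  together with ground-truth contact and charge tables.
* :func:`make_markov_trajectory` - Gillespie-simulated U/CC/B chains with a
  known rate matrix, plus contact-count series consistent with the labels,
  so the state-assignment -> rates path can be checked against the
  generator's own kinetics.
* :func:`make_thermo_samples` - exact Boltzmann samples of analytic models
  (harmonic modes, two-level system) for WHAM validation.

The toys are deliberately small (10-30 residues per chain) so a full
build -> replica-exchange -> WHAM -> production -> rates pipeline runs in
minutes; they do not mimic real IDP sequences or helicities.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .constants import KB

HELIX_RADIUS = 2.3      # A
HELIX_RISE = 1.5        # A per residue
HELIX_TWIST = 100.0     # degrees per residue
EXTENDED_STEP = 3.8     # A per residue (virtual bond length)
CLASH_DISTANCE = 2.5    # A, non-bonded pairs closer than this are rejected


@dataclass(frozen=True)
class ChainSpec:
    chain_id: str
    ss: str                      # 'H' (helix) / 'C' (coil) per residue
    charges: str                 # '+', '-', '0' per residue
    offset: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.ss) != len(self.charges):
            raise ValueError("ss and charge strings must have equal length")
        if len(self.ss) < 5:
            raise ValueError("chains must have at least 5 residues")
        if set(self.ss) - set("HC") or set(self.charges) - set("+-0"):
            raise ValueError("ss in {H,C}; charges in {+,-,0}")


@dataclass(frozen=True)
class ToyComplexSpec:
    chains: tuple                        # of ChainSpec
    contact_cutoff: float = 6.5          # A, C-alpha criterion
    min_seq_sep: int = 3
    jitter: float = 0.0                  # A, optional coordinate noise
    seed: int = 0


def _chain_coords(spec: ChainSpec) -> np.ndarray:
    """Ideal-geometry C-alpha trace: helical runs and extended runs."""
    n = len(spec.ss)
    coords = np.zeros((n, 3))
    pos = np.zeros(3)
    k = 0
    while k < n:
        run_char = spec.ss[k]
        j = k
        while j < n and spec.ss[j] == run_char:
            j += 1
        length = j - k
        if run_char == "H":
            t = np.deg2rad(HELIX_TWIST) * np.arange(length)
            run = np.stack(
                [HELIX_RADIUS * np.cos(t), HELIX_RADIUS * np.sin(t),
                 HELIX_RISE * np.arange(length)], axis=1)
        else:
            run = np.stack(
                [1.0 * (-1.0) ** np.arange(length),
                 np.zeros(length),
                 np.sqrt(EXTENDED_STEP ** 2 - 4.0) * np.arange(length)], axis=1)
        run = run - run[0]
        if k > 0:
            pos = coords[k - 1] + np.array([0.0, 0.0, EXTENDED_STEP])
        coords[k:j] = run + pos
        k = j
    return coords + np.asarray(spec.offset, dtype=float)


_CHARGE_RESIDUE = {"+": "LYS", "-": "GLU", "0": "ALA"}


def _pseudo_cb(ca: np.ndarray) -> np.ndarray:
    """C-beta dummy positions 1.53 A from each C-alpha, pointing away from
    the local backbone midpoint."""
    n = len(ca)
    cb = np.empty_like(ca)
    for i in range(n):
        lo, hi = max(i - 1, 0), min(i + 1, n - 1)
        direction = ca[i] - 0.5 * (ca[lo] + ca[hi])
        nrm = np.linalg.norm(direction)
        if nrm < 1e-6:
            direction, nrm = np.array([1.0, 0.0, 0.0]), 1.0
        cb[i] = ca[i] + 1.53 * direction / nrm
    return cb


def _brute_force_contacts(coords, chain_of, cutoff, min_seq_sep):
    """Independent O(n^2) contact scan (the generator's own oracle)."""
    n = len(coords)
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            r = float(np.linalg.norm(coords[i] - coords[j]))
            if r > cutoff:
                continue
            if chain_of[i] == chain_of[j] and j - i < min_seq_sep:
                continue
            kind = "inter" if chain_of[i] != chain_of[j] else f"intra:{chain_of[i]}"
            out.append({"i": i, "j": j, "r_native": r, "kind": kind})
    return out


def make_toy_complex(spec: ToyComplexSpec) -> tuple[str, dict]:
    """Emit a toy complex as PDB text plus its ground-truth tables.

    The ground truth contains per-residue charges, per-chain net charges,
    and the native-contact list obtained by brute-force enumeration with
    the spec's C-alpha criterion, so every topology-construction operation
    can be verified exactly.  Deterministic for a fixed spec.
    """
    rng = np.random.default_rng(spec.seed)
    ca_list, names, chain_of = [], [], []
    for c in spec.chains:
        xyz = _chain_coords(c)
        if spec.jitter > 0:
            xyz = xyz + rng.normal(0.0, spec.jitter, xyz.shape)
        ca_list.append(xyz)
        names.extend(_CHARGE_RESIDUE[ch] for ch in c.charges)
        chain_of.extend([c.chain_id] * len(c.ss))
    ca = np.concatenate(ca_list, axis=0)

    # clash check on non-bonded pairs
    n = len(ca)
    for i in range(n):
        for j in range(i + 1, n):
            same = chain_of[i] == chain_of[j]
            if same and j - i == 1:
                continue
            if np.linalg.norm(ca[i] - ca[j]) < CLASH_DISTANCE:
                raise ValueError(
                    f"infeasible design: residues {i} and {j} clash")

    cb = _pseudo_cb(ca)
    atoms = []
    serial = 1
    for k in range(n):
        res_id = k + 1
        for atom_name, coord, element in (("CA", ca[k], "C"), ("CB", cb[k], "C")):
            a = struc.Atom(
                coord, chain_id=chain_of[k], res_id=res_id,
                res_name=names[k], atom_name=atom_name, element=element,
                hetero=False)
            atoms.append(a)
            serial += 1
    array = struc.array(atoms)
    pdb = PDBFile()
    pdb.set_structure(array)
    buf = io.StringIO()
    pdb.write(buf)
    pdb_text = buf.getvalue()

    charges = [
        {"+": 1, "-": -1, "0": 0}[ch]
        for c in spec.chains for ch in c.charges
    ]
    truth = {
        "chain_ids": [c.chain_id for c in spec.chains],
        "chain_lengths": [len(c.ss) for c in spec.chains],
        "res_names": names,
        "ca_coords": ca.tolist(),
        "charges": charges,
        "net_charge_per_chain": [
            sum({"+": 1, "-": -1, "0": 0}[ch] for ch in c.charges)
            for c in spec.chains
        ],
        "contacts": _brute_force_contacts(
            ca, chain_of, spec.contact_cutoff, spec.min_seq_sep),
        "contact_cutoff": spec.contact_cutoff,
        "min_seq_sep": spec.min_seq_sep,
    }
    return pdb_text, truth


def default_binding_toy(charged: bool = True) -> ToyComplexSpec:
    """The standard two-helix binding toy used across the analysis scripts:
    a 16-residue 'substrate' helix carrying +4 and a 12-residue IDP helix
    carrying -4, packed at helix-helix distance ~9 A."""
    a = ChainSpec("A", "H" * 16,
                  "0+00+000+00+0000" if charged else "0" * 16,
                  offset=(0.0, 0.0, 0.0))
    b = ChainSpec("B", "H" * 12,
                  "0-00-00-00-0" if charged else "0" * 12,
                  offset=(9.0, 0.0, 3.0))
    return ToyComplexSpec(chains=(a, b), contact_cutoff=7.5)


# ----------------------------------------------------------------- kinetics

@dataclass(frozen=True)
class MarkovSpec:
    """Continuous-time Markov chain over {U, CC, B} with rates in 1/ns."""

    k_cap: float           # U  -> CC
    k_esc: float           # CC -> U
    k_evo: float           # CC -> B
    k_unbind: float        # B  -> CC
    length_ns: float = 1e4
    frame_spacing_ps: float = 10.0
    bound_threshold: int = 11
    seed: int = 0

    def rate_matrix(self) -> np.ndarray:
        q = np.zeros((3, 3))
        q[0, 1] = self.k_cap
        q[1, 0] = self.k_esc
        q[1, 2] = self.k_evo
        q[2, 1] = self.k_unbind
        np.fill_diagonal(q, -q.sum(axis=1))
        return q


def make_markov_trajectory(spec: MarkovSpec) -> dict:
    """Gillespie-simulate the chain and discretize at the frame spacing.

    Also emits specific/nonspecific contact-count series consistent with
    the labels (B frames above the bound threshold, CC frames with
    nonspecific contacts only), so the full assign_states -> rates path can
    be exercised against the known generator kinetics.
    """
    rng = np.random.default_rng(spec.seed)
    q = spec.rate_matrix()
    t, state = 0.0, 0
    event_times, event_states = [0.0], [0]
    while t < spec.length_ns:
        rates = q[state].copy()
        rates[state] = 0.0
        total = rates.sum()
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        state = int(rng.choice(3, p=rates / total))
        event_times.append(t)
        event_states.append(state)
    event_times = np.array(event_times)
    event_states = np.array(event_states)

    dt_ns = spec.frame_spacing_ps / 1000.0
    n_frames = int(spec.length_ns / dt_ns)
    frame_t = dt_ns * np.arange(1, n_frames + 1)
    idx = np.searchsorted(event_times, frame_t, side="right") - 1
    states = event_states[idx]

    n_inter = np.zeros(n_frames, dtype=np.int64)
    n_nonspec = np.zeros(n_frames, dtype=np.int64)
    cc_mask = states == 1
    b_mask = states == 2
    n_nonspec[cc_mask] = 1 + rng.poisson(2.0, cc_mask.sum())
    n_inter[b_mask] = spec.bound_threshold + rng.poisson(3.0, b_mask.sum())
    n_nonspec[b_mask] = rng.poisson(5.0, b_mask.sum())

    return {
        "times_ps": frame_t * 1000.0,
        "states": states,
        "n_inter": n_inter,
        "n_nonspec": n_nonspec,
        "event_times_ns": event_times,
        "event_states": event_states,
        "spec": spec,
    }


# -------------------------------------------------------------- thermodynamics

def make_thermo_samples(model: str, temperatures, n: int, seed: int = 0,
                        n_modes: int = 1, delta_e: float = 1.0,
                        g0: int = 1, g1: int = 1) -> dict:
    """Exact Boltzmann samples of analytic models at each temperature.

    ``model="harmonic"``: potential energy of ``n_modes`` quadratic modes,
    U ~ (k_B T / 2) chi^2(n_modes); mean energy n_modes k_B T / 2 and
    C_V = n_modes k_B / 2, flat in T.

    ``model="two_level"``: energies {0, delta_e} with degeneracies (g0, g1);
    occupancy P1(T) = g1 e^{-b dE} / (g0 + g1 e^{-b dE}) and a Schottky
    heat-capacity peak.
    """
    if n < 100:
        raise ValueError("need at least 100 samples per temperature")
    rng = np.random.default_rng(seed)
    temperatures = np.asarray(temperatures, dtype=float)
    energies, levels = [], []
    for t in temperatures:
        if model == "harmonic":
            u = 0.5 * KB * t * rng.chisquare(n_modes, n)
            energies.append(u)
        elif model == "two_level":
            w1 = g1 * np.exp(-delta_e / (KB * t))
            p1 = w1 / (g0 + w1)
            lev = (rng.random(n) < p1).astype(np.int64)
            levels.append(lev)
            energies.append(lev * delta_e)
        else:
            raise ValueError(f"unknown model {model!r}")
    out = {"temperatures": temperatures, "energies": energies}
    if model == "two_level":
        out["levels"] = levels
    return out
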