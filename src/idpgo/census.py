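"""Charge census of an IDP complex: interface, surface and vicinity.

Region definitions:

* interface (IDP binding site): substrate residues losing more than
  1.0 A^2 of solvent-accessible surface area upon complex formation
  (strict inequality);
* surface: residues with more than 5% relative accessibility (per-residue
  SASA over a maximal-exposure reference value);
* vicinity: surface residues of the substrate within 15 A minimal
  C-alpha - C-alpha distance of the bound IDP, excluding interface
  residues (the two sets are disjoint by construction).

For each region the census reports the Lys/Arg/Asp/Glu counts and the net
formal charge (His neutral).  SASA is Shrake-Rupley with 960 sphere points
by default, so the report is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import biotite.structure as struc

from .constants import RESIDUE_CHARGES
from .structure import ComplexStructure

DELTA_SASA_THRESHOLD = 1.0      # A^2, strictly greater
SURFACE_ACCESSIBILITY = 0.05    # relative accessibility
VICINITY_DISTANCE = 15.0        # A, C-alpha - C-alpha
DEFAULT_POINTS = 960


def _max_sasa_table() -> dict[str, float]:
    with resources.files("idpgo.data").joinpath("max_sasa.csv").open() as fh:
        next(fh)
        return {name: float(v) for name, v in
                (line.strip().split(",") for line in fh if line.strip())}


def _concat_atoms(structure: ComplexStructure, chain_indices) -> tuple:
    arrays, res_offsets = [], []
    for ci in chain_indices:
        chain = structure.chains[ci]
        if chain.atoms is None:
            raise ValueError(f"chain {chain.chain_id} lacks all-atom records")
        arrays.append(chain.atoms)
        res_offsets.append(structure.chain_start(ci))
    merged = arrays[0]
    for a in arrays[1:]:
        merged = merged + a
    global_res = np.concatenate([
        off + arr.res_index for off, arr in zip(res_offsets, arrays)
    ])
    return merged, global_res


def sasa(structure: ComplexStructure, chain_indices=None,
         probe_radius: float = 1.4,
         point_number: int = DEFAULT_POINTS) -> dict[int, float]:
    """Per-residue solvent-accessible surface area (A^2), Shrake-Rupley.

    ``chain_indices`` restricts the computation to an isolated sub-complex
    (other chains removed); keys are global residue indices.
    """
    if chain_indices is None:
        chain_indices = range(len(structure.chains))
    atoms, global_res = _concat_atoms(structure, chain_indices)
    per_atom = struc.sasa(atoms, probe_radius=probe_radius,
                          point_number=point_number, vdw_radii="Single")
    per_atom = np.nan_to_num(per_atom)
    out: dict[int, float] = {}
    for ri in np.unique(global_res):
        out[int(ri)] = float(per_atom[global_res == ri].sum())
    return out


def interface_residues(structure: ComplexStructure, idp_chain: int,
                       point_number: int = DEFAULT_POINTS) -> dict[int, float]:
    """Residues with > 1.0 A^2 SASA loss upon complex formation.

    Returns {global residue index: delta-SASA} over *all* chains; filter by
    chain for the substrate-side binding site.
    """
    complexed = sasa(structure, point_number=point_number)
    out: dict[int, float] = {}
    for ci in range(len(structure.chains)):
        isolated = sasa(structure, [ci], point_number=point_number)
        for ri, a_iso in isolated.items():
            delta = a_iso - complexed[ri]
            if delta > DELTA_SASA_THRESHOLD:
                out[ri] = delta
    return out


def vicinity_residues(structure: ComplexStructure, idp_chain: int,
                      interface: dict[int, float] | None = None,
                      point_number: int = DEFAULT_POINTS) -> dict[int, float]:
    """Substrate surface residues within 15 A of the IDP, excluding the
    interface.  Returns {global residue index: min C-alpha distance}."""
    if interface is None:
        interface = interface_residues(structure, idp_chain,
                                       point_number=point_number)
    max_table = _max_sasa_table()
    complexed = sasa(structure, point_number=point_number)
    idp_start = structure.chain_start(idp_chain)
    idp_ca = structure.chains[idp_chain].ca_coords
    res_names = structure.res_names
    out: dict[int, float] = {}
    for ci in range(len(structure.chains)):
        if ci == idp_chain:
            continue
        start = structure.chain_start(ci)
        for k, ca in enumerate(structure.chains[ci].ca_coords):
            ri = start + k
            if ri in interface:
                continue
            rel = complexed[ri] / max_table[res_names[ri]]
            if rel <= SURFACE_ACCESSIBILITY:
                continue
            dmin = float(np.min(np.linalg.norm(idp_ca - ca, axis=1)))
            if dmin <= VICINITY_DISTANCE:
                out[ri] = dmin
    return out


@dataclass
class RegionCensus:
    residues: list[int]
    n_charged: int
    net_charge: int
    justification: dict[int, float] = field(default_factory=dict)


@dataclass
class CensusReport:
    idp: RegionCensus
    binding_site: RegionCensus
    vicinity: RegionCensus

    def as_dict(self) -> dict:
        return {
            region: {
                "residues": c.residues,
                "n_charged": c.n_charged,
                "net_charge": c.net_charge,
            }
            for region, c in [("idp", self.idp),
                              ("binding_site", self.binding_site),
                              ("vicinity", self.vicinity)]
        }


def _count_charges(res_indices, res_names) -> tuple[int, int]:
    n, net = 0, 0
    for ri in res_indices:
        q = RESIDUE_CHARGES.get(res_names[ri], 0)
        if q:
            n += 1
            net += int(q)
    return n, net


def charge_census(structure: ComplexStructure, idp_chain: int = 1,
                  point_number: int = DEFAULT_POINTS) -> CensusReport:
    """Charged-residue counts and net charges of the IDP, its binding site
    on the substrate, and the binding-site vicinity."""
    res_names = structure.res_names
    interface = interface_residues(structure, idp_chain,
                                   point_number=point_number)
    vicinity = vicinity_residues(structure, idp_chain, interface,
                                 point_number=point_number)
    idp_start = structure.chain_start(idp_chain)
    idp_set = list(range(idp_start, idp_start + len(structure.chains[idp_chain])))
    site_set = sorted(ri for ri in interface if ri not in idp_set)
    vic_set = sorted(vicinity)

    def region(res, just):
        n, net = _count_charges(res, res_names)
        return RegionCensus(list(res), n, net, just)

    return CensusReport(
        idp=region(idp_set, {}),
        binding_site=region(site_set, {ri: interface[ri] for ri in site_set}),
        vicinity=region(vic_set, dict(vicinity)),
    )
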