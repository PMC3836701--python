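"""Reading protein-complex structures into a chain-ordered representation.

Structures come from standard PDB files (experimental NMR/X-ray entries or
the synthetic fixtures shipped with this package).  Only the first model of
a multi-model entry is used.  Residues are renumbered contiguously, 0-based,
per chain and globally in chain-selection order; every downstream module
(topology, observables, census) indexes residues by that global index.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .constants import STANDARD_RESIDUES

#: heavy-atom distance below which a residue is taken to coordinate a
#: hetero metal site (typical Zn-ligand bond lengths are 2.0-2.3 A)
_COORDINATION_CUTOFF = 3.0


@dataclass
class ChainRecord:
    """One polypeptide chain: residue names, C-alpha coordinates and
    (optionally) the full heavy-atom record for SASA / contact detection."""

    chain_id: str
    res_names: list[str]
    ca_coords: np.ndarray                       # (n_res, 3) Angstrom
    atoms: struc.AtomArray | None = None        # heavy atoms, annotated with res_index

    def __len__(self) -> int:
        return len(self.res_names)


@dataclass
class HeteroSite:
    element: str
    coord: np.ndarray                           # (3,)
    coordinating: list[int] = field(default_factory=list)  # global residue indices


@dataclass
class ComplexStructure:
    chains: list[ChainRecord]
    hetero_sites: list[HeteroSite] = field(default_factory=list)

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    @property
    def chain_lengths(self) -> list[int]:
        return [len(c) for c in self.chains]

    def chain_start(self, chain_index: int) -> int:
        """Global index of the first residue of a chain."""
        return sum(len(c) for c in self.chains[:chain_index])

    def chain_of_residue(self, global_index: int) -> int:
        offset = 0
        for k, c in enumerate(self.chains):
            if global_index < offset + len(c):
                return k
            offset += len(c)
        raise IndexError(global_index)

    @property
    def ca_coords(self) -> np.ndarray:
        """(n_residues, 3) global C-alpha coordinate array."""
        return np.concatenate([c.ca_coords for c in self.chains], axis=0)

    @property
    def res_names(self) -> list[str]:
        out: list[str] = []
        for c in self.chains:
            out.extend(c.res_names)
        return out

    def validate(self) -> None:
        for c in self.chains:
            if len(c) < 2:
                raise ValueError(f"chain {c.chain_id} has fewer than 2 residues")
            if c.ca_coords.shape != (len(c), 3):
                raise ValueError(f"chain {c.chain_id}: C-alpha array shape mismatch")
            if not np.all(np.isfinite(c.ca_coords)):
                raise ValueError(f"chain {c.chain_id}: non-finite coordinates")


def _read_atom_array(pdb_source) -> struc.AtomArray:
    if isinstance(pdb_source, (str, Path)) and "\n" not in str(pdb_source):
        pdb = PDBFile.read(str(pdb_source))
    else:
        pdb = PDBFile.read(io.StringIO(str(pdb_source)))
    # first model of multi-model (NMR) entries
    return pdb.get_structure(model=1)


def load_complex(pdb_source, chain_selection: list[str] | None = None) -> ComplexStructure:
    """Load a protein complex from a PDB file, path or text.

    Parameters
    ----------
    pdb_source
        Path to a PDB file, or the PDB text itself.
    chain_selection
        Chain identifiers to load, in the desired order.  ``None`` loads all
        polypeptide chains in file order.

    Returns
    -------
    ComplexStructure
        Chains in selection order, residues renumbered contiguously 0-based.
        Hetero zinc sites are retained with their coordinating residues
        identified by a heavy-atom distance criterion.

    Raises
    ------
    ValueError
        If a selected chain is missing, a residue lacks a C-alpha atom, or a
        residue name is not one of the 20 standard amino acids.
    """
    atoms = _read_atom_array(pdb_source)
    heavy = atoms[atoms.element != "H"]

    protein = heavy[struc.filter_amino_acids(heavy)]
    present = list(dict.fromkeys(protein.chain_id))
    if chain_selection is None:
        chain_selection = present
    missing = [c for c in chain_selection if c not in present]
    if missing:
        raise ValueError(f"selected chains not present in structure: {missing}")

    chains: list[ChainRecord] = []
    for cid in chain_selection:
        # no silent skipping: any polymer (ATOM) residue with an unknown
        # name is a hard error, not a drop
        polymer = heavy[(heavy.chain_id == cid) & (~heavy.hetero)]
        for name, rid in zip(polymer.res_name, polymer.res_id):
            if name not in STANDARD_RESIDUES:
                raise ValueError(
                    f"unknown residue name {name!r} at chain {cid}, "
                    f"residue {rid}")
        chain_atoms = protein[protein.chain_id == cid]
        res_starts = struc.get_residue_starts(chain_atoms)
        res_names: list[str] = []
        ca_list: list[np.ndarray] = []
        res_index = np.empty(chain_atoms.array_length(), dtype=np.int64)
        bounds = list(res_starts) + [chain_atoms.array_length()]
        for ri, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
            res = chain_atoms[a:b]
            name = res.res_name[0]
            if name not in STANDARD_RESIDUES:
                raise ValueError(
                    f"unknown residue name {name!r} at chain {cid}, "
                    f"residue {res.res_id[0]}"
                )
            ca = res[res.atom_name == "CA"]
            if ca.array_length() != 1:
                raise ValueError(
                    f"residue {name} {res.res_id[0]} of chain {cid} has "
                    f"{ca.array_length()} C-alpha atoms (expected exactly 1)"
                )
            res_names.append(name)
            ca_list.append(ca.coord[0])
            res_index[a:b] = ri
        chain_atoms.set_annotation("res_index", res_index)
        chains.append(
            ChainRecord(cid, res_names, np.asarray(ca_list, dtype=float), chain_atoms)
        )

    structure = ComplexStructure(chains)
    structure.validate()

    # hetero metal sites (zinc); coordinating residues by heavy-atom distance
    zn = heavy[(heavy.hetero) & (np.char.upper(heavy.element) == "ZN")]
    for k in range(zn.array_length()):
        site = HeteroSite("ZN", zn.coord[k].astype(float))
        for ci, chain in enumerate(structure.chains):
            if chain.atoms is None:
                continue
            d = np.linalg.norm(chain.atoms.coord - zn.coord[k], axis=1)
            close = np.unique(chain.atoms.res_index[d < _COORDINATION_CUTOFF])
            start = structure.chain_start(ci)
            site.coordinating.extend(int(start + r) for r in close)
        structure.hetero_sites.append(site)

    return structure
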