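"""Relative contact order from atomic coordinates.

The relative contact order (RCO) of a chain of L residues is

    RCO = (1 / (L·N)) · Σ |i − j|,

summed over the N heavy-atom pairs that lie within the distance cutoff and
belong to residues separated by at least ``min_separation`` in sequence
(each qualifying atom pair contributes one contact — the original
contact-order convention).  RCO is an empirical correlate of two-state
folding rates; across the UCH paralogs the values are nearly identical
(≈0.14), too close to explain their orders-of-magnitude rate differences.

Structures are read with gemmi (PDB or mmCIF); contacts are found with a
k-d tree rather than an all-pairs scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .exceptions import DataError

logger = logging.getLogger(__name__)

__all__ = ["ChainContacts", "relative_contact_order", "contacts_from_coords"]


@dataclass
class ChainContacts:
    """Qualifying heavy-atom contacts of one chain."""

    residue_count: int
    contacts: list          # (residue_i, residue_j, |i-j|) per atom pair, i < j
    cutoff: float
    min_separation: int

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    @property
    def rco(self) -> float:
        if not self.contacts:
            raise DataError("no qualifying contacts: RCO undefined")
        total_sep = sum(sep for _, _, sep in self.contacts)
        return total_sep / (self.residue_count * self.n_contacts)


def contacts_from_coords(
    coords: np.ndarray,
    residue_index: np.ndarray,
    cutoff: float = 6.0,
    min_separation: int = 2,
) -> ChainContacts:
    """Contact list from raw heavy-atom coordinates and residue assignments.

    ``residue_index`` gives, per atom, the 1-based compacted sequence index
    of the residue the atom belongs to.
    """
    coords = np.asarray(coords, dtype=float)
    residue_index = np.asarray(residue_index, dtype=int)
    if coords.shape[0] != len(residue_index):
        raise DataError("one residue index per atom required")
    n_res = len(np.unique(residue_index))
    if n_res < 3:
        raise DataError("need at least 3 residues with heavy-atom coordinates")
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    contacts = []
    for a, b in pairs:
        ri, rj = residue_index[a], residue_index[b]
        if ri > rj:
            ri, rj = rj, ri
        sep = rj - ri
        if sep >= min_separation:
            contacts.append((int(ri), int(rj), int(sep)))
    return ChainContacts(
        residue_count=n_res, contacts=contacts,
        cutoff=cutoff, min_separation=min_separation,
    )


def _chain_heavy_atoms(structure: gemmi.Structure, chain_id: str | None):
    structure.setup_entities()
    model = structure[0]
    polymer_chains = [ch for ch in model if ch.get_polymer()]
    if chain_id is None:
        if len(polymer_chains) > 1:
            raise DataError(
                f"structure has {len(polymer_chains)} polymer chains "
                f"({', '.join(ch.name for ch in polymer_chains)}); select one "
                "with chain_id"
            )
        if not polymer_chains:
            raise DataError("no polymer chain found")
        chain = polymer_chains[0]
    else:
        match = [ch for ch in model if ch.name == chain_id]
        if not match:
            raise DataError(f"chain '{chain_id}' not found")
        chain = match[0]
    coords, res_idx = [], []
    seq_i = 0
    last_seqid = None
    for residue in chain:
        info = gemmi.find_tabulated_residue(residue.name)
        if info is None or not info.is_amino_acid():
            continue
        if last_seqid is not None and residue.seqid.num - last_seqid > 1:
            logger.info(
                "gap before residue %s%d; numbering compacted",
                residue.name, residue.seqid.num,
            )
        last_seqid = residue.seqid.num
        seq_i += 1
        for atom in residue:
            if atom.element == gemmi.Element("H") or atom.element == gemmi.Element("D"):
                continue
            coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
            res_idx.append(seq_i)
    if seq_i < 3:
        raise DataError("need at least 3 residues with heavy-atom coordinates")
    return np.array(coords), np.array(res_idx)


def relative_contact_order(
    path_or_structure,
    cutoff: float = 6.0,
    min_separation: int = 2,
    chain_id: str | None = None,
):
    """Relative contact order of a single chain.

    Accepts a PDB/mmCIF file path or a ``gemmi.Structure``.  Residues
    missing from the model are skipped and the chain length L is the count
    of resolved residues (numbering compacted across gaps).  Returns
    ``(rco, n_contacts)``.
    """
    if isinstance(path_or_structure, gemmi.Structure):
        structure = path_or_structure
    else:
        structure = gemmi.read_structure(str(Path(path_or_structure)))
    coords, res_idx = _chain_heavy_atoms(structure, chain_id)
    cc = contacts_from_coords(coords, res_idx, cutoff, min_separation)
    return cc.rco, cc.n_contacts
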