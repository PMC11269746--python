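"""Structure-derived site groups: interface and ligand contacts, and the
mapping from structure residue numbers to alignment columns.

Contacts follow an any-atom distance rule (default 5.0 Å, inclusive): a
subject-chain residue is a contact when any of its atoms lies within the
cutoff of any counterpart atom (another chain, or a ligand by residue name).
PDB input is parsed through gemmi.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

from .errors import InvalidArgumentError, ParseError

__all__ = [
    "AtomRecord",
    "ContactSet",
    "parse_structure",
    "chain_interface",
    "ligand_contacts",
    "map_residues_to_msa",
]

_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True)
class AtomRecord:
    """One atom with chain, residue and Cartesian coordinates (Å)."""

    chain: str
    resnum: int
    resname: str
    atom: str
    x: float
    y: float
    z: float
    het: bool = False
    altloc: str = ""


@dataclass
class ContactSet:
    """Subject-chain residues in contact with a counterpart at a cutoff."""

    residues: set[tuple[str, int]]
    cutoff: float
    counterpart: str
    min_distance: dict[tuple[str, int], float] = field(default_factory=dict)

    def resnums(self) -> set[int]:
        return {r for _, r in self.residues}

    def __len__(self) -> int:
        return len(self.residues)


def parse_structure(
    pdb_text: str, keep_waters: bool = False, altloc: str = "first"
) -> list[AtomRecord]:
    """Parse PDB-format ATOM/HETATM records.

    Keeps the first altloc per (chain, residue, atom name) by default
    (``altloc='occupancy'`` keeps the highest-occupancy conformer); waters
    are excluded unless requested.
    """
    if altloc not in ("first", "occupancy"):
        raise InvalidArgumentError("altloc policy must be 'first' or 'occupancy'")
    try:
        structure = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"could not parse PDB input: {exc}") from exc
    records: list[AtomRecord] = []
    chosen: dict[tuple[str, int, str], tuple[float, int]] = {}
    if len(structure) == 0:
        return records
    model = structure[0]
    for chain in model:
        for residue in chain:
            resname = residue.name.strip()
            if not keep_waters and resname in _WATER_NAMES:
                continue
            het = residue.het_flag == "H"
            for atom in residue:
                key = (chain.name, residue.seqid.num, atom.name)
                rec = AtomRecord(
                    chain=chain.name,
                    resnum=residue.seqid.num,
                    resname=resname,
                    atom=atom.name,
                    x=atom.pos.x,
                    y=atom.pos.y,
                    z=atom.pos.z,
                    het=het,
                    altloc=atom.altloc or "",
                )
                if key in chosen:
                    occ_old, idx = chosen[key]
                    if altloc == "occupancy" and atom.occ > occ_old:
                        records[idx] = rec
                        chosen[key] = (atom.occ, idx)
                    continue  # 'first' policy: keep the existing conformer
                chosen[key] = (atom.occ, len(records))
                records.append(rec)
    return records


def _coords(atoms: Sequence[AtomRecord]) -> np.ndarray:
    return np.array([[a.x, a.y, a.z] for a in atoms])


def _contact_set(subject: list[AtomRecord], counterpart: list[AtomRecord],
                 cutoff: float, label: str) -> ContactSet:
    if cutoff < 0:
        raise InvalidArgumentError("cutoff must be >= 0")
    result = ContactSet(set(), cutoff, label)
    if not subject or not counterpart:
        return result
    d = cdist(_coords(subject), _coords(counterpart))
    mins = d.min(axis=1)
    for atom, dist in zip(subject, mins):
        key = (atom.chain, atom.resnum)
        prev = result.min_distance.get(key)
        if prev is None or dist < prev:
            result.min_distance[key] = float(dist)
    for key, dist in result.min_distance.items():
        if dist <= cutoff:
            result.residues.add(key)
    return result


def chain_interface(
    atoms: Sequence[AtomRecord],
    subject_chain: str,
    counterpart_chain: str,
    cutoff: float = 5.0,
) -> ContactSet:
    """Subject-chain residues with any atom within `cutoff` (inclusive) of
    any counterpart-chain atom."""
    subject = [a for a in atoms if a.chain == subject_chain]
    counterpart = [a for a in atoms if a.chain == counterpart_chain]
    if not subject:
        raise KeyError(f"chain {subject_chain!r} not present")
    if not counterpart:
        raise KeyError(f"chain {counterpart_chain!r} not present")
    return _contact_set(subject, counterpart, cutoff, f"chain {counterpart_chain}")


def ligand_contacts(
    atoms: Sequence[AtomRecord],
    subject_chain: str,
    ligand_resname: str,
    cutoff: float = 5.0,
) -> ContactSet:
    """Subject-chain residues with any atom within `cutoff` of any atom of
    the named (HETATM) ligand."""
    subject = [
        a for a in atoms if a.chain == subject_chain and a.resname != ligand_resname
    ]
    ligand = [a for a in atoms if a.resname == ligand_resname]
    if not subject:
        raise KeyError(f"chain {subject_chain!r} not present")
    if not ligand:
        raise KeyError(f"ligand {ligand_resname!r} not found")
    return _contact_set(subject, ligand, cutoff, f"ligand {ligand_resname}")


def map_residues_to_msa(
    reference_seq_id: str,
    msa: Mapping[str, str],
    residue_numbers: Sequence[int],
    offset: int = 0,
) -> tuple[dict[int, int], list[int]]:
    """Map structure residue numbers to 1-based alignment columns.

    The k-th non-gap character of the reference alignment row corresponds to
    residue number ``offset + k``.  Returns (residue -> column, unmapped
    residues).
    """
    if reference_seq_id not in msa:
        raise KeyError(f"reference {reference_seq_id!r} not in alignment")
    ref = msa[reference_seq_id]
    col_of: dict[int, int] = {}
    k = 0
    for col, ch in enumerate(ref, start=1):
        if ch not in "-.":
            k += 1
            col_of[offset + k] = col
    mapped: dict[int, int] = {}
    unmapped: list[int] = []
    for r in residue_numbers:
        if r in col_of:
            mapped[r] = col_of[r]
        else:
            unmapped.append(int(r))
    return mapped, unmapped
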