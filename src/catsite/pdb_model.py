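"""Protein-chain model: PDB parsing, chain/ligand extraction and dataset filtering.

A structure is decomposed into individual polymer chains; every hetero group
(excluding water) becomes a candidate ligand and is attached to the chain
whose C-alpha trace it is nearest to.  Dataset cleaning then keeps chains
with at least ``min_residues`` amino acids and ligands with at least
``min_heavy`` non-hydrogen atoms whose minimum distance to the chain's
C-alpha atoms is at most ``max_min_dist`` angstroms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: van der Waals radii (angstrom) for the elements the workflow types.
VDW_RADII = {
    "H": 1.2, "D": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "MG": 1.73, "ZN": 1.39, "MN": 2.05, "CA": 2.31, "FE": 2.05,
    "NA": 2.27, "K": 2.75, "CU": 1.4, "NI": 1.63, "CO": 2.0,
}
DEFAULT_VDW = 1.7

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O", "TIP", "SOL"}


class ParseError(ValueError):
    """Raised when a PDB record cannot be interpreted."""


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)


@dataclass
class Atom:
    """One atom with element, position and van der Waals radius."""

    element: str
    coords: np.ndarray
    name: str = ""
    res_name: str = ""
    res_id: tuple = (1, "")  # (residue number, insertion code)
    is_heavy: bool = True
    vdw_radius: float = DEFAULT_VDW

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom coords must be a finite 3-vector, got {self.coords!r}")
        self.element = self.element.upper()
        self.is_heavy = self.element not in ("H", "D")
        self.vdw_radius = vdw_radius(self.element)


@dataclass
class Ligand:
    """A hetero group: identifier plus its atoms."""

    het_id: str
    atoms: list
    res_seq: int = 0
    source: str = ""   # "structureid_chain" the ligand was observed on

    @property
    def heavy_atom_count(self) -> int:
        return sum(1 for a in self.atoms if a.is_heavy)

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        atoms = [a for a in self.atoms if a.is_heavy] if heavy_only else self.atoms
        return np.array([a.coords for a in atoms], dtype=float).reshape(-1, 3)


@dataclass
class ChainEntry:
    """One protein chain with its sequence, atoms, C-alpha trace and ligands."""

    structure_id: str
    chain_id: str
    sequence: str
    atoms: list
    ca_coords: np.ndarray
    ligands: list = field(default_factory=list)

    def __post_init__(self):
        self.ca_coords = np.asarray(self.ca_coords, dtype=float).reshape(-1, 3)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def atom_coords(self, heavy_only: bool = False) -> np.ndarray:
        atoms = [a for a in self.atoms if a.is_heavy] if heavy_only else self.atoms
        return np.array([a.coords for a in atoms], dtype=float).reshape(-1, 3)


def _one_letter(res_name: str) -> str:
    info = gemmi.find_tabulated_residue(res_name)
    if info is None or not info.is_amino_acid():
        return "X"
    code = info.one_letter_code.upper()
    return code if code.isalpha() else "X"


def _is_amino(res_name: str) -> bool:
    info = gemmi.find_tabulated_residue(res_name)
    return info is not None and info.is_amino_acid()


def _keep_altloc(altloc: str) -> bool:
    return altloc in ("", "A", "\0")


def parse_structure(pdb_text: str, structure_id: str | None = None) -> list[ChainEntry]:
    """Parse PDB-format text into per-chain entries.

    ATOM records of amino-acid residues define polymer chains; HETATM groups
    (grouped by residue name, chain and residue number) become candidate
    ligands attached to the nearest chain by C-alpha distance.  Waters are
    always discarded.  Chains without any C-alpha atom are skipped with a
    warning.  Only altloc '' or 'A' atoms are kept.
    """
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # gemmi reports the line in its message
        raise ParseError(f"malformed PDB record: {exc}") from exc
    if len(st) == 0:
        return []
    sid = structure_id or (st.name.lower() if st.name else "struct")
    model = st[0]

    entries: list[ChainEntry] = []
    het_groups: list[Ligand] = []
    for chain in model:
        seq = []
        atoms: list[Atom] = []
        ca = []
        for res in chain:
            if res.name in WATER_NAMES:
                continue
            res_atoms = [
                Atom(a.element.name, [a.pos.x, a.pos.y, a.pos.z], name=a.name,
                     res_name=res.name, res_id=(res.seqid.num, res.seqid.icode.strip()))
                for a in res if _keep_altloc(a.altloc)
            ]
            if not res_atoms:
                continue
            if _is_amino(res.name):
                seq.append(_one_letter(res.name))
                atoms.extend(res_atoms)
                for a in res_atoms:
                    if a.name == "CA":
                        ca.append(a.coords)
                        break
            else:
                het_groups.append(
                    Ligand(het_id=res.name, atoms=res_atoms, res_seq=res.seqid.num)
                )
        if seq:
            if not ca:
                logger.warning("chain %s/%s has no C-alpha atoms; skipped", sid, chain.name)
                continue
            entries.append(ChainEntry(sid, chain.name, "".join(seq), atoms,
                                      np.array(ca), []))

    # attach every hetero group to the chain whose C-alpha set is nearest
    for lig in het_groups:
        if not entries:
            break
        lig_xyz = lig.coords()
        best, best_d = None, np.inf
        for entry in entries:
            d = np.linalg.norm(entry.ca_coords[:, None, :] - lig_xyz[None, :, :],
                               axis=-1).min()
            if d < best_d:
                best, best_d = entry, d
        lig.source = f"{best.structure_id}_{best.chain_id}"
        best.ligands.append(lig)
    return entries


def write_pdb(entries: list[ChainEntry]) -> str:
    """Emit ATOM/HETATM/TER records for the given chain entries."""
    lines = []
    serial = 1

    def fmt(record, serial, name, res_name, chain_id, res_seq, icode, xyz, element):
        nm = name if len(name) >= 4 else f" {name:<3s}"
        return (f"{record:<6s}{serial:>5d} {nm:<4s}{'':1s}{res_name:>3s} "
                f"{chain_id:1s}{res_seq:>4d}{icode or ' ':1s}   "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {element:>2s}")

    for entry in entries:
        for a in entry.atoms:
            lines.append(fmt("ATOM", serial, a.name or a.element, a.res_name or "UNK",
                             entry.chain_id, a.res_id[0], a.res_id[1], a.coords,
                             a.element))
            serial += 1
        lines.append(f"TER   {serial:>5d}      {'':3s} {entry.chain_id:1s}")
        serial += 1
        for lig in entry.ligands:
            for a in lig.atoms:
                lines.append(fmt("HETATM", serial, a.name or a.element, lig.het_id,
                                 entry.chain_id, lig.res_seq or a.res_id[0],
                                 "", a.coords, a.element))
                serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def filter_chains(entries: list[ChainEntry], min_residues: int = 28) -> list[ChainEntry]:
    """Keep chains with at least ``min_residues`` amino acids (order preserved)."""
    if min_residues < 1:
        raise ValueError("min_residues must be >= 1")
    return [e for e in entries if e.n_residues >= min_residues]


def min_ligand_ca_distance(lig: Ligand, ca_coords: np.ndarray) -> float:
    """Minimum distance between any ligand atom and any chain C-alpha atom."""
    xyz = lig.coords()
    if xyz.size == 0 or ca_coords.size == 0:
        return np.inf
    return float(np.linalg.norm(ca_coords[:, None, :] - xyz[None, :, :], axis=-1).min())


def filter_ligands(entry: ChainEntry, min_heavy: int = 7,
                   max_min_dist: float = 5.0) -> ChainEntry:
    """Keep ligands with >= ``min_heavy`` heavy atoms lying within
    ``max_min_dist`` angstroms of the chain's C-alpha trace (both inclusive).
    """
    kept = [
        lig for lig in entry.ligands
        if lig.heavy_atom_count >= min_heavy
        and min_ligand_ca_distance(lig, entry.ca_coords) <= max_min_dist
    ]
    return ChainEntry(entry.structure_id, entry.chain_id, entry.sequence,
                      entry.atoms, entry.ca_coords, kept)
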