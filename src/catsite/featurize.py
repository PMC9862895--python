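"""Voxel featurization: atom typing, chemical-property grids, SAS points, labels.

Every atom receives one AutoDock-style type code (aliphatic/aromatic carbon,
acceptor nitrogen/oxygen/sulfur, polar hydrogen, metal, ...) which maps onto
eight boolean property channels: hydrophobicity, aromaticity, H-bond
acceptor, H-bond donor, positive ionizability, negative ionizability, metal,
and excluded volume (the last is set for every atom).  The spatial influence
of an atom on a point at distance d is the occupancy

    occ(d) = 1 - exp(-(r_vdw / d)^12),

a smooth step that is ~1 inside the van der Waals sphere and falls below
1e-4 at about 2.15 r_vdw.  A property grid is an 8-channel 19x19x19 cube of
per-channel maxima of the occupancy over the atoms carrying that channel.

Surface points are a solvent-accessible dot surface: icosphere vertices on
each heavy atom's expanded sphere (r_vdw + solvent radius), with points
buried inside any other expanded sphere removed.  A surface point is
labelled ligandable when the excluded-volume occupancy of some retained
ligand exceeds 1e-4 there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .pdb_model import Atom, ChainEntry, Ligand

logger = logging.getLogger(__name__)

CHANNELS = ("hydrophobic", "aromatic", "acceptor", "donor",
            "positive", "negative", "metal", "excluded")
N_CHANNELS = len(CHANNELS)
GRID_SIZE = 19
DEFAULT_SPACING = 1.0
DEFAULT_SOLVENT_RADIUS = 1.4
DEFAULT_TESS_LEVEL = 4
LIGANDABLE_THRESHOLD = 1e-4

METAL_ELEMENTS = {"MG", "ZN", "MN", "CA", "FE"}

# type code -> channel memberships beyond excluded volume
_TYPE_CHANNELS = {
    "C": {"hydrophobic"},
    "A": {"hydrophobic", "aromatic"},
    "NA": {"acceptor"},
    "NS": {"acceptor"},
    "OA": {"acceptor"},
    "OS": {"acceptor"},
    "SA": {"acceptor"},
    "HD": {"donor"},
    "HS": {"donor"},
    "N": set(),       # non-acceptor nitrogen
    "MG": {"metal", "positive"},
    "ZN": {"metal", "positive"},
    "MN": {"metal", "positive"},
    "CA": {"metal", "positive"},
    "FE": {"metal", "positive"},
    "other": set(),
}

# aromatic ring carbons per residue (side-chain typing templates)
_AROMATIC_CARBONS = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "CD2", "CE1"},
}
# formally charged side-chain atoms (template formal charges)
_POSITIVE_ATOMS = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2")}
_NEGATIVE_ATOMS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
# side-chain nitrogens that accept an H-bond; all other N are donors/amides
_ACCEPTOR_NITROGENS = {("HIS", "ND1"), ("HIS", "NE2")}

_COVALENT_RADII = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05,
                   "P": 1.07, "F": 0.57, "CL": 1.02, "BR": 1.2, "I": 1.39}


@dataclass
class TypedAtom:
    """An atom with its chemistry type code and 8-channel membership vector."""

    base: Atom
    type_code: str
    channels: np.ndarray  # bool (8,)

    @classmethod
    def from_code(cls, atom: Atom, code: str, extra: set = frozenset()) -> "TypedAtom":
        members = _TYPE_CHANNELS.get(code, set()) | set(extra) | {"excluded"}
        bits = np.array([c in members for c in CHANNELS], dtype=bool)
        return cls(atom, code, bits)


def _protein_atom_type(atom: Atom) -> tuple:
    """(type code, extra channels) for an atom in a standard residue context."""
    el, res, name = atom.element, atom.res_name, atom.name
    extra = set()
    if (res, name) in _POSITIVE_ATOMS:
        extra.add("positive")
    if (res, name) in _NEGATIVE_ATOMS:
        extra.add("negative")
    if el == "C":
        code = "A" if name in _AROMATIC_CARBONS.get(res, ()) else "C"
    elif el == "N":
        code = "NA" if (res, name) in _ACCEPTOR_NITROGENS else "N"
    elif el == "O":
        code = "OA"
    elif el == "S":
        code = "SA"
    elif el in ("H", "D"):
        code = "HD" if name.startswith(("H", "D")) else "HS"
    elif el in METAL_ELEMENTS:
        code = el
    else:
        code = "other"
        logger.debug("untyped element %s (%s %s): excluded volume only", el, res, name)
    return code, extra


def _perceive_bonds(atoms: list) -> nx.Graph:
    """Distance-based bond perception (covalent radii, 1.3x slack)."""
    g = nx.Graph()
    g.add_nodes_from(range(len(atoms)))
    xyz = np.array([a.coords for a in atoms])
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            ri = _COVALENT_RADII.get(atoms[i].element, 1.0)
            rj = _COVALENT_RADII.get(atoms[j].element, 1.0)
            if np.linalg.norm(xyz[i] - xyz[j]) < 1.3 * (ri + rj):
                g.add_edge(i, j)
    return g


def _planar(xyz: np.ndarray, tol: float = 0.3) -> bool:
    centered = xyz - xyz.mean(axis=0)
    if len(centered) < 3:
        return False
    _, s, _ = np.linalg.svd(centered)
    return bool(s[-1] < tol * np.sqrt(len(centered)))


def _ligand_aromatic_indices(atoms: list, bonds: nx.Graph) -> set:
    """Carbons in planar 5/6-membered rings of C/N/O/S atoms."""
    aromatic = set()
    xyz = np.array([a.coords for a in atoms])
    for ring in nx.cycle_basis(bonds):
        if len(ring) not in (5, 6):
            continue
        if not all(atoms[i].element in ("C", "N", "O", "S") for i in ring):
            continue
        if _planar(xyz[ring]):
            aromatic.update(i for i in ring if atoms[i].element == "C")
    return aromatic


def assign_atom_types(obj: ChainEntry | Ligand) -> list:
    """Type every atom of a chain (residue templates) or ligand (perceived bonds)."""
    if isinstance(obj, ChainEntry):
        return [TypedAtom.from_code(a, *_protein_atom_type(a)) for a in obj.atoms]
    atoms = obj.atoms
    bonds = _perceive_bonds(atoms)
    aromatic = _ligand_aromatic_indices(atoms, bonds)
    typed = []
    for i, a in enumerate(atoms):
        el = a.element
        if el == "C":
            code = "A" if i in aromatic else "C"
        elif el == "N":
            code = "NA"
        elif el == "O":
            code = "OA"
        elif el == "S":
            code = "SA"
        elif el in ("H", "D"):
            partners = [atoms[j].element for j in bonds.neighbors(i)]
            code = "HD" if any(p in ("N", "O") for p in partners) else "HS"
        elif el in METAL_ELEMENTS:
            code = el
        else:
            code = "other"
        typed.append(TypedAtom.from_code(a, code))
    return typed


def occupancy(distance, vdw_radius):
    """Occupancy 1 - exp(-(r/d)^12); 1 at d=0, strictly decreasing in d."""
    d = np.asarray(distance, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(d > 0, vdw_radius / np.maximum(d, 1e-300), np.inf)
        occ = -np.expm1(-np.minimum(ratio**12, 7.0e2))
    occ = np.where(d <= 0, 1.0, occ)
    return occ if occ.shape else float(occ)


def occupancy_crossing_distance(vdw_radius: float,
                                level: float = LIGANDABLE_THRESHOLD) -> float:
    """Distance at which the occupancy decays to `level` (closed-form inverse)."""
    return float(vdw_radius * (-np.log1p(-level)) ** (-1.0 / 12.0))


@dataclass
class PropertyGrid:
    """8-channel cube of property values centered on one surface point."""

    values: np.ndarray    # (8, size, size, size) in [0, 1]
    center: np.ndarray
    spacing: float

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)


def grid_offsets(spacing: float = DEFAULT_SPACING, size: int = GRID_SIZE) -> np.ndarray:
    """Voxel-center offsets from the cube center, (size^3, 3), odd grid."""
    half = (size - 1) // 2
    ax = spacing * (np.arange(size) - half)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    return np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)


def _channel_fields(voxels: np.ndarray, typed_atoms: list) -> np.ndarray:
    """(8, n_voxels) per-channel max occupancy over the atoms."""
    n_vox = len(voxels)
    out = np.zeros((N_CHANNELS, n_vox))
    if not typed_atoms:
        return out
    xyz = np.array([t.base.coords for t in typed_atoms])
    radii = np.array([t.base.vdw_radius for t in typed_atoms])
    bits = np.array([t.channels for t in typed_atoms])  # (n_atoms, 8)
    # chunk voxels to bound the distance-matrix memory
    chunk = max(1, int(2e6) // max(len(xyz), 1))
    for lo in range(0, n_vox, chunk):
        v = voxels[lo:lo + chunk]
        d = np.linalg.norm(v[:, None, :] - xyz[None, :, :], axis=-1)
        occ = occupancy(d, radii[None, :])  # (chunk, n_atoms)
        for k in range(N_CHANNELS):
            sel = bits[:, k]
            if sel.any():
                out[k, lo:lo + chunk] = occ[:, sel].max(axis=1)
    return out


def compute_grid(typed_atoms: list, center, spacing: float = DEFAULT_SPACING,
                 size: int = GRID_SIZE) -> PropertyGrid:
    """Property cube centered at `center` (per-channel max aggregation)."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    center = np.asarray(center, dtype=float)
    voxels = center[None, :] + grid_offsets(spacing, size)
    fields = _channel_fields(voxels, typed_atoms)
    return PropertyGrid(fields.reshape(N_CHANNELS, size, size, size), center, spacing)


def compute_grids(typed_atoms: list, centers: np.ndarray,
                  spacing: float = DEFAULT_SPACING, size: int = GRID_SIZE,
                  occ_cutoff: float = 1e-6) -> np.ndarray:
    """Stacked grids for many centers, (n, 8, size, size, size), float32.

    Voxel-atom pairs beyond the distance where the occupancy falls under
    ``occ_cutoff`` are skipped (sparse neighbor search), which changes
    values by at most ``occ_cutoff`` relative to :func:`compute_grid`.
    """
    centers = np.asarray(centers, dtype=float).reshape(-1, 3)
    offsets = grid_offsets(spacing, size)
    n_vox = len(offsets)
    out = np.zeros((len(centers), N_CHANNELS, size, size, size), dtype=np.float32)
    if not typed_atoms:
        return out
    xyz = np.array([t.base.coords for t in typed_atoms])
    radii = np.array([t.base.vdw_radius for t in typed_atoms])
    bits = np.array([t.channels for t in typed_atoms])  # (n_atoms, 8)
    patterns, pattern_id = np.unique(bits, axis=0, return_inverse=True)
    reach = float(radii.max()) * occ_cutoff ** (-1.0 / 12.0)
    atom_tree = cKDTree(xyz)
    tmp = np.zeros((len(patterns), n_vox))
    for idx, c in enumerate(centers):
        voxels = c[None, :] + offsets
        pairs = cKDTree(voxels).sparse_distance_matrix(
            atom_tree, reach, output_type="ndarray")
        tmp[:] = 0.0
        if len(pairs):
            occ = occupancy(pairs["v"], radii[pairs["j"]])
            pat = pattern_id[pairs["j"]]
            for p in range(len(patterns)):
                sel = pat == p
                if sel.any():
                    np.maximum.at(tmp[p], pairs["i"][sel], occ[sel])
        fields = np.zeros((N_CHANNELS, n_vox), dtype=np.float32)
        for k in range(N_CHANNELS):
            members = patterns[:, k]
            if members.any():
                fields[k] = tmp[members].max(axis=0)
        out[idx] = fields.reshape(N_CHANNELS, size, size, size)
    return out


@dataclass
class SurfacePointSet:
    """SAS dot-surface points of one chain with labels and model predictions."""

    points: np.ndarray                 # (n, 3)
    is_ligandable: np.ndarray = None   # bool (n,)
    prediction: np.ndarray = None      # float (n,) in [0, 1]
    chain_ref: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.is_ligandable is None:
            self.is_ligandable = np.zeros(len(self.points), dtype=bool)
        self.is_ligandable = np.asarray(self.is_ligandable, dtype=bool)
        if self.prediction is not None:
            self.prediction = np.asarray(self.prediction, dtype=float)

    def __len__(self) -> int:
        return len(self.points)


def unit_sphere_points(tessellation_level: int) -> np.ndarray:
    """Vertices of a recursively subdivided icosahedron on the unit sphere."""
    mesh = trimesh.creation.icosphere(subdivisions=tessellation_level, radius=1.0)
    return np.asarray(mesh.vertices, dtype=float)


def sas_points(entry: ChainEntry, solvent_radius: float = DEFAULT_SOLVENT_RADIUS,
               tessellation_level: int = DEFAULT_TESS_LEVEL) -> SurfacePointSet:
    """Solvent-accessible dot surface of the chain's heavy atoms.

    Candidate points sit on each heavy atom's sphere of radius
    (r_vdw + solvent_radius); points buried inside any other atom's expanded
    sphere are discarded, and coincident duplicates (from exactly
    overlapping atoms) are removed.
    """
    heavy = [a for a in entry.atoms if a.is_heavy]
    if not heavy:
        raise ValueError("chain has no heavy atoms")
    unit = unit_sphere_points(tessellation_level)
    xyz = np.array([a.coords for a in heavy])
    radii = np.array([a.vdw_radius for a in heavy])
    expanded = radii + solvent_radius
    tree = cKDTree(xyz)
    eps = 1e-9
    kept = []
    for i, (c, r) in enumerate(zip(xyz, expanded)):
        cand = c[None, :] + r * unit
        neighbors = [j for j in tree.query_ball_point(c, r + expanded.max())
                     if j != i]
        if neighbors:
            d = np.linalg.norm(cand[:, None, :] - xyz[neighbors][None, :, :], axis=-1)
            buried = (d < expanded[neighbors][None, :] - eps).any(axis=1)
            cand = cand[~buried]
        kept.append(cand)
    pts = np.vstack(kept)
    # drop exact duplicates from coincident atoms
    _, uniq = np.unique(np.round(pts, 6), axis=0, return_index=True)
    pts = pts[np.sort(uniq)]
    return SurfacePointSet(pts, chain_ref=f"{entry.structure_id}_{entry.chain_id}")


def ligand_occupancy(points: np.ndarray, ligand: Ligand) -> np.ndarray:
    """Max excluded-volume occupancy of one ligand at each point."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    xyz = ligand.coords()
    if xyz.size == 0:
        return np.zeros(len(points))
    radii = np.array([a.vdw_radius for a in ligand.atoms])
    d = np.linalg.norm(points[:, None, :] - xyz[None, :, :], axis=-1)
    return occupancy(d, radii[None, :]).max(axis=1)


def label_ligandability(points: SurfacePointSet, ligands: list,
                        threshold: float = LIGANDABLE_THRESHOLD) -> SurfacePointSet:
    """Label a point ligandable when some ligand's excluded-volume occupancy
    exceeds `threshold` there (strict)."""
    labels = np.zeros(len(points), dtype=bool)
    for lig in ligands:
        labels |= ligand_occupancy(points.points, lig) > threshold
    return SurfacePointSet(points.points, labels, points.prediction, points.chain_ref)


def write_grids(path, grids: np.ndarray, centers: np.ndarray,
                spacing: float = DEFAULT_SPACING, chain_ref: str = "") -> None:
    """Binary grid container: npz with a JSON header describing shape,
    spacing, grid centers and channel names."""
    import json

    grids = np.asarray(grids, dtype=np.float32)
    header = {"shape": list(grids.shape), "spacing": float(spacing),
              "channels": list(CHANNELS), "chain_ref": chain_ref}
    np.savez_compressed(
        path, header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
        grids=grids, centers=np.asarray(centers, dtype=np.float64))


def read_grids(path) -> tuple:
    """Inverse of write_grids: (grids, centers, header dict)."""
    import json

    with np.load(path) as data:
        header = json.loads(bytes(data["header"]).decode())
        return data["grids"], data["centers"], header


def write_points_tsv(points: SurfacePointSet, path) -> None:
    """Serialize points as TSV (x, y, z, label, prediction)."""
    pred = points.prediction if points.prediction is not None \
        else np.full(len(points), np.nan)
    with open(path, "w") as fh:
        fh.write("x\ty\tz\tlabel\tprediction\n")
        for p, lab, pr in zip(points.points, points.is_ligandable, pred):
            fh.write(f"{p[0]:.3f}\t{p[1]:.3f}\t{p[2]:.3f}\t{int(lab)}\t{pr:.6f}\n")


def read_points_tsv(path, chain_ref: str = "") -> SurfacePointSet:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    pred = df["prediction"].to_numpy() if "prediction" in df else None
    lab = df["label"].to_numpy(dtype=bool) if "label" in df else None
    return SurfacePointSet(df[["x", "y", "z"]].to_numpy(), lab, pred, chain_ref)
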