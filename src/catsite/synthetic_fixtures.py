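"""Synthetic inputs for every stage of the workflow.

Three generators, all pure functions of (spec, seed):

* toy protein chains -- a compact self-avoiding C-alpha walk decorated with
  backbone and side-chain pseudo-atoms, with concave pockets carved at
  surface anchors and a rigid ligand planted in each pocket (within 5 A of
  a C-alpha), emitted as PDB text plus ground-truth pocket annotations;
* amino-acid sequence families with a controlled point-mutation rate, for
  clustering tests;
* pointwise ligandability score fields with planted binding-site blobs,
  for exercising the site-grouping algorithm without a trained model.

The geometry is deliberately not physically realistic (no rotamers, no
energetics); it only needs to satisfy the workflow's structural contracts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .pdb_model import Atom, ChainEntry, Ligand, write_pdb

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
AA_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}

CA_STEP = 3.8
SELF_AVOID = 3.5


@dataclass
class FixtureSpec:
    """Parameters of one synthetic structure."""

    seed: int = 0
    n_residues: int = 60
    n_pockets: int = 2
    pocket_radius: float = 3.5    # carve margin around ligand atoms
    ligand_size: int = 8          # heavy atoms
    ligand_shape: str = "ring"    # "ring" | "blob" | "chain"
    sequence_mutation_rate: float = 0.05
    noise_sigma: float = 0.05
    structure_id: str = "toy1"
    chain_id: str = "A"

    def __post_init__(self):
        if self.n_residues < 1 or self.n_pockets < 0 or self.ligand_size < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.sequence_mutation_rate <= 1:
            raise ValueError("mutation rate must be in [0, 1]")
        if self.ligand_shape not in ("ring", "blob", "chain"):
            raise ValueError("ligand_shape must be ring, blob or chain")


@dataclass
class ToyProtein:
    entry: ChainEntry
    pdb_text: str
    pockets: list = field(default_factory=list)  # [{"center", "ligand_index"}]

    def truth_json(self) -> str:
        return json.dumps({"pockets": [
            {"center": list(map(float, p["center"])),
             "ligand_index": p["ligand_index"]} for p in self.pockets
        ]}, indent=1)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _ca_walk(n: int, rng) -> np.ndarray:
    """Compact self-avoiding walk with 3.8 A steps, biased toward its centroid."""
    pts = [np.zeros(3)]
    direction = _unit(rng.normal(size=3))
    for _ in range(n - 1):
        for attempt in range(200):
            centroid = np.mean(pts, axis=0)
            bias = _unit(centroid - pts[-1]) if len(pts) > 3 else np.zeros(3)
            proposal = _unit(direction + 0.9 * rng.normal(size=3)
                             + 0.35 * bias)
            cand = pts[-1] + CA_STEP * proposal
            d = np.linalg.norm(np.array(pts[:-1]) - cand, axis=1) \
                if len(pts) > 1 else np.array([np.inf])
            if d.min() > SELF_AVOID:
                pts.append(cand)
                direction = proposal
                break
        else:
            raise RuntimeError("self-avoiding walk failed to place a residue")
    return np.array(pts)


def _perp(v: np.ndarray, rng) -> np.ndarray:
    w = rng.normal(size=3)
    w -= w.dot(v) * v
    return _unit(w)


def _hexagon(bond: float = 1.4) -> np.ndarray:
    # regular hexagon: circumradius equals the bond length
    ang = np.arange(6) * np.pi / 3
    return np.stack([bond * np.cos(ang), bond * np.sin(ang),
                     np.zeros(6)], axis=1)


def _ligand_coords(size: int, shape: str, rng) -> tuple:
    """Heavy-atom coordinates and elements for one rigid ligand.

    ring  -- planar carbon hexagon plus jittered extra C/N/O atoms;
    blob  -- compact 3D cluster grown greedily toward its own centroid;
    chain -- elongated zig-zag, one atom per 1.25 angstrom of length.
    """
    extra_el = ["N", "O", "C"]
    if shape == "ring":
        coords = list(_hexagon())
        elements = ["C"] * 6
        k = 0
        while len(coords) < size:
            base = coords[k % 6]
            offset = _unit(rng.normal(size=3)) * 1.45
            cand = base + offset
            if min(np.linalg.norm(np.array(coords) - cand, axis=1)) > 1.1:
                coords.append(cand)
                elements.append(extra_el[k % len(extra_el)])
                k += 1
    elif shape == "blob":
        coords = [np.zeros(3)]
        elements = ["C"]
        while len(coords) < size:
            cur = np.array(coords)
            best = None
            for _ in range(30):
                base = cur[rng.integers(len(cur))]
                cand = base + _unit(rng.normal(size=3)) * 1.5
                if np.linalg.norm(cur - cand, axis=1).min() > 1.3:
                    r = np.linalg.norm(cand - cur.mean(axis=0))
                    if best is None or r < best[0]:
                        best = (r, cand)
            if best is None:
                continue
            coords.append(best[1])
            elements.append(extra_el[len(coords) % len(extra_el)])
    else:  # chain
        ii = np.arange(size)
        coords = list(np.stack([1.25 * ii, 0.5 * (-1.0) ** ii,
                                np.zeros(size)], axis=1)
                      + rng.normal(0, 0.15, size=(size, 3)))
        elements = ["C" if i % 3 else "N" for i in range(size)]
    return np.array(coords[:size]), elements[:size]


def _make_ligand(size: int, center: np.ndarray, rng, het_id: str,
                 res_seq: int, shape: str = "ring") -> Ligand:
    """Rigid ligand of the requested shape, randomly oriented at `center`."""
    coords, elements = _ligand_coords(size, shape, rng)
    # random rigid orientation, then translate to the pocket anchor
    q = rng.normal(size=(3, 3))
    u, _, vt = np.linalg.svd(q)
    rot = u @ vt
    if np.linalg.det(rot) < 0:
        rot[:, 0] *= -1
    coords = (coords - coords.mean(axis=0)) @ rot.T + center
    atoms = [Atom(el, xyz, name=f"{el}{i+1}", res_name=het_id,
                  res_id=(res_seq, ""))
             for i, (el, xyz) in enumerate(zip(elements, coords))]
    return Ligand(het_id, atoms, res_seq=res_seq)


def make_toy_protein(spec: FixtureSpec) -> ToyProtein:
    """Generate one toy chain with carved pockets and planted ligands."""
    rng = np.random.default_rng(spec.seed)
    if spec.n_residues < 2:
        raise ValueError("need at least 2 residues")
    ca = _ca_walk(spec.n_residues, rng)
    centroid = ca.mean(axis=0)
    seq = "".join(rng.choice(list(AA_LETTERS), size=spec.n_residues))

    atoms: list = []
    filler_index: list = []  # indices of carvable side-chain filler atoms
    for i, (letter, p) in enumerate(zip(seq, ca)):
        res = AA_THREE[letter]
        rid = (i + 1, "")
        prev_dir = _unit(ca[i] - ca[i - 1]) if i > 0 else _unit(ca[1] - ca[0])
        side = _perp(prev_dir, rng)
        outward = _unit(p - centroid)
        atoms.append(Atom("N", p - 1.2 * prev_dir + 0.4 * side, name="N",
                          res_name=res, res_id=rid))
        atoms.append(Atom("C", p + 1.2 * prev_dir + 0.4 * side, name="C",
                          res_name=res, res_id=rid))
        atoms.append(Atom("O", p + 1.2 * prev_dir + 1.5 * side, name="O",
                          res_name=res, res_id=rid))
        atoms.append(Atom("C", p, name="CA", res_name=res, res_id=rid))
        cb = p + 1.5 * outward
        atoms.append(Atom("C", cb, name="CB", res_name=res, res_id=rid))
        for j, tilt in enumerate((0.35, -0.35)):
            fil = cb + 1.4 * _unit(outward + tilt * side)
            atoms.append(Atom("C", fil, name=f"CG{j+1}", res_name=res,
                              res_id=rid))
            filler_index.append(len(atoms) - 1)

    # pocket anchor candidates: surface residues far from the centroid,
    # well separated; pockets are placed at the first candidates where a
    # clash-free ligand fits, so a bad anchor is skipped rather than fatal
    radial = np.linalg.norm(ca - centroid, axis=1)
    order = np.argsort(-radial)

    # place each ligand at an anchor, then carve the cavity complementary
    # to it: side-chain atoms within `pocket_radius` of a ligand atom are
    # removed (backbone N/CA/C/O stay so the sequence is untouched).  The
    # tight margin keeps the cavity surface close to the ligand, so labeled
    # points and pocket-shaped points largely coincide.
    carvable = np.array([a.name.startswith("C") and a.name not in ("C", "CA")
                         for a in atoms])
    backbone_xyz = np.array([a.coords for k, a in enumerate(atoms)
                             if not carvable[k]])
    atom_xyz = np.array([a.coords for a in atoms])

    ligands = []
    pockets = []
    used_anchors: list = []
    carve = np.zeros(len(atoms), dtype=bool)
    for i in order:
        if len(ligands) == spec.n_pockets:
            break
        anchor = ca[i] + 3.7 * _unit(ca[i] - centroid)
        if any(np.linalg.norm(anchor - a) <= 16.0 for a in used_anchors):
            continue
        center = anchor.copy()
        lig = None
        for attempt in range(30):  # re-orient / nudge until feasible
            cand = _make_ligand(spec.ligand_size, center, rng, het_id="LIG",
                                res_seq=900 + len(ligands),
                                shape=spec.ligand_shape)
            xyz = cand.coords()
            d_bb = np.linalg.norm(backbone_xyz[:, None, :] - xyz[None, :, :],
                                  axis=-1).min()
            dca = np.linalg.norm(ca[:, None, :] - xyz[None, :, :],
                                 axis=-1).min()
            if d_bb > 2.0 and dca <= 5.0:
                lig = cand
                break
            if attempt % 10 == 9:
                center = center + 0.4 * _unit(center - centroid)
        if lig is None:
            continue  # this anchor cannot host a ligand; try the next
        dmin = np.linalg.norm(atom_xyz[:, None, :] - lig.coords()[None, :, :],
                              axis=-1).min(axis=1)
        carve |= carvable & (dmin < spec.pocket_radius)
        used_anchors.append(anchor)
        ligands.append(lig)
        pockets.append({"center": lig.coords().mean(axis=0),
                        "ligand_index": len(ligands) - 1})
    if len(ligands) < spec.n_pockets:
        raise RuntimeError("could not place the requested number of pockets")

    kept_atoms = [a for k, a in enumerate(atoms) if not carve[k]]
    entry = ChainEntry(spec.structure_id, spec.chain_id, seq, kept_atoms,
                       ca, ligands)
    return ToyProtein(entry, write_pdb([entry]), pockets)


def make_sequence_family(base_len: int, n_members: int, mutation_rate: float,
                         seed: int, base: str | None = None) -> list:
    """Point-substitution family around one random base sequence."""
    if base_len < 10:
        raise ValueError("base_len must be >= 10")
    rng = np.random.default_rng(seed)
    letters = np.array(list(AA_LETTERS))
    if base is None:
        base = "".join(rng.choice(letters, size=base_len))
    members = []
    for _ in range(n_members):
        chars = list(base)
        for i in range(len(chars)):
            if rng.random() < mutation_rate:
                options = [c for c in AA_LETTERS if c != chars[i]]
                chars[i] = options[rng.integers(len(options))]
        members.append("".join(chars))
    return members


def make_prediction_field(points: np.ndarray, planted_sites: list,
                          noise_sigma: float, seed: int) -> np.ndarray:
    """Scores 0.9 inside planted sites, 0.05 outside, plus clipped noise."""
    rng = np.random.default_rng(seed)
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    base = np.full(len(points), 0.05)
    for idx in planted_sites:
        base[np.asarray(idx, dtype=int)] = 0.9
    if noise_sigma > 0:
        base = base + rng.normal(0, noise_sigma, size=len(points))
    return np.clip(base, 0.0, 1.0)


def make_point_cloud(n_points: int, extent: float, seed: int) -> np.ndarray:
    """Uniform random points in a cube of side `extent` (surface stand-in)."""
    rng = np.random.default_rng(seed)
    return rng.uniform(-extent / 2, extent / 2, size=(n_points, 3))


def plant_sites(points: np.ndarray, n_sites: int, radius: float,
                seed: int, min_separation: float = None) -> list:
    """Choose well-separated centers and return per-site point-index arrays."""
    rng = np.random.default_rng(seed)
    points = np.asarray(points, dtype=float)
    min_separation = min_separation or 3.0 * radius
    centers = []
    order = rng.permutation(len(points))
    for i in order:
        c = points[i]
        if all(np.linalg.norm(c - o) > min_separation for o in centers):
            centers.append(c)
        if len(centers) == n_sites:
            break
    if len(centers) < n_sites:
        raise RuntimeError("could not place well-separated sites")
    return [np.flatnonzero(np.linalg.norm(points - c, axis=1) <= radius)
            for c in centers]
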