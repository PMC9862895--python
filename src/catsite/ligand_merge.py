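"""Merging ligands of similar chains onto one representative chain.

Within each sequence cluster the chains are sorted by how much ligand
information they carry, a representative is chosen, every other chain is
rigidly superposed onto it (Kabsch least-squares fit over the C-alpha pairs
matched by the local sequence alignment), and ligands from chains that fit
with RMSD below 2 angstroms are transplanted onto the representative --
unless they clash with an already kept ligand or with the chain, or end up
too far from the C-alpha trace.  Chains that cannot be merged are treated as
a fresh cluster and the procedure repeats, so every chain ends up either
merged away or as a representative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .pdb_model import Atom, ChainEntry, Ligand, min_ligand_ca_distance
from .seq_cluster import GAP, covering, similarity, smith_waterman

logger = logging.getLogger(__name__)

RMSD_MAX = 2.0        # strict upper bound for a mergeable superposition
CLASH_DIST = 1.5      # heavy-atom pair closer than this is a physical overlap
MAX_LIGAND_CA_DIST = 5.0


@dataclass
class Superposition:
    """Rigid-body map (rotation, translation) of a mobile chain onto a reference."""

    rotation: np.ndarray      # 3x3, det +1
    translation: np.ndarray   # 3-vector
    matched_pairs: list       # [(ref_residue_idx, mobile_residue_idx), ...]
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def rmsd(p1: np.ndarray, p2: np.ndarray) -> float:
    """Root mean square deviation over matched point pairs."""
    p1 = np.asarray(p1, dtype=float).reshape(-1, 3)
    p2 = np.asarray(p2, dtype=float).reshape(-1, 3)
    if p1.shape != p2.shape:
        raise ValueError("point lists must have equal length")
    if len(p1) == 0:
        raise ValueError("need at least one pair")
    return float(np.sqrt(np.mean(np.sum((p1 - p2) ** 2, axis=1))))


def kabsch(mobile: np.ndarray, ref: np.ndarray) -> tuple:
    """Least-squares rotation + translation mapping `mobile` onto `ref`."""
    mobile = np.asarray(mobile, dtype=float)
    ref = np.asarray(ref, dtype=float)
    mu_m, mu_r = mobile.mean(axis=0), ref.mean(axis=0)
    h = (mobile - mu_m).T @ (ref - mu_r)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = mu_r - rot @ mu_m
    return rot, trans


def matched_ca_pairs(ref: ChainEntry, mobile: ChainEntry) -> tuple:
    """Residue index pairs from non-gap columns of the local alignment,
    plus the alignment's similarity and the two coverings."""
    swapped = mobile.sequence < ref.sequence
    a, b = (mobile, ref) if swapped else (ref, mobile)
    aln = smith_waterman(a.sequence, b.sequence)
    s = similarity(aln)
    if aln.N == 0:
        return [], 0.0, 0.0, 0.0
    cov_a = covering(len(a.sequence), aln.span_a)
    cov_b = covering(len(b.sequence), aln.span_b)
    pairs = []
    ia, ib = aln.span_a[0] - 1, aln.span_b[0] - 1
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x != GAP and y != GAP:
            pairs.append((ib, ia) if swapped else (ia, ib))
        if x != GAP:
            ia += 1
        if y != GAP:
            ib += 1
    if swapped:
        cov_a, cov_b = cov_b, cov_a
    return pairs, s, cov_a, cov_b


def superpose(ref: ChainEntry, mobile: ChainEntry, seqid: float = 0.9,
              overlap: float = 0.9) -> Superposition | None:
    """Rigid superposition of `mobile` onto `ref`, gated on sequence
    similarity > seqid and both coverings > overlap.  Returns None on failure."""
    pairs, s, cov_r, cov_m = matched_ca_pairs(ref, mobile)
    if s <= seqid or cov_r <= overlap or cov_m <= overlap:
        return None
    pairs = [(i, j) for i, j in pairs
             if i < len(ref.ca_coords) and j < len(mobile.ca_coords)]
    if len(pairs) < 3:
        return None
    p_ref = ref.ca_coords[[i for i, _ in pairs]]
    p_mob = mobile.ca_coords[[j for _, j in pairs]]
    rot, trans = kabsch(p_mob, p_ref)
    fitted = p_mob @ rot.T + trans
    return Superposition(rot, trans, pairs, rmsd(fitted, p_ref))


def sort_chains(cluster: list) -> list:
    """Descending by ligand count, then by total ligand atom count (stable)."""
    return sorted(cluster, key=lambda e: (-len(e.ligands),
                                          -sum(len(l.atoms) for l in e.ligands)))


def _clash(xyz_a: np.ndarray, xyz_b: np.ndarray, cutoff: float = CLASH_DIST) -> bool:
    if xyz_a.size == 0 or xyz_b.size == 0:
        return False
    d = np.linalg.norm(xyz_a[:, None, :] - xyz_b[None, :, :], axis=-1)
    return bool(d.min() < cutoff)


def _transform_ligand(lig: Ligand, sup: Superposition) -> Ligand:
    new_atoms = [Atom(a.element, sup.apply(a.coords[None, :])[0], name=a.name,
                      res_name=a.res_name, res_id=a.res_id) for a in lig.atoms]
    return Ligand(lig.het_id, new_atoms, res_seq=lig.res_seq,
                  source=lig.source)


def merge_cluster(cluster: list, seqid: float = 0.9, overlap: float = 0.9,
                  rmsd_max: float = RMSD_MAX) -> list:
    """Merge ligands within one cluster onto representative chains.

    Returns the representatives; every input chain is accounted for (merged
    into a representative or itself a representative).  Source ligands are
    used at most once and representative coordinates are never modified.
    """
    if not cluster:
        raise ValueError("cluster must be non-empty")
    remaining = list(cluster)
    representatives = []
    while remaining:
        ordered = sort_chains(remaining)
        others_of_ref = None
        ref = None
        # find a chain that superposes well with at least half of the others
        for cand in ordered:
            others = [c for c in ordered if c is not cand]
            sups = {id(c): superpose(cand, c, seqid, overlap) for c in others}
            ok = [c for c in others
                  if sups[id(c)] is not None and sups[id(c)].rmsd < rmsd_max]
            if not others or len(ok) * 2 >= len(others):
                ref, others_of_ref = cand, (others, sups)
                break
        if ref is None:  # nothing aligns: keep the best-ranked chain as-is
            ref = ordered[0]
            others_of_ref = ([c for c in ordered if c is not ref], {})
        others, sups = others_of_ref

        kept = list(ref.ligands)
        ref_xyz = ref.atom_coords(heavy_only=True)
        merged_away = []
        for chain in others:
            sup = sups.get(id(chain))
            if sup is None or sup.rmsd >= rmsd_max:
                continue
            for lig in sorted(chain.ligands, key=lambda l: -l.heavy_atom_count):
                moved = _transform_ligand(lig, sup)
                xyz = moved.coords(heavy_only=True)
                if any(_clash(xyz, k.coords(heavy_only=True)) for k in kept):
                    continue
                if _clash(xyz, ref_xyz):
                    continue
                if min_ligand_ca_distance(moved, ref.ca_coords) > MAX_LIGAND_CA_DIST:
                    continue
                kept.append(moved)
            merged_away.append(chain)
        representatives.append(
            ChainEntry(ref.structure_id, ref.chain_id, ref.sequence,
                       ref.atoms, ref.ca_coords, kept))
        absorbed = {id(ref)} | {id(c) for c in merged_away}
        remaining = [c for c in remaining if id(c) not in absorbed]
    return representatives
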