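"""Sequence clustering by local alignment similarity.

All chain pairs are aligned with the Smith-Waterman algorithm (affine gaps,
BLOSUM62 by default).  For an aligned pair the similarity is the fraction of
identical aligned columns, and the covering of each input is the fraction of
that sequence spanned by its aligned region.  Two sequences are joined by an
edge when similarity exceeds ``s_bar`` and both coverings exceed ``c_bar``
(all three strictly); clusters are the connected components of this graph.

The clustering deliberately runs the full all-pairs dynamic program without
any k-mer prefilter -- the intended inputs are dataset-scale chain sets, not
sequence databases.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
import numpy as np
from Bio.Align import substitution_matrices

GAP = "-"
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0


@lru_cache(maxsize=None)
def blosum62() -> dict:
    """BLOSUM62 as a dict over residue-letter pairs (symmetric, includes X)."""
    mat = substitution_matrices.load("BLOSUM62")
    table = {}
    for a in mat.alphabet:
        for b in mat.alphabet:
            table[(a, b)] = float(mat[a, b])
    return table


def _sub_score(table: dict, a: str, b: str) -> float:
    a = a if (a, a) in table else "X"
    b = b if (b, b) in table else "X"
    return table[(a, b)]


@dataclass
class AlignmentResult:
    """A local alignment: gapped strings, score and 1-based spans on each input."""

    aligned_a: str
    aligned_b: str
    score: float
    span_a: tuple  # (n1, n2) 1-based inclusive on A; (0, -1) for empty alignment
    span_b: tuple

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")

    @property
    def N(self) -> int:
        return len(self.aligned_a)


def smith_waterman(a: str, b: str, substitution: dict | None = None,
                   gap_open: float = DEFAULT_GAP_OPEN,
                   gap_extend: float = DEFAULT_GAP_EXTEND) -> AlignmentResult:
    """Maximum-scoring local alignment (Gotoh affine-gap dynamic program).

    A gap run of length L costs ``gap_open + (L-1) * gap_extend``.  Unknown
    letters score as X.  Tie-breaking is deterministic: the traceback prefers
    diagonal over up (gap in B) over left (gap in A), and among equal-score
    maxima the smallest (row, col) cell is chosen, so results do not depend
    on dictionary or iteration order.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    table = substitution if substitution is not None else blosum62()
    n, m = len(a), len(b)
    NEG = -1e30
    # H: best ending in a match/mismatch; E: gap in A (consume b); F: gap in B
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    best = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(best[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            F[i, j] = max(best[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            H[i, j] = best[i - 1, j - 1] + _sub_score(table, a[i - 1], b[j - 1])
            best[i, j] = max(0.0, H[i, j], F[i, j], E[i, j])
    score = float(best.max())
    if score <= 0.0:
        return AlignmentResult("", "", 0.0, (0, -1), (0, -1))
    # smallest (row, col) among maxima
    flat = int(np.argmax(best))  # argmax returns first occurrence in row-major order
    i, j = divmod(flat, m + 1)

    end_a, end_b = i, j
    out_a, out_b = [], []
    state = "best"
    while i > 0 and j > 0:
        if state == "best":
            if best[i, j] == 0.0:
                break
            if best[i, j] == H[i, j]:
                out_a.append(a[i - 1]); out_b.append(b[j - 1])
                i -= 1; j -= 1
                continue
            state = "F" if best[i, j] == F[i, j] else "E"
        elif state == "F":  # gap in B: consume a
            out_a.append(a[i - 1]); out_b.append(GAP)
            from_best = best[i - 1, j] - gap_open
            state = "best" if F[i, j] == from_best else "F"
            i -= 1
        else:  # gap in A: consume b
            out_a.append(GAP); out_b.append(b[j - 1])
            from_best = best[i, j - 1] - gap_open
            state = "best" if E[i, j] == from_best else "E"
            j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    start_a = i + 1
    start_b = j + 1
    return AlignmentResult(aligned_a, aligned_b, score,
                           (start_a, end_a), (start_b, end_b))


def similarity(aln: AlignmentResult) -> float:
    """Fraction of aligned columns whose letters are identical (gaps never match)."""
    if aln.N == 0:
        return 0.0
    matches = sum(1 for x, y in zip(aln.aligned_a, aln.aligned_b)
                  if x == y and x != GAP)
    return matches / aln.N


def covering(seq_len: int, span: tuple) -> float:
    """Fraction of the original sequence spanned by its aligned region."""
    n1, n2 = span
    if n2 < n1:  # empty alignment
        return 0.0
    if not (1 <= n1 <= n2 <= seq_len):
        raise ValueError(f"span {span} outside sequence of length {seq_len}")
    return (n2 - n1 + 1) / seq_len


@dataclass
class ClusterSet:
    """A partition of sequence indices with the thresholds that produced it."""

    clusters: list  # list of sorted lists of indices
    params: tuple   # (s_bar, c_bar)

    @property
    def labels(self) -> dict:
        return {i: k for k, cl in enumerate(self.clusters) for i in cl}


def align_pair(a: str, b: str, **kw) -> tuple:
    """Align an unordered pair canonically and return (S, cov_a, cov_b).

    Inputs are ordered lexicographically before alignment so the measure is
    symmetric under input swap.
    """
    swapped = b < a
    x, y = (b, a) if swapped else (a, b)
    aln = smith_waterman(x, y, **kw)
    s = similarity(aln)
    cov_x = covering(len(x), aln.span_a) if aln.N else 0.0
    cov_y = covering(len(y), aln.span_b) if aln.N else 0.0
    return (s, cov_y, cov_x) if swapped else (s, cov_x, cov_y)


def build_cluster_set(seqs: list, s_bar: float = 0.8, c_bar: float = 0.9,
                      **align_kw) -> ClusterSet:
    """All-pairs alignment graph; clusters are its connected components.

    Edge (i, j) exists iff S > s_bar and both coverings > c_bar (strict).
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    g = nx.Graph()
    g.add_nodes_from(range(len(seqs)))
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            s, ci, cj = align_pair(seqs[i], seqs[j], **align_kw)
            if s > s_bar and ci > c_bar and cj > c_bar:
                g.add_edge(i, j)
    comps = sorted((sorted(c) for c in nx.connected_components(g)),
                   key=lambda c: c[0])
    return ClusterSet(comps, (s_bar, c_bar))


def write_clusters_tsv(cluster_set: ClusterSet, ids: list, path) -> None:
    """Emit (sequence_id, cluster_id) pairs as TSV."""
    with open(path, "w") as fh:
        fh.write("sequence_id\tcluster_id\n")
        for k, cl in enumerate(cluster_set.clusters):
            for i in cl:
                fh.write(f"{ids[i]}\t{k}\n")
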