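"""Grouping pointwise ligandability predictions into binding sites.

True binding sites in a dataset are summarized by three shape statistics --
point count, mean distance of points from the geometric center, and the
standard deviation of that distance (small for sphere-like sites, large for
elongated ones).  Their empirical 10th/90th percentiles bound what a
plausible predicted site may look like.

The grouping algorithm thresholds predictions at an adaptive cutoff c,
clusters the selected points into connected components (4 angstrom
neighbor graph), accepts components whose three statistics all fit within
the percentile bounds, removes their points, and then moves c inside a
shrinking interval (a, b): raising a raises c, lowering b lowers c.  It
always terminates within 21 iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

COMPONENT_CUTOFF = 4.0   # angstrom; strict (<) edge condition
MAX_ITERATIONS = 20
INIT_A, INIT_B, INIT_C = 0.3, 1.0, 0.5


@dataclass
class BindingSite:
    """A set of surface-point indices with its geometric summary."""

    point_indices: np.ndarray
    points: np.ndarray          # (n, 3) coordinates of the member points

    def __post_init__(self):
        self.point_indices = np.asarray(self.point_indices, dtype=int)
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 1:
            raise ValueError("a binding site needs at least one point")

    @property
    def size(self) -> int:
        return len(self.points)

    @property
    def center(self) -> np.ndarray:
        return self.points.mean(axis=0)

    @property
    def _dists(self) -> np.ndarray:
        return np.linalg.norm(self.points - self.center, axis=1)

    @property
    def avg_dist(self) -> float:
        return float(self._dists.mean())

    @property
    def std_dist(self) -> float:
        return float(self._dists.std())


@dataclass
class SiteStats:
    """10th/90th percentile bounds of the three site-shape properties."""

    qv: tuple  # point count
    qa: tuple  # mean distance to center (angstrom)
    qs: tuple  # std of distance to center (angstrom)

    def admits(self, site: BindingSite) -> bool:
        return (self.qv[0] <= site.size <= self.qv[1]
                and self.qa[0] <= site.avg_dist <= self.qa[1]
                and self.qs[0] <= site.std_dist <= self.qs[1])


def site_statistics(true_sites: list) -> SiteStats:
    """Empirical 10th/90th percentiles (linear interpolation) over sites."""
    if len(true_sites) < 2:
        raise ValueError("need at least 2 sites to estimate percentile bounds")
    if len(true_sites) < 10:
        logger.warning("site statistics from only %d sites; percentiles are "
                       "coarse", len(true_sites))
    props = {
        "qv": np.array([s.size for s in true_sites], dtype=float),
        "qa": np.array([s.avg_dist for s in true_sites]),
        "qs": np.array([s.std_dist for s in true_sites]),
    }
    bounds = {}
    for key, vals in props.items():
        lo, hi = np.percentile(vals, [10, 90])  # linear interpolation
        if not lo < hi:
            raise ValueError(
                f"degenerate {key} percentile bounds ({lo} == {hi}); the site "
                "set has no spread in this property -- supply a more varied "
                "site collection or widen the percentile pair")
        bounds[key] = (float(lo), float(hi))
    return SiteStats(**bounds)


def components(points: np.ndarray, cutoff: float = COMPONENT_CUTOFF) -> list:
    """Connected components of the strict distance graph d(x, y) < cutoff."""
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) == 0:
        return []
    tree = cKDTree(points)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs):  # query_pairs uses <=; enforce strict <
        d = np.linalg.norm(points[pairs[:, 0]] - points[pairs[:, 1]], axis=1)
        pairs = pairs[d < cutoff]
    g = nx.Graph()
    g.add_nodes_from(range(len(points)))
    g.add_edges_from(map(tuple, pairs))
    return [np.array(sorted(c), dtype=int) for c in nx.connected_components(g)]


def select_ligandable_points(yp: np.ndarray, point_indices: np.ndarray,
                             c: float) -> np.ndarray:
    """Indices (subset of point_indices) whose prediction is strictly above c."""
    point_indices = np.asarray(point_indices, dtype=int)
    return point_indices[yp[point_indices] > c]


def compute_condition(clusters: list, iteration: int, n_points: int,
                      stats: SiteStats, fix_avg_distance_branch: bool = True)\
        -> str:
    """Decision ladder steering the adaptive threshold.

    Evaluated in order: iteration cap -> clustered fraction > 0.2 ->
    no clusters -> max size vs qv bounds -> max avg-distance vs qa bounds ->
    max std-distance vs qs bounds -> default "decrease b".

    The printed pseudocode's avg-distance upper branch compares with "<",
    which would shadow the lower branch; ``fix_avg_distance_branch`` applies
    the symmetric reading (``> qa(0.9)`` -> "increase a").  Set it to False
    for the literal transcription.
    """
    if iteration > MAX_ITERATIONS:
        return "break"
    clustered = sum(c.size for c in clusters)
    if n_points > 0 and clustered / n_points > 0.2:
        return "increase a"
    if not clusters:
        return "decrease b"
    sizes = [c.size for c in clusters]
    avg_d = [c.avg_dist for c in clusters]
    std_d = [c.std_dist for c in clusters]
    if max(sizes) < stats.qv[0]:
        return "decrease b"
    if max(sizes) > stats.qv[1]:
        return "increase a"
    if max(avg_d) < stats.qa[0]:
        return "decrease b"
    if fix_avg_distance_branch:
        if max(avg_d) > stats.qa[1]:
            return "increase a"
    elif max(avg_d) < stats.qa[1]:
        return "increase a"
    if max(std_d) < stats.qs[0]:
        return "decrease b"
    if max(std_d) > stats.qs[1]:
        return "increase a"
    return "decrease b"


def increase_a(a: float, b: float) -> float:
    return 0.2 * (b - a) + a


def decrease_b(a: float, b: float) -> float:
    return 0.2 * (a - b) + b


def binding_sites(yp: np.ndarray, points: np.ndarray, stats: SiteStats,
                  cutoff: float = COMPONENT_CUTOFF,
                  fix_avg_distance_branch: bool = True) -> list:
    """Adaptive-threshold grouping of predictions into binding sites.

    Returns accepted sites (pairwise disjoint point memberships), ordered by
    descending size.  Indices in the returned sites refer to `points` rows.
    """
    yp = np.asarray(yp, dtype=float)
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if yp.shape[0] != points.shape[0]:
        raise ValueError("predictions and points must align")
    if yp.size and (yp.min() < 0 or yp.max() > 1):
        raise ValueError("predictions must lie in [0, 1]")

    a, b, c = INIT_A, INIT_B, INIT_C
    remaining = np.arange(len(points))
    ligandable = select_ligandable_points(yp, remaining, c)
    sites: list = []
    iteration = 0
    condition = "continue"
    while condition != "break":
        comp_local = components(points[ligandable], cutoff)
        clusters = [BindingSite(ligandable[idx], points[ligandable[idx]])
                    for idx in comp_local]
        accepted_points: list = []
        for cl in clusters:
            if stats.admits(cl):
                sites.append(cl)
                accepted_points.append(cl.point_indices)
        if accepted_points:
            used = np.concatenate(accepted_points)
            remaining = np.setdiff1d(remaining, used, assume_unique=False)
        if condition == "increase a":
            a = increase_a(a, b)
        elif condition == "decrease b":
            b = decrease_b(a, b)
        c = (a + b) / 2.0
        assert INIT_A < c < INIT_B or np.isclose(c, (INIT_A + INIT_B) / 2), \
            "threshold escaped its interval"
        iteration += 1
        ligandable = select_ligandable_points(yp, remaining, c)
        condition = compute_condition(clusters, iteration, len(remaining),
                                      stats, fix_avg_distance_branch)
    return sorted(sites, key=lambda s: -s.size)


def write_sites_tsv(sites: list, path) -> None:
    with open(path, "w") as fh:
        fh.write("site_id\tsize\tcenter_x\tcenter_y\tcenter_z\tavg_dist\t"
                 "std_dist\tpoint_indices\n")
        for k, s in enumerate(sites):
            cx, cy, cz = s.center
            idx = ",".join(map(str, s.point_indices))
            fh.write(f"{k}\t{s.size}\t{cx:.3f}\t{cy:.3f}\t{cz:.3f}\t"
                     f"{s.avg_dist:.3f}\t{s.std_dist:.3f}\t{idx}\n")
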