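"""Binding-site and per-chain classification metrics.

Site-level metrics: DCC (distance between geometric centers of the
predicted and true site's points) and DVO (Jaccard-style ratio of the
intersection to the union of the two index sets -- computed on raw point
sets, not convex hulls).  True sites above a size bound are paired with
predicted sites, and three groupings are reported: all pairings, the best
pairing per chain, and pairings with DVO > 0.

Point-level metrics: the usual confusion-matrix statistics per chain at
thresholds t in {0.3, 0.5, 0.7, 0.9} (a point is called ligandable when its
prediction is strictly above t), plus the threshold-free mean cross-entropy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .featurize import LIGANDABLE_THRESHOLD, SurfacePointSet, ligand_occupancy
from .site_grouping import BindingSite

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.3, 0.5, 0.7, 0.9)
DCC_CUTOFF = 4.0


def dcc(pred: BindingSite, true_site: BindingSite) -> float:
    """Distance between the geometric centers of the two sites' points."""
    return float(np.linalg.norm(pred.center - true_site.center))


def dvo(pred: BindingSite, true_site: BindingSite) -> float:
    """|Vp ∩ Vt| / |Vp ∪ Vt| on point indices of a shared point universe."""
    sp, st = set(pred.point_indices.tolist()), set(true_site.point_indices.tolist())
    union = sp | st
    if not union:
        return 0.0
    return len(sp & st) / len(union)


@dataclass
class SitePairing:
    predicted: BindingSite | None
    true_site: BindingSite
    dcc: float
    dvo: float


@dataclass
class PairingGroups:
    all: list = field(default_factory=list)
    best: list = field(default_factory=list)      # best per chain (min DCC)
    best_dvo: list = field(default_factory=list)  # best per chain (max DVO)
    dvo_positive: list = field(default_factory=list)


def pair_sites(predicted: list, true_sites: list, size_bound: int = 0) -> PairingGroups:
    """Pair every true site larger than `size_bound` (strict) with its nearest
    predicted site by DCC; groupings per chain are formed from these pairings.
    True sites with no predicted partner get dcc = inf, dvo = 0."""
    groups = PairingGroups()
    selected = [t for t in true_sites if t.size > size_bound]
    dvo_pairings = []
    for t in selected:
        if predicted:
            d = [dcc(p, t) for p in predicted]
            v = [dvo(p, t) for p in predicted]
            i = int(np.argmin(d))
            groups.all.append(SitePairing(predicted[i], t, d[i], v[i]))
            if v[i] > 0:
                groups.dvo_positive.append(groups.all[-1])
            j = int(np.argmax(v))
            dvo_pairings.append(SitePairing(predicted[j], t, d[j], v[j]))
        else:
            pairing = SitePairing(None, t, math.inf, 0.0)
            groups.all.append(pairing)
            dvo_pairings.append(pairing)
    if groups.all:
        groups.best.append(min(groups.all, key=lambda p: p.dcc))
    if dvo_pairings:
        groups.best_dvo.append(max(dvo_pairings, key=lambda p: p.dvo))
    return groups


def merge_pairing_groups(per_chain: list) -> PairingGroups:
    merged = PairingGroups()
    for g in per_chain:
        merged.all.extend(g.all)
        merged.best.extend(g.best)
        merged.best_dvo.extend(g.best_dvo)
        merged.dvo_positive.extend(g.dvo_positive)
    return merged


def dcc_hit_rate(pairings: list, cutoff: float = DCC_CUTOFF) -> float:
    """Fraction of pairings whose DCC is at most `cutoff`."""
    if not pairings:
        raise ValueError("no pairings")
    return float(np.mean([p.dcc <= cutoff for p in pairings]))


def summarize_group(pairings: list) -> dict:
    """Mean +/- sd of DCC and DVO plus the 4-angstrom hit rate."""
    finite = [p.dcc for p in pairings if math.isfinite(p.dcc)]
    return {
        "n": len(pairings),
        "dcc_mean": float(np.mean(finite)) if finite else math.inf,
        "dcc_sd": float(np.std(finite)) if finite else math.nan,
        "dvo_mean": float(np.mean([p.dvo for p in pairings])) if pairings else 0.0,
        "dvo_sd": float(np.std([p.dvo for p in pairings])) if pairings else 0.0,
        "dcc_le_4": dcc_hit_rate(pairings) if pairings else math.nan,
    }


def true_sites_from_ligands(points: SurfacePointSet, ligands: list,
                            threshold: float = LIGANDABLE_THRESHOLD) -> list:
    """One true site per ligand = surface points that ligand labels;
    sites sharing points are merged."""
    memberships = []
    for lig in ligands:
        mask = ligand_occupancy(points.points, lig) > threshold
        idx = np.flatnonzero(mask)
        if len(idx):
            memberships.append(set(idx.tolist()))
    # merge overlapping memberships
    merged: list = []
    for m in memberships:
        overlapping = [g for g in merged if g & m]
        for g in overlapping:
            merged.remove(g)
            m = m | g
        merged.append(m)
    return [BindingSite(np.array(sorted(m)), points.points[sorted(m)])
            for m in merged]


def _confusion(labels: np.ndarray, preds: np.ndarray, t: float) -> tuple:
    call = preds > t
    tp = int(np.sum(call & labels))
    fp = int(np.sum(call & ~labels))
    fn = int(np.sum(~call & labels))
    tn = int(np.sum(~call & ~labels))
    return tp, fp, fn, tn


def _safe_div(num, den):
    return num / den if den > 0 else math.nan


def _mcc(tp, fp, fn, tn) -> float:
    den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if den == 0:
        return 0.0  # convention for degenerate confusion matrices
    return (tp * tn - fp * fn) / den


@dataclass
class ChainMetrics:
    per_threshold: dict   # t -> dict of metric name -> value
    loss: float           # threshold-free mean cross-entropy
    has_positives: bool


def chain_classification_metrics(points: SurfacePointSet,
                                 thresholds=DEFAULT_THRESHOLDS) -> ChainMetrics:
    """Standard per-chain confusion-matrix metrics at each threshold."""
    if points.prediction is None:
        raise ValueError("points carry no predictions")
    labels = points.is_ligandable.astype(bool)
    preds = np.clip(points.prediction, 0.0, 1.0)
    eps = 1e-12
    loss = float(-np.mean(labels * np.log(preds + eps)
                          + (~labels) * np.log(1 - preds + eps)))
    has_pos = bool(labels.any())
    if not has_pos:
        logger.debug("chain %s has no positive labels; sensitivity undefined",
                     points.chain_ref)
    out = {}
    for t in thresholds:
        tp, fp, fn, tn = _confusion(labels, preds, t)
        sens = _safe_div(tp, tp + fn)
        spec = _safe_div(tn, tn + fp)
        prec = _safe_div(tp, tp + fp)
        acc = _safe_div(tp + tn, tp + fp + fn + tn)
        bal = (sens + spec) / 2 if not (math.isnan(sens) or math.isnan(spec)) \
            else math.nan
        f1 = _safe_div(2 * tp, 2 * tp + fp + fn)
        out[t] = {
            "tp": tp, "fp": fp, "fn": fn, "tn": tn,
            "sensitivity": sens, "specificity": spec, "precision": prec,
            "accuracy": acc, "balanced_accuracy": bal, "f1": f1,
            "mcc": _mcc(tp, fp, fn, tn),
        }
    return ChainMetrics(out, loss, has_pos)


def aggregate_metrics(per_chain: list, metric: str, threshold: float) -> tuple:
    """Mean +/- sd of one metric over chains (NaNs excluded)."""
    vals = [m.per_threshold[threshold][metric] for m in per_chain]
    vals = [v for v in vals if not (isinstance(v, float) and math.isnan(v))]
    if not vals:
        return math.nan, math.nan
    return float(np.mean(vals)), float(np.std(vals))


def size_bound_sweep(predicted_by_chain: dict, true_by_chain: dict,
                     bounds=range(0, 61, 5)) -> list:
    """DCC/DVO summaries per size bound for the all/best/DVO>0 groupings."""
    rows = []
    for bound in bounds:
        per_chain = [pair_sites(predicted_by_chain[k], true_by_chain[k], bound)
                     for k in true_by_chain]
        merged = merge_pairing_groups(per_chain)
        row = {"size_bound": bound}
        for name, group in (("all", merged.all), ("best", merged.best),
                            ("dvo_pos", merged.dvo_positive)):
            if group:
                s = summarize_group(group)
                row[f"{name}_dcc_mean"] = s["dcc_mean"]
                row[f"{name}_dvo_mean"] = s["dvo_mean"]
                row[f"{name}_n"] = s["n"]
        rows.append(row)
    return rows
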