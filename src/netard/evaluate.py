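"""Edge-recovery metrics for inferred gene networks.

An estimated graph is compared with the true graph over all unordered gene
pairs: recall Re = TP/(TP+FN), fall-out Fa = FP/(FP+TN) and precision
Pr = TP/(TP+FP). Sweeping a threshold through the edge weights yields the
ROC curve (Re vs Fa) and the PR curve (Pr vs Re); AUROC is computed by the
trapezoid rule, AUPR by the continuous (Davis–Goadrich) interpolation of
the PR curve, in which the true-positive and false-positive counts are
interpolated linearly between adjacent thresholds so precision varies
hyperbolically with recall along each segment.

Topology summaries: the sparsity level SL is the fraction of absent edges
among all unordered pairs, and the hub level HL is Freeman's degree
centralization sum_i(d_max - d_i) / ((p-1)(p-2)), which is 0 for a regular
graph and 1 for a star.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EvalResult",
    "confusion_at_graph",
    "roc_pr",
    "sparsity_level",
    "hub_level",
    "degrees",
]


@dataclass
class EvalResult:
    auroc: float
    aupr: float
    roc_points: np.ndarray = field(repr=False, default=None)
    pr_points: np.ndarray = field(repr=False, default=None)


def _edge_set(edges):
    out = set()
    for a, b in edges:
        a, b = int(a), int(b)
        if a != b:
            out.add((min(a, b), max(a, b)))
    return out


def confusion_at_graph(est_edges, true_edges, p: int):
    """(re, fa, pr) over unordered pairs; pr is None for an empty estimate."""
    est = _edge_set(est_edges)
    true = _edge_set(true_edges)
    n_pairs = p * (p - 1) // 2
    tp = len(est & true)
    fp = len(est - true)
    fn = len(true - est)
    tn = n_pairs - tp - fp - fn
    re = tp / (tp + fn) if (tp + fn) else 0.0
    fa = fp / (fp + tn) if (fp + tn) else 0.0
    pr = tp / (tp + fp) if (tp + fp) else None
    return re, fa, pr


def _counts_by_threshold(w: np.ndarray, true_edges, p: int):
    """Cumulative TP/FP counts as the threshold descends through the weights."""
    iu = np.triu_indices(p, k=1)
    scores = np.asarray(w, dtype=float)[iu]
    true = _edge_set(true_edges)
    labels = np.fromiter(((i, j) in true for i, j in zip(*iu)),
                         dtype=bool, count=scores.size)
    order = np.argsort(-scores, kind="stable")
    scores = scores[order]
    labels = labels[order]
    # collapse ties: cumulative counts at each distinct score
    distinct = np.nonzero(np.diff(scores))[0]
    cut = np.r_[distinct, scores.size - 1]
    tp = np.cumsum(labels)[cut].astype(float)
    fp = np.cumsum(~labels)[cut].astype(float)
    pos = float(labels.sum())
    neg = float(scores.size - pos)
    return np.r_[0.0, tp], np.r_[0.0, fp], pos, neg


def _dg_segment_area(tp_a, fp_a, tp_b, fp_b, pos):
    """PR area between two operating points under linear TP/FP interpolation."""
    d_tp = tp_b - tp_a
    if d_tp <= 0:
        return 0.0
    slope = (fp_b - fp_a) / d_tp
    # along the segment TP = tp_a + x, FP = fp_a + slope*x for x in [0, d_tp];
    # area = (1/pos) * int (tp_a + x) / (c0 + a*x) dx with a = 1 + slope >= 1
    a = 1.0 + slope
    c0 = tp_a + fp_a
    const = tp_a - c0 / a
    integral = d_tp / a
    if const != 0.0 and c0 > 0.0:
        integral += (const / a) * np.log((c0 + a * d_tp) / c0)
    return integral / pos


def roc_pr(w: np.ndarray, true_edges, p: int,
           pr_interpolation: str = "continuous") -> EvalResult:
    """ROC and PR curves with AUROC/AUPR from a weighted adjacency.

    ``pr_interpolation`` is ``"continuous"`` (Davis–Goadrich, default) or
    ``"trapezoid"``.
    """
    tp, fp, pos, neg = _counts_by_threshold(w, true_edges, p)
    if pos == 0:
        raise ValueError("true graph has no edges; PR curve undefined")
    if neg == 0:
        raise ValueError("true graph is complete; ROC curve undefined")
    re = tp / pos
    fa = fp / neg
    auroc = float(np.trapezoid(re, fa))
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1e-300), 1.0)
    if pr_interpolation == "trapezoid":
        aupr = float(np.trapezoid(prec[1:], re[1:]))
        if re[1] > 0:  # extend flat to recall 0 from the first operating point
            aupr += float(re[1] * prec[1])
    elif pr_interpolation == "continuous":
        aupr = 0.0
        for i in range(len(tp) - 1):
            aupr += _dg_segment_area(tp[i], fp[i], tp[i + 1], fp[i + 1], pos)
    else:
        raise ValueError(f"unknown pr_interpolation: {pr_interpolation}")
    roc_points = np.column_stack([fa, re])
    pr_points = np.column_stack([re, prec])
    return EvalResult(auroc=auroc, aupr=float(aupr),
                      roc_points=roc_points, pr_points=pr_points)


def degrees(edges, p: int) -> np.ndarray:
    d = np.zeros(p, dtype=int)
    for a, b in _edge_set(edges):
        d[a] += 1
        d[b] += 1
    return d


def sparsity_level(edges, p: int) -> float:
    """Fraction of missing edges among all p(p-1)/2 unordered pairs."""
    if p < 2:
        raise ValueError("need at least 2 nodes")
    return 1.0 - len(_edge_set(edges)) / (p * (p - 1) / 2)


def hub_level(edges, p: int) -> float:
    """Freeman degree centralization, in [0, 1]; 1 for a star graph."""
    if p < 3:
        raise ValueError("hub level requires at least 3 nodes")
    d = degrees(edges, p)
    return float(np.sum(d.max() - d) / ((p - 1) * (p - 2)))
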