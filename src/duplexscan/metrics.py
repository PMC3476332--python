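"""Evaluation statistics for predicted duplexes.

Base-pair-level confusion metrics (sensitivity, PPV, F-measure and the
geometric-mean form of the Matthews coefficient, valid when true negatives
dominate), rank-based method comparison (rank product over fractional
ranks, relative hit score), and energy-agreement summaries (Pearson /
Spearman correlation and top-k% ranking overlap).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "BasePairSet",
    "MetricReport",
    "confusion",
    "rank_product",
    "relative_hit_score",
    "CorrelationReport",
    "correlation_report",
    "intervals_overlap",
]

BasePair = Tuple[int, int]


def BasePairSet(pairs: Iterable[BasePair]) -> Set[BasePair]:
    """Validated set of (query_pos, target_pos) pairs; every position may
    pair at most once (duplex monogamy)."""
    out = set(pairs)
    for axis, label in ((0, "query"), (1, "target")):
        positions = [p[axis] for p in out]
        if len(positions) != len(set(positions)):
            raise ValueError(f"duplicate {label} position in base-pair set")
    return out


@dataclass(frozen=True)
class MetricReport:
    tp: int
    fp: int
    fn: int
    sen: float
    ppv: float
    f: float
    mcc: float
    degenerate: bool = False  # a denominator was zero and reported as 0


def confusion(predicted: Set[BasePair], truth: Set[BasePair]) -> MetricReport:
    """Base-pair-level confusion between predicted and verified pairs."""
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    degenerate = (tp + fn == 0) or (tp + fp == 0)
    sen = tp / (tp + fn) if tp + fn else 0.0
    ppv = tp / (tp + fp) if tp + fp else 0.0
    f = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return MetricReport(
        tp=tp, fp=fp, fn=fn, sen=sen, ppv=ppv, f=f,
        mcc=math.sqrt(sen * ppv), degenerate=degenerate,
    )


def _rank_matrix(counts: Mapping[str, Sequence[float]]) -> Tuple[List[str], np.ndarray]:
    methods = list(counts)
    if len(methods) < 2:
        raise ValueError("need at least two methods")
    mat = np.asarray([counts[g] for g in methods], dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 1:
        raise ValueError("need at least one interaction")
    return methods, mat


def rank_product(counts: Mapping[str, Sequence[float]]) -> Dict[str, float]:
    """Geometric mean of each method's fractional rank across interactions;
    the method with the lowest hit count ranks first, ties share the
    average rank."""
    methods, mat = _rank_matrix(counts)
    ranks = np.apply_along_axis(stats.rankdata, 0, mat)  # fractional ranks
    rp = np.exp(np.log(ranks).mean(axis=1))
    return dict(zip(methods, rp.tolist()))


def relative_hit_score(counts: Mapping[str, Sequence[float]]) -> Dict[str, float]:
    """Scale-free margin to the worst method.

    For interaction i with per-method hit counts c and maximum N_i, a
    method scores (N_i - c) / N_i; the method score is the mean over
    interactions (interactions where every method counts zero are
    skipped).  0 = worst method everywhere, larger is better.
    """
    methods, mat = _rank_matrix(counts)
    nmax = mat.max(axis=0)
    keep = nmax > 0
    if not keep.any():
        raise ValueError("all interactions have zero counts for every method")
    rhs = ((nmax[keep] - mat[:, keep]) / nmax[keep]).mean(axis=1)
    return dict(zip(methods, rhs.tolist()))


@dataclass(frozen=True)
class CorrelationReport:
    pearson_r: float
    spearman_rho: float
    top_overlap_pct: float
    top_k_pct: float
    n: int
    flagged: bool = False  # a constant vector made correlations undefined


def correlation_report(
    x: Sequence[float], y: Sequence[float], top_k_pct: float = 5.0
) -> CorrelationReport:
    """Agreement between two energy vectors over the same duplex set.

    ``top_overlap_pct`` is the overlap (percent) between the two methods'
    sets of the ceil(k%) most stable duplexes (lowest energies).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two aligned vectors of >= 3 energies")
    flagged = bool(np.ptp(x) == 0 or np.ptp(y) == 0)
    if flagged:
        pear = rho = float("nan")
    else:
        pear = float(stats.pearsonr(x, y).statistic)
        rho = float(stats.spearmanr(x, y).statistic)
    size = max(1, math.ceil(top_k_pct / 100.0 * len(x)))
    top_x = set(np.argsort(x, kind="stable")[:size].tolist())
    top_y = set(np.argsort(y, kind="stable")[:size].tolist())
    overlap = 100.0 * len(top_x & top_y) / size
    return CorrelationReport(
        pearson_r=pear, spearman_rho=rho, top_overlap_pct=overlap,
        top_k_pct=top_k_pct, n=len(x), flagged=flagged,
    )


def intervals_overlap(a: Tuple[int, int], b: Tuple[int, int]) -> bool:
    """Binding-site recovery rule: 1-based inclusive intervals overlap by
    at least one nucleotide."""
    return max(a[0], b[0]) <= min(a[1], b[1])
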