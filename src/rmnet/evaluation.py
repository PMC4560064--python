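"""Evaluation of predicted networks against a known truth.

The candidate universe for an n-OTU community is every (ordered pair, sign)
combination: ``2 * n * (n - 1)`` signed directed links (180 for n = 10).
TPR, TNR, accuracy and the TPR/TNR harmonic-mean F-measure are computed over
that universe; a network's "efficiency" is the largest value attained by at
least three of the four measures, i.e. their third-largest order statistic.

The Pr analysis quantifies how many retained true-positive triplets involve
regulator-target pairs with low Spearman correlation — relationships that
pure correlation networks would miss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .triplet_scan import COMPETITIVE, COOPERATIVE, RegulatoryNetwork

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "PrCounts",
    "confusion_counts",
    "metrics",
    "efficiency",
    "occurrence_rate",
    "best_metrics",
    "spearman_rho",
    "pr_analysis",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Signed-link confusion counts over the 2*n*(n-1) candidate universe."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """TPR, TNR, their harmonic-mean F-measure, and accuracy; each in [0, 1]."""

    tpr: float
    tnr: float
    f_measure: float
    accuracy: float

    def as_array(self) -> np.ndarray:
        return np.array([self.tpr, self.tnr, self.f_measure, self.accuracy])


@dataclass(frozen=True)
class PrCounts:
    """Counts behind the Pr value (% of low-correlation true-positive pairs)."""

    om_ot_count: int
    oc_ot_count: int
    total_count: int

    @property
    def pr_value(self) -> float:
        if self.total_count == 0:
            return 0.0
        return (self.om_ot_count + self.oc_ot_count) * 100.0 / self.total_count


def confusion_counts(
    predicted: RegulatoryNetwork, truth: RegulatoryNetwork, n_otus: int
) -> ConfusionCounts:
    """Partition the signed-link universe into TP / FP / TN / FN.

    Both networks must live on the same node universe of ``n_otus`` OTUs;
    nodes outside the truth's node set (plus prediction's) are allowed only
    insofar as the combined set does not exceed ``n_otus``.
    """
    nodes = set(truth.nodes) | set(predicted.nodes)
    if len(nodes) > n_otus:
        raise ValueError(
            f"networks reference {len(nodes)} nodes but universe has {n_otus} OTUs"
        )
    universe = 2 * n_otus * (n_otus - 1)
    pred, true = predicted.edge_set(), truth.edge_set()
    tp = len(pred & true)
    fp = len(pred - true)
    fn = len(true - pred)
    tn = universe - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(c: ConfusionCounts) -> MetricSet:
    """TPR = TP/(TP+FN); TNR = TN/(TN+FP); F = 2*TPR*TNR/(TPR+TNR); accuracy."""
    if c.tp + c.fn == 0:
        raise ValueError("no positive links in truth: TPR undefined")
    if c.tn + c.fp == 0:
        raise ValueError("no negative links in truth: TNR undefined")
    tpr = c.tp / (c.tp + c.fn)
    tnr = c.tn / (c.tn + c.fp)
    f = 0.0 if tpr + tnr == 0 else 2.0 * tpr * tnr / (tpr + tnr)
    acc = (c.tp + c.tn) / c.total
    return MetricSet(tpr=tpr, tnr=tnr, f_measure=f, accuracy=acc)


def efficiency(m: MetricSet) -> float:
    """Third-largest of the four measures: the largest v with >= 3 measures >= v."""
    return float(np.sort(m.as_array())[1])


def occurrence_rate(metric_sets, v: float) -> float:
    """Percentage of networks whose efficiency is >= ``v``."""
    if len(metric_sets) == 0:
        raise ValueError("empty metric list")
    eff = np.array([efficiency(m) for m in metric_sets])
    return float(100.0 * np.mean(eff >= v))


def best_metrics(metric_sets) -> MetricSet:
    """Per-measure maximum across networks."""
    if len(metric_sets) == 0:
        raise ValueError("empty metric list")
    arr = np.array([m.as_array() for m in metric_sets])
    tpr, tnr, f, acc = arr.max(axis=0)
    return MetricSet(tpr=float(tpr), tnr=float(tnr), f_measure=float(f), accuracy=float(acc))


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("series must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant series: Spearman correlation undefined")
    return float(stats.spearmanr(x, y).statistic)


def pr_analysis(true_positive_triplets, srp, rho_cut: float = 0.5) -> PrCounts:
    """Pr counts over retained triplets that carry a true-positive link.

    ``om_ot_count`` counts triplets whose cooperator-target Spearman
    correlation is below ``rho_cut``; ``oc_ot_count`` those whose
    competitor-target correlation is above ``-rho_cut`` — i.e. pairs whose
    correlation is weaker than the sign of the true interaction suggests.
    """
    values = srp.values if hasattr(srp, "values") else np.asarray(srp, dtype=float)
    om = oc = 0
    for trip in true_positive_triplets:
        if spearman_rho(values[trip.m], values[trip.t]) < rho_cut:
            om += 1
        if spearman_rho(values[trip.c], values[trip.t]) > -rho_cut:
            oc += 1
    return PrCounts(om_ot_count=om, oc_ot_count=oc, total_count=len(true_positive_triplets))
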