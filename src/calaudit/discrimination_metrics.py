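"""Discrimination metrics: Harrell's c-index and threshold confusion metrics.

The c-index for a binary outcome is the probability that a randomly chosen
case receives a higher prediction than a randomly chosen control, with ties
counted as one half — i.e. the Mann-Whitney form of the AUC.  Confusion
metrics are computed at a probability cutoff; deployments with site-specific
cutoffs are supported by judging each record at its own site's threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


class DiscriminationError(ValueError):
    """Raised when a discrimination metric is undefined for the input."""


def c_index(p_hat, outcome) -> float:
    """Harrell's concordance index via midranks, O(n log n).

    Equals the exact pairwise definition: over all case-control pairs, the
    fraction where the case has the higher prediction, ties weighted 0.5.
    """
    p_hat = np.asarray(p_hat, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    n1 = int(outcome.sum())
    n0 = outcome.size - n1
    if n1 == 0 or n0 == 0:
        raise DiscriminationError("c-index undefined: single-class outcome")
    ranks = rankdata(p_hat)  # midranks handle ties as 1/2
    u = ranks[outcome == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


class WeightedCIndex:
    """c-index for count-weighted resamples of a fixed score vector.

    Bootstrap resamples of a cell reweight the original records, so the
    score order and tie structure can be precomputed once; each evaluation
    is then a few O(n) passes over per-distinct-score weight totals.
    Equals :func:`c_index` on the equivalent expanded sample.
    """

    def __init__(self, p_hat, outcome):
        p = np.asarray(p_hat, dtype=float)
        y = np.asarray(outcome, dtype=float)
        order = np.argsort(p, kind="stable")
        ps = p[order]
        self._order = order
        self._y_sorted = y[order]
        # group id per sorted record, one per distinct score
        self._group = np.concatenate(([0], np.cumsum(np.diff(ps) != 0.0)))
        self._n_groups = int(self._group[-1]) + 1

    def __call__(self, counts) -> float:
        c = np.asarray(counts, dtype=float)[self._order]
        case_w = c * self._y_sorted
        ctrl_w = c - case_w
        a = np.bincount(self._group, case_w, minlength=self._n_groups)
        b = np.bincount(self._group, ctrl_w, minlength=self._n_groups)
        total_a, total_b = a.sum(), b.sum()
        if total_a == 0 or total_b == 0:
            raise DiscriminationError("c-index undefined: single-class resample")
        cum_b = np.cumsum(b) - b
        u = a @ (cum_b + 0.5 * b)
        return float(u / (total_a * total_b))


@dataclass(frozen=True)
class DiscriminationReport:
    """Confusion counts and derived metrics at a decision threshold.

    Metrics with a zero denominator are ``nan`` (undefined), never silently 0.
    ``threshold`` is ``nan`` in per-record (site-specific) threshold mode.
    """
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    c_index: float | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def confusion_at_threshold(p_hat, outcome, threshold,
                           with_c_index: bool = False) -> DiscriminationReport:
    """Confusion metrics calling positive when ``p_hat >= threshold``.

    ``threshold`` may be a scalar (single pooled cutoff) or an array aligned
    with the records (each record judged at its own site's cutoff).
    """
    p_hat = np.asarray(p_hat, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    thr = np.asarray(threshold, dtype=float)
    if np.any((thr <= 0.0) | (thr >= 1.0)):
        raise ValueError("threshold must lie strictly in (0, 1)")
    pos = p_hat >= thr
    case = outcome == 1
    tp = int(np.sum(pos & case))
    fp = int(np.sum(pos & ~case))
    fn = int(np.sum(~pos & case))
    tn = int(np.sum(~pos & ~case))
    ci = c_index(p_hat, outcome) if with_c_index else None
    return DiscriminationReport(
        threshold=float(thr) if thr.ndim == 0 else math.nan,
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        accuracy=_ratio(tp + tn, tp + fp + tn + fn),
        c_index=ci,
    )
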