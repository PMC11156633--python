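"""Bootstrap confidence intervals and empirical subgroup-difference tests.

All inference here is nonparametric: percentile confidence intervals from
resampling records with replacement, and two-sided empirical p-values for a
metric difference between two disjoint subgroups, each group resampled
independently.  P-values use an add-one correction so they are never exactly
zero: the smallest attainable value is ``2 / (B + 1)`` at ``B`` resamples.
Multiplicity is controlled by Bonferroni division.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

#: Bootstrap replicates used by default throughout the pipeline.
DEFAULT_REPS = 100

#: Fraction of failed resamples above which the bootstrap is abandoned.
MAX_FAILURE_FRACTION = 0.2


class BootstrapError(RuntimeError):
    """Raised when the metric is undefined on the sample or on too many resamples."""


@dataclass(frozen=True)
class BootstrapResult:
    """Point estimate with a percentile bootstrap confidence interval."""
    point: float
    ci_lo: float
    ci_hi: float
    reps: int
    seed: int
    n_failed: int = 0


@dataclass(frozen=True)
class ComparisonResult:
    """A subgroup metric difference with its empirical two-sided p-value."""
    metric: str
    group1: str
    group2: str
    difference: float
    p_raw: float
    alpha_adjusted: float
    significant: bool
    reps: int
    seed: int


def _take(records, idx: np.ndarray):
    if isinstance(records, (pd.DataFrame, pd.Series)):
        return records.take(idx)
    return np.asarray(records)[idx]


def _size(records) -> int:
    return len(records)


def _evaluate(metric_fn: Callable, records) -> float:
    """Apply the metric, mapping domain failures to nan."""
    try:
        value = metric_fn(records)
    except (ValueError, ZeroDivisionError, FloatingPointError):
        return np.nan
    if value is None:
        return np.nan
    return float(value)


def _resample_distribution(metric_fn, records, reps, rng,
                           strata=None) -> np.ndarray:
    n = _size(records)
    if strata is not None:
        groups = [np.flatnonzero(np.asarray(strata) == s)
                  for s in np.unique(strata)]
    out = np.empty(reps)
    for b in range(reps):
        if strata is None:
            idx = rng.integers(0, n, n)
        else:
            idx = np.concatenate(
                [g[rng.integers(0, g.size, g.size)] for g in groups])
        out[b] = _evaluate(metric_fn, _take(records, idx))
    return out


def bootstrap_ci(metric_fn: Callable, records, reps: int = DEFAULT_REPS,
                 seed: int = 0, level: float = 0.95,
                 strata=None) -> BootstrapResult:
    """Percentile bootstrap CI for ``metric_fn`` over record resamples.

    Resamples with replacement at the original size.  Resamples where the
    metric is undefined (raises or returns nan) are dropped and counted; the
    bootstrap fails outright if the metric is undefined on the full sample or
    on more than 20% of resamples.  ``strata`` (an optional per-record label
    array, e.g. facility) switches to resampling within each stratum, keeping
    stratum sizes fixed.
    """
    if reps < 2:
        raise ValueError(f"reps must be >= 2, got {reps}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    point = _evaluate(metric_fn, records)
    if np.isnan(point):
        raise BootstrapError("metric undefined on the full sample")
    rng = np.random.default_rng(seed)
    dist = _resample_distribution(metric_fn, records, reps, rng, strata=strata)
    ok = dist[~np.isnan(dist)]
    n_failed = reps - ok.size
    if n_failed > MAX_FAILURE_FRACTION * reps:
        raise BootstrapError(
            f"metric undefined on {n_failed}/{reps} resamples (> 20%)")
    alpha = 1.0 - level
    lo, hi = np.quantile(ok, [alpha / 2.0, 1.0 - alpha / 2.0])
    return BootstrapResult(point=point, ci_lo=float(lo), ci_hi=float(hi),
                           reps=reps, seed=seed, n_failed=n_failed)


def bootstrap_diff_pvalue(metric_fn: Callable, records_g1, records_g2,
                          reps: int = DEFAULT_REPS, seed: int = 0,
                          alpha_adjusted: float = 0.05, metric: str = "",
                          groups: Sequence[str] = ("group1", "group2"),
                          ) -> ComparisonResult:
    """Empirical two-sided p-value for a metric difference between two groups.

    Each group is resampled independently with replacement (the groups are
    disjoint patient sets, so no pairing is assumed).  With bootstrap
    differences ``D*_b = metric(g1*) - metric(g2*)``,

        p = 2 * min( (1 + #{D* <= 0}) / (B + 1), (1 + #{D* >= 0}) / (B + 1) )

    capped at 1.  The reported ``difference`` is computed on the full samples.
    """
    if reps < 2:
        raise ValueError(f"reps must be >= 2, got {reps}")
    point1 = _evaluate(metric_fn, records_g1)
    point2 = _evaluate(metric_fn, records_g2)
    if np.isnan(point1) or np.isnan(point2):
        raise BootstrapError("metric undefined on a full group sample")
    ss1, ss2 = np.random.SeedSequence(seed).spawn(2)
    d1 = _resample_distribution(metric_fn, records_g1, reps, np.random.default_rng(ss1))
    d2 = _resample_distribution(metric_fn, records_g2, reps, np.random.default_rng(ss2))
    diffs = d1 - d2
    ok = diffs[~np.isnan(diffs)]
    n_failed = reps - ok.size
    if n_failed > MAX_FAILURE_FRACTION * reps:
        raise BootstrapError(
            f"metric undefined on {n_failed}/{reps} resample pairs (> 20%)")
    b = ok.size
    m_le = (1 + np.sum(ok <= 0.0)) / (b + 1)
    m_ge = (1 + np.sum(ok >= 0.0)) / (b + 1)
    p_raw = min(1.0, 2.0 * min(m_le, m_ge))
    return ComparisonResult(
        metric=metric, group1=str(groups[0]), group2=str(groups[1]),
        difference=point1 - point2, p_raw=float(p_raw),
        alpha_adjusted=alpha_adjusted, significant=p_raw < alpha_adjusted,
        reps=reps, seed=seed)


def bonferroni_threshold(alpha: float, k: int) -> float:
    """Bonferroni-adjusted per-test significance threshold ``alpha / k``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return alpha / k


def format_pvalue(p_raw: float, reps: int) -> str:
    """Render a p-value, flooring at the resolution of the bootstrap.

    An empirical p-value from ``B`` resamples cannot be smaller than
    ``2/(B+1)``; values at the floor are printed as ``"< floor"`` rather than
    as 0.
    """
    floor = 2.0 / (reps + 1)
    if p_raw <= floor:
        return f"< {floor:.3g}"
    return f"{p_raw:.3g}"
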