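"""Cohort assembly: event reduction, temporal splitting, and baseline tables.

The analysis unit is one record per patient: the *maximum* predicted
probability during the admission among predictions that are followed by at
least one dietitian assessment, paired with the *first* assessment dated on
or after that prediction.  Patients with no assessment (or no prediction
preceding any assessment) are excluded, with counts logged.

Baseline characteristics are contrasted between outcome groups with
standardized mean differences (SMDs): the usual pooled-variance formula for
binary and continuous variables, and the Mahalanobis-distance generalization
over the multinomial covariance for multicategory variables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class AssemblyError(ValueError):
    pass


@dataclass(frozen=True)
class ReductionSummary:
    retained: int
    excluded_no_assessment: int
    excluded_no_pairing: int


def reduce_admissions(predictions: pd.DataFrame, assessments: pd.DataFrame,
                      ) -> tuple[pd.DataFrame, ReductionSummary]:
    """Reduce longitudinal events to one (p_hat, outcome) record per patient.

    ``predictions`` needs columns (patient_id, date, p_hat); ``assessments``
    needs (patient_id, date, diagnosis).  A same-day assessment counts as
    occurring *after* the prediction (daily granularity).  Duplicate
    (patient, date) predictions are resolved by keeping the larger p_hat.
    Returns the reduced records plus exclusion counts.
    """
    preds = predictions.copy()
    preds["date"] = pd.to_datetime(preds["date"])
    assess = assessments.copy()
    assess["date"] = pd.to_datetime(assess["date"])
    # duplicate same-day predictions: keep the larger p_hat
    dup = preds.duplicated(subset=["patient_id", "date"], keep=False)
    if dup.any():
        logger.info("resolving %d duplicate (patient, date) predictions "
                    "by keeping the larger p_hat", int(dup.sum()))
        preds = (preds.sort_values("p_hat")
                 .drop_duplicates(subset=["patient_id", "date"], keep="last"))

    assess_by_patient = {
        pid: g.sort_values("date") for pid, g in assess.groupby("patient_id")}
    rows = []
    no_assessment = 0
    no_pairing = 0
    for pid, g in preds.groupby("patient_id"):
        pa = assess_by_patient.get(pid)
        if pa is None or pa.empty:
            no_assessment += 1
            continue
        last_assess = pa["date"].iloc[-1]
        eligible = g[g["date"] <= last_assess]
        if eligible.empty:
            no_pairing += 1
            continue
        best = eligible.loc[eligible["p_hat"].idxmax()]
        after = pa[pa["date"] >= best["date"]]
        first = after.iloc[0]
        rows.append((pid, best["date"], float(best["p_hat"]),
                     int(first["diagnosis"])))
    records = pd.DataFrame(rows,
                           columns=["patient_id", "admit_date", "p_hat", "outcome"])
    summary = ReductionSummary(retained=len(records),
                               excluded_no_assessment=no_assessment,
                               excluded_no_pairing=no_pairing)
    logger.info("reduced %d patients: retained %d, excluded %d (no assessment) "
                "+ %d (no eligible prediction)", len(preds["patient_id"].unique()),
                summary.retained, no_assessment, no_pairing)
    return records, summary


def split_train_holdout(records: pd.DataFrame, boundary_date) -> pd.DataFrame:
    """Label records ``train`` (admitted on/before the boundary) or ``holdout``.

    The boundary is inclusive on the training side: an admission dated
    exactly on the boundary belongs to the training sample.
    """
    if "admit_date" not in records.columns:
        raise AssemblyError("records lack an admit_date column")
    dates = pd.to_datetime(records["admit_date"])
    missing = records.loc[dates.isna(), "patient_id"].tolist()
    if missing:
        raise AssemblyError(f"records with missing admit_date: {missing[:20]}")
    boundary = pd.Timestamp(boundary_date)
    out = records.copy()
    out["sample"] = np.where(dates <= boundary, "train", "holdout")
    n_train = int((out["sample"] == "train").sum())
    n_hold = len(out) - n_train
    if n_train == 0 or n_hold == 0:
        logger.warning("temporal split produced an empty sample "
                       "(train=%d, holdout=%d)", n_train, n_hold)
    else:
        logger.info("temporal split: %d train, %d holdout", n_train, n_hold)
    return out


# ---------------------------------------------------------------------------
# Standardized mean differences


def smd_binary(k1: int, n1: int, k2: int, n2: int) -> float:
    """SMD for a binary variable from event counts in two groups.

    ``|p1 - p2| / sqrt((p1(1-p1) + p2(1-p2)) / 2)`` with ``p_i = k_i / n_i``.
    """
    if n1 < 1 or n2 < 1 or not (0 <= k1 <= n1) or not (0 <= k2 <= n2):
        raise AssemblyError("counts must satisfy 0 <= k <= n, n >= 1")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (p1 * (1 - p1) + p2 * (1 - p2)) / 2.0
    if pooled == 0.0:
        if p1 == p2:
            return 0.0
        raise AssemblyError("zero variance in both groups with unequal proportions")
    return abs(p1 - p2) / np.sqrt(pooled)


def smd_continuous(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """SMD for a continuous variable: ``|m1 - m2| / sqrt((s1^2 + s2^2)/2)``."""
    pooled = (sd1 ** 2 + sd2 ** 2) / 2.0
    if pooled == 0.0:
        if mean1 == mean2:
            return 0.0
        raise AssemblyError("zero variance in both groups with unequal means")
    return abs(mean1 - mean2) / np.sqrt(pooled)


def smd_multicategory(counts_g1, counts_g2) -> float:
    """Mahalanobis SMD for a multicategory variable from per-category counts.

    ``sqrt(T' S^{-1} T)`` where ``T`` stacks the proportion differences over
    the first ``k - 1`` categories and ``S`` averages the two groups'
    multinomial covariance matrices.  Invariant to category order and to
    which category is dropped.
    """
    c1 = np.asarray(counts_g1, dtype=float)
    c2 = np.asarray(counts_g2, dtype=float)
    if c1.shape != c2.shape or c1.ndim != 1 or c1.size < 2:
        raise AssemblyError("need matching count vectors over >= 2 categories")
    if c1.sum() <= 0 or c2.sum() <= 0:
        raise AssemblyError("each group needs a positive total count")
    p1 = c1 / c1.sum()
    p2 = c2 / c2.sum()
    if ((c1 + c2) == 0).any():
        raise AssemblyError(
            "category absent from both groups; drop it before computing the SMD")
    t = (p1 - p2)[:-1]
    s = (_multinomial_cov(p1) + _multinomial_cov(p2)) / 2.0
    try:
        sol = np.linalg.solve(s, t)
    except np.linalg.LinAlgError as exc:
        raise AssemblyError(f"singular covariance matrix: {exc}") from exc
    return float(np.sqrt(t @ sol))


def _multinomial_cov(p: np.ndarray) -> np.ndarray:
    q = p[:-1]
    return np.diag(q) - np.outer(q, q)


# ---------------------------------------------------------------------------
# Baseline characteristics table


@dataclass(frozen=True)
class SMDEntry:
    variable: str
    smd: float
    kind: str  # binary | multicategory | continuous


def summarize_baseline(records: pd.DataFrame, variables: dict[str, str],
                       group_col: str = "outcome") -> pd.DataFrame:
    """Baseline-characteristics table grouped by outcome, with SMD per variable.

    ``variables`` maps column name to kind: ``"categorical"`` (counts and
    percentages per level; SMD binary for two levels, Mahalanobis otherwise)
    or ``"continuous"`` (median [IQR] displayed; SMD from means and SDs).
    Missing values get their own row and are excluded from the SMD.
    """
    unknown = [v for v in variables if v not in records.columns]
    if unknown:
        raise AssemblyError(f"unknown variables: {unknown}")
    groups = sorted(records[group_col].unique())
    if len(groups) != 2:
        raise AssemblyError(f"{group_col} must have exactly 2 levels, "
                            f"found {groups}")
    g1 = records[records[group_col] == groups[0]]
    g2 = records[records[group_col] == groups[1]]
    rows = []
    for var, kind in variables.items():
        if kind == "continuous":
            rows.extend(_continuous_rows(var, records, g1, g2, groups))
        elif kind == "categorical":
            rows.extend(_categorical_rows(var, records, g1, g2, groups))
        else:
            raise AssemblyError(f"unknown kind {kind!r} for variable {var!r}")
    return pd.DataFrame(rows, columns=[
        "variable", "level", f"{group_col}={groups[0]}",
        f"{group_col}={groups[1]}", "overall", "smd", "kind"])


def _fmt_n_pct(k: int, n: int) -> str:
    return f"{k} ({100.0 * k / n:.1f}%)" if n else "0"

def _fmt_median_iqr(x: pd.Series) -> str:
    x = x.dropna()
    if x.empty:
        return ""
    q1, med, q3 = x.quantile([0.25, 0.5, 0.75])
    return f"{med:.1f} ({q3 - q1:.2f})"


def _continuous_rows(var, records, g1, g2, groups):
    x1, x2 = g1[var].dropna(), g2[var].dropna()
    smd = smd_continuous(x1.mean(), x1.std(ddof=1), x2.mean(), x2.std(ddof=1))
    rows = [(var, "Median [IQR]", _fmt_median_iqr(g1[var]),
             _fmt_median_iqr(g2[var]), _fmt_median_iqr(records[var]),
             round(smd, 4), "continuous")]
    n_missing = int(records[var].isna().sum())
    if n_missing:
        rows.append((var, "Missing",
                     _fmt_n_pct(int(g1[var].isna().sum()), len(g1)),
                     _fmt_n_pct(int(g2[var].isna().sum()), len(g2)),
                     _fmt_n_pct(n_missing, len(records)), np.nan, "continuous"))
    return rows


def _categorical_rows(var, records, g1, g2, groups):
    levels = sorted(records[var].dropna().unique().tolist())
    c1 = np.array([(g1[var] == lev).sum() for lev in levels])
    c2 = np.array([(g2[var] == lev).sum() for lev in levels])
    if len(levels) < 2:
        smd = 0.0
        kind = "binary"
    elif len(levels) == 2:
        smd = smd_binary(int(c1[0]), int(c1.sum()), int(c2[0]), int(c2.sum()))
        kind = "binary"
    else:
        smd = smd_multicategory(c1, c2)
        kind = "multicategory"
    rows = []
    for i, lev in enumerate(levels):
        rows.append((var, str(lev),
                     _fmt_n_pct(int(c1[i]), len(g1)),
                     _fmt_n_pct(int(c2[i]), len(g2)),
                     _fmt_n_pct(int(c1[i] + c2[i]), len(records)),
                     round(smd, 4) if i == 0 else np.nan, kind))
    n_missing = int(records[var].isna().sum())
    if n_missing:
        rows.append((var, "Missing",
                     _fmt_n_pct(int(g1[var].isna().sum()), len(g1)),
                     _fmt_n_pct(int(g2[var].isna().sum()), len(g2)),
                     _fmt_n_pct(n_missing, len(records)), np.nan, kind))
    return rows
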