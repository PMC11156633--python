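"""End-to-end calibration audit of a deployed binary risk model.

``run_audit`` fits recalibration-in-the-large and logistic recalibration on
the training sample only, then evaluates every recalibration variant (none /
ritl / logistic) on both the training and hold-out samples, overall and
within each configured subgroup: weak calibration (intercept, slope, CITL),
moderate calibration (Brier, scaled Brier, Eavg, Emax), discrimination
(c-index, confusion metrics at site thresholds), each with percentile
bootstrap confidence intervals, plus smoothed calibration curves, risk
percentiles, and pairwise subgroup comparisons with empirical two-sided
p-values under Bonferroni control.

Within a metric cell all bootstrap CIs share one set of resamples (a single
loess fit per resample serves both Eavg and Emax); subgroup comparisons use
:func:`calaudit.resampling_inference.bootstrap_diff_pvalue` per metric.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .calibration_metrics import (CalibrationError, FrozenLoessDesign,
                                  ModerateCalibration, SmoothedCurve,
                                  WeakCalibration, _weak_from_logits, brier,
                                  clipped_logit, eavg_emax, fit_loess_curve,
                                  fit_weak_calibration, moderate_calibration)
from .discrimination_metrics import (DiscriminationError, DiscriminationReport,
                                     WeightedCIndex, c_index,
                                     confusion_at_threshold)
from .recalibration import RecalibrationModel, apply_recalibration, fit_recalibration
from .resampling_inference import (BootstrapError, BootstrapResult,
                                   ComparisonResult, bonferroni_threshold,
                                   bootstrap_diff_pvalue)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

VARIANTS = ("none", "ritl", "logistic")

#: Metrics compared between subgroups by default.
COMPARISON_METRICS = ("intercept", "slope", "brier", "eavg", "emax")

#: Metrics given bootstrap confidence intervals within every cell.
CELL_BOOTSTRAP_METRICS = ("intercept", "slope", "citl", "brier", "eavg",
                          "emax", "c_index")


class AuditError(ValueError):
    pass


@dataclass(frozen=True)
class AuditConfig:
    """Knobs of the audit; defaults mirror the deployment study design."""
    subgroup_vars: tuple[str, ...] = ("gender", "race")
    comparison_pairs: tuple[tuple[str, str, str], ...] = (
        ("race", "White", "Black"), ("gender", "Female", "Male"))
    variants: tuple[str, ...] = VARIANTS
    comparison_metrics: tuple[str, ...] = COMPARISON_METRICS
    comparison_sample: str = "holdout"
    bootstrap_reps: int = 100
    seed: int = 0
    span: float = 0.75
    degree: int = 1
    max_eval_points: int = 400
    bootstrap_eval_points: int = 100
    alpha: float = 0.05
    fixed_threshold: float | None = None
    min_subgroup_n: int = 50
    single_threshold: float | None = None
    ci_level: float = 0.95

    def __post_init__(self):
        unknown = set(self.variants) - set(VARIANTS)
        if unknown:
            raise AuditError(f"unknown recalibration variants: {sorted(unknown)}")
        for var, l1, l2 in self.comparison_pairs:
            if var not in self.subgroup_vars:
                raise AuditError(
                    f"comparison pair references undeclared subgroup {var!r}")


@dataclass
class MetricCell:
    """All metrics for one (variant, sample, subgroup) combination."""
    variant: str
    sample: str
    subgroup_var: str
    subgroup_level: str
    n: int
    weak: WeakCalibration | None = None
    moderate: ModerateCalibration | None = None
    discrimination: DiscriminationReport | None = None
    bootstrap: dict[str, BootstrapResult] = field(default_factory=dict)
    curve: SmoothedCurve | None = None
    error: str | None = None


@dataclass
class ComparisonCell:
    variant: str
    sample: str
    subgroup_var: str
    result: ComparisonResult


@dataclass
class AuditReport:
    cells: list[MetricCell]
    comparisons: list[ComparisonCell]
    models: dict[str, RecalibrationModel]
    risk_percentiles: pd.DataFrame
    skipped: list[dict]
    config: AuditConfig
    provenance: dict


# ---------------------------------------------------------------------------


def _config_hash(config: AuditConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _require_columns(records: pd.DataFrame, cols: Sequence[str]):
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise AuditError(f"records lack required columns: {missing}")


def run_audit(records: pd.DataFrame, config: AuditConfig | None = None,
              ) -> AuditReport:
    """Run the full calibration audit over a labelled record table.

    ``records`` needs columns ``p_hat``, ``outcome`` and ``sample`` (train /
    holdout) plus any configured subgroup columns; ``threshold`` per record
    enables site-specific confusion metrics.  Recalibration is fitted on the
    training sample only and applied everywhere.  Deterministic given the
    configured seed.
    """
    config = config or AuditConfig()
    _require_columns(records, ["p_hat", "outcome", "sample"])
    for var in config.subgroup_vars:
        if var not in records.columns:
            raise AuditError(f"subgroup column {var!r} missing from records")
    train = records[records["sample"] == "train"]
    if train.empty:
        raise AuditError("training sample is empty; cannot fit recalibration")
    if train["outcome"].nunique() < 2:
        raise AuditError("training outcome is single-class")

    models = {}
    for variant in config.variants:
        models[variant] = fit_recalibration(
            variant, train["p_hat"].to_numpy(), train["outcome"].to_numpy(),
            fit_sample="train")

    seed_stream = np.random.default_rng(config.seed)
    cells: list[MetricCell] = []
    skipped: list[dict] = []
    recal: dict[str, np.ndarray] = {
        v: apply_recalibration(m, records["p_hat"].to_numpy())
        for v, m in models.items()}

    for variant in config.variants:
        work = records.assign(p_hat=recal[variant])
        for sample in ("train", "holdout"):
            sub = work[work["sample"] == sample]
            for sg_var, sg_level, cell_df in _iter_cells(sub, config, skipped,
                                                         variant, sample):
                cell_seed = int(seed_stream.integers(2 ** 31))
                cells.append(_compute_cell(cell_df, variant, sample, sg_var,
                                           sg_level, config, cell_seed))

    k_tests = (len(config.comparison_pairs) * len(config.comparison_metrics)
               * len(config.variants))
    alpha_adj = (config.fixed_threshold if config.fixed_threshold is not None
                 else bonferroni_threshold(config.alpha, max(1, k_tests)))
    comparisons: list[ComparisonCell] = []
    comp_sample = records[records["sample"] == config.comparison_sample]
    for variant in config.variants:
        comp_df = comp_sample.assign(
            p_hat=recal[variant][(records["sample"] == config.comparison_sample
                                  ).to_numpy()])
        for pair in config.comparison_pairs:
            pair_seed = int(seed_stream.integers(2 ** 31))
            try:
                results = compare_groups(comp_df, pair,
                                         config.comparison_metrics, config,
                                         alpha_adjusted=alpha_adj,
                                         seed=pair_seed)
            except (CalibrationError, DiscriminationError, AuditError,
                    BootstrapError) as exc:
                skipped.append({"variant": variant, "pair": list(pair),
                                "reason": str(exc)})
                continue
            comparisons.extend(
                ComparisonCell(variant, config.comparison_sample, pair[0], r)
                for r in results)

    percentiles = _risk_percentiles(comp_sample, recal, records, config)
    provenance = {"schema_version": SCHEMA_VERSION, "seed": config.seed,
                  "config_hash": _config_hash(config),
                  "n_records": int(len(records)),
                  "package_version": __version__}
    return AuditReport(cells=cells, comparisons=comparisons, models=models,
                       risk_percentiles=percentiles, skipped=skipped,
                       config=config, provenance=provenance)


def _iter_cells(sample_df, config, skipped, variant, sample):
    yield "overall", "overall", sample_df
    for var in config.subgroup_vars:
        for level, cell_df in sample_df.groupby(var, sort=True):
            if len(cell_df) < config.min_subgroup_n:
                skipped.append({"variant": variant, "sample": sample,
                                "subgroup_var": var, "subgroup_level": str(level),
                                "reason": f"n={len(cell_df)} below minimum "
                                          f"{config.min_subgroup_n}"})
                continue
            yield var, str(level), cell_df


def _compute_cell(cell_df, variant, sample, sg_var, sg_level, config,
                  seed) -> MetricCell:
    cell = MetricCell(variant=variant, sample=sample, subgroup_var=sg_var,
                      subgroup_level=sg_level, n=len(cell_df))
    p = cell_df["p_hat"].to_numpy()
    y = cell_df["outcome"].to_numpy()
    try:
        cell.weak = fit_weak_calibration(p, y)
        cell.moderate = moderate_calibration(
            p, y, span=config.span, degree=config.degree,
            max_eval_points=config.max_eval_points)
        thr = _thresholds_for(cell_df, config)
        cell.discrimination = confusion_at_threshold(p, y, thr, with_c_index=True)
        cell.curve = fit_loess_curve(p, y, span=config.span, degree=config.degree,
                                     max_eval_points=config.max_eval_points)
        cell.bootstrap = _cell_bootstrap(p, y, cell, config, seed)
    except (CalibrationError, DiscriminationError, ValueError) as exc:
        cell.error = str(exc)
        logger.warning("cell (%s, %s, %s=%s) failed: %s", variant, sample,
                       sg_var, sg_level, exc)
    return cell


def _thresholds_for(cell_df, config):
    if config.single_threshold is not None:
        return config.single_threshold
    if "threshold" in cell_df.columns and cell_df["threshold"].notna().all():
        return cell_df["threshold"].to_numpy()
    return 0.5


def _cell_bootstrap(p, y, cell: MetricCell, config: AuditConfig,
                    seed: int) -> dict[str, BootstrapResult]:
    """Percentile CIs for all cell metrics sharing one set of resamples.

    A resample only reweights records (multinomial counts), so the weak
    calibration fit runs on fixed logits with count weights and the loess
    refits reuse a frozen design (see
    :class:`calaudit.calibration_metrics.FrozenLoessDesign`), evaluated on
    the coarser ``bootstrap_eval_points`` grid.
    """
    reps = config.bootstrap_reps
    rng = np.random.default_rng(seed)
    n = p.size
    draws = {m: np.full(reps, np.nan) for m in CELL_BOOTSTRAP_METRICS}
    x_logit = clipped_logit(p)
    sq_err = (p - y) ** 2
    design = FrozenLoessDesign(p, y, span=config.span, degree=config.degree,
                               max_eval_points=config.bootstrap_eval_points)
    grid = design.curve.eval_points
    wcindex = WeightedCIndex(p, y)
    for b in range(reps):
        idx = rng.integers(0, n, n)
        counts = np.bincount(idx, minlength=n).astype(float)
        events = counts @ y
        if 0 < events < n:
            try:
                a, slope, citl = _weak_from_logits(x_logit, y, counts)
                draws["intercept"][b] = a
                draws["slope"][b] = slope
                draws["citl"][b] = citl
            except CalibrationError:
                pass
            draws["c_index"][b] = wcindex(counts)
        draws["brier"][b] = (counts @ sq_err) / n
        fitted = design.refit(counts)
        dev = np.abs(np.interp(p, grid, fitted) - p)
        draws["eavg"][b] = (counts @ dev) / n
        draws["emax"][b] = dev[counts > 0].max()
    points = {
        "intercept": cell.weak.intercept, "slope": cell.weak.slope,
        "citl": cell.weak.citl, "brier": cell.moderate.brier,
        "eavg": cell.moderate.eavg, "emax": cell.moderate.emax,
        "c_index": cell.discrimination.c_index,
    }
    alpha = 1.0 - config.ci_level
    out = {}
    for name, dist in draws.items():
        ok = dist[~np.isnan(dist)]
        if ok.size < max(2, 0.8 * reps):
            continue
        lo, hi = np.quantile(ok, [alpha / 2, 1 - alpha / 2])
        out[name] = BootstrapResult(point=float(points[name]), ci_lo=float(lo),
                                    ci_hi=float(hi), reps=reps, seed=seed,
                                    n_failed=reps - ok.size)
    return out


# ---------------------------------------------------------------------------
# Subgroup comparisons


def _metric_fn(name: str, config: AuditConfig):
    span, deg, mep = config.span, config.degree, config.bootstrap_eval_points

    def curve_metric(df, which):
        p = df["p_hat"].to_numpy()
        y = df["outcome"].to_numpy()
        curve = fit_loess_curve(p, y, span=span, degree=deg, max_eval_points=mep)
        return eavg_emax(curve, p)[which]

    fns = {
        "intercept": lambda d: fit_weak_calibration(
            d["p_hat"].to_numpy(), d["outcome"].to_numpy()).intercept,
        "slope": lambda d: fit_weak_calibration(
            d["p_hat"].to_numpy(), d["outcome"].to_numpy()).slope,
        "citl": lambda d: fit_weak_calibration(
            d["p_hat"].to_numpy(), d["outcome"].to_numpy()).citl,
        "brier": lambda d: brier(
            d["p_hat"].to_numpy(), d["outcome"].to_numpy()).brier,
        "eavg": lambda d: curve_metric(d, 0),
        "emax": lambda d: curve_metric(d, 1),
        "c_index": lambda d: c_index(
            d["p_hat"].to_numpy(), d["outcome"].to_numpy()),
    }
    if name not in fns:
        raise AuditError(f"unknown comparison metric {name!r}")
    return fns[name]


def compare_groups(records: pd.DataFrame, pair: tuple[str, str, str],
                   metrics: Sequence[str], config: AuditConfig,
                   alpha_adjusted: float | None = None,
                   seed: int | None = None) -> list[ComparisonResult]:
    """Bootstrap subgroup-difference tests for one pair of subgroup levels.

    ``pair`` is ``(subgroup_var, level1, level2)``; the reported difference
    is ``metric(level1) - metric(level2)``.
    """
    var, l1, l2 = pair
    if var not in records.columns:
        raise AuditError(f"subgroup column {var!r} missing from records")
    levels = set(records[var].astype(str).unique())
    for lev in (l1, l2):
        if lev not in levels:
            raise AuditError(f"level {lev!r} not found in column {var!r}")
    g1 = records[records[var].astype(str) == l1]
    g2 = records[records[var].astype(str) == l2]
    if alpha_adjusted is None:
        alpha_adjusted = (config.fixed_threshold if config.fixed_threshold
                          is not None else
                          bonferroni_threshold(config.alpha, len(metrics)))
    seed = config.seed if seed is None else seed
    out = []
    for i, metric in enumerate(metrics):
        out.append(bootstrap_diff_pvalue(
            _metric_fn(metric, config), g1, g2, reps=config.bootstrap_reps,
            seed=seed + i, alpha_adjusted=alpha_adjusted, metric=metric,
            groups=(l1, l2)))
    return out


def _risk_percentiles(comp_sample, recal, records, config) -> pd.DataFrame:
    """Deciles of recalibrated risk per (variant, comparison group)."""
    qs = np.arange(0, 101, 10)
    rows = []
    mask = (records["sample"] == config.comparison_sample).to_numpy()
    for variant in config.variants:
        p = recal[variant][mask]
        for var, l1, l2 in config.comparison_pairs:
            for level in (l1, l2):
                sel = (comp_sample[var].astype(str) == level).to_numpy()
                if sel.sum() == 0:
                    continue
                pct = np.percentile(p[sel], qs)
                rows.append({"variant": variant, "subgroup_var": var,
                             "subgroup_level": level,
                             **{f"p{q}": v for q, v in zip(qs, pct)}})
    return pd.DataFrame(rows).drop_duplicates(
        subset=["variant", "subgroup_var", "subgroup_level"])


# ---------------------------------------------------------------------------
# Export


def _metrics_frame(report: AuditReport) -> pd.DataFrame:
    rows = []
    for cell in report.cells:
        base = {"variant": cell.variant, "sample": cell.sample,
                "subgroup_var": cell.subgroup_var,
                "subgroup_level": cell.subgroup_level, "n": cell.n}
        if cell.error:
            rows.append({**base, "metric": "error", "point": math.nan,
                         "ci_lo": math.nan, "ci_hi": math.nan,
                         "note": cell.error})
            continue
        point_only = {
            "brier_scaled": cell.moderate.brier_scaled,
            "sensitivity": cell.discrimination.sensitivity,
            "specificity": cell.discrimination.specificity,
            "ppv": cell.discrimination.ppv, "npv": cell.discrimination.npv,
            "accuracy": cell.discrimination.accuracy,
        }
        for metric, bs in cell.bootstrap.items():
            rows.append({**base, "metric": metric, "point": bs.point,
                         "ci_lo": bs.ci_lo, "ci_hi": bs.ci_hi, "note": ""})
        for metric, value in point_only.items():
            rows.append({**base, "metric": metric,
                         "point": math.nan if value is None else value,
                         "ci_lo": math.nan, "ci_hi": math.nan, "note": ""})
    return pd.DataFrame(rows)


def _comparisons_frame(report: AuditReport) -> pd.DataFrame:
    cols = ["variant", "sample", "subgroup_var", "metric", "group1", "group2",
            "difference", "p_raw", "alpha_adjusted", "significant", "reps"]
    rows = [{"variant": c.variant, "sample": c.sample,
             "subgroup_var": c.subgroup_var, "metric": c.result.metric,
             "group1": c.result.group1, "group2": c.result.group2,
             "difference": c.result.difference, "p_raw": c.result.p_raw,
             "alpha_adjusted": c.result.alpha_adjusted,
             "significant": c.result.significant, "reps": c.result.reps}
            for c in report.comparisons]
    return pd.DataFrame(rows, columns=cols)


def export_tables(report: AuditReport, destination) -> dict[str, Path]:
    """Write metrics.csv, comparisons.csv, per-cell curve CSVs and audit.json."""
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    paths = {}
    metrics = _metrics_frame(report)
    paths["metrics"] = dest / "metrics.csv"
    metrics.to_csv(paths["metrics"], index=False)
    comps = _comparisons_frame(report)
    paths["comparisons"] = dest / "comparisons.csv"
    comps.to_csv(paths["comparisons"], index=False)

    curve_dir = dest / "curves"
    curve_dir.mkdir(exist_ok=True)
    for cell in report.cells:
        if cell.curve is None:
            continue
        name = (f"{cell.variant}_{cell.sample}_{cell.subgroup_var}_"
                f"{cell.subgroup_level}.csv").replace(" ", "-").replace("/", "-")
        pd.DataFrame({"eval_point": cell.curve.eval_points,
                      "fitted": cell.curve.fitted}).to_csv(
            curve_dir / name, index=False)
    paths["curves"] = curve_dir

    bundle = {
        "provenance": report.provenance,
        "config": asdict(report.config),
        "models": {v: m.to_dict() for v, m in report.models.items()},
        "metrics": metrics.to_dict(orient="records"),
        "comparisons": comps.to_dict(orient="records"),
        "risk_percentiles": report.risk_percentiles.to_dict(orient="records"),
        "skipped": report.skipped,
    }
    paths["json"] = dest / "audit.json"
    with open(paths["json"], "w") as fh:
        json.dump(bundle, fh, indent=1, default=str)
    logger.info("audit exported to %s", dest)
    return paths
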