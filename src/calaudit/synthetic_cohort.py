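"""Synthetic patient cohorts with known, subgroup-specific miscalibration.

Each admission carries a predicted malnutrition probability and a binary
dietitian-confirmed outcome.  The generator works on the logit scale: for a
record in subgroup ``g`` a latent score ``z ~ Normal(mu_g, sigma_g)`` becomes
the model's prediction ``p_hat = expit(z)``, while the *true* event
probability is ``expit(a_g + b_g * z)``.  A logistic regression of the
outcome on ``logit(p_hat)`` within group ``g`` therefore has population
intercept ``a_g`` and slope ``b_g`` — so every downstream calibration fit has
an exact ground truth to recover.

The default configuration mirrors the deployment this package audits: about
a 24% event rate, a roughly balanced gender split, the observed race /
ethnicity / payor / service-line composition, five facilities with
site-specific decision thresholds between 0.44 and 0.58, and gender-specific
miscalibration of realistic magnitude (intercepts near -1.5 to -0.9, slopes
near 1.4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


@dataclass(frozen=True)
class AttributeSpec:
    """A categorical admission attribute with category probabilities."""
    name: str
    labels: tuple[str, ...]
    probs: tuple[float, ...]

    def __post_init__(self):
        if len(self.labels) != len(self.probs) or not self.labels:
            raise ConfigurationError(f"attribute {self.name}: labels/probs mismatch")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"attribute {self.name}: probabilities sum to {sum(self.probs)}, not 1")
        if any(p < 0 for p in self.probs):
            raise ConfigurationError(f"attribute {self.name}: negative probability")


@dataclass(frozen=True)
class GroupTruth:
    """Logit-scale truth for one subgroup.

    ``(a, b)`` are the population calibration intercept and slope; ``(mu,
    sigma)`` locate the latent score distribution on the logit scale.
    """
    a: float
    b: float
    mu: float
    sigma: float

    def __post_init__(self):
        vals = (self.a, self.b, self.mu, self.sigma)
        if not all(math.isfinite(v) for v in vals):
            raise ConfigurationError(f"non-finite group truth {vals}")
        if self.sigma <= 0:
            raise ConfigurationError(f"sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class SynthConfig:
    """Full specification of a synthetic cohort."""
    n: int
    seed: int
    attributes: tuple[AttributeSpec, ...]
    group_truth: dict[str, GroupTruth]
    facility_thresholds: dict[str, float] = field(default_factory=dict)
    train_frac: float = 0.742
    mode: str = "single_attribute"
    train_period: tuple[str, str] = ("2021-01-01", "2022-12-31")
    holdout_period: tuple[str, str] = ("2023-01-01", "2023-09-30")

    def __post_init__(self):
        if self.n < 1:
            raise ConfigurationError(f"n must be >= 1, got {self.n}")
        if self.mode not in ("single_attribute", "composite"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if not 0.0 < self.train_frac < 1.0:
            raise ConfigurationError("train_frac must be in (0, 1)")
        for fac, thr in self.facility_thresholds.items():
            if not 0.0 < thr < 1.0:
                raise ConfigurationError(
                    f"threshold for {fac} must be in (0, 1), got {thr}")
        known = {lab for attr in self.attributes for lab in attr.labels}
        missing = set(self.group_truth) - known
        if missing:
            raise ConfigurationError(
                f"group_truth labels not found among attributes: {sorted(missing)}")

    def truth_attributes(self) -> list[AttributeSpec]:
        """Attributes whose every label has a group-truth entry."""
        return [a for a in self.attributes
                if all(lab in self.group_truth for lab in a.labels)]


# ---------------------------------------------------------------------------
# Prevalence calibration


def _prevalence(a: float, b: float, mu: float, sigma: float) -> float:
    """E[expit(a + b*Z)] with Z ~ Normal(mu, sigma), by adaptive quadrature."""
    f = lambda z: expit(a + b * z) * norm.pdf(z, loc=mu, scale=sigma)
    lo, hi = mu - 12.0 * sigma, mu + 12.0 * sigma
    val, _ = quad(f, lo, hi, epsabs=1e-10, epsrel=1e-10, limit=200)
    return val


def solve_mu_for_prevalence(a: float, b: float, sigma: float,
                            target_prevalence: float) -> float:
    """Latent-score mean producing a given event rate.

    Solves ``E[expit(a + b*Z)] = target`` for the mean of ``Z ~ Normal(mu,
    sigma)`` by bracketed root finding on the numerically integrated
    expectation (accurate to 1e-6 in prevalence).
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ConfigurationError("target_prevalence must be in (0, 1)")
    if sigma <= 0:
        raise ConfigurationError("sigma must be > 0")
    if not all(math.isfinite(v) for v in (a, b, sigma, target_prevalence)):
        raise ConfigurationError("non-finite parameters")
    f = lambda mu: _prevalence(a, b, mu, sigma) - target_prevalence
    lo, hi = -60.0, 60.0
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ConfigurationError(
            f"no bracketing interval: prevalence {target_prevalence} unreachable "
            f"with (a, b, sigma) = ({a}, {b}, {sigma})")
    return float(brentq(f, lo, hi, xtol=1e-10, rtol=8.9e-16))


# ---------------------------------------------------------------------------
# Cohort generation

RISK_RECORD_COLUMNS = ("patient_id", "sample", "admit_date", "year", "p_hat",
                       "outcome", "threshold")


def generate_cohort(config: SynthConfig) -> pd.DataFrame:
    """Generate a cohort of admission records with known miscalibration.

    Returns one row per admission with prediction, outcome, subgroup
    attributes, sample label, admission date and site threshold.  The same
    configuration (including seed) always yields a byte-identical table:
    child random streams are derived deterministically per attribute and per
    group, so draws do not depend on iteration order.
    """
    n = config.n
    root = np.random.SeedSequence(config.seed)
    # fixed spawn layout: [attributes..., z-per-group, outcome, sample, dates]
    n_attr = len(config.attributes)
    children = root.spawn(n_attr + 4)
    attr_seeds, z_seed, y_seed, s_seed, d_seed = (
        children[:n_attr], children[n_attr], children[n_attr + 1],
        children[n_attr + 2], children[n_attr + 3])

    data: dict[str, np.ndarray] = {}
    for attr, ss in zip(config.attributes, attr_seeds):
        rng = np.random.default_rng(ss)
        idx = rng.choice(len(attr.labels), size=n, p=attr.probs)
        data[attr.name] = np.asarray(attr.labels, dtype=object)[idx]

    a_vec, b_vec, mu_vec, sg_vec = _per_record_truth(config, data)

    if not config.group_truth:
        raise ConfigurationError("group_truth must contain at least one group")
    key = _group_key(config, data)
    for label in config.group_truth:
        if config.mode == "single_attribute" and not (key == label).any():
            raise ConfigurationError(f"group {label!r} received no records")
    z = mu_vec + sg_vec * _draw_latent(config, key, z_seed)

    p_hat = expit(z)
    p_true = expit(a_vec + b_vec * z)
    outcome = (np.random.default_rng(y_seed).random(n) < p_true).astype(int)

    sample = np.where(np.random.default_rng(s_seed).random(n) < config.train_frac,
                      "train", "holdout")
    admit = _draw_dates(config, sample, d_seed)

    data["patient_id"] = np.array([f"P{i:07d}" for i in range(n)], dtype=object)
    data["sample"] = sample
    data["admit_date"] = admit
    data["year"] = pd.DatetimeIndex(admit).year.astype(str)
    data["p_hat"] = p_hat
    data["outcome"] = outcome
    if config.facility_thresholds and "facility" in data:
        data["threshold"] = np.array(
            [config.facility_thresholds[f] for f in data["facility"]])
    df = pd.DataFrame(data)
    front = [c for c in RISK_RECORD_COLUMNS if c in df.columns]
    rest = [c for c in df.columns if c not in front]
    return df[front + rest]


def _group_key(config: SynthConfig, data: dict[str, np.ndarray]) -> np.ndarray:
    attrs = config.truth_attributes()
    if not attrs:
        raise ConfigurationError(
            "no attribute has group_truth entries for all its labels")
    if config.mode == "single_attribute":
        if len(attrs) != 1:
            raise ConfigurationError(
                "single_attribute mode requires exactly one attribute covered "
                f"by group_truth, found {[a.name for a in attrs]}")
        return data[attrs[0].name]
    parts = [data[a.name] for a in attrs]
    return np.array(["|".join(vals) for vals in zip(*parts)], dtype=object)


def _draw_latent(config: SynthConfig, key: np.ndarray,
                 z_seed: np.random.SeedSequence) -> np.ndarray:
    """Standard-normal draws, one deterministic child stream per group key."""
    uniq = sorted(set(key.tolist()))
    streams = z_seed.spawn(len(uniq))
    z = np.empty(key.size)
    for ss, k in zip(streams, uniq):
        mask = key == k
        z[mask] = np.random.default_rng(ss).standard_normal(int(mask.sum()))
    return z


def _per_record_truth(config: SynthConfig, data: dict[str, np.ndarray]):
    """Per-record (a, b, mu, sigma), composed across truth attributes.

    In composite mode intercepts add and slopes multiply across attributes,
    while mu and sigma average; the composition is approximate by design and
    exact parameter recovery is only guaranteed in single_attribute mode.
    """
    attrs = config.truth_attributes()
    if not attrs:
        raise ConfigurationError(
            "no attribute has group_truth entries for all its labels")
    if config.mode == "single_attribute":
        attrs = attrs[:1]
    n = next(iter(data.values())).size
    a = np.zeros(n)
    b = np.ones(n)
    mu = np.zeros(n)
    sg = np.zeros(n)
    for attr in attrs:
        gt = {lab: config.group_truth[lab] for lab in attr.labels}
        vals = data[attr.name]
        a += np.array([gt[v].a for v in vals])
        b *= np.array([gt[v].b for v in vals])
        mu += np.array([gt[v].mu for v in vals])
        sg += np.array([gt[v].sigma for v in vals])
    k = len(attrs)
    return a, b, mu / k, sg / k


def _draw_dates(config: SynthConfig, sample: np.ndarray,
                d_seed: np.random.SeedSequence) -> np.ndarray:
    rng = np.random.default_rng(d_seed)
    out = np.empty(sample.size, dtype="datetime64[D]")
    for label, (start, end) in (("train", config.train_period),
                                ("holdout", config.holdout_period)):
        mask = sample == label
        d0 = np.datetime64(start, "D")
        span = int((np.datetime64(end, "D") - d0).astype(int)) + 1
        out[mask] = d0 + rng.integers(0, span, int(mask.sum()))
    return out


# ---------------------------------------------------------------------------
# Default study-like configuration

#: Observed composition of the audited deployment cohort (proportions).
TABLE1_COMPOSITION = {
    "gender": (("Female", "Male"), (0.499, 0.501)),
    "race": (("Asian", "Black", "Other", "White"), (0.066, 0.296, 0.283, 0.355)),
    "ethnicity": (("Hispanic", "Not Hispanic/Latino"), (0.241, 0.759)),
    "payor": (("Commercial", "Medicaid", "Medicare", "Other", "Uninsured"),
              (0.169, 0.278, 0.548, 0.0005, 0.0045)),
    "service_line": (("Med", "Surg"), (0.665, 0.335)),
    "facility": (("Facility 1", "Facility 2", "Facility 3", "Facility 4",
                  "Facility 5"), (0.104, 0.146, 0.406, 0.186, 0.158)),
}

#: Site-specific decision thresholds spread across the deployed range.
DEFAULT_FACILITY_THRESHOLDS = {
    "Facility 1": 0.44, "Facility 2": 0.475, "Facility 3": 0.51,
    "Facility 4": 0.545, "Facility 5": 0.58,
}

FACILITY_HOSPITAL_TYPE = {
    "Facility 1": "Community Hospital", "Facility 2": "Community Hospital",
    "Facility 3": "Quaternary Academic Hospital",
    "Facility 4": "Tertiary Acute Care", "Facility 5": "Tertiary Acute Care",
}

#: Gender-specific miscalibration of the magnitude seen in the audited model.
DEFAULT_GENDER_TRUTH = {"Female": (-1.49, 1.42), "Male": (-0.88, 1.40)}

DEFAULT_EVENT_RATE = 0.24
DEFAULT_SIGMA = 1.5


def _normalized(probs):
    t = sum(probs)
    return tuple(p / t for p in probs)


def default_config(n: int = 66_930, seed: int = 0,
                   event_rate: float = DEFAULT_EVENT_RATE,
                   sigma: float = DEFAULT_SIGMA,
                   group_truth_ab: dict[str, tuple[float, float]] | None = None,
                   ) -> SynthConfig:
    """Study-like default configuration.

    ``n`` defaults to the audited deployment's combined sample size (49,652
    training + 17,278 hold-out admissions); the event rate targets 24% within
    every truth group, with the latent-score mean solved per group so that
    the configured miscalibration still yields that prevalence.
    """
    attributes = tuple(
        AttributeSpec(name, labels, _normalized(probs))
        for name, (labels, probs) in TABLE1_COMPOSITION.items())
    ab = DEFAULT_GENDER_TRUTH if group_truth_ab is None else group_truth_ab
    group_truth = {}
    for label, (a, b) in ab.items():
        mu = solve_mu_for_prevalence(a, b, sigma, event_rate)
        group_truth[label] = GroupTruth(a=a, b=b, mu=mu, sigma=sigma)
    return SynthConfig(n=n, seed=seed, attributes=attributes,
                       group_truth=group_truth,
                       facility_thresholds=dict(DEFAULT_FACILITY_THRESHOLDS))


def single_group_config(a: float, b: float, n: int, seed: int,
                        sigma: float = DEFAULT_SIGMA, mu: float | None = None,
                        event_rate: float | None = DEFAULT_EVENT_RATE,
                        ) -> SynthConfig:
    """One-group cohort with truth ``(a, b)`` — parameter-recovery workhorse."""
    if mu is None:
        if event_rate is None:
            raise ConfigurationError("give either mu or event_rate")
        mu = solve_mu_for_prevalence(a, b, sigma, event_rate)
    attributes = (AttributeSpec("cohort", ("all",), (1.0,)),)
    return SynthConfig(n=n, seed=seed, attributes=attributes,
                       group_truth={"all": GroupTruth(a, b, mu, sigma)})


# ---------------------------------------------------------------------------
# Longitudinal event streams (exercises the admission-reduction rules)


def generate_longitudinal(config: SynthConfig,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily prediction and dietitian-assessment event streams per admission.

    Emulates the deployed workflow: predictions are generated daily; after a
    *negative* assessment further predictions are suppressed for three days;
    after a *positive* assessment they are suppressed permanently.  The
    admission's maximum prediction and the first assessment at or after it
    reproduce the cohort row, so reducing these events must recover
    ``generate_cohort`` output for the same configuration.
    """
    cohort = generate_cohort(config)
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(len(config.attributes) + 5)[-1])
    pred_rows, assess_rows = [], []
    for row in cohort.itertuples(index=False):
        d0 = np.datetime64(row.admit_date, "D")
        peak_day = int(rng.integers(0, 3))
        assess_day = peak_day + int(rng.integers(0, 3))
        for day in range(assess_day + 1):
            if day == peak_day:
                p = row.p_hat
            else:
                p = row.p_hat * rng.uniform(0.4, 0.95)
            pred_rows.append((row.patient_id, d0 + day, p))
        assess_rows.append((row.patient_id, d0 + assess_day, int(row.outcome)))
        if row.outcome == 0 and rng.random() < 0.5:
            # predictions resume on day +4 after the 3-day suppression window
            resume = assess_day + 4
            for day in range(resume, resume + int(rng.integers(1, 3))):
                pred_rows.append(
                    (row.patient_id, d0 + day, row.p_hat * rng.uniform(0.3, 0.9)))
    predictions = pd.DataFrame(pred_rows, columns=["patient_id", "date", "p_hat"])
    assessments = pd.DataFrame(assess_rows,
                               columns=["patient_id", "date", "diagnosis"])
    return predictions, assessments
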