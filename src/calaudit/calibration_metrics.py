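"""Weak and moderate calibration metrics for binary risk predictions.

Weak calibration summarises miscalibration by the intercept and slope of a
logistic regression of the outcome on the logit of the predicted probability
(ideal: intercept 0, slope 1).  Calibration-in-the-large (CITL) is the
intercept of the same regression with the slope fixed at 1, i.e. the logit of
the prediction entered as an offset.  Under the standard convention a
*negative* intercept indicates overestimation of risk and a slope above 1
indicates an underfitted (too narrow) risk distribution.

Moderate calibration compares a smoothed observed-event curve against the
diagonal: the Brier score, its skill-rescaled variant, and the mean (Eavg,
also called the integrated calibration index, ICI) and maximum (Emax)
absolute deviation of a loess curve from the identity line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

#: Default probability clipping applied before any logit transform.
EPS = 1e-6

#: Absolute coefficient size beyond which the logistic fit is declared separated.
SEPARATION_BOUND = 50.0


class CalibrationError(ValueError):
    """Base class for calibration-fit failures."""


class DegenerateOutcomeError(CalibrationError):
    """Raised when the outcome vector contains a single class."""


class UnidentifiableSlopeError(CalibrationError):
    """Raised when all predictions are identical, so no slope is estimable."""


class ConvergenceError(CalibrationError):
    """Raised when the logistic fit fails to converge (e.g. separation)."""


def clipped_logit(p, eps: float = EPS):
    """Logit of ``p`` after clipping into ``[eps, 1 - eps]``.

    A numerical guard shared by every calibration fit: predictions of exactly
    0 or 1 would otherwise map to infinite logits.

    Parameters
    ----------
    p : array_like
        Probabilities in ``[0, 1]``.
    eps : float
        Clipping bound, ``0 < eps < 0.5``.
    """
    if not 0.0 < eps < 0.5:
        raise ValueError(f"eps must be in (0, 0.5), got {eps}")
    p = np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)
    return np.log(p / (1.0 - p))


def _validate_pairs(p_hat, outcome, min_n: int):
    p_hat = np.asarray(p_hat, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    if p_hat.shape != outcome.shape or p_hat.ndim != 1:
        raise ValueError("p_hat and outcome must be 1-D arrays of equal length")
    if p_hat.size < min_n:
        raise CalibrationError(f"need at least {min_n} records, got {p_hat.size}")
    if not np.isin(outcome, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    if outcome.min() == outcome.max():
        raise DegenerateOutcomeError("outcome contains a single class")
    if np.ptp(p_hat) == 0.0:
        raise UnidentifiableSlopeError("all predictions identical; slope not identifiable")
    return p_hat, outcome


def _newton_logistic(x: np.ndarray, y: np.ndarray, weight: np.ndarray | None = None,
                     tol: float = 1e-8, max_iter: int = 100) -> tuple[float, float]:
    """(Weighted) ML fit of ``logit P(y=1) = a + b*x`` by Newton-Raphson.

    ``weight`` holds per-record case weights (e.g. multinomial bootstrap
    counts); ``None`` means unit weights.
    """
    v = np.ones_like(x) if weight is None else weight
    vy = v * y
    vsum = v.sum()
    a, b = 0.0, 1.0
    polish = False
    for _ in range(max_iter):
        eta = a + b * x
        mu = expit(eta)
        r = v * (y - mu)
        g0, g1 = r.sum(), r @ x
        if max(abs(g0), abs(g1)) < tol * vsum:
            if polish:
                return a, b
            # one extra Newton step: quadratic convergence pushes the
            # parameter error far below the score tolerance
            polish = True
        w = v * mu * (1.0 - mu)
        h00 = w.sum()
        h01 = w @ x
        h11 = w @ (x * x)
        det = h00 * h11 - h01 * h01
        if det <= 0 or not np.isfinite(det):
            raise ConvergenceError("singular Hessian in logistic calibration fit")
        da = (h11 * g0 - h01 * g1) / det
        db = (h00 * g1 - h01 * g0) / det
        # step-halve if the log-likelihood worsens beyond rounding noise
        ll = _bernoulli_ll(eta, vy, v)
        slack = 1e-9 * (abs(ll) + 1.0)
        step = 1.0
        for _ in range(30):
            a_new, b_new = a + step * da, b + step * db
            if _bernoulli_ll(a_new + b_new * x, vy, v) >= ll - slack:
                break
            step /= 2.0
        a, b = a + step * da, b + step * db
        if max(abs(a), abs(b)) > SEPARATION_BOUND:
            raise ConvergenceError(
                "coefficients diverged (|coef| > 50); possible separation")
    raise ConvergenceError("logistic calibration fit did not converge")


def _newton_offset(x: np.ndarray, y: np.ndarray, weight: np.ndarray | None = None,
                   tol: float = 1e-8, max_iter: int = 100) -> float:
    """(Weighted) ML fit of ``logit P(y=1) = c + x`` (slope fixed at 1)."""
    v = np.ones_like(x) if weight is None else weight
    vsum = v.sum()
    c = 0.0
    for _ in range(max_iter):
        mu = expit(c + x)
        g = v @ (y - mu)
        if abs(g) < tol * vsum:
            return c
        h = v @ (mu * (1.0 - mu))
        if h <= 0:
            raise ConvergenceError("flat likelihood in offset fit")
        c += g / h
        if abs(c) > SEPARATION_BOUND:
            raise ConvergenceError("offset intercept diverged (|coef| > 50)")
    raise ConvergenceError("offset calibration fit did not converge")


def _bernoulli_ll(eta: np.ndarray, vy: np.ndarray, v: np.ndarray) -> float:
    # log-lik in the linear predictor; logaddexp avoids overflow at |eta| >> 0
    return float(vy @ eta - v @ np.logaddexp(0.0, eta))


@dataclass(frozen=True)
class WeakCalibration:
    """Logistic calibration summary: joint-fit intercept/slope plus CITL."""
    intercept: float
    slope: float
    citl: float
    n: int
    converged: bool = True


def fit_weak_calibration(p_hat, outcome, min_n: int = 20,
                         eps: float = EPS) -> WeakCalibration:
    """Fit the logistic calibration model of outcomes on logit predictions.

    Returns the jointly-estimated (intercept, slope) and, separately, the
    calibration-in-the-large intercept estimated with the slope fixed at 1.

    Raises
    ------
    DegenerateOutcomeError
        If only one outcome class is present.
    UnidentifiableSlopeError
        If all predictions are identical.
    ConvergenceError
        On separation (any |coefficient| > 50) or non-convergence.
    """
    p_hat, outcome = _validate_pairs(p_hat, outcome, min_n)
    x = clipped_logit(p_hat, eps)
    a, b, c = _weak_from_logits(x, outcome)
    return WeakCalibration(intercept=a, slope=b, citl=c, n=len(outcome))


def _weak_from_logits(x: np.ndarray, y: np.ndarray,
                      weight: np.ndarray | None = None,
                      ) -> tuple[float, float, float]:
    """(intercept, slope, citl) from pre-computed logits, optionally weighted.

    Skips input validation; used by resampling loops where the logits are
    fixed and only case weights change between refits.
    """
    a, b = _newton_logistic(x, y, weight)
    c = _newton_offset(x, y, weight)
    return a, b, c


# ---------------------------------------------------------------------------
# Brier score


@dataclass(frozen=True)
class BrierScores:
    """Raw Brier score plus its skill-rescaled variant.

    ``brier_scaled = 1 - brier / (ybar * (1 - ybar))`` compares the model
    against the constant outcome-prevalence predictor; higher is better, 1 is
    perfect, 0 matches the null predictor.  It is ``None`` (undefined) when
    the outcome is single-class.
    """
    brier: float
    brier_scaled: float | None
    n: int


def brier(p_hat, outcome) -> BrierScores:
    """Mean squared difference between prediction and binary outcome."""
    p_hat = np.asarray(p_hat, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    if p_hat.size < 1:
        raise ValueError("need at least one record")
    b = float(np.mean((p_hat - outcome) ** 2))
    ybar = float(outcome.mean())
    null = ybar * (1.0 - ybar)
    scaled = None if null == 0.0 else 1.0 - b / null
    return BrierScores(brier=b, brier_scaled=scaled, n=p_hat.size)


# ---------------------------------------------------------------------------
# Loess calibration curve and Eavg / Emax


@dataclass(frozen=True)
class SmoothedCurve:
    """A loess-smoothed observed-event curve evaluated on a probability grid."""
    eval_points: np.ndarray
    fitted: np.ndarray
    span: float
    degree: int


def fit_loess_curve(p_hat, response, span: float = 0.75, degree: int = 1,
                    max_eval_points: int | None = None) -> SmoothedCurve:
    """Locally weighted polynomial regression of ``response`` on ``p_hat``.

    Classic loess: for each evaluation point the nearest ``ceil(span * n)``
    observations receive tricube weights scaled by the distance to the
    furthest neighbour, and a degree-``degree`` polynomial is fitted by
    weighted least squares.  Fitted values are clipped to ``[0, 1]``.

    ``response`` is typically the 0/1 outcome but any numeric response is
    accepted (useful for testing against known smooth functions).  By default
    the curve is evaluated at the deduplicated sorted ``p_hat`` values; when
    ``max_eval_points`` is set and there are more unique predictions, an
    evenly spaced quantile grid of that size is used instead (downstream
    deviation summaries interpolate linearly between grid points).
    """
    x = np.asarray(p_hat, dtype=float)
    y = np.asarray(response, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("p_hat and response must be 1-D arrays of equal length")
    if not 0.0 < span <= 1.0:
        raise ValueError(f"span must be in (0, 1], got {span}")
    if degree not in (0, 1, 2):
        raise ValueError(f"degree must be 0, 1 or 2, got {degree}")
    if x.size < 20:
        raise CalibrationError(f"need at least 20 records for loess, got {x.size}")
    uniq = np.unique(x)
    if uniq.size < degree + 2:
        raise CalibrationError(
            f"need at least {degree + 2} distinct predictions for degree {degree}")

    if max_eval_points is not None and uniq.size > max_eval_points:
        qs = np.linspace(0.0, 1.0, max_eval_points)
        grid = np.unique(np.quantile(uniq, qs))
    else:
        grid = uniq

    fitted = _loess_at(x, y, grid, span, degree)
    return SmoothedCurve(eval_points=grid, fitted=np.clip(fitted, 0.0, 1.0),
                         span=span, degree=degree)


def _weight_blocks(x: np.ndarray, grid: np.ndarray, span: float, degree: int):
    """Yield (offset, dx, w) blocks of the loess weight structure.

    For each grid point the bandwidth is the distance to the r-th nearest
    observation, r = ceil(span * n), and weights are tricube in the scaled
    distance.  Degenerate grid rows (zero bandwidth from heavy ties, or ties
    at the bandwidth edge zeroing out too many weights) are repaired by
    expanding the bandwidth just past the tie.
    """
    n = x.size
    r = min(n, max(int(np.ceil(span * n)), degree + 2))
    block = max(8, int(4_000_000 // max(n, 1)))
    for start in range(0, grid.size, block):
        g = grid[start:start + block]
        dx = x[None, :] - g[:, None]
        d = np.abs(dx)
        h = np.partition(d, r - 1, axis=1)[:, r - 1]
        bad = h <= 0.0
        h_safe = np.where(bad, 1.0, h)
        w = (1.0 - np.clip(d / h_safe[:, None], 0.0, 1.0) ** 3) ** 3
        thin = np.count_nonzero(w > 0.0, axis=1) < degree + 1
        for i in np.nonzero(bad | thin)[0]:
            w[i] = _repaired_weights(d[i], r)
        yield start, dx, w


def _repaired_weights(d: np.ndarray, r: int) -> np.ndarray:
    h = np.partition(d, r - 1)[r - 1]
    if h <= 0.0:
        return (d == 0.0).astype(float)
    larger = d[d > h]
    h = larger.min() if larger.size else h
    return (1.0 - np.clip(d / (h * (1 + 1e-9)), 0.0, 1.0) ** 3) ** 3


def _moments(w: np.ndarray, dx: np.ndarray, y: np.ndarray, degree: int,
             ) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise moment sums m_k = sum w dx^k (k <= 2*degree) and
    t_k = sum w dx^k y (k <= degree)."""
    rows = w.shape[0]
    mk = np.empty((rows, 2 * degree + 1))
    tk = np.empty((rows, degree + 1))
    wk = w.copy()
    mk[:, 0] = wk.sum(axis=1)
    tk[:, 0] = wk @ y
    for k in range(1, 2 * degree + 1):
        wk *= dx
        mk[:, k] = wk.sum(axis=1)
        if k <= degree:
            tk[:, k] = wk @ y
    return mk, tk


def _solve_moment_systems(mk: np.ndarray, tk: np.ndarray, degree: int) -> np.ndarray:
    """Fitted values at dx = 0 from stacked normal equations.

    A locally singular polynomial system (all in-window points at one
    location) degrades to the local weighted mean.
    """
    mean = np.where(mk[:, 0] > 0, tk[:, 0] / np.where(mk[:, 0] > 0, mk[:, 0], 1.0),
                    np.nan)
    if degree == 0:
        return mean
    if degree == 1:
        det = mk[:, 0] * mk[:, 2] - mk[:, 1] ** 2
        scale = np.maximum(mk[:, 0] * mk[:, 2] + mk[:, 1] ** 2, 1e-300)
        singular = det <= 1e-12 * scale
        safe = np.where(singular, 1.0, det)
        vals = (mk[:, 2] * tk[:, 0] - mk[:, 1] * tk[:, 1]) / safe
        return np.where(singular, mean, vals)
    rows = mk.shape[0]
    a = np.empty((rows, degree + 1, degree + 1))
    for i in range(degree + 1):
        a[:, i, :] = mk[:, i:i + degree + 1]
    vals = np.empty(rows)
    for i in range(rows):  # degree 2 is rare; row-wise solve is fine
        try:
            vals[i] = np.linalg.solve(a[i], tk[i])[0]
        except np.linalg.LinAlgError:
            vals[i] = mean[i]
    return vals


def _loess_at(x: np.ndarray, y: np.ndarray, grid: np.ndarray, span: float,
              degree: int) -> np.ndarray:
    """Loess fitted values on a grid, vectorised over blocks of grid points."""
    fitted = np.empty(grid.size)
    for start, dx, w in _weight_blocks(x, grid, span, degree):
        mk, tk = _moments(w, dx, y, degree)
        fitted[start:start + w.shape[0]] = _solve_moment_systems(mk, tk, degree)
    return fitted


class FrozenLoessDesign:
    """Loess design with the bandwidth pattern frozen at the full-sample fit.

    A multinomial bootstrap resample reweights the original records rather
    than moving them, so the local moment sums of a resample are linear in
    the count vector: ``m_k = (W * dx^k) @ counts``.  Precomputing those
    matrices turns each bootstrap loess refit into a handful of
    matrix-vector products.  The tricube weights (and hence bandwidths) are
    those of the full sample — the nearest-neighbour bandwidth is a span
    quantile of the distances and is stable under resampling.
    """

    def __init__(self, p_hat, response, span: float = 0.75, degree: int = 1,
                 max_eval_points: int | None = 100):
        curve = fit_loess_curve(p_hat, response, span=span, degree=degree,
                                max_eval_points=max_eval_points)
        self.curve = curve
        self.degree = degree
        x = np.asarray(p_hat, dtype=float)
        y = np.asarray(response, dtype=float)
        g = curve.eval_points
        self._design = np.empty((2 * degree + 1, g.size, x.size))
        for start, dx, w in _weight_blocks(x, g, span, degree):
            sl = slice(start, start + w.shape[0])
            wk = w.copy()
            self._design[0, sl] = wk
            for k in range(1, 2 * degree + 1):
                wk *= dx
                self._design[k, sl] = wk
        self._y = y

    def refit(self, counts: np.ndarray) -> np.ndarray:
        """Fitted values on the grid for a resample given by record counts."""
        d = self.degree
        mk = (self._design @ counts).T
        tk = (self._design[:d + 1] @ (counts * self._y)).T
        return np.clip(_solve_moment_systems(mk, tk, d), 0.0, 1.0)


def eavg_emax(curve: SmoothedCurve, p_hat) -> tuple[float, float]:
    """Mean (Eavg/ICI) and maximum (Emax) absolute deviation of the smoothed
    observed-event curve from the diagonal, averaged over the records."""
    p = np.asarray(p_hat, dtype=float)
    fitted_at = np.interp(p, curve.eval_points, curve.fitted)
    dev = np.abs(fitted_at - p)
    return float(dev.mean()), float(dev.max())


@dataclass(frozen=True)
class ModerateCalibration:
    """Bundle of moderate-calibration summaries."""
    brier: float
    brier_scaled: float | None
    eavg: float
    emax: float
    n: int


def moderate_calibration(p_hat, outcome, span: float = 0.75, degree: int = 1,
                         max_eval_points: int | None = 400) -> ModerateCalibration:
    """Brier scores plus loess-based Eavg/Emax in one pass."""
    scores = brier(p_hat, outcome)
    curve = fit_loess_curve(p_hat, outcome, span=span, degree=degree,
                            max_eval_points=max_eval_points)
    eavg, emax = eavg_emax(curve, p_hat)
    return ModerateCalibration(brier=scores.brier, brier_scaled=scores.brier_scaled,
                               eavg=eavg, emax=emax, n=scores.n)
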