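"""Recalibration of predicted probabilities on the logit scale.

Two updating strategies for a miscalibrated but otherwise fixed model:

* recalibration-in-the-large (``ritl``): the slope is fixed at 1 and only the
  intercept is re-estimated (the CITL offset fit);
* logistic recalibration: intercept and slope are both freely estimated.

Either yields a linear map of the logit, ``logit(p') = alpha + beta *
logit(p)``, fitted on a training sample and then applied to new predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .calibration_metrics import EPS, clipped_logit, fit_weak_calibration

METHODS = ("none", "ritl", "logistic")


@dataclass(frozen=True)
class RecalibrationModel:
    """A fitted logit-scale recalibration map ``alpha + beta * logit(p)``."""
    method: str
    alpha: float
    beta: float
    fit_n: int = 0
    fit_sample: str = ""

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.method == "none" and (self.alpha, self.beta) != (0.0, 1.0):
            raise ValueError("method 'none' requires (alpha, beta) = (0, 1)")
        if self.method == "ritl" and self.beta != 1.0:
            raise ValueError("method 'ritl' requires beta = 1")

    def to_dict(self) -> dict:
        return {"method": self.method, "alpha": self.alpha, "beta": self.beta,
                "fit_n": self.fit_n, "fit_sample": self.fit_sample}


def fit_recalibration(method: str, p_hat, outcome,
                      fit_sample: str = "") -> RecalibrationModel:
    """Fit a recalibration model of the given method on (p_hat, outcome)."""
    if method == "none":
        return RecalibrationModel("none", 0.0, 1.0,
                                  fit_n=np.asarray(p_hat).size, fit_sample=fit_sample)
    weak = fit_weak_calibration(p_hat, outcome)
    if method == "ritl":
        return RecalibrationModel("ritl", weak.citl, 1.0,
                                  fit_n=weak.n, fit_sample=fit_sample)
    if method == "logistic":
        return RecalibrationModel("logistic", weak.intercept, weak.slope,
                                  fit_n=weak.n, fit_sample=fit_sample)
    raise ValueError(f"unknown recalibration method {method!r}")


def apply_recalibration(model: RecalibrationModel, p_hat,
                        eps: float = EPS) -> np.ndarray:
    """Map probabilities through ``expit(alpha + beta * logit(p))``.

    Order-preserving whenever ``beta > 0``; a non-positive beta is applied as
    requested but triggers a warning, since it reverses or collapses ranks.
    The identity model returns its input unchanged (up to the shared eps
    clipping) rather than round-tripping through the logit.
    """
    if model.method == "none":
        return np.clip(np.asarray(p_hat, dtype=float), eps, 1.0 - eps)
    if model.beta <= 0.0:
        warnings.warn(
            f"recalibration beta = {model.beta} <= 0: ranks will be reversed "
            "or collapsed", RuntimeWarning, stacklevel=2)
    return expit(model.alpha + model.beta * clipped_logit(p_hat, eps))
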