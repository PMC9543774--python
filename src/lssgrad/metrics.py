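"""Prediction-error measures for gradient retention times.

Two measures are implemented. The familiar relative error

    Error% = 100 * (tr_pred - tr_exp) / tr_exp

with the conventional 2% acceptability bound, and the resolution-based
statistic lambda = |tr_pred - tr_exp| / w, where w is the 4-sigma gradient
peak width estimated from the column plate number N and the gradient
steepness b:

    w = (4 * t0 / sqrt(N)) * (1 + ln10*b) / (ln10*b)

lambda is the chromatographic resolution achievable between the experimental
and the predicted peak; a prediction is acceptable when lambda <= 0.5. Unlike
Error%, lambda accounts for the fact that gradient peak widths are set by b
rather than by the retention time, so it remains comparable across compounds
with very different S and across gradient programs: for strongly retained
compounds or thin peaks Error% can look excellent while the predicted and
experimental peaks are fully resolved from each other.

The normalized pair (lambda/0.5, Error%/2) puts both measures on a common
acceptability scale of 1; they coincide exactly for an isocratic reference
peak of width w = 4*tr/sqrt(N), for which a 2% time error is resolution 0.5
on a 10,000-plate column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import (
    LN10,
    ElutionRegime,
    GradientProgram,
    LSSParameters,
    predict_retention_time,
    steepness,
)

__all__ = [
    "ERROR_PERCENT_BOUND",
    "LAMBDA_THRESHOLD",
    "PredictionAssessment",
    "error_percent",
    "gradient_peak_width",
    "lambda_resolution",
    "assess_prediction",
]

ERROR_PERCENT_BOUND = 2.0
LAMBDA_THRESHOLD = 0.5


@dataclass(frozen=True)
class PredictionAssessment:
    """Predicted vs experimental retention time, under both error measures.

    ``error_percent`` is signed; use ``abs()`` against the 2% bound.
    ``lam_norm = lam / 0.5`` and ``err_norm = |error_percent| / 2`` are the
    normalized pair; both <= 1 means acceptable under the respective rule.
    """

    tr_pred: float
    tr_exp: float
    error_percent: float
    width: float
    lam: float
    regime: ElutionRegime
    n_plates: float

    @property
    def lam_norm(self) -> float:
        return self.lam / LAMBDA_THRESHOLD

    @property
    def err_norm(self) -> float:
        return abs(self.error_percent) / ERROR_PERCENT_BOUND

    @property
    def acceptable(self) -> bool:
        """True when the resolution-based error is within 0.5."""
        return self.lam <= LAMBDA_THRESHOLD


def error_percent(tr_pred: float, tr_exp: float) -> float:
    """Signed relative retention-time error in percent."""
    if not tr_exp > 0.0:
        raise ValueError(f"experimental retention time must be > 0, got {tr_exp}")
    return 100.0 * (tr_pred - tr_exp) / tr_exp


def gradient_peak_width(b: float, t0: float, n_plates: float) -> float:
    """4-sigma gradient peak width (min) from steepness b and plate number N.

    N is the best-case (van Deemter minimum) plate number of the column; the
    true width of badly behaved solutes (large proteins at non-optimal flow)
    is larger, so resolutions computed from this width are upper bounds.
    """
    if not b > 0.0:
        raise ValueError(f"steepness b must be > 0, got {b}")
    if not n_plates > 0.0:
        raise ValueError(f"plate number must be > 0, got {n_plates}")
    return (4.0 * t0 / math.sqrt(n_plates)) * (1.0 + LN10 * b) / (LN10 * b)


def lambda_resolution(tr_pred: float, tr_exp: float, w: float) -> float:
    """Resolution between predicted and experimental peaks: |dt| / w."""
    if not w > 0.0:
        raise ValueError(f"peak width must be > 0, got {w}")
    return abs(tr_pred - tr_exp) / w


def assess_prediction(
    p: LSSParameters,
    g: GradientProgram,
    tr_exp: float,
    n_plates: float,
) -> PredictionAssessment:
    """Predict the retention time under ``g`` and score it against ``tr_exp``."""
    tr_pred, regime = predict_retention_time(p, g)
    b = steepness(p, g)
    w = gradient_peak_width(b, g.t0, n_plates)
    return PredictionAssessment(
        tr_pred=tr_pred,
        tr_exp=tr_exp,
        error_percent=error_percent(tr_pred, tr_exp),
        width=w,
        lam=lambda_resolution(tr_pred, tr_exp, w),
        regime=regime,
        n_plates=n_plates,
    )
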