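"""Fitting LSS retention parameters (S, log k0) from scouting gradient runs.

Two estimators are provided, both scikit-learn compatible (``fit`` /
``predict``, ``get_params`` / ``set_params``, trailing-underscore fitted
attributes). Rows of ``X`` are gradient programs in the column order
``(Ci, Cf, tg_min, t0_min, tD_min)``; ``y`` is the measured retention time in
minutes.

``LSSGradientRegressor`` implements the linear-regression treatment: each
run's measured retention time is inverted to the composition at elution Ce,
and Ce is regressed on log10 of the normalized gradient slope s*. Under the
strongly-retained approximation (1/ki negligible) that relationship is exactly
linear, with S = 1/slope and log k0 = S*intercept - log10(ln10 * S). The
approximation — and hence the estimator — is trustworthy only when the
retention factor at the initial composition is large (log10 ki >= ~2.1,
i.e. ki >= ~125); the fit carries an ``applicable_`` flag for that rule.

``LSSExactTwoRunRegressor`` is the conventional alternative it is benchmarked
against: it solves the two dwell-corrected retention-time equations exactly
for (S, log k0) by one-dimensional bracketed root finding, with no
large-ki assumption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import linregress
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .core import (
    LN10,
    ElutionRegime,
    GradientProgram,
    LSSParameters,
    elution_composition,
    log_retention_factor_initial,
    normalized_slope,
    predict_retention_time,
)

__all__ = [
    "PROGRAM_COLUMNS",
    "RunObservation",
    "RegressionFit",
    "EstimationError",
    "DegenerateDesignError",
    "NonPhysicalFitError",
    "RegimeError",
    "NoSolutionError",
    "LSSGradientRegressor",
    "LSSExactTwoRunRegressor",
    "runs_to_Xy",
    "fit_lss_regression",
    "fit_lss_exact_two_runs",
    "applicability_report",
]

#: Column order expected in the estimator design matrix X.
PROGRAM_COLUMNS = ("Ci", "Cf", "tg_min", "t0_min", "tD_min")

DEFAULT_KI_CUTOFF = 2.1
DEFAULT_R2_THRESHOLD = 0.995


class EstimationError(ValueError):
    """Base class for LSS fitting failures."""


class DegenerateDesignError(EstimationError):
    """The gradient runs cannot identify the parameters (e.g. identical s*)."""


class NonPhysicalFitError(EstimationError):
    """The fitted slope implies retention increasing with gradient steepness."""


class RegimeError(EstimationError):
    """An observed retention time implies elution outside the gradient ramp."""


class NoSolutionError(EstimationError):
    """The exact two-run equations have no root inside the S bracket."""


@dataclass(frozen=True)
class RunObservation:
    """One scouting gradient run: a program plus the measured retention time."""

    program: GradientProgram
    tr_obs: float
    compound_id: str = ""

    def __post_init__(self) -> None:
        if not self.tr_obs > 0.0:
            raise ValueError(f"observed retention time must be > 0, got {self.tr_obs}")


@dataclass(frozen=True)
class RegressionFit:
    """Result of the Ce-vs-log10(s*) linear regression for one compound.

    ``alpha``/``beta`` are the fitted slope and intercept; ``r2`` is the
    coefficient of determination (NaN for a two-point fit, where the line is
    exact by construction). ``params`` holds the derived (S, log k0);
    ``log_ki`` the derived log retention factor at the initial composition.
    ``applicable`` records the large-ki rule log_ki >= ki_cutoff (inclusive);
    ``linearity_ok`` records r2 >= r2_threshold (None when r2 is undefined).
    """

    alpha: float
    beta: float
    r2: float
    n_runs: int
    params: LSSParameters
    log_ki: float
    applicable: bool
    linearity_ok: bool | None
    ki_cutoff: float = DEFAULT_KI_CUTOFF
    r2_threshold: float = DEFAULT_R2_THRESHOLD
    method: str = "regression"


def runs_to_Xy(runs: Sequence[RunObservation]) -> tuple[np.ndarray, np.ndarray]:
    """Stack run observations into an (n, 5) design matrix and target vector."""
    X = np.array(
        [[r.program.Ci, r.program.Cf, r.program.tg, r.program.t0, r.program.tD] for r in runs],
        dtype=float,
    )
    y = np.array([r.tr_obs for r in runs], dtype=float)
    return X, y


def _programs_from_X(X: np.ndarray) -> list[GradientProgram]:
    return [GradientProgram(Ci=r[0], Cf=r[1], tg=r[2], t0=r[3], tD=r[4]) for r in X]


def _check_shared_window(programs: Sequence[GradientProgram]) -> None:
    ref = programs[0]
    for g in programs[1:]:
        same = (
            math.isclose(g.Ci, ref.Ci, abs_tol=1e-12)
            and math.isclose(g.Cf, ref.Cf, abs_tol=1e-12)
            and math.isclose(g.t0, ref.t0, rel_tol=1e-9)
            and math.isclose(g.tD, ref.tD, rel_tol=1e-9, abs_tol=1e-12)
        )
        if not same:
            raise DegenerateDesignError(
                "all runs in one fit must share Ci, Cf, t0 and tD and differ "
                "only in gradient time"
            )


def _validate_X(X, *, min_runs: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(PROGRAM_COLUMNS):
        raise ValueError(
            f"X must be 2D with columns {PROGRAM_COLUMNS}, got shape {getattr(X, 'shape', None)}"
        )
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    if X.shape[0] < min_runs:
        raise DegenerateDesignError(
            f"need at least {min_runs} gradient runs, got {X.shape[0]}"
        )
    return X


class LSSGradientRegressor(RegressorMixin, BaseEstimator):
    """Fit (S, log k0) by ordinary least squares of Ce on log10 s*.

    Parameters
    ----------
    ki_cutoff : float, default 2.1
        Applicability rule on the fitted log10 ki (inclusive). Below it the
        large-ki approximation underlying the regression is unreliable.
    r2_threshold : float, default 0.995
        Warning level on the regression R^2 for runs of three or more
        gradients; below it the retention model is suspect of non-linearity.

    Attributes
    ----------
    alpha_, beta_ : float
        Slope and intercept of Ce vs log10 s*.
    r2_ : float
        Coefficient of determination (NaN for exactly two runs).
    S_, log_k0_, log_ki_ : float
        Derived LSS parameters and log retention factor at Ci.
    params_ : LSSParameters
    applicable_ : bool
    linearity_ok_ : bool or None
    fit_result_ : RegressionFit
    """

    def __init__(
        self,
        ki_cutoff: float = DEFAULT_KI_CUTOFF,
        r2_threshold: float = DEFAULT_R2_THRESHOLD,
    ) -> None:
        self.ki_cutoff = ki_cutoff
        self.r2_threshold = r2_threshold

    def fit(self, X, y) -> "LSSGradientRegressor":
        X = _validate_X(X, min_runs=2)
        y = np.asarray(y, dtype=float)
        if y.shape != (X.shape[0],):
            raise ValueError(f"y must have shape ({X.shape[0]},), got {y.shape}")
        programs = _programs_from_X(X)
        _check_shared_window(programs)

        sstar = np.array([normalized_slope(g) for g in programs])
        if np.unique(np.round(np.log10(sstar), 12)).size < sstar.size:
            raise DegenerateDesignError(
                "normalized gradient slopes must be distinct (vary tg between runs)"
            )
        ce = np.array([elution_composition(g, tr).value for g, tr in zip(programs, y)])

        x = np.log10(sstar)
        n = x.size
        if n == 2:
            alpha = (ce[1] - ce[0]) / (x[1] - x[0])
            beta = ce[0] - alpha * x[0]
            r2 = math.nan
        else:
            res = linregress(x, ce)
            alpha, beta = res.slope, res.intercept
            r2 = res.rvalue**2

        if alpha <= 0.0:
            raise NonPhysicalFitError(
                "fitted slope of Ce vs log10 s* is non-positive: retention "
                "increases with gradient steepness, inconsistent with the LSS model"
            )

        S = 1.0 / alpha
        log_k0 = S * beta - math.log10(LN10 * S)
        params = LSSParameters(S=S, log_k0=log_k0)
        log_ki = log_retention_factor_initial(params, programs[0].Ci)
        linearity_ok = None if math.isnan(r2) else bool(r2 >= self.r2_threshold)

        self.alpha_, self.beta_, self.r2_ = alpha, beta, r2
        self.S_, self.log_k0_, self.log_ki_ = S, log_k0, log_ki
        self.params_ = params
        self.n_runs_ = n
        self.applicable_ = bool(log_ki >= self.ki_cutoff)
        self.linearity_ok_ = linearity_ok
        self.fit_result_ = RegressionFit(
            alpha=alpha,
            beta=beta,
            r2=r2,
            n_runs=n,
            params=params,
            log_ki=log_ki,
            applicable=self.applicable_,
            linearity_ok=linearity_ok,
            ki_cutoff=self.ki_cutoff,
            r2_threshold=self.r2_threshold,
            method="regression",
        )
        return self

    def predict(self, X) -> np.ndarray:
        """Predict retention times (min) for gradient programs in X."""
        check_is_fitted(self, "params_")
        X = _validate_X(X, min_runs=1)
        return np.array(
            [predict_retention_time(self.params_, g).tr for g in _programs_from_X(X)]
        )

    def predict_with_regime(self, X) -> list[tuple[float, ElutionRegime]]:
        """Like :meth:`predict` but also reporting the elution regime per run."""
        check_is_fitted(self, "params_")
        X = _validate_X(X, min_runs=1)
        return [tuple(predict_retention_time(self.params_, g)) for g in _programs_from_X(X)]


class LSSExactTwoRunRegressor(RegressorMixin, BaseEstimator):
    """Solve the two dwell-corrected retention-time equations exactly.

    This is the conventional determination used by HPLC modeling software:
    given exactly two gradient runs it finds (S, log k0) such that both
    predicted retention times match the observations, with no assumption on
    the size of ki. log k0 is eliminated by inverting the first run's
    equation, leaving a one-dimensional root find in S over ``s_bracket``.

    Parameters
    ----------
    s_bracket : (float, float), default (0.5, 2000.0)
        Search interval for S; the defaults span small molecules to mAbs.
    residual_tol : float, default 1e-8
        Maximum absolute residual (min) allowed on both equations at the
        solution.
    """

    def __init__(
        self,
        s_bracket: tuple[float, float] = (0.5, 2000.0),
        residual_tol: float = 1e-8,
    ) -> None:
        self.s_bracket = s_bracket
        self.residual_tol = residual_tol

    # -- internals ---------------------------------------------------------
    @staticmethod
    def _log_ki_from_run(S: float, g: GradientProgram, tr: float) -> float:
        """Invert the in-gradient retention-time equation for log10 ki at given S."""
        b = S * normalized_slope(g)
        A = LN10 * b
        E = b * (tr - g.t0 - g.tD) / g.t0
        if E > 30.0:
            # 10**E dominates; corrections below double precision.
            return E - math.log10(A)
        ki = (10.0**E - 1.0 + A * g.tD / g.t0) / A
        return math.log10(ki)

    def _residual(self, S: float, g1: GradientProgram, tr1: float, g2: GradientProgram) -> float:
        log_ki = self._log_ki_from_run(S, g1, tr1)
        params = LSSParameters(S=S, log_k0=log_ki + S * g1.Ci)
        return predict_retention_time(params, g2).tr

    def fit(self, X, y) -> "LSSExactTwoRunRegressor":
        X = _validate_X(X, min_runs=2)
        y = np.asarray(y, dtype=float)
        if X.shape[0] != 2:
            raise DegenerateDesignError(
                f"the exact solver uses exactly two runs, got {X.shape[0]}; "
                "use LSSGradientRegressor for multi-run fits"
            )
        if y.shape != (2,):
            raise ValueError(f"y must have shape (2,), got {y.shape}")
        g1, g2 = _programs_from_X(X)
        _check_shared_window([g1, g2])
        if math.isclose(g1.tg, g2.tg, rel_tol=1e-12):
            raise DegenerateDesignError(
                "the two runs must have distinct gradient times"
            )
        tr1, tr2 = float(y[0]), float(y[1])
        for g, tr in ((g1, tr1), (g2, tr2)):
            ce = elution_composition(g, tr)
            if not ce.in_window:
                raise RegimeError(
                    f"observed tr={tr:g} min implies elution composition "
                    f"{ce.value:.4f} outside the gradient window "
                    f"[{g.Ci:g}, {g.Cf:g}]; the solute did not elute on the ramp"
                )

        lo, hi = self.s_bracket
        grid = np.geomspace(lo, hi, 120)
        f = np.array([self._residual(S, g1, tr1, g2) - tr2 for S in grid])
        idx = np.nonzero(np.diff(np.sign(f)) != 0)[0]
        if idx.size == 0:
            raise NoSolutionError(
                f"no root of the two-run equations for S in [{lo:g}, {hi:g}]; "
                "widen s_bracket or check the run data"
            )
        a, b_ = grid[idx[0]], grid[idx[0] + 1]
        S = brentq(
            lambda s: self._residual(s, g1, tr1, g2) - tr2,
            a,
            b_,
            xtol=1e-13,
            rtol=8.9e-16,
            maxiter=200,
        )
        log_ki = self._log_ki_from_run(S, g1, tr1)
        params = LSSParameters(S=S, log_k0=log_ki + S * g1.Ci)

        r1 = predict_retention_time(params, g1).tr - tr1
        r2_resid = predict_retention_time(params, g2).tr - tr2
        if max(abs(r1), abs(r2_resid)) > self.residual_tol:
            raise NoSolutionError(
                "root finding converged but the retention-time equations are "
                f"not satisfied (residuals {r1:.3g}, {r2_resid:.3g} min); the "
                "observations are inconsistent with in-gradient LSS elution"
            )

        self.S_, self.log_k0_ = params.S, params.log_k0
        self.log_ki_ = log_ki
        self.params_ = params
        self.n_runs_ = 2
        self.residuals_ = (r1, r2_resid)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        X = _validate_X(X, min_runs=1)
        return np.array(
            [predict_retention_time(self.params_, g).tr for g in _programs_from_X(X)]
        )

    def predict_with_regime(self, X) -> list[tuple[float, ElutionRegime]]:
        check_is_fitted(self, "params_")
        X = _validate_X(X, min_runs=1)
        return [tuple(predict_retention_time(self.params_, g)) for g in _programs_from_X(X)]


# -- functional wrappers ---------------------------------------------------


def fit_lss_regression(
    runs: Sequence[RunObservation],
    *,
    ki_cutoff: float = DEFAULT_KI_CUTOFF,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> RegressionFit:
    """Fit the Ce-vs-log10(s*) regression to a series of gradient runs."""
    X, y = runs_to_Xy(runs)
    est = LSSGradientRegressor(ki_cutoff=ki_cutoff, r2_threshold=r2_threshold)
    est.fit(X, y)
    return est.fit_result_


def fit_lss_exact_two_runs(
    run1: RunObservation,
    run2: RunObservation,
    *,
    s_bracket: tuple[float, float] = (0.5, 2000.0),
    residual_tol: float = 1e-8,
) -> LSSParameters:
    """Exactly invert two gradient runs for (S, log k0); no large-ki assumption."""
    X, y = runs_to_Xy([run1, run2])
    est = LSSExactTwoRunRegressor(s_bracket=s_bracket, residual_tol=residual_tol)
    est.fit(X, y)
    return est.params_


def applicability_report(fit: RegressionFit) -> dict:
    """Machine- and human-readable applicability diagnostics for a fit.

    Checks the fitted log10 ki against the large-ki cutoff and (when defined)
    R^2 against the linearity warning level, and phrases the standard remedy
    when the cutoff fails: rerun the scouting gradients starting from the
    lowest practical initial composition so the compound is strongly retained
    at the gradient start.
    """
    lines = [
        f"log ki = {fit.log_ki:.3f} vs cutoff {fit.ki_cutoff:g}: "
        + ("pass" if fit.applicable else "FAIL"),
    ]
    if fit.linearity_ok is None:
        lines.append("R^2 undefined (two-point fit): linearity not assessable")
    else:
        lines.append(
            f"R^2 = {fit.r2:.5f} vs threshold {fit.r2_threshold:g}: "
            + ("pass" if fit.linearity_ok else "FAIL (retention model may be non-linear)")
        )
    recommendation = ""
    if not fit.applicable:
        recommendation = (
            "retention factor at the initial composition is too low for the "
            "regression treatment; repeat the scouting gradients starting with "
            "the lowest possible initial composition, or use the exact two-run solver"
        )
        lines.append("recommendation: " + recommendation)
    return {
        "log_ki": fit.log_ki,
        "ki_cutoff": fit.ki_cutoff,
        "applicable": fit.applicable,
        "r2": fit.r2,
        "r2_threshold": fit.r2_threshold,
        "linearity_ok": fit.linearity_ok,
        "n_runs": fit.n_runs,
        "recommendation": recommendation,
        "text": "\n".join(lines),
    }
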