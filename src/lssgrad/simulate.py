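"""Synthetic gradient runs from known retention models, and a numerical oracle.

The oracle solves the fundamental gradient-elution balance

    integral_0^tau dt / k(C_in(t)) = t0

for the migration time tau, where C_in(t) is the composition at the column
inlet: Ci during the dwell delay, the linear ramp from Ci to Cf over tg, and
Cf afterwards. The retention time is tr = t0 + tau. For a log-linear model
the dwell and ramp segments integrate in closed form; a quadratic model
log10 k(C) = log_k0 - s1*C + s2*C^2 is handled by adaptive quadrature with a
bracketed root solve on the ramp. The oracle therefore makes none of the
approximations of the closed-form prediction and serves as the independent
ground truth for every estimator and error metric in the package.

The generators emulate the standard scouting-gradient design: a fixed
composition window and instrument, with a series of gradient times chosen to
span steepness values b from about 1 (fastest) down to 0.05 (slowest), and
optional additive Gaussian noise on the observed retention times. Presets
sketch the three compound classes — small molecules (S ~ 3-12), peptides
(S ~ 15-50) and intact proteins (S ~ 80-300, on-off retention with very large
initial retention factors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq

from .core import (
    LN10,
    ElutionRegime,
    GradientProgram,
    LSSParameters,
    RetentionPrediction,
    normalized_slope,
)
from .estimation import (
    LSSExactTwoRunRegressor,
    LSSGradientRegressor,
    RunObservation,
    runs_to_Xy,
)
from .metrics import assess_prediction

__all__ = [
    "RetentionModel",
    "GradientSeries",
    "CompoundPreset",
    "PRESETS",
    "ElutionTimeoutError",
    "oracle_retention_time",
    "generate_run_series",
    "gradient_time_for_b",
    "sample_compounds",
    "linearity_experiment",
]


class ElutionTimeoutError(RuntimeError):
    """The solute did not elute within the configured time horizon."""


@dataclass(frozen=True)
class RetentionModel:
    """Ground-truth retention model log10 k(C) = log_k0 - s1*C + s2*C^2.

    ``s2 = 0`` gives the log-linear (LSS) model; ``s2 != 0`` the quadratic
    model used only as simulation truth for probing non-linearity. k(C) is
    positive by construction.
    """

    log_k0: float
    s1: float
    s2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("log_k0", "s1", "s2"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @classmethod
    def linear(cls, p: LSSParameters) -> "RetentionModel":
        return cls(log_k0=p.log_k0, s1=p.S, s2=0.0)

    @classmethod
    def quadratic(cls, log_k0: float, s1: float, s2: float) -> "RetentionModel":
        return cls(log_k0=log_k0, s1=s1, s2=s2)

    @property
    def is_linear(self) -> bool:
        return self.s2 == 0.0

    def to_lss(self) -> LSSParameters:
        if not self.is_linear:
            raise ValueError("quadratic model has no exact LSS parameters")
        return LSSParameters(S=self.s1, log_k0=self.log_k0)

    def log_k(self, C: float) -> float:
        return self.log_k0 - self.s1 * C + self.s2 * C * C

    def k(self, C: float) -> float:
        return 10.0 ** self.log_k(C)


@dataclass(frozen=True)
class GradientSeries:
    """A shared gradient window/instrument with a series of gradient times."""

    Ci: float
    Cf: float
    t0: float
    tD: float
    tg_list: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.tg_list) < 2:
            raise ValueError("a gradient series needs at least two gradient times")
        if any(b <= a for a, b in zip(self.tg_list, self.tg_list[1:])):
            raise ValueError("gradient times must be strictly increasing")
        # window validation by constructing one program
        GradientProgram(self.Ci, self.Cf, self.tg_list[0], self.t0, self.tD)

    @classmethod
    def from_b_targets(
        cls,
        S: float,
        Ci: float,
        Cf: float,
        t0: float,
        tD: float,
        b_targets: Sequence[float],
    ) -> "GradientSeries":
        """Series whose gradient times give the requested steepness values.

        ``b_targets`` are interpreted for a compound of solvent-strength S;
        they must be strictly decreasing (slower gradient = smaller b).
        """
        window = GradientProgram(Ci, Cf, max(b_targets) + 1.0, t0, tD)  # template
        tgs = tuple(gradient_time_for_b(S, window, b) for b in b_targets)
        return cls(Ci=Ci, Cf=Cf, t0=t0, tD=tD, tg_list=tgs)

    def programs(self) -> list[GradientProgram]:
        return [GradientProgram(self.Ci, self.Cf, tg, self.t0, self.tD) for tg in self.tg_list]


def gradient_time_for_b(
    p: LSSParameters | float, window: GradientProgram, b_target: float
) -> float:
    """Gradient time giving steepness ``b_target`` for a compound in ``window``.

    Inverts b = S * t0 * (Cf - Ci) / tg; the window's own tg is ignored.
    """
    if not b_target > 0.0:
        raise ValueError(f"b_target must be > 0, got {b_target}")
    S = p.S if isinstance(p, LSSParameters) else float(p)
    return S * window.t0 * window.delta_c() / b_target


def oracle_retention_time(
    m: RetentionModel,
    g: GradientProgram,
    tol: float = 1e-6,
    horizon_factor: float = 100.0,
) -> RetentionPrediction:
    """Retention time by piecewise integration of the gradient-elution balance.

    Parameters
    ----------
    tol : float
        Absolute tolerance on the returned retention time, minutes. Only the
        quadratic ramp segment is iterative; linear-segment arithmetic is
        exact.
    horizon_factor : float
        Raise :class:`ElutionTimeoutError` if migration exceeds
        ``horizon_factor * (tD + tg)`` after the dead time.
    """
    if not tol > 0.0:
        raise ValueError(f"tol must be > 0, got {tol}")
    log_ki = m.log_k(g.Ci)
    k_i = 10.0**log_ki if log_ki < 300.0 else math.inf
    horizon = horizon_factor * (g.tD + g.tg)

    # Dwell segment: inlet composition held at Ci for tD.
    if math.isfinite(k_i) and g.t0 * k_i <= g.tD:
        return RetentionPrediction(g.t0 * (1.0 + k_i), ElutionRegime.PRE_GRADIENT)
    consumed_dwell = g.tD / k_i if math.isfinite(k_i) else 0.0
    t_rem = g.t0 - consumed_dwell  # remaining migration integral, target units: min

    if m.is_linear:
        tau_ramp, ramp_total = _linear_ramp(m, g, log_ki, t_rem)
    else:
        tau_ramp, ramp_total = _quadratic_ramp(m, g, t_rem, tol)
    if tau_ramp is not None:
        tr = g.t0 + g.tD + tau_ramp
        if tr - g.t0 > horizon:
            raise ElutionTimeoutError(f"no elution within {horizon:g} min after t0")
        return RetentionPrediction(tr, ElutionRegime.IN_GRADIENT)

    # Post-gradient: finish isocratically at Cf.
    log_kf = m.log_k(g.Cf)
    k_f = 10.0**log_kf
    tau_hold = (t_rem - ramp_total) * k_f
    tau = g.tD + g.tg + tau_hold
    if tau > horizon:
        raise ElutionTimeoutError(
            f"solute still retained {tau:g} min after t0 (horizon {horizon:g} min); "
            "it is effectively not eluting under this program"
        )
    return RetentionPrediction(g.t0 + tau, ElutionRegime.POST_GRADIENT)


def _linear_ramp(
    m: RetentionModel, g: GradientProgram, log_ki: float, t_rem: float
) -> tuple[float | None, float]:
    """Closed-form ramp segment for the log-linear model.

    Returns ``(tau_on_ramp, full_ramp_integral)``; tau is None when the
    solute survives the whole ramp.
    """
    dC = g.delta_c()
    if m.s1 == 0.0:
        # Composition-independent retention: isocratic everywhere.
        k = 10.0**log_ki if log_ki < 300.0 else math.inf
        ramp_total = g.tg / k
        if ramp_total >= t_rem:
            return t_rem * k, ramp_total
        return None, ramp_total
    b = m.s1 * normalized_slope(g)
    # Full-ramp integral: (t0/(b*ln10)) * (1/kf - 1/ki).
    log_kf = m.log_k(g.Cf)
    inv_kf = 10.0**-log_kf if log_kf > -300.0 else math.inf
    inv_ki = 10.0**-log_ki if log_ki > -300.0 else math.inf
    ramp_total = (g.t0 / (b * LN10)) * (inv_kf - inv_ki)
    if ramp_total >= t_rem:
        # Solve (t0/(b*ln10*ki)) * (10**(b*tau/t0) - 1) = t_rem for tau.
        x_log = math.log10(t_rem * b * LN10 / g.t0) + log_ki
        if x_log > 15.0:
            log_arg = x_log
        else:
            log_arg = math.log10(1.0 + 10.0**x_log)
        return (g.t0 / b) * log_arg, ramp_total
    return None, ramp_total


def _quadratic_ramp(
    m: RetentionModel, g: GradientProgram, t_rem: float, tol: float
) -> tuple[float | None, float]:
    """Quadrature + root-solve ramp segment for the quadratic model."""
    dC = g.delta_c()

    def inv_k(t: float) -> float:
        return 10.0 ** -m.log_k(g.Ci + dC * t / g.tg)

    def cum(tau: float) -> float:
        val, _ = quad(inv_k, 0.0, tau, epsabs=1e-14, epsrel=1e-11, limit=200)
        return val

    ramp_total = cum(g.tg)
    if ramp_total >= t_rem:
        tau = brentq(lambda t: cum(t) - t_rem, 0.0, g.tg, xtol=min(tol, 1e-9), maxiter=200)
        return tau, ramp_total
    return None, ramp_total


def generate_run_series(
    m: RetentionModel,
    series: GradientSeries,
    noise_sd: float = 0.0,
    seed: int | None = None,
    compound_id: str = "sim",
    tol: float = 1e-9,
) -> list[RunObservation]:
    """Simulate one compound's scouting runs over a gradient-time series.

    Retention times come from the integration oracle, plus additive Gaussian
    noise of standard deviation ``noise_sd`` minutes (0 = exact). The same
    seed reproduces the same table bit for bit.
    """
    if noise_sd < 0.0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    runs = []
    for g in series.programs():
        tr = oracle_retention_time(m, g, tol=tol).tr
        if noise_sd > 0.0:
            tr += rng.normal(0.0, noise_sd)
        runs.append(RunObservation(program=g, tr_obs=tr, compound_id=compound_id))
    return runs


@dataclass(frozen=True)
class CompoundPreset:
    """Sampling ranges emulating one compound class on a typical instrument.

    Windows and dead/dwell times approximate common short-column UHPLC
    setups; S ranges follow the characteristic scales of each class and the
    log ki ranges are placed around the 2.1 applicability cutoff (entirely
    above it for proteins, whose on-off retention makes ki enormous at any
    reasonable starting composition).
    """

    name: str
    s_range: tuple[float, float]
    log_ki_range: tuple[float, float]
    Ci: float
    Cf: float
    t0: float
    tD: float
    b_targets: tuple[float, ...]

    def series_for(self, S: float) -> GradientSeries:
        """Gradient-time series hitting this preset's b targets for slope S."""
        b_desc = tuple(sorted(self.b_targets, reverse=True))
        return GradientSeries.from_b_targets(S, self.Ci, self.Cf, self.t0, self.tD, b_desc)


PRESETS: dict[str, CompoundPreset] = {
    "small_molecule": CompoundPreset(
        name="small_molecule",
        s_range=(3.0, 12.0),
        log_ki_range=(1.0, 4.0),
        Ci=0.05,
        Cf=0.95,
        t0=0.21,
        tD=0.34,
        b_targets=(1.0, 0.5, 0.3, 0.2, 0.1, 0.05),
    ),
    "peptide": CompoundPreset(
        name="peptide",
        s_range=(15.0, 50.0),
        log_ki_range=(0.8, 6.0),
        Ci=0.05,
        Cf=0.50,
        t0=0.05,
        tD=0.08,
        b_targets=(1.0, 0.5, 0.3, 0.2, 0.1, 0.05),
    ),
    "protein": CompoundPreset(
        name="protein",
        s_range=(80.0, 300.0),
        log_ki_range=(2.5, 15.0),
        Ci=0.25,
        Cf=0.45,
        t0=0.42,
        tD=0.2,
        b_targets=(0.5, 0.3, 0.2, 0.1, 0.05),
    ),
}


def sample_compounds(
    preset: CompoundPreset,
    n: int,
    rng: np.random.Generator,
    curvature_range: tuple[float, float] | None = None,
) -> list[tuple[str, RetentionModel]]:
    """Draw ``n`` ground-truth compounds from a preset.

    S is uniform over the preset's range and log ki uniform over its range;
    log k0 follows from the preset's initial composition. With
    ``curvature_range`` a quadratic term s2 = c * s1 is added, c uniform over
    the range, keeping log ki at Ci fixed (mild, convex curvature of the
    retention model).
    """
    out = []
    for i in range(n):
        s1 = rng.uniform(*preset.s_range)
        log_ki = rng.uniform(*preset.log_ki_range)
        if curvature_range is None:
            s2 = 0.0
        else:
            s2 = rng.uniform(*curvature_range) * s1
        log_k0 = log_ki + s1 * preset.Ci - s2 * preset.Ci**2
        out.append((f"{preset.name}_{i:03d}", RetentionModel(log_k0=log_k0, s1=s1, s2=s2)))
    return out


def linearity_experiment(
    m: RetentionModel,
    series: GradientSeries,
    fit_runs: tuple[int, int],
    eval_runs: Sequence[int],
    n_plates: float,
    methods: Sequence[str] = ("regression", "exact"),
) -> pd.DataFrame:
    """Fit on two designated gradients, score predictions on the others.

    Simulates noiseless runs for every gradient time in ``series``, fits the
    regression and/or exact two-run estimator on the ``fit_runs`` pair, and
    returns per-evaluated-gradient prediction errors (lambda and Error%),
    each labeled interpolation or extrapolation relative to the fitted
    gradient-time range. This is the standard check of retention-model
    linearity: a truly log-linear compound predicts equally well inside and
    outside the fitted range, a curved one degrades under extrapolation.
    """
    runs = generate_run_series(m, series, noise_sd=0.0)
    i1, i2 = fit_runs
    if i1 == i2:
        raise ValueError("fit_runs must be two distinct indices")
    fit_pair = [runs[i1], runs[i2]]
    tg_lo = min(fit_pair[0].program.tg, fit_pair[1].program.tg)
    tg_hi = max(fit_pair[0].program.tg, fit_pair[1].program.tg)
    X_fit, y_fit = runs_to_Xy(fit_pair)

    estimators = {}
    if "regression" in methods:
        estimators["regression"] = LSSGradientRegressor().fit(X_fit, y_fit)
    if "exact" in methods:
        estimators["exact"] = LSSExactTwoRunRegressor().fit(X_fit, y_fit)
    if not estimators:
        raise ValueError(f"unknown methods {methods!r}")

    records = []
    for method, est in estimators.items():
        for idx in eval_runs:
            run = runs[idx]
            tg = run.program.tg
            kind = "interpolation" if tg_lo < tg < tg_hi else "extrapolation"
            a = assess_prediction(est.params_, run.program, run.tr_obs, n_plates)
            records.append(
                {
                    "method": method,
                    "run_index": idx,
                    "tg_min": tg,
                    "kind": kind,
                    "tr_obs": run.tr_obs,
                    "tr_pred": a.tr_pred,
                    "lam": a.lam,
                    "error_percent": a.error_percent,
                    "regime": a.regime.value,
                }
            )
    return pd.DataFrame.from_records(records)
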