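"""Closed-form algebra of linear-solvent-strength (LSS) gradient elution.

Under the LSS model the isocratic retention factor of a solute is
log10 k = log10 k0 - S*C, where C is the organic-modifier volume fraction,
k0 the retention factor extrapolated to pure water, and S the solvent-strength
parameter. A linear gradient is described by its start/end compositions
(Ci, Cf), gradient time tg, column dead time t0, and instrument dwell time tD
(the delay before the programmed gradient reaches the column inlet).

Everything here is exact arithmetic on that model: the normalized gradient
slope s* = t0*(Cf-Ci)/tg, the steepness b = S*s*, the retention factor at
elution, the dwell-corrected retention-time prediction, and the inversion of a
measured retention time to the composition at elution. Compositions are
dimensionless fractions in [0, 1]; times are minutes. The factor commonly
printed as 2.3 or 2.303 in chromatography texts is ln(10) exactly.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "LN10",
    "GradientProgram",
    "LSSParameters",
    "ElutionRegime",
    "ElutionComposition",
    "RetentionPrediction",
    "normalized_slope",
    "steepness",
    "retention_factor",
    "log_retention_factor_initial",
    "retention_factor_at_elution",
    "elution_composition",
    "predict_retention_time",
    "delta_ce",
]

LN10 = math.log(10.0)

# Above this log10 ki the "+1" and dwell terms inside the retention-time
# logarithm are below double precision; switch to the log-space asymptote
# to stay finite for on-off retained proteins (log ki can exceed 300/S*C).
_LOG_KI_ASYMPTOTIC = 15.0


class ElutionRegime(enum.Enum):
    """Where along the gradient program a solute left the column.

    ``PRE_GRADIENT``: eluted isocratically at Ci before the gradient front
    arrived at the column inlet. ``IN_GRADIENT``: eluted on the ramp (the
    closed-form prediction applies). ``POST_GRADIENT``: still on the column
    when the ramp ended; finishes isocratically at Cf.
    """

    PRE_GRADIENT = "pre_gradient"
    IN_GRADIENT = "in_gradient"
    POST_GRADIENT = "post_gradient"


@dataclass(frozen=True)
class GradientProgram:
    """One linear gradient's geometry and instrument offsets.

    Parameters
    ----------
    Ci, Cf : float
        Organic volume fraction at gradient start/end, 0 <= Ci < Cf <= 1.
    tg : float
        Gradient time in minutes, > 0.
    t0 : float
        Column dead time in minutes (dead volume / flow rate), > 0.
    tD : float
        Instrument dwell time in minutes (dwell volume / flow rate), >= 0.
    """

    Ci: float
    Cf: float
    tg: float
    t0: float
    tD: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.Ci < self.Cf <= 1.0):
            raise ValueError(
                f"need 0 <= Ci < Cf <= 1, got Ci={self.Ci}, Cf={self.Cf}"
            )
        if not self.tg > 0.0:
            raise ValueError(f"gradient time tg must be > 0, got {self.tg}")
        if not self.t0 > 0.0:
            raise ValueError(f"dead time t0 must be > 0, got {self.t0}")
        if self.tD < 0.0:
            raise ValueError(f"dwell time tD must be >= 0, got {self.tD}")

    @classmethod
    def from_volumes(
        cls,
        Ci: float,
        Cf: float,
        tg: float,
        V0_ml: float,
        VD_ml: float,
        flow_ml_min: float,
    ) -> "GradientProgram":
        """Build from column dead volume, dwell volume (ml) and flow (ml/min)."""
        if flow_ml_min <= 0.0:
            raise ValueError(f"flow must be > 0 ml/min, got {flow_ml_min}")
        return cls(Ci=Ci, Cf=Cf, tg=tg, t0=V0_ml / flow_ml_min, tD=VD_ml / flow_ml_min)

    def delta_c(self) -> float:
        """Composition span Cf - Ci of the ramp."""
        return self.Cf - self.Ci

    def with_tg(self, tg: float) -> "GradientProgram":
        """Same window and instrument offsets, different gradient time."""
        return GradientProgram(self.Ci, self.Cf, tg, self.t0, self.tD)

    def ramp_end(self) -> float:
        """Time (min after injection) at which the ramp finishes at the inlet."""
        return self.t0 + self.tD + self.tg


@dataclass(frozen=True)
class LSSParameters:
    """A compound's linear retention model: log10 k(C) = log_k0 - S*C.

    ``S`` is the solvent-strength parameter (slope magnitude of log k vs C,
    per unit volume fraction; ~3-12 for small molecules, up to several hundred
    for intact proteins). ``log_k0`` is log10 of the retention factor
    extrapolated to pure water.
    """

    S: float
    log_k0: float

    def __post_init__(self) -> None:
        if not self.S > 0.0:
            raise ValueError(f"S must be > 0, got {self.S}")
        if not math.isfinite(self.log_k0):
            raise ValueError(f"log_k0 must be finite, got {self.log_k0}")


class ElutionComposition(NamedTuple):
    """Composition at elution plus a flag for whether it lies on the ramp."""

    value: float
    in_window: bool


class RetentionPrediction(NamedTuple):
    """Predicted retention time (min) and the regime that produced it."""

    tr: float
    regime: ElutionRegime


def normalized_slope(g: GradientProgram) -> float:
    """Normalized gradient slope s* = t0 * (Cf - Ci) / tg (dimensionless)."""
    return g.t0 * g.delta_c() / g.tg


def steepness(p: LSSParameters, g: GradientProgram) -> float:
    """LSS gradient steepness b = S * s*."""
    return p.S * normalized_slope(g)


def retention_factor(p: LSSParameters, C: float) -> float:
    """Isocratic retention factor k = 10**(log_k0 - S*C) at composition C."""
    if not 0.0 <= C <= 1.0:
        raise ValueError(f"composition must be in [0, 1], got {C}")
    return 10.0 ** (p.log_k0 - p.S * C)


def log_retention_factor_initial(p: LSSParameters, Ci: float) -> float:
    """log10 ki = log_k0 - S*Ci, the log retention factor at the gradient start."""
    return p.log_k0 - p.S * Ci


def retention_factor_at_elution(
    p: LSSParameters, g: GradientProgram, approximate: bool = False
) -> float:
    """Retention factor ke at the moment of elution under the gradient.

    Exact form: ke = 1 / (ln10 * b + 1/ki). With ``approximate=True`` the
    strongly-retained limit ke = 1 / (ln10 * b) is used (1/ki neglected),
    which always over-estimates the exact value for finite ki.
    """
    b = steepness(p, g)
    if approximate:
        return 1.0 / (LN10 * b)
    ki = retention_factor(p, g.Ci)
    return 1.0 / (LN10 * b + 1.0 / ki)


def elution_composition(g: GradientProgram, tr: float) -> ElutionComposition:
    """Invert a measured retention time to the composition at elution.

    Ce = Ci + (Cf - Ci)/tg * (tr - t0 - tD). Assumes the solute eluted on the
    ramp; when the resulting Ce falls outside [Ci, Cf] the value is still
    returned but flagged ``in_window=False`` (the solute eluted before the
    gradient front arrived or after the ramp ended, and the linear inversion
    does not apply to it).
    """
    if not tr > 0.0:
        raise ValueError(f"retention time must be > 0, got {tr}")
    ce = g.Ci + g.delta_c() / g.tg * (tr - g.t0 - g.tD)
    return ElutionComposition(ce, g.Ci <= ce <= g.Cf)


def predict_retention_time(p: LSSParameters, g: GradientProgram) -> RetentionPrediction:
    """Predict the gradient retention time of a compound with known (S, log k0).

    On the ramp the dwell-corrected closed form applies:

        tr = (t0/b) * log10( ln10*ki*b*(1 - tD/(t0*ki)) + 1 ) + t0 + tD

    Two other regimes are handled explicitly rather than by extrapolating the
    formula: a weakly retained solute that traverses the column at Ci before
    the gradient front reaches the inlet elutes isocratically at
    tr = t0*(1 + ki); a solute still retained when the ramp ends completes its
    migration isocratically at Cf (piecewise migration-fraction balance).
    """
    b = steepness(p, g)
    log_ki = log_retention_factor_initial(p, g.Ci)

    # Pre-gradient: the solute's isocratic elution time t0*(1+ki) falls before
    # the gradient front arrives at t0 + tD, i.e. t0*ki <= tD.
    if log_ki < 300.0:  # 10**300 * t0 cannot be <= tD for any sane program
        ki = 10.0**log_ki
        if g.t0 * ki <= g.tD:
            return RetentionPrediction(g.t0 * (1.0 + ki), ElutionRegime.PRE_GRADIENT)
    else:
        ki = math.inf

    if log_ki <= _LOG_KI_ASYMPTOTIC:
        arg = LN10 * ki * b * (1.0 - g.tD / (g.t0 * ki)) + 1.0
        if arg <= 0.0:
            # The pre-gradient branch fires whenever t0*ki <= tD, which keeps
            # 1 - tD/(t0*ki) > 0 here; reaching this point is a logic error.
            raise AssertionError(
                "non-positive logarithm argument in gradient retention-time "
                f"prediction (arg={arg}); regime classification is inconsistent"
            )
        log_arg = math.log10(arg)
    else:
        # ln10*b*ki dominates both the dwell correction and the +1 term by
        # >= ~10 orders of magnitude; evaluate the logarithm asymptotically.
        log_arg = math.log10(LN10 * b) + log_ki

    tr = (g.t0 / b) * log_arg + g.t0 + g.tD
    if tr <= g.ramp_end():
        return RetentionPrediction(tr, ElutionRegime.IN_GRADIENT)

    # Post-gradient: migration fraction left over after dwell + full ramp is
    # completed isocratically at Cf with retention factor kf.
    log_kf = p.log_k0 - p.S * g.Cf
    kf = 10.0**log_kf
    frac_dwell = g.tD / (g.t0 * ki) if math.isfinite(ki) else 0.0
    # Ramp migration fraction: (1/kf - 1/ki) / (ln10 * b).
    frac_ramp = (1.0 / kf - (1.0 / ki if math.isfinite(ki) else 0.0)) / (LN10 * b)
    remaining = max(0.0, 1.0 - frac_dwell - frac_ramp)
    tr = g.ramp_end() + remaining * g.t0 * kf
    return RetentionPrediction(tr, ElutionRegime.POST_GRADIENT)


def delta_ce(p: LSSParameters, s1: float, s2: float) -> float:
    """Change in elution composition between two normalized slopes.

    delta_Ce = (1/S) * log10(s2/s1): how much later in the gradient (in
    composition units) a compound elutes when the gradient is made shallower.
    Tiny for proteins (on-off retention), large for small molecules.
    """
    if not (s1 > 0.0 and s2 > 0.0):
        raise ValueError(f"normalized slopes must be > 0, got {s1}, {s2}")
    return math.log10(s2 / s1) / p.S
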