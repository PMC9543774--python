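# Methods

## Retention model and gradient geometry

The package works with the linear-solvent-strength (LSS) description of
reversed-phase gradient elution. The isocratic retention factor of a solute
is log-linear in the organic-modifier volume fraction C:

    log10 k(C) = log10 k0 − S·C,   C ∈ [0, 1]

A gradient program is the tuple (Ci, Cf, tg, t0, tD): start and end
compositions of the linear ramp (fractions), gradient time, column dead
time, and instrument dwell time, all in minutes. Optional constructors
accept the dead volume V0 and dwell volume VD in ml together with the flow
rate. Compositions are stored internally as fractions; percent input is
converted at the I/O boundary behind an explicit unit flag, so no unit
ambiguity can reach the numerics. Derived quantities are the normalized
gradient slope s* = t0·(Cf−Ci)/tg and the steepness b = S·s*.

Assumptions inherited from the closed-form theory: the programmed gradient
reaches the column inlet undistorted after the dwell delay, retention
responds instantaneously to the local composition, and extra-column
broadening is ignored. Curved or multi-segment gradient programs and
temperature/flow effects on S are out of scope.

## Retention-time prediction and elution regimes

For a solute that elutes while the ramp is passing through the column, the
dwell-corrected retention time is

    tr = (t0/b)·log10( ln10·ki·b·(1 − tD/(t0·ki)) + 1 ) + t0 + tD

with ki = 10^(log10 k0 − S·Ci). The two constants conventionally printed as
2.3 and 2.303 in chromatography formulas are the same base-conversion
factor; both are implemented as ln(10) exactly, which shifts results by
under 0.15% relative to a literal-2.3 evaluation (quantified in the test
suite).

The closed form silently assumes on-ramp elution, so predictions are
classified into explicit regimes rather than extrapolated:

* **pre_gradient** — t0·ki ≤ tD: the solute finishes migrating at Ci before
  the gradient front arrives and elutes isocratically at tr = t0·(1+ki).
  Because this branch is checked first, the dwell-correction term inside the
  logarithm is always positive in the in-gradient branch.
* **in_gradient** — the closed form above, when it lands before the ramp end
  t0 + tD + tg.
* **post_gradient** — the solute is still on the column when the ramp ends;
  the remaining migration fraction (a piecewise balance over dwell and ramp
  segments) is completed isocratically at Cf.

For on-off retained proteins log10 ki can exceed the double-precision
exponent range. Above log10 ki = 15 the logarithm is evaluated
asymptotically as log10(ln10·b) + log10 ki (the neglected terms are below
1e−13 relative), keeping predictions finite for arbitrarily retained
compounds.

## Parameter estimation

**Regression treatment.** Each run's measured tr is inverted to the elution
composition Ce = Ci + (Cf−Ci)/tg·(tr−t0−tD), and Ce is regressed on
log10 s* by unweighted ordinary least squares: S = 1/slope and
log10 k0 = S·intercept − log10(ln10·S). The linearity of Ce in log10 s*
rests on neglecting 1/ki against ln10·b in the retention factor at elution,
so the estimator is reliable only for strongly retained starts. The fitted
log10 ki is compared (inclusively) against a configurable cutoff of 2.1
(ki ≈ 125) for the `applicable` flag; the cutoff is the empirical rule below
which scouting-pair predictions exceed the λ = 0.5 acceptability line. Since
the true ki is unknown in real use, the flag is computed from the *fitted*
parameters, which are themselves biased when the assumption fails — the flag
is a warning, not a guarantee. For three or more runs the regression R² is
reported and compared against a linearity warning level (default 0.995, a
package choice — the R² values seen in practice range from ~0.96 for
visibly curved models to >0.9998 for linear ones, and the threshold is fully
configurable); a two-point fit has no residual degrees of freedom, so R² is
reported as undefined rather than 1.

**Exact two-run solver.** The conventional determination used by HPLC
modeling software: with exactly two runs, log10 ki is eliminated by
inverting the first run's retention-time equation in closed form at a trial
S (computed in log space when the exponent exceeds 30), and the second run's
predicted time is matched by bracketed one-dimensional root finding in S
(default bracket 0.5–2000, covering small molecules to mAbs; a sign-change
scan over a 120-point geometric grid precedes Brent's method at xtol 1e−13).
Both equations' residuals must close to below 1e−8 min or the fit is
rejected. Observations whose implied elution composition falls outside
[Ci, Cf] are rejected with a regime error: the solute did not elute on the
ramp and neither treatment applies to it.

Both estimators are scikit-learn compatible (rows of X are gradient
programs in the column order Ci, Cf, tg_min, t0_min, tD_min; y is tr in
minutes), with thin functional wrappers for the run-observation API.

## Error metrics

Error% = 100·(tr_pred − tr_exp)/tr_exp is reported signed, with the
conventional 2% bound applied to its magnitude. The resolution-based
statistic λ = |Δtr|/w uses the 4σ gradient peak width
w = (4·t0/√N)·(1+ln10·b)/(ln10·b). N is the column's best-case (van Deemter
minimum) plate number and is a required input with no default — it is an
instrument/column property the package cannot guess, and every λ report
echoes the N used. The two normalized scores λ/0.5 and |Error%|/2 coincide
exactly for an isocratic reference peak of width 4·tr/√N, which anchors the
2%-error ↔ 0.5-resolution correspondence at N = 10,000. For large proteins
the actual plate number at practical flow rates is far below the van
Deemter minimum, so λ computed this way is an upper bound on the true
resolution error; no correction is applied and reports should be read with
that in mind.

## Simulator and oracle

The oracle integrates the fundamental gradient-elution balance
∫0^τ dt / k(C_in(t)) = t0 piecewise over the dwell (constant Ci), ramp
(linear C), and hold (constant Cf) segments, and returns tr = t0 + τ with
the regime the solution landed in. For the log-linear model every segment
integral is closed-form, so the oracle is an independent re-derivation of
the prediction equations rather than a re-implementation of them; agreement
to better than 1e−4 min over randomized compounds and gradients in all
three regimes is part of the acceptance suite. For the quadratic truth
model log10 k = log10 k0 − s1·C + s2·C² (the standard form; used only as
simulation ground truth, never fitted) the ramp segment uses adaptive
quadrature (epsrel 1e−11) inside a bracketed root solve with xtol equal to
the requested time tolerance (default 1e−6 min, 1e−9 in test fixtures).
Solutes whose migration exceeds a configurable horizon (default 100·(tD+tg)
past the dead time) raise an elution-timeout error — such draws correspond
to compounds that would simply never be observed to elute.

Run generation adds optional Gaussian noise (sd in minutes, default 0) to
the oracle times under a caller-supplied seed; identical seeds reproduce
tables bit for bit.

**Presets.** Three compound classes sketch the standard scouting design on
typical short-column UHPLC setups:

| class | S range | log10 ki range | window Ci–Cf | t0 (min) | tD (min) | b targets |
|---|---|---|---|---|---|---|
| small_molecule | 3–12 | 1.0–4.0 | 0.05–0.95 | 0.21 | 0.34 | 1, 0.5, 0.3, 0.2, 0.1, 0.05 |
| peptide | 15–50 | 0.8–6.0 | 0.05–0.50 | 0.05 | 0.08 | 1, 0.5, 0.3, 0.2, 0.1, 0.05 |
| protein | 80–300 | 2.5–15 | 0.25–0.45 | 0.42 | 0.2 | 0.5, 0.3, 0.2, 0.1, 0.05 |

Dead and dwell times follow reported dead/dwell volumes and flow rates of
representative instruments (a 50×2.1 mm column at 0.5 ml/min with a 0.17 ml
dwell volume for small molecules; the same column at 2.1 ml/min for
peptides; a 100×2.1 mm column at 0.5 ml/min with a 0.1 ml dwell volume for
proteins). S ranges follow the characteristic scales of each class; log10 ki
ranges straddle the 2.1 cutoff for small molecules and peptides and sit
entirely above it for proteins (on-off retention). Gradient-time series are
built per compound from target b values, so the fastest/slowest pair spans
the conventional b ≈ 1 → 0.05 range with a 5:1 time ratio between the two
scouting runs (b = 0.5 and 0.1) and 10:1 between the fastest and slowest
scouting-relevant pair.

What the simulator does **not** emulate: peak shapes and widths (widths come
from the plate-number formula, not from simulated signals), gradient
deformation in the column, extra-column volumes, detector noise, or
adsorption/mixed-mode/Neue-Kuss retention. Passing tests therefore
demonstrate the self-consistency and numerical correctness of the method
under its own model assumptions — with model misfit probed only through the
quadratic truth — not its accuracy on any particular real instrument.

## Study designs used in the validation suite

* **Parameter recovery**: 200 random compounds, S uniform on [3, 300] and
  log10 ki uniform on [4, 25], noiseless 5-gradient series with b from 1 to
  0.05 on a wide 5–95% window. Draws whose elution falls off the ramp for
  any gradient in the series are rejected and resampled: such (S, ki)
  combinations cannot be measured with the window at all (e.g. a compound
  with S = 3 and log10 ki ≥ 4 is still strongly retained in pure organic),
  so they lie outside the method's precondition rather than inside its error
  budget. Recovery is required to 0.5% relative on both parameters.
* **Exact-solver inversion**: randomized (S, log10 ki) with log10 ki capped
  by the window capacity, plus fixed cases at log10 ki = 0.5–2.0, inverted
  to 1e−6 relative.
* **Cutoff sweep**: S fixed at 20 on the peptide-class instrument, scouting
  pair b = 0.5/0.1, prediction scored on the shallower scouting run at
  N = 10,000, log10 ki swept from 4 to 0.5. This mirrors the standard
  applicability experiment: the resolution error crosses the 0.5 line
  almost exactly at the log10 ki = 2.1 cutoff.
* **Linearity/curvature**: quadratic truth with relative curvature
  s2/s1 uniform on [0.05, 0.3] (mild, convex — strong enough to probe
  extrapolation without driving scouting runs off the ramp), exact two-run
  fit on the b = 0.5/0.1 pair, interpolated (b = 0.3, 0.2) vs extrapolated
  (b = 1, 0.05) predictions over 50 seeded compounds.

All randomized suites are seeded and run in seconds; the problem sizes above
are the defaults the package itself validates against.

## Known limitation: dwell time breaks λ-monotonicity at very low ki

The resolution error of the regression treatment grows monotonically as
log10 ki falls on a dwell-free system (this is asserted as a property test),
because the only error source is the neglected 1/ki term. With a real dwell
delay the picture changes at the extreme low end: once t0·ki approaches tD,
a large fraction of the migration happens before the gradient arrives, and
in the limit of pre-gradient elution both the observed and the predicted
retention times converge to the same isocratic value — so λ must turn over
and fall back toward zero. On the peptide-class instrument (tD/t0 ≈ 1.6)
this reversal sets in below log10 ki ≈ 0.75, well below the 2.1
applicability cutoff but inside a sweep that extends to 0.5. The dwell-free
idealization is monotone everywhere but shifts the λ = 0.5 crossing
slightly above 2.1; the dwell-bearing instrument reproduces the 2.1 rule
but is non-monotone at the bottom of the sweep. Monotonicity of λ in ki is
therefore not treated as a universal invariant of the method, only of its
dwell-free idealization.
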