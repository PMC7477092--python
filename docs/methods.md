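# Methods

This note documents the models behind `leafdyn`, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and
the numerical decisions that a user extending the package should know.

## Demand model and constants

Net assimilation follows the three-limitation FvCB structure with gross
rates Ac (Rubisco), Aj (RuBP regeneration) and Ap = 3·TPU (triose-phosphate
export), and A = min(Ac, Aj, Ap) − Rd. All measurements the package targets
are at 25 °C and a single measuring irradiance, so no temperature response
is implemented and the electron-transport parameter is the rate at the
measuring irradiance (J1500), fitted directly rather than through a light
response. Kinetic constants default to the standard 25 °C set in partial
pressure units — Kc = 404.9 µbar, Ko = 278.4 mbar, Γ* = 42.75 µbar,
O = 210 mbar — and every one of them is overridable.

Regime membership during fitting is the plain minimum of the three
hypotheses at each point (no smooth minimum), with ties broken toward
Rubisco, then RuBP; this is deterministic and matches how the classic
spreadsheet fitters assign limitation states. The optimizer is multi-start
trust-region least squares from a fixed 3×3×3 grid
(Vcmax ∈ {50,100,150} × J ∈ {100,175,250} × TPU ∈ {5,10,15}); it contains
no randomness, so a fitted result is exactly reproducible. A parameter
whose regime is absent from the fitted curve is *unidentifiable*: the fit
flags it and warns instead of silently returning an arbitrary bound value.
Parameter-recovery studies therefore co-sample (Vcmax, J, TPU) so that all
three regimes are expressed on the curve (`sample_identifiable_fvcb`);
a recovery claim is meaningless for a curve that never visits a regime.

## Supply side

The CO2 supply law is A = (Ca − Ci)/rt with rt = 1.6/gs by default
(`aci_with_supply`), gs being conductance to water vapour. The simulator's
presets additionally include a boundary-layer term rt = 1.6/gs + 1.37/gb
with gb = 1.4 mol m⁻² s⁻¹, a typical value for a small clamp-on
fluorescence chamber. The finite gb matters: the measured steady-state
(A, gs, Ci) triples that anchor the presets are mutually consistent to
about 2 % only once the boundary layer is included, while the pure
stomatal law misplaces Ci by 6–8 %. The intersection of supply and demand
is found by bracketed Brent root finding on Ci ∈ (Γ*, Ca] (extended above
Ca when demand is negative, i.e. a respiring leaf), with residuals below
10⁻⁸ µmol m⁻² s⁻¹.

## Fluorescence and calibration

Fo′ is always the Oxborough–Baker estimate Fo/(Fv/Fm + Fo/Fm′) — the
targeted studies compute rather than measure it — which makes the identity
ΦPSII = qP · Fv′/Fm′ algebraically exact; the test suite enforces it to
10⁻⁹ relative.

The calibration of Rd, s and Γ* is a two-step regression:

1. under non-photorespiratory conditions (2 % O2, Ca ≈ 2000 µbar) and
   strictly light-limited irradiance (PAR ≤ 200 µmol m⁻² s⁻¹ by default),
   A is affine in PAR·ΦPSII/4 with slope s and intercept −Rd;
2. Γ* then minimizes the squared residual of the RuBP-limited expression
   over the low-Ci points (Ci ≤ 200 µbar by default) of the 21 % O2 A/Ci
   curve, with per-point J = s·PAR·ΦPSII, searched on [10, 100] µbar.

Step 2 runs on Ci, not chloroplastic Cc, so the result is the *apparent*
compensation point. With a finite mesophyll conductance it is biased
upward — on the synthetic wildtype leaf (gm = 0.4 mol m⁻² s⁻¹) the
apparent value is ≈ 49 µbar against a true 42.75, about +15 %. The bias is
systematic, grows with A/gm, and propagates strongly into the variable-J
gm estimate (which needs Γ* at the chloroplast): feeding the apparent Γ*
into the Harley expression at the standard operating point roughly doubles
gm. The package therefore keeps the two routes explicit: calibration
reports the apparent Γ*, and gm recovery is exact (to 10⁻⁸) when the
chloroplastic Γ* is supplied. A misspecified Rd shifts the apparent Γ* in
the opposite direction (overstated Rd → smaller Γ*); the sensitivity test
pins the sign and magnitude of both effects.

Whether the ΦPSII → J conversion should also correct for alternative
electron sinks is deliberately left inside s: s is a per-leaf lumped
factor and absorbs absorptance, PSII fraction and sink corrections by
construction.

## Variable-J mesophyll conductance

gm = A/(Ci − Cc(J)) with Cc(J) = Γ*(J + 8(A+Rd))/(J − 4(A+Rd)). Points
within 5 % (relative, configurable) of the J = 4(A+Rd) singularity are
flagged unreliable; a computed Cc outside (Γ*, Ci) flags the sample invalid
rather than raising, and batch processing always returns one result per
input row so nothing is dropped silently. The irradiance at which the gm
inputs are taken is an argument (default 1500 µmol m⁻² s⁻¹), not a
constant, because published protocols disagree between 1000 and 1500.

## Induction metrics

Ai and Af are window means, by default the 5 min before the step and
minutes 55–60 (the long transients need 40–60 min to settle); both windows
are configurable and the shorter simulated runs in the tests use the last
five minutes of their duration. Crossing times t50/t90 are first upward
crossings of the rolling-median-smoothed PI (width 5 samples ≈ 10 s at the
2-s logging cadence), linearly interpolated between bracketing samples.
First-crossing semantics mean a transient dip followed by re-crossing
cannot inflate the metrics; the dip is characterized separately as the
maximum peak-to-trough drawdown of smoothed A within 0.5–4 min after the
step, reported present above a 0.5 µmol m⁻² s⁻¹ threshold. Five-minute
integrals are trapezoidal and reported in field-units·min. The Ag-vs-J
relation is summarized by an OLS quadratic; "upwards curvature" is a
significantly positive quadratic coefficient (95 % CI excluding zero).

## Synthetic generator

What it emulates: exponential stomatal opening with a 1-min lag
(τ_gs = 6 min for both genotypes — their measured stomatal opening
amplitudes match, so a shared time constant is the fewest-assumptions
choice); exponential activation of Vcmax (τ_R = 4 min from an initial
fraction 0.3) and of RuBP-regeneration capacity (τ_J = 1.5 min from 0.5),
generic magnitudes from the induction literature since the target study
reports none — all simulator kinetics are declared assumptions, never
measured values; a non-rectangular-hyperbola light response
(α = 0.375, θ = 0.7) anchored at J(1500) = J1500, with partial activation
scaling the asymptote rather than the quantum slope; per-step exact
supply–demand intersection; fluorescence inverted from the demand model so
that gas exchange and ΦPSII are mutually consistent, with a
phenomenological NPQ trajectory (fast rise, partial relaxation, slow
rise); saturating flashes scheduled once per minute for the first ten
minutes and every two minutes after, plus one pre-step flash; Gaussian
noise per channel (σ_A = 0.3 µmol m⁻² s⁻¹, σ_gs = 0.01 mol m⁻² s⁻¹,
0.5 % on fluorescence counts), with Ci recomputed from the noisy A and gs
through the supply law the way the instrument derives it.

Preset anchors: the gs endpoints, chamber CO2 and VPD of the six
genotype × treatment presets reproduce the measured steady-state table of
the flacca/wildtype study; biochemistry (Vcmax = 140, J1500 = 175,
TPU = 11 µmol m⁻² s⁻¹, gm = 0.4 mol m⁻² s⁻¹) is shared between genotypes
because their A/Ci responses are statistically indistinguishable, with
Rd = 1.2 (WT) and 1.5 (flacca) µmol m⁻² s⁻¹ — day respiration below the
measured dark effluxes of 1.2 and 1.9. α and s (= 0.455) were set so the
shade steady state matches the measured A ≈ 2 µmol m⁻² s⁻¹ at
50 µmol m⁻² s⁻¹ PAR while keeping the implied ΦPSII below Fv′/Fm′
(qP ≤ 1). VPD enters only through the preset gs endpoints, not the demand
model. The transient TPU-depression dip is off by default and can be
switched on to exercise dip detection mechanistically.

What it does not emulate — and hence what passing tests do not show about
real data: leaf energy balance (leaf temperature is implicitly constant),
guard-cell mechanics and ABA signalling (stomata follow a prescribed
exponential), patchy stomatal closure, chloroplast movement, slow NPQ
components coupled back onto assimilation (NPQ is cosmetic for the gas
exchange), instrument drift and matching errors. The simulated t50/t90
magnitudes (≈ 1 and 5–8 min) and their genotype ratios are therefore
model-scale quantities: the qualitative orderings (flacca faster under
control and high VPD, no genotype difference under low CO2, WUEi roughly
1.6× higher in the wildtype, larger five-minute ∫A and ∫Ci in flacca) are
the reproducible content, not the absolute minutes. Likewise the
t90-vs-initial-gs relation is threshold-like but retains a mild slope above
0.4 mol m⁻² s⁻¹ because higher gs still raises Cc slightly during the
activation-limited phase.

## Problem sizes and numerics

Simulations run at the instrument's 2-s cadence for 60 min plus a 5-min
baseline (≈ 1950 supply–demand solves per transient, ~70 ms). Replicate
studies in the tests and the acceptance script use 50–200 simulations or
fits per claim, sized to finish in seconds to a couple of minutes on one
CPU while leaving the Monte-Carlo error far below the asserted margins.
Root finding uses Brent's method at xtol 10⁻¹⁰; the bounded Γ* search uses
xatol 10⁻¹⁰; least-squares tolerances are 10⁻¹². CSV round trips are exact
because floats are written in shortest-roundtrip form and parsed with the
round-trip parser.

## Known limitations

* The apparent-Γ* bias means the fully automated calibrate → variable-J
  chain overestimates gm at realistic mesophyll conductances; an unbiased
  chain needs an independent (e.g. isotopic or curvature-based) Γ*, which
  is out of scope.
* TPU is represented as a hard plateau; the declining-A region seen above
  the optimum Ci in real curves is not modelled.
* The dip detector is tuned for the 2-s cadence; at coarser logging the
  0.5–4 min window may contain too few samples for the default smoothing.
* Leak correction defaults to k_leak = 0 because no instrument coefficient
  is published for the target protocol; users should supply their
  chamber's value.
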