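# Methods

This note documents the modeling conventions, estimation procedure,
synthetic-data generator and numerical choices behind `glufa`, and what
the test suite does and does not demonstrate.

## Models and conventions

Three model variants share one framing: measured plasma insulin is an
exogenous input, interpolated piecewise-linearly between samples and
clamped to the first/last sample outside the record (delayed lookups
I(t − delay) therefore always have a defined value). Glucose is in
mg/dL, insulin in µU/mL, FFA in mmol/L (the assay unit is not critical;
only Ra magnitudes scale with it), time in minutes.

* **MOD 1** (glucose + action + FFA): glucose follows the Bergman
  minimal model; the remote action compartment X relaxes toward
  I(t) − I_bx at rate C_x; lipolysis is l_0 plus a Hill-suppressed l_2
  term in X; clearance is insulin-stimulated, C_f·(1 + h/(1+h)) with
  h = (X/K_Cl)^A_Cl, i.e. bounded between C_f and 2·C_f.
* **MOD 2**: same glucose/X block; constant clearance C_f0; lipolysis
  Hill exponent A_l free.
* **MOD 3** (FFA only): insulin acts directly with delays t_DelayLip
  and t_DelayRem. The clearance term is taken in the standard
  saturating Hill form k_Rem + V_m_Rem·I^h/(K_Rem^h + I^h); the single
  half-activation constant K_Rem is used throughout.

I_bx is a *fitted* action threshold, not the measured basal insulin.
Consequently X(0) = 0 (the protocol convention) is generally not an
equilibrium: when basal insulin exceeds I_bx the model develops an
early insulin-action transient at the start of either test. This is a
structural feature of the convention, and it matters for Ra
back-calculation (below).

Hill terms clamp X (and I) at zero before exponentiation so transient
negative solver excursions cannot produce complex powers. Fixed-by-
convention parameters — A_lipo = A_Cl = 2 for MOD 1, and the FFA-Ra
constants t_0F = 60 min (chylomicron lag) and m_F = 300 min — are held
fixed by default and excluded from the free-parameter count k; they can
be overridden or freed through the fitting configuration.

Steady states are the X = 0, Ra = 0 fixed points: G* = G_b and
F* = (l_0 + l_2)/C_f (MOD 1), (l_0 + l_2)/C_f0 (MOD 2), or
V_m_Lip/k_Rem (MOD 3 at zero insulin).

## Protocols

* **FSIGT**: sampling at −10, −1, 0, 1, …, 8, 10, 12, …, 180 min;
  only the 10–180 min window is fitted. The initial state is the mean
  of the [0, 10) samples (times 0–8), and integration starts at t = 10,
  so the t = 10 sample is a fitted datum, not also the initial
  condition. The −10/−1 samples serve only basal summaries (AIRg). Meal
  Ra terms never apply to the FSIGT.
* **MT**: sampling every 30 min over 0–360 min, all fitted; the initial
  state is the t = 0 measurement; Ra terms apply according to the
  combination (C1 none; C2 Type I glucose + Type I FFA; C3 Type I
  glucose; C4 Type II glucose; S1 FSIGT only; S2/S3 MT only with
  Type I/Type II glucose Ra).

Integration uses a stiff-capable adaptive solver (LSODA) at rtol 1e-8 /
atol 1e-9 with output on a 1-min grid that contains every sample time,
so residual extraction and Ra back-calculation never re-interpolate.
Halving the tolerances moves sampled values by < 1e-6 relative.

## Variance estimation (rank-1 SSA)

The objective weights each (protocol, channel) by a variance estimated
from the raw data alone: embed the fitted-window series in a Hankel
trajectory matrix of window length L = ⌊n/2⌋ (the standard SSA choice;
configurable), keep only the leading singular triple, reconstruct by
anti-diagonal averaging, and take σ² as the plain mean of squared
deviations from that trend (per time point, no degrees-of-freedom
correction). A floor of (0.01 × channel mean)² prevents infinite
weights on noiseless synthetic data. One scalar per (protocol, channel)
pair is used, never per time point.

Limitation: a single singular triple tracks gently varying meal-test
channels well (recovering an injected 5% CV almost exactly) but cannot
follow the sharp FSIGT excursions, so FSIGT σ² estimates also absorb
unmodeled trend and are biased upward. Synthetic-recovery tests
therefore use unit weights (noiseless) or the generator's true noise
variances (noisy), keeping the SSA estimator itself under its own
dedicated tests.

## Fitting

The objective is Σ_p Σ_m Σ_t (y_data − y_model)²/σ²_{p,m} over the
active protocols and the glucose/FFA channels (insulin is input, never
a residual channel; MOD 3 contributes FFA only). For the full C3 fit of
MOD 1 this gives n = 2·21 + 2·13 = 68 residuals and k = 13 free
parameters.

Minimization uses scipy's bounded trust-region reflective least-squares
solver with ftol = xtol = gtol = 1e-10, from a configurable multi-start
set: by default the reference group means and their 0.5×/1.5×
scalings (optionally extra seeded log-normal jitters). Lower bounds are
0 (a tiny epsilon for strictly positive parameters such as Hill
half-effects and widths); upper bounds are 5× the reference means, with
insulin delays additionally capped by the protocol window. Parameters
are scaled by their reference magnitudes inside the solver.

Two numerical details matter:

* Finite-difference Jacobians use a relative step of 1e-4. The
  adaptive ODE solver makes the residuals noisy at the ~rtol level, so
  the default √ε steps produce derivative estimates dominated by solver
  noise and the optimizer stalls far from the optimum; the larger step
  restores clean convergence (noiseless synthetic fits reach objective
  ≲ 1e-12 and recover every generating parameter to ≪ 1%).
* Integration failures inside the objective return a large finite
  penalty (1e12) rather than raising, so the optimizer can back away
  from pathological parameter regions.

After the best start converges, each parameter is profiled at ±10%; a
parameter whose objective change stays below 1e-6 is flagged as flat
(possibly unidentifiable) in the result rather than silently reported.
Fits are deterministic given the configuration and seed.

## Ra back-calculation

Meal glucose Ra is recovered pointwise from
Ra(t) = dG/dt − S_G·G_b + (S_G + S_I·X)·G, with G and dG/dt from a
natural cubic spline of the 13 MT samples on the 1-min grid and X from
a model simulation. The derivative is the spline's analytic derivative,
not a finite difference, and no positivity constraint is applied —
negative stretches are reported as computed.

Accuracy, measured on the closed loop (simulate a known Type I Ra,
sample, back-calculate): the AUC over the MT window is recovered to
≪ 1%, and for t ≥ 30 min the pointwise error stays within ~14% of the
Ra peak. Within the first sampling interval the recovery is poor (error
up to ~30% of peak at t = 0): the insulin-action transient created by
the X(0) = 0 convention gives the true glucose curve a positive initial
slope followed by a dip, while the 0→30 min data secant is negative —
no interpolant of the sparse samples can see this, so the endpoint
derivative (and hence Ra near t = 0) is structurally wrong. This is the
same early-window spline artifact known for sparsely sampled meal
tests; no correction is applied.

## Synthetic subjects

The generator emulates the study conditions so every stage is testable
without real data:

* **Insulin input**: deterministic gamma-like pulses. FSIGT: basal
  10 µU/mL, endogenous first-phase peak +90 at 3 min, exogenous peak
  +60 starting at the 20-min bolus (≈10× basal overall); MT: monophasic
  +35 peaking at 40 min (≈4.5× basal), relaxed by 360 min. Values are
  realistic for nondiabetic women but are conventions, not data.
* **Glucose/FFA**: the fixture's model and combination are simulated
  with these inputs. MT starts from (G = 90 mg/dL, X = 0, F at the
  model's X = 0 fixed point); FSIGT integrates from t = 10 starting at
  (G = 250, X = 0, F basal), with the pre-window samples pinned to that
  state so the 0–10 min average used by the fitting convention
  reproduces it exactly, and pre-zero glucose at a fasting 90 mg/dL.
* **Noise**: independent multiplicative Gaussian noise of coefficient
  of variation `noise_cv` applied at sample times only (an additive
  option exists); the stored σ² are the true per-channel noise
  variances when noise is on, and 1 otherwise. Same seed ⇒ bit-identical
  subjects.

Fixtures are group-mean parameter sets per model and combination
(`AA-C3`, `WH-C4`, `AA-C2`, `AA-MOD2-C3`, `AA-MOD3-C1`); they double as
reference means for bounds and starts.

What passing recovery tests show: the estimation machinery finds the
generating parameters of self-consistent, protocol-faithful data, and
the S_I estimate degrades gracefully under 5% assay noise (median
relative error ≈18% across 20 replicates). What they do not show:
robustness to model misspecification, to the multiphasic glucose
responses seen in some subjects, to correlated assay errors, or to the
real (unknown) identifiability profile of clinical data.

## Model comparison and indices

BIC is computed as objective + k·ln(n), treating the weighted objective
as a Gaussian deviance with known variances (a documented convention —
with externally fixed σ² the objective is the deviance up to an
additive constant). RMSE is reported per (protocol, channel) as the
root mean square of variance-normalized residuals, so the objective
decomposes as Σ n_{p,m}·RMSE²_{p,m}. AIRg is the trapezoidal insulin
AUC above basal over 0–10 min of the FSIGT, with basal the mean of the
−10/−1 min samples; DI = AIRg × S_I.

## Problem sizes and determinism

Default experiment sizes used by the tests and the acceptance script:
one noiseless recovery fit per fixture (single 1.5× start), a
20-replicate noise study at CV 5%, 200-draw Monte-Carlo checks for the
SSA and noise-calibration estimators. All randomness flows through
explicit integer seeds; noiseless paths are fully deterministic.
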