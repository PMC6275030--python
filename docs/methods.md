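# Methods

## The model and its assumptions

Two subcutaneous tumors grow in contralateral flanks of one host (primary
implanted on Day 0, secondary on Day 2). Each site carries four interacting
populations: viable tumor volume *C* (mm³), non-immunogenically dying volume
*D*, immunogenically dying volume *I*, and effector-cell (activated CD8⁺
CTL) density *E* (cells/mm³). Measured tumor volume is *V = C + D + I*;
effector cells are assumed not to contribute measurable volume.

Viable tissue grows logistically toward a shared carrying capacity and is
killed by effector cells by mass action (`a C E`). Crowding losses
(`r C V/K`) and immune kills are non-immunogenic: they enter *D* and clear
at rate `d`. Radiation is the *only* source of the immunogenic compartment
*I* (also cleared at `d`): each fraction instantaneously rescales the viable
compartment by the survival fraction `SF_D` and splits the killed volume
between immunogenic (`AI_D`) and non-immunogenic death. The impulse
conserves total volume exactly — caliper volume cannot jump at the moment
of irradiation.

Effector dynamics are written for the product *A = V·E*. Recruitment is
systemic: newly activated T cells extravasate at site *i* with probability
`p_i = V_i/(V1+V2)` (each site's share of total burden) and the
recruitment rate is proportional to total burden, amplified per site *j* by
immunogenic death (`1 + w2·I_j/V_j`) and globally by checkpoint blockade
(`1 + u(t)`). The blockade signal is the closed-form convolution of bolus
injections with first-order clearance, `u(t) = Σ_{t̄≤t} e·exp(−clr(t−t̄))`;
intraperitoneal absorption kinetics are deliberately omitted, so the model
is biased toward immunotherapy acting instantaneously at injection times.
Exhaustion removes effectors at rate `l`.

Assumptions worth keeping in mind: both sites share all rate constants
(same cell line, same host); there are exactly two sites; radiation targets
site 1 only; delivery time enters only through the protraction factor in
`SF_D`, not through the timeline (fractions are instantaneous impulses);
the model is deterministic and fits mean growth curves, not
animal-to-animal variability.

## Parameters

| name | meaning | unit | default |
|------|---------|------|---------|
| r | viable volumetric growth rate | 1/day | 0.195 |
| K | carrying capacity (per site) | mm³ | 1423.1 |
| a | CTL killing rate | mm³/(cell·day) | 0.0177 |
| d | clearance of dying tissue | 1/day | 0.264 |
| l | effector exhaustion rate | 1/day | 0.03 |
| w | baseline recruitment rate | cell/(mm³·day) | 0.135 |
| w2 | recruitment fold-change per unit I/V | – | 15.37 |
| e | recruitment fold-change per 9H10 bolus | – | 8.495 |
| clr | 9H10 clearance rate | 1/day | 0.967 |
| SF₆/SF₈/SF₂₀ | per-fraction survival at 6/8/20 Gy | – | 0.783 / 0.664 / 0.265 |
| AI₆/AI₈/AI₂₀ | immunogenic-death fraction | – | 0.367 / 0.984 / 0.194 |

The defaults are the calibrated values for the TSA murine breast-carcinoma
bilateral-tumor experiment the model was trained on. The non-monotone AI
values (maximal near 8 Gy) are the scientific crux: intermediate doses per
fraction are the most immunogenic.

Dose–response interpolation to untested doses uses
`SF(D) = exp(−αD − β·G(λT)·D²)` with `G(x) = 2(x + e^(−x) − 1)/x²`,
`T = D/dose_rate`, and `AI(D) = min((γ/D)·exp(−(ln D − μ)²/ρ), 1)`; default
curve parameters α = 2.8×10⁻⁸ /Gy, β = 0.0132 /Gy², λ = 2.0358 /min,
γ = 14.173 Gy, μ = 2.448, ρ = 0.232. Two unit conventions are implicit in
the printed λ and are resolved numerically: only delivery time measured in
minutes at 6 Gy/min (600 cGy/min) and a natural-log `ln D` in the AI curve
reproduce the tabulated SF/AI values from these curve parameters (e.g.
SF(20 Gy) = 0.2652, AI(20 Gy) = 0.1945), so those conventions are adopted.
At exactly 6, 8 and 20 Gy the calibrated table values are used verbatim;
the curves exist to interpolate doses that were never tested. Schedules at
equal biological effect are compared through `BED = nD(1 + D/θ)` with
θ = 20 Gy.

Note that re-fitting (α, β, λ) to the three tabulated SF values by
unweighted least squares drives α to zero and yields a slightly *lower*
SSE than the published curve parameters (residual 0.009 at 8 Gy vs 0.018
at 6 Gy for the published set); both fits are kept available — `fit_lq`
returns the least-squares optimum, `default_dose_response_model` the
published curve.

## Initial conditions

Only the Day-12 palpable volumes (32 and 21 mm³) are reported for treatment
start. The simulator back-solves pure logistic growth from those anchors to
the implantation days (closed form `V0 = K·Vp/(Vp + (K−Vp)e^{rΔt})`), with
*D = I = 0* and an initial effector density of 0 at implantation; the
secondary site is dormant (contributes nothing to trafficking or
recruitment) before Day 2. Every element is overridable through
`InitialConditionSpec`. This reconstruction uses only reported numbers, but
it is not unique, and the Day-32 burden of strongly responding
(hypofractionated) schedules is sensitive to the unreported initial
effector state: a homeostatic initialization `E(0) = w/l` (= 4.5 cells/mm³)
lowers those burdens by roughly a factor of two. Absolute burden
predictions should therefore be read as order-of-magnitude; burden *ratios*
between schedules are much more stable.

## Numerics

The ODE system (state `[C, D, I, A]` per site, `A = V·E`, `E = A/max(V,
10⁻¹⁰)`) is integrated with adaptive RK45 at 10⁻⁸ relative and absolute
tolerance. Integration hard-restarts at every discontinuity: radiation
impulses, the secondary-site implantation, and each immunotherapy
injection. Within a segment the set of active boluses is frozen at the
segment start, so `u(t)` is smooth inside every solver step (a bolus at a
segment's right edge belongs to the next segment); without this the
endpoint stage of the step ending exactly at an injection time contaminates
the solution with a first-order error. The term `(1 + w2·I_j/V_j)·V_j` is
evaluated as `V_j + w2·I_j`, which also encodes the `I/V → 0` convention at
`V = 0`; an empty two-site system uses `p = (0.5, 0.5)`, where the
recruitment term vanishes anyway. Output grids default to 0.1-day spacing;
grid values at an event time are the post-impulse (right-continuous) state,
and the event log records pre/post states. Compartments may undershoot zero
by solver tolerance and are clamped to zero for reporting.

A second, independent integrator — a classical fixed-step RK4 operating on
a batch of treatment arms simultaneously (numba-compiled) — serves both as
a cross-check oracle (it agrees with the adaptive solver to ~10⁻⁷ relative
at Day 32 at its default 0.05-day step) and as the fast inner loop of the
calibrator, where a single objective evaluation must solve all sixteen
arms.

## Calibration

The objective sums squared *relative* volume errors over arms, sites and
measurement times, plus squared errors of the simulated Day-35
secondary-site infiltration ratio `E₂(35)/E₂,ctrl(35)` against measured
relative infiltration, for arms carrying that readout. Thirteen parameters
are free (K, a, d, w, w2, e, clr, SF and AI at the three tested doses; SF/AI
as free scalars, with the continuous curves fitted afterwards); r and l are
fixed inputs. Estimation is bounded trust-region least squares
(`scipy.optimize.least_squares`, TRF) from log-uniform random starts
(uniform for the SF/AI fractions) within box bounds chosen for positivity
and physiological plausibility (K ∈ [10², 10⁴] mm³, rates spanning a few
decades around their plausible scales, fractions in (0, 1]); rates are
optimized in log₁₀ space for conditioning. Terminal vectors are clustered
at 1% relative tolerance; the report carries the best cluster's
representative, the fraction of starts reaching it, and local sensitivity
diagnostics (normalized-Jacobian correlations; pairs above |0.99| are
flagged). Non-finite trial solves (explosive parameter combinations) map to
a large flat penalty. Everything is deterministic given the seed.

**Structural non-identifiability.** The dynamics are linear in effector
density, so the rescaling `E → cE, a → a/c, w → cw` leaves every volume
trajectory *and* the infiltration ratio (a ratio of densities) unchanged;
similarly *D* and *I* clear at the same rate, so volumes constrain only
`D + I` and recruitment only the products `w2·AI_D`. From this experiment's
observables, only K, d, e, clr, the SF values, the product `a·w` and the
products `w2·AI_D` are identifiable; the individual values of a, w, w2 and
AI_D are gauge freedoms. The fit report flags the degenerate directions
rather than hiding them; recovery tests assert the identifiable
combinations.

## Synthetic experiments

The generator reproduces the calibrating design: control; three
primary-site RT fractionations (20 Gy × 1, 8 Gy × 3, 6 Gy × 5, daily from
Day 12 at 600 cGy/min); three 9H10 schedules (three injections two days
apart starting Day 12, 14 or 16); and their combinations (the published
description does not enumerate the pairing, so the full 3 × 3 cross product
is the default, with a flag to pair index-to-index). Volumes of both sites
are sampled on a 2–3-day grid from Day 12 to Day 32 (nine days by default —
the per-arm measurement bookkeeping of the original experiment is not
recoverable from the text, so the default full design carries
16 × 2 × 9 = 288 points), and combination arms carry a Day-35 infiltration
ratio. Noise is multiplicative and mean-preserving, log-normal by default
at 20% CV (caliper error scales with size and volumes stay positive); a
truncated-Gaussian option exists for sensitivity checks.

What passing synthetic tests do **not** show: the generator shares the
simulator's model family, so recovery tests certify the estimation
machinery and identifiability structure, not model adequacy for real
tumors; there is no inter-animal heterogeneity, no measurement dropout, and
noise is exactly the assumed family.

## Fractionation search

Sweeps evaluate every candidate fraction count n (default 1–15) at dose per
fraction `value/n` (fixed total dose) or the positive root of
`nD(1 + D/θ) = value` (fixed BED), delivered daily from Day 12 (weekends
included — a murine protocol), with immunotherapy fixed at Days 12/15/18,
and record the Day-32 burden V1 + V2. Schedules extending beyond the
evaluation day are flagged and excluded from the optimum rather than
silently truncated; ties break toward fewer fractions. With the default
parameters the optimum at 60 Gy total is 5 × 12 Gy, and hypofractionation
beats conventional ~2.7 Gy fractions by an order of magnitude at fixed
total dose — intermediate doses per fraction maximize `AI_D` and hence the
systemic immune boost, while very large single doses are immunologically
cold and very small fractions kill too little.

## Known limitations

- Absolute Day-32 burdens inherit the uncertainty of the unreported initial
  effector state (see above); schedule rankings and burden ratios are the
  robust outputs.
- The effector-density scale is a gauge freedom; absolute values of a, w,
  w2 (and the AI levels separately from w2) should not be interpreted.
- Immunotherapy acts instantaneously at injection (no absorption
  compartment), biasing toward concurrent radio-immunotherapy.
- No normal-tissue toxicity model: "optimal" means minimal tumor burden at
  the evaluation day only.
- Two sites, fixed; organ-specific extravasation is out of scope.
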