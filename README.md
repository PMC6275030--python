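# abscopal

Mechanistic modeling of the radiation-induced **abscopal effect**: a
two-site tumor–immune ODE model for bilateral mouse tumors in which one
site receives focal radiotherapy and both receive the systemic benefit of
the anti-tumor immune response, optionally boosted by checkpoint blockade
(anti-CTLA-4, clone 9H10). The package provides

- an event-driven **simulator** for impulsive irradiation of the primary
  site with concurrent immunotherapy,
- radiation **dose–response curves** (linear-quadratic survival with a
  Lea–Catcheside-type protraction factor; a capped log-normal immunogenic
  cell-death fraction) to interpolate untested doses, plus BED algebra,
- a multistart **calibrator** fitting 13 free parameters to per-arm tumor
  volume time series and a Day-35 immune-infiltration readout,
- a **fractionation optimizer** finding the number of daily fractions that
  minimizes total tumor burden at fixed total dose or fixed biologically
  effective dose (BED), and
- a **synthetic-data generator** reproducing the statistical structure of
  the calibrating four-group bilateral-tumor experiment.

It is aimed at mathematical oncologists and radiobiology modelers who want
to explore how dose per fraction trades off direct cell kill against
immunogenic cell death and systemic T-cell-mediated control.

## Model

Each site *i* ∈ {1, 2} carries viable tumor volume *C*, non-immunogenically
dying volume *D*, immunogenically dying volume *I* (total measurable volume
*V = C + D + I*) and effector-cell density *E*:

    dC/dt  = r C (1 − V/K) − a C E
    dD/dt  = r C V/K + a C E − d D
    dI/dt  = −d I
    d(VE)/dt = −l E V + (1 + u(t)) p_i w Σ_j (1 + w2 I_j/V_j) V_j

with trafficking probability `p_i = V_i/(V1+V2)` and checkpoint-blockade
signal `u(t) = Σ e·exp(−clr(t−t̄))` over past injections. A radiation
fraction of dose *D* Gy instantaneously maps `C → C·SF_D`, routing the
killed volume into *I* (fraction `AI_D`, immunogenic) and *D* (the rest);
`SF_D = exp(−αD − βG(λT)D²)` with delivery-time protraction factor
`G(x) = 2(x + e^(−x) − 1)/x²`, and `AI_D = min((γ/D)·e^(−(ln D−μ)²/ρ), 1)`.
Schedules are compared at fixed `BED = nD(1 + D/θ)`, θ = 20 Gy.

## Worked example

```python
from abscopal import (default_parameters, default_dose_response_model,
                      RadiationProtocol, ImmunotherapyProtocol, simulate,
                      SweepSpec, sweep)

params, table = default_parameters()          # calibrated rates + SF/AI table
drm = default_dose_response_model(table)      # continuous dose-response curves

rt = RadiationProtocol.daily(12, 3, 8.0)      # 8 Gy x 3, Days 12-14, site 1
it = ImmunotherapyProtocol(injection_times=[12, 14, 16])
res = simulate(params, drm, rt, it, horizon=32.0)
print(f"irradiated site  V1(32) = {res.volume(1, 32.0):6.1f} mm^3")
print(f"abscopal site    V2(32) = {res.volume(2, 32.0):6.1f} mm^3")

untreated = simulate(params, drm, horizon=32.0)
print(f"untreated burden V1+V2  = {untreated.burden(32.0):6.1f} mm^3")

opt = sweep(SweepSpec(constraint_kind="total_dose", constraint_value=60.0),
            params, drm)
print(f"optimal 60 Gy schedule  = {opt.optimal_n} x "
      f"{opt.optimal_dose_per_fraction:.0f} Gy "
      f"(burden {opt.optimal_burden:.1f} mm^3)")
```

prints

```
irradiated site  V1(32) =    1.7 mm^3
abscopal site    V2(32) =   69.4 mm^3
untreated burden V1+V2  = 1287.8 mm^3
optimal 60 Gy schedule  = 5 x 12 Gy (burden 26.6 mm^3)
```

The combination arm nearly eradicates the irradiated tumor and shrinks the
*non-irradiated* contralateral tumor twenty-fold relative to no treatment —
the abscopal effect the model was built to dissect. Sweeping fractionation
at a fixed 60 Gy total dose, the burden-minimizing schedule is
hypofractionated (5 × 12 Gy), because intermediate doses per fraction
maximize immunogenic cell death while retaining substantial direct kill.

A command-line interface mirrors the library:

```sh
abscopal generate --noise-cv 0.2 --seed 0 --outdir data/
abscopal calibrate --data data/volumes.csv --protocols data/protocols.json \
    --infiltration data/infiltration.csv --starts 50 --seed 17 --out fit.json
abscopal sweep --mode total --value 60 --out sweep.csv
abscopal optimize --mode bed --grid 20:140:5 --out optmap.csv
```

## Documentation

See `docs/methods.md` for the modeling assumptions, parameter meanings and
defaults, the synthetic-experiment design, numerical choices, and known
limitations (including the structural non-identifiability of the
effector-density scale).
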