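# pedtmdd

Simulation toolkit for asking a deceptively simple pediatric-dosing question:
if a monoclonal antibody (mAb) is eliminated partly through binding to its
pharmacological target — target-mediated drug disposition, TMDD — does scaling
the adult dose to a child by body weight still give the child comparable
exposure and, more importantly, comparable target occupancy?

For mAbs with linear clearance, mg/kg dosing plus allometric scaling
(CL ∝ BW^0.75, V ∝ BW^1) is standard practice. With TMDD the answer depends on
how target expression itself changes with body size, which is rarely measured
in children. `pedtmdd` makes that dependence explicit and explorable: it
simulates pediatric age groups under competing assumptions about the target
(same concentration vs same whole-body amount as adults) and competing dosing
policies (mg/kg vs fixed mg), using both the full TMDD model and its
Michaelis–Menten (MM) approximation. The intended users are pharmacometricians
planning first-in-pediatric dosing for mAbs with saturable elimination.

## The model

Full TMDD model (Mager–Jusko scheme, binding in the central compartment,
1:1 stoichiometry, IV bolus as initial condition; C = A1/V1):

    dA1/dt = −kel·A1 − Q·(A1/V1 − A2/V2) − kon·C·R·V1 + koff·DR·V1
    dA2/dt =           Q·(A1/V1 − A2/V2)
    dR/dt  = ksyn − kdeg·R − kon·C·R + koff·DR
    dDR/dt = kon·C·R − (koff + kint)·DR

with baseline target R0 = ksyn/kdeg, occupancy DR/(R + DR), and the
clearance decomposition

    CL_TOT(C) = kel·V1 + kint·R0·V1 / (Km + C).

The quasi-steady-state MM reduction keeps the two-compartment drug
disposition and replaces binding with saturable elimination:

    Vmax = kint·R0,      Km = (koff + kint)/kon.

The shipped adult reference set is constrained to published constants for an
anti-ALK1 mAb — R0 = 1.74 nmol/l, Vmax = 7.6038 nmol/l/day,
Km = 0.403 nmol/l — with the remaining disposition values (CL_linear = 0.25
l/day, V1 = V2 = 2.8 l, Q = 0.6 l/day, kdeg = 2/day) as documented surrogates
in the typical mAb range, all overridable by config (`examples/config.yaml`).

Pediatric groups (2 y / 6 y / 12 y / 18 y at 12.8 / 21.3 / 43.5 / 66.1 kg)
are scaled allometrically; the target level is set per policy (equal
concentration, or equal amount converted through a BW-proportional plasma
volume, 2.8 l at 70 kg). Exposure is summarized by non-compartmental analysis
(linear-up/log-down AUC, best-adjusted-R² terminal slope), clearance
partitioning (CL_TMDD = Dose/AUC₀₋∞ − kel·V1), and time above an occupancy
threshold.

## Worked example

Same target concentration in children and adults, 4.5 mg/kg IV bolus:

```python
import pedtmdd as pt

adult = pt.make_reference_params()
policy = pt.ScalingPolicy()                      # CL ~ BW^0.75, V ~ BW^1
target = pt.TargetPolicy("same_concentration", adult_r0=1.74)

for age in ("2y", "18y"):
    subject = pt.Subject.from_age(age)
    params = pt.apply_target_policy(
        pt.scale_parameters(adult, subject, policy), subject, target, policy
    )
    regimen = pt.build_regimen(4.5, "per_kg", subject)   # 30 nmol/kg
    profile = pt.simulate_tmdd(params, regimen)
    nca = pt.clearance_partition(regimen.molar_dose, pt.run_nca(profile), params)
    days = pt.occupancy_duration(profile, threshold=0.90)
    print(f"{age:>3}: Cmax {nca.cmax:7.1f} nmol/l   AUC {nca.auc_0_inf:7.0f} nmol*day/l   "
          f"CL_TMDD/CL_TOT {nca.cl_fraction:5.1%}   occupancy>90% for {days:4.1f} d")
```

prints

```
 2y: Cmax   750.0 nmol/l   AUC    4389 nmol*day/l   CL_TMDD/CL_TOT 20.1%   occupancy>90% for 39.4 d
18y: Cmax   750.0 nmol/l   AUC    6131 nmol*day/l   CL_TMDD/CL_TOT 26.0%   occupancy>90% for 51.1 d
```

Cmax is identical because dose and central volume both scale linearly with
weight, but the 2-year-old's exposure is only 72% of the adult's (faster
weight-normalized catabolic clearance) and target suppression is maintained
12 days less — the PK difference understates the pharmacodynamic one.

The same comparisons over all doses, target levels, ages, policies and both
model kinds come from the scenario engine, or the CLI:

```
pedtmdd grid --config examples/config.yaml --out results/
pedtmdd simulate --age 2y --dose 4.5 --out results/
pedtmdd recover --seed 1 --out results/
```

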