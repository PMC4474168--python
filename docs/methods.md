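# Methods

## Model

The full model is the standard target-mediated drug disposition (TMDD) scheme
for an intravenously dosed monoclonal antibody: two-compartment disposition of
free drug (amounts A1, A2 in nmol; central concentration C = A1/V1), linear
catabolic elimination `kel·A1`, and 1:1 reversible binding in the central
compartment to a target that turns over by zero-order synthesis `ksyn` and
first-order degradation `kdeg`. The complex DR is internalized with rate
constant `kint`; this is the target-mediated elimination route. Target
species are carried as concentrations referenced to the central volume, so
binding terms convert through V1. Assumptions inherited from this scheme:
binding only in the central compartment, no feedback of occupancy on target
synthesis or degradation, no distinction between soluble and membrane targets
beyond the semantics of `kint`, single dose only (the bolus is the initial
condition `A1(0) = dose`, with the target at its drug-free steady state
`R(0) = R0 = ksyn/kdeg`, `DR(0) = 0`).

The Michaelis–Menten (MM) approximation is the quasi-steady-state reduction:
two-compartment drug disposition plus saturable elimination
`Vmax·C/(Km + C)` with

    Vmax = kint · R0        Km = (koff + kint) / kon .

It assumes total target stays near its baseline R0; the same assumption
underlies the algebraic clearance decomposition

    CL_TOT(C) = kel·V1 + kint·R0·V1/(Km + C),

which interpolates between the target-saturated linear limit (C → ∞) and the
maximal total clearance at vanishing drug. Because Vmax depends on R0, the
reduction is applied after scaling and after the target-level policy, so each
age group gets its own Vmax.

## Parameters

| parameter | units | default | provenance / rationale |
|---|---|---|---|
| R0 | nmol/l | 1.74 | published baseline target concentration (anti-ALK1 mAb) |
| Vmax | nmol/l/day | 7.6038 | published; fixes kint = Vmax/R0 = 4.37/day |
| Km | nmol/l | 0.403 | published; with kon fixes koff = Km·kon − kint = 3.69/day |
| kon | 1/(nmol/l)/day | 20 | surrogate; sets the binding timescale, any kon ≥ kint/Km is admissible — the anchors constrain only Km and Vmax |
| CL_linear | l/day | 0.25 | surrogate; typical IgG catabolic clearance (~3.6 ml/day/kg) |
| V1, V2 | l | 2.8, 2.8 | surrogate; plasma-like central volume, shallow peripheral space |
| Q | l/day | 0.6 | surrogate; typical mAb inter-compartmental clearance |
| kdeg | 1/day | 2 | surrogate; ~8 h target half-life, fast relative to the drug |

The three published constants are reproduced exactly by construction; the
surrogate choices are in the physiological mAb range and are overridable via
the config file (`examples/config.yaml`). Quantitative conclusions that
depend on the disposition parameters (absolute AUC ratios, occupancy
durations) therefore characterize this reference set, not the original
published antibody — see Limitations.

## Scaling and policies

Volumes scale as BW^1 and clearances (CL_linear and Q) as BW^0.75 from the
70-kg adult reference; `kel` is recomputed as scaled clearance over scaled
volume. Q is treated as a clearance — the conventional choice. Binding and
turnover micro-constants (`kon`, `koff`, `kint`, `kdeg`) are cell-level
quantities and are held age-invariant. The 18-year group (66.1 kg) is itself
scaled from the 70-kg reference; this is what makes its same-amount target
concentration 4.87 nmol / 2.644 l = 1.84 nmol/l rather than the adult-anchor
1.74 nmol/l.

Target-level policies fix R0 per subject: `same_concentration` copies the
adult concentration; `same_amount` divides the adult whole-body amount by a
BW-proportional plasma volume (2.8 l at 70 kg). `ksyn` is then re-derived as
`R0·kdeg` so every simulation starts at steady state — the policies are
statements about target level, not about synthesis rates. Doses convert to
molar units at 150 kDa; printed values like 3.33 nmol/kg are 3-significant-
figure displays of exact conversions.

## Numerics

Integration uses BDF with an analytic Jacobian, rtol 1e-8 and atol 1e-10
nmol(/l): the binding terms make the system stiff for fast association
(verified up to kon = 100 1/(nmol/l)/day). The output grid is log-spaced
over the first two days (61 points from 1.4 min) and half-daily thereafter;
the default 120-day horizon doubles automatically (capped at 1920 days) until
the free-drug concentration falls below 1e-4 of Cmax, keeping the AUC
extrapolation small. States below −1e-6 nmol(/l) raise as solver failure;
undershoot inside [−1e-6, 0) is clipped to zero in derived outputs only.
Linear-limit accuracy against the bi-exponential closed form is ~6e-7
relative; drug conservation with all elimination off holds to machine
precision (the conserved quantity is linear in the state, so the implicit
multistep method preserves it exactly).

NCA uses the linear-up/log-down trapezoid (exact on exponential decline;
differs from the pure linear rule by <0.5% at the default grid density — not
configurable). The terminal slope is the log-linear regression over the
window (≥3 points, excluding Cmax, positive concentrations only) with maximal
adjusted R², ties within 1e-4 broken toward more points; AUC₀₋∞ adds
`C_last/λz`, and an extrapolated fraction above 20% sets a warning flag.
`CL_TMDD = Dose/AUC₀₋∞ − kel·V1` is floored at zero (a warning is emitted
only if the negative excursion exceeds numerical noise). Occupancy duration
is total time with DR/(R+DR) ≥ threshold (default 0.90), crossings located by
linear interpolation; for these single-dose profiles, which cross the
threshold at most twice, this equals the contiguous interval, and it
coincides with "time until occupancy first falls below threshold" for
monotone-decline profiles. Occupancy at R + DR = 0 is reported as NaN (an
undefined ratio, only reachable in synthesis-free edge cases), never as 0/0.

The scenario grid (2 target policies × 2 dose policies × 5 doses × 7 target
levels × 4 ages × 2 model kinds = 1120 records) executes in deterministic
lexicographic order; failed cells are recorded with an error code, never
dropped. The target-level axis is interpreted per policy: concentrations for
`same_concentration`, amounts for `same_amount`. Tables are written as
RFC-4180 CSV at full repr precision, so reruns are byte-identical. The full
grid takes about three minutes on one CPU; the acceptance script instead runs
the 160-cell slice containing the canonical target levels (1.74 nmol/l,
4.87 nmol) plus the lowest sensitivity level, and the 2-year/18-year contrast,
which contains every reported quantity.

## Synthetic data and parameter recovery

The generator emulates the study conditions plus the variability needed for
recovery testing: virtual cohorts draw body weight lognormally around the
age-group means (CV 15%; the lognormal is parameterized so the arithmetic
mean equals the group mean), and observations apply proportional error
`C·(1+ε)`, ε ~ N(0, CV²) with CV 10%, redrawn on the rare nonpositive
draws — the standard error model for mAb assays. Sampling uses a 12-point
schedule from 6 h to 84 days. Every stochastic output is a pure function of
the config seed.

`fit_mm` estimates (kel, Vmax, Km, V1) in log space by Levenberg–Marquardt on
residuals `(pred − obs)/pred` (1/pred² weighting), simulating the same MM
model at slightly relaxed tolerances (rtol 1e-7) for the objective; V2 and Q
are fixed, as they are not identifiable from a sparse single-dose schedule.
The initial guess is deliberately displaced from the truth (×1.5, ×0.6, ×2,
×1.3). Noise-free data are recovered to ≪1%; at 10% CV with 20 naive-pooled
subjects, the median absolute Vmax error over 50 replicates is ~2%.

What passing these tests does not show: the generator has no inter-individual
parameter variability beyond body weight, no assay LLOQ or censoring, no
model misspecification beyond the TMDD→MM gap, and naive pooling rather than
mixed-effects estimation — recovery performance on real pediatric data would
be worse on all four counts.

## Design choices where the design was open

- Whether the central volume V1 equals the plasma volume used to convert
  target amounts is not fixed by the science; they are separate configurable
  quantities (defaults happen to coincide at 2.8 l).
- Rate constants may be zero so that limiting cases (no binding → linear
  two-compartment model; no elimination → conservation law) are first-class
  members of the parameter space; volumes and Q must be strictly positive.
- A zero dose is a valid degenerate regimen: the profile is identically zero
  and NCA reports it as non-estimable rather than erroring upstream.
- MM-vs-full comparison cells where the child/adult AUC-ratio agreement
  deviates from 100% by more than 25 percentage points are flagged; this
  threshold marks the regime (low dose, high target load) where the reduction
  misorders the pediatric/adult comparison, not a statistical bound.

## Limitations

- The published exposure-ratio and occupancy values for the source antibody
  depend on its full adult disposition parameter set, which is not public;
  with the shipped surrogate set the package reproduces the qualitative
  structure (direction and dose-trends of all comparisons) but not those
  exact percentages. Users holding the original set can supply it via config.
- Single IV bolus only: no multiple dosing, infusions, or subcutaneous/
  intramuscular absorption; no FcRn-maturation or immunogenicity effects; no
  target-synthesis feedback. These are outside the model scheme, not solver
  restrictions.
- Allometric exponents are fixed inputs (0.75/1 by default), not estimated.
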