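# Methods

## Scope

`cytara` models white-blood-cell (WBC) dynamics under cytarabine (Ara-C)
consolidation chemotherapy for AML. It covers: a two-compartment Ara-C
pharmacokinetic (PK) model with pooled estimation from concentration data; a
family of twelve transit-compartment myelosuppression models; per-cycle and
per-patient personalisation by penalised nonlinear least squares;
cross-validated prediction of a held-out cycle; Monte-Carlo propagation of
estimation uncertainty; schedule construction and recovery statistics;
model-discrimination, treatment-timing and PK-variability simulation
studies; a synthetic-cohort generator; and NONMEM-dialect dataset I/O.
Population (mixed-effects) estimation, G-CSF dynamics and leukemic-cell
dynamics are deliberately out of scope.

## Pharmacokinetics

Amounts `x1` (central) and `x2` (peripheral), in mg, obey a linear mamillary
system with zero-order infusion input; concentrations are `x1/Vc`. Rate
constants are stored in 1/h (the reporting convention) and converted to
1/day at model construction because all dosing and sampling times are in
days (a 3-h infusion has duration 0.125 d). The default parameters
(`HIDAC_PK`: CL 154.2 L/h, Q 4.18 L/h, Vc 37.66 L, Vp 7.78 L) come from a
naive-pooled fit to published high-dose concentration-time data (Kern et
al., 1997; 3 g/m² q12h 3-h infusions, BSA assumed 1.78 m²); low-dose
literature models underpredict high-dose peak concentrations and are not
used.

Because the PK block is linear with piecewise-constant input it is solved
*exactly*: per segment between dosing discontinuities the solution is the
particular (forced) steady state plus an eigen-decomposed homogeneous part.
No integrator error enters the PK side; the test suite checks the closed
form against an independent numerical integration at 1e-8 relative
agreement. Overlapping infusion events sum their rates; zero-duration
events are rejected.

`fit_pk_pooled` minimises the sum of squared log residuals (exponential
error model) over (k10, k12, k21, Vc), all records pooled as one subject.
Optimisation is bounded trust-region least squares in log-parameter space
with a multistart (default 10 starts, seed 1, log-uniform over 10^±2 times
the starting values). The covariance is the Gauss-Newton asymptotic
estimate `σ̂²(JᵀJ)⁻¹` with `σ̂² = RSS/(n−p)` and J mapped to natural
parameters by the chain rule; relative standard errors are
`100·sd/estimate`.

## Myelosuppression models

All variants share the maturation chain: proliferating pool `x_pr`, `n_tr`
transit stages, circulating pool `x_ma`, all in G/L referenced to
peripheral blood. The circulating death rate is fixed at
`k_ma = 2.3765/day` (7-h circulating half-life, the convention of the
Friberg/Quartino model family) — profile fits are insensitive to it, and
fixing it preserves identifiability. The drug acts through
`E = slope·ln(1 + c_V·x1)` and `S(x1) = 1 + ln(1 + c_V·x1)`.

**Unit constant.** `c_V = 1000/(Vc·MM_cyt)` with `MM_cyt = 243.22 g/mol`,
so `c_V·x1` is the molar central concentration in µmol/L. A 3 g/m² infusion
peaks near 50 µmol/L, putting `E` and `S` on the O(1) scale on which the
slope bounds (1e-3–10) and the sign-change threshold
`c_V·x1 = e^{1/slope} − 1` are meaningful. On a mmol/L scale (peak ≈ 0.05)
no slope within those bounds could drive `F` negative and the secondary
term would be inert, which contradicts the observed suppression dynamics;
this is the package's resolution of an under-specified unit convention.

The variants (see the table in `cytara.models`): M1/M2/M3 vary
`n_tr ∈ {6,3,1}` with steady-state initialisation; M4/M5 free the initial
conditions; M6 replaces rate reduction by a direct kill term `−E·x_pr`
(the net per-cell rate may go negative; it is deliberately not clipped);
M7 slows maturation by `1/S`; M8/M9 divide the proliferation law by `S`;
M9/M10/M12 scale the feedback exponent to `γ·S(x1)`; M11/M12 replace the
feedback source by the bone-marrow pool `0.01·x_pr + 0.99·x_tr` compared
against its baseline `B_bm = B·k_ma/k_tr`. Feedback denominators are
floored at 1e-12 to survive transient deep suppression. Without drug all
one-transit variants collapse onto the reference vector field (the marrow
pair onto each other) — a structural identity the tests assert.

**Initial conditions.** I1 pins every compartment at steady state
(`x_pr = x_tr = B_bm`, `x_ma = B`); I2 frees the initial circulating count
`B0`; I3 additionally frees `x_pr(0)` and `x_tr(0)`, with the fitting
objective penalising their deviation from `B_bm` at weight `α = 1/2500`
(`B0` is never penalised). I2/I3 exist because real cycles start before the
previous cycle's perturbation has fully decayed (carry-over). PK states
always start at zero — a single high-dose infusion washes out (both amounts
< 1e-6 mg) in under two days, far inside the ≥ 2-week inter-cycle gap.

**Integration.** The PD states are integrated with LSODA (`scipy`'s
`odeint`, rtol 1e-8 / atol 1e-10 for simulation, 1e-7 / 1e-9 inside the
fitting loop) with the exact PK solution supplied as a forcing function and
every dosing discontinuity declared as a critical time. Decoupling the PK
keeps its fast rates (~98/day) out of the numerically integrated system.
The integrator evaluates a specialised closure of the vector field; its
equality with the readable reference implementation is asserted in the
tests, as is agreement of the three-transit variant with an independently
coded textbook Friberg implementation integrating the full coupled system.

## Personalisation

A *cycle* (dosing events + WBC observations, clock zeroed at the first
record) is the estimation unit. Residuals are `log(pred) − log(obs)`
(switchable to linear): the log scale weights the clinically decisive nadir
region appropriately and matches the multiplicative error of WBC counts.
Reported RMSEs are always on the linear G/L scale. Patientwise fits share
the four core parameters across a patient's cycles; I2/I3 initial-state
parameters stay per-cycle, and each cycle restarts with a zero PK state (no
Ara-C carry-over between cycles).

Estimation boxes: B ∈ [1, 20] G/L, slope ∈ [1e-3, 10], k_tr ∈ [0.01, 5]/d,
γ ∈ [0.01, 10], B0 ∈ [0.05, 50] G/L, initial marrow states ∈ [1e-3, 500].
The multistart evaluates 20 candidate vectors (one data-driven — baseline
from the pre-/early-treatment samples — the rest log-uniform in the boxes,
seed 1) and polishes the best three by bounded trust-region least squares
in log space. The finite-difference step for the Jacobian is fixed at 1e-3
relative — well above the ODE-solution noise floor, below which the
Jacobian degenerates and the optimiser stalls. Failed simulations inside
the loop return a large constant residual so the optimiser retreats.
Covariance and RSEs as in the PK fit, with penalty rows included in J;
parameter correlations above 0.9 (which do occur between γ and k_tr or
slope) are recorded on the result rather than suppressed.

## Prediction and uncertainty

Cross-validation fits all but a patient's last cycle and simulates the
held-out cycle from the homeostatic state implied by the fitted baseline
(the held-out cycle's own initial state cannot be estimated without
touching its data; only its dosing schedule and observation times enter the
prediction). Monte-Carlo bands draw parameter vectors from the
multivariate normal at (estimate, covariance) — repaired to the nearest
PSD matrix if needed — resampling out-of-bounds draws up to 100 times each
rather than clipping (clipping would pile probability mass on the box
edges and distort the quantiles); pointwise 2.5/50/97.5% quantiles of the
simulated WBC curves are reported.

## Schedules and recovery statistics

Schedule labels: capital D = 3 g/m², lowercase d = 1 g/m², two 3-h
infusions 12 h apart on the named cycle days, day *d* mapping to
t = d − 1; C100/C400 are 5-day continuous infusions at 100/400 mg/m²/day.
Amounts are BSA-scaled at construction.

On simulated trajectories (dense 0.05-d grid), `nadir` is the minimum WBC,
`t_leu` the total time at or below 1 G/L (crossings linearly interpolated),
and `t_rec` the first up-crossing of 1 G/L after the global nadir (missing
when the threshold is never reached). On measured series the same
statistics are evaluated on the discrete grid: `t_leu` counts measurement
days at or below threshold and `t_rec` is the first measurement above
threshold after the observed minimum — hence coarse sampling can only delay
`t_rec`, never advance it.

The discrimination study simulates every personalised cycle under both
D123 and D135 and excludes any cycle for which *any* (model, schedule)
combination predicts no leukopenia, so recovery times are never compared
against a non-event; medians/SD/min/max per model × schedule and the median
per-cycle D135−D123 recovery difference are reported. The timing study
moves a patient's last dosing block by −10…+10 days over their fixed
earlier cycles and records the nadir: dosing into the post-rebound decline
makes the nadir monotone non-increasing in the start shift. The PK
variability study draws CL (CV 45%) and Vc (CV 70%) lognormally
(`sdlog = sqrt(ln(1+CV²))`, median preserved), re-derives the micro
constants and `c_V` per draw, and compares recovery-time distributions of
the plain and γ-scaled one-transit models (steady-state initialisation)
under both schedules.

## Synthetic cohorts

The generator emulates the structure of a small consolidation cohort: 23
patients with 1/2/3 cycles in proportions 9/9/5; schedules D135, d135,
D123, D12 in cycle-frequency mix 23/15/2/2 (assigned per patient); BSA
normal (1.78 ± 0.15 m², truncated); almost-daily sampling over 30-day
cycles with 10% dropout; multiplicative lognormal measurement noise
σ = 0.15; per-cycle carry-over perturbations of the starting states
(lognormal, CV 20% around the homeostatic values).

True parameters are lognormal around medians B = 5.5 G/L, slope = 5.5,
k_tr = 0.1875/d, γ = 0.55 (CVs 25–30%), clipped into the estimation boxes.
The medians were fixed once, before any end-to-end measurement, so that the
median patient under the γ-scaled model and the standard D135 schedule
reproduces typical observed consolidation-cycle summaries (nadir ≈ 0.3 G/L,
recovery ≈ day 23, ≈ 12 leukopenic days) — B sits 2 G/L below classic
healthy-population baselines as expected after induction, and k_tr encodes
a 128-h corrected mean maturation time with one transit compartment. The
default generating model is the γ-scaled variant M10.

What the generator does *not* emulate: G-CSF rescue, leukemic blast
dynamics, progressive inter-cycle damage (nadirs do not deepen from cycle
to cycle), informative dropout, or assay detection limits. Passing
recovery tests on synthetic cohorts therefore demonstrates estimator
correctness under the stated noise model, not clinical transportability.

## Problem sizes and runtimes

The test suite's end-to-end studies use 40 single-cycle patients for the
parameter-recovery experiment and 12 for the discrimination
self-consistency experiment, with the default multistart; each per-cycle
fit takes a few seconds. Monte-Carlo bands default to 1000 draws in the
API and use 20–40 draws in unit tests. The washout computation scans a
1e-3-day grid and refines the crossing by bisection to ~1e-12 d.

## Known limitations

- The clinical-data checks (pooled PK refit, RMSE and recovery-time table
  reproduction) require the original deposited datasets under
  `data/clinical/`; without them those tests fail by design.
- Naive pooling of concentration data ignores between-subject PK
  variability (none could be estimated from pooled digitised data); the
  variability study uses literature CVs instead.
- The I3 penalty weight α = 1/2500 is a fixed regularisation choice, not
  estimated; very large α reproduces the steady-state-initialisation fit
  (asserted in the tests), very small α inflates initial-state RSEs.
- Bone-marrow compartments are expressed per litre of peripheral blood; no
  blood-to-marrow volume conversion is attempted, so `x_pr`/`x_tr` are not
  literal marrow cell densities.
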