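# Methods

## Model and assumptions

`cllcart` models chronic lymphocytic leukemia in the blood circulatory
system of an adult patient as four coupled ODEs over absolute counts in a
5 L blood volume: live tumor cells A, dead tumor cells A_d, chlorambucil
molecules C, and CAR-T cells T. The structural assumptions are:

* logistic tumor growth toward a carrying capacity b = 7.2e11 cells
  (lymphocytes as 1.6% of ~4.5e13 total cells in an adult);
* necrosis by crowding as mass action between live and dead cells;
* drug kill saturating in the drug pool (Michaelis–Menten with
  half-effect amount a = 1e7 molecules), with every kill consuming drug
  (mu_CA = 10 mu_AC, mu_CT = 10 mu_TC);
* one-compartment first-order drug decay, mu_C = ln2 / t_half with
  t_half = 0.0625 d, so mu_C = 11.090/d — no absorption or distribution
  phases;
* CAR-T activation proportional to encounters with antigen-bearing cells
  (rho_T (A+T) T), exhaustion/death at mu_T, and quadratic fratricide
  alpha_T T^2. The efficacy must exceed the mitosis rate
  (alpha_T > rho_T); parameter construction enforces this because the
  boundedness and threshold formulas divide by (alpha_T − rho_T);
* the eradication-threshold convention: a population whose solution drops
  strictly below one cell (or one molecule) is extinct and is set to 0.

Default parameters are the published calibration: rho_A = 0.168/d (10% of
the in-vitro growth rate), mu_A = 1.63199e-12 /cell/d, mu_d = 0.408/d,
mu_T = 1/14 d^-1, rho_T = 2.9409e-13 /cell/d (persistence regime) and
alpha_T = 1.2560e-7 /cell/d from the fitted efficacy law. Soft
plausibility ranges (rho_A ≤ 1.68, mu_T in [1/30, 1/14]) warn rather
than error; the printed ordering of the mu_T range is ambiguous in the
source table, so we validate against the closed interval between the two
endpoints.

## Dose-response laws and fitting

Chlorambucil cytotoxicity follows a log-kill-inspired law in blood
concentration k (mg/L): mu_AC(k) = (log10(1 + eps1 k))^(1/eps2). The
typeset form of this law is ambiguous about grouping; the implemented
reading is the only one consistent with the worked 6.4 mg/L = 0.2806/d
example and every tabulated fitted value, and is pinned by table-level
regression tests. The same applies to the additive three-term CAR-T
efficacy law.

Fits minimize unweighted squared residuals on the rate scale using
`scipy.optimize.curve_fit` with positivity bounds (trust-region
reflective). The CAR-T fit's residuals are O(1e-9), far below the default
termination scales, so residuals are rescaled by a constant sigma (the
response mean) and the step scaling follows the initial guess; neither
changes the optimum. Confidence intervals are linearized (Jacobian-based)
95% intervals with a Student-t critical value at n−p degrees of freedom.
The CI construction behind the published tables is not stated, so
intervals are expected to match to about two significant figures, not
bit-exactly; the point estimates are required (and verified) to fall
inside the published intervals, with R^2 ≥ 0.999 and ≥ 0.995 for the two
laws.

The calibration tables ship as plain-text TSV fixtures mirroring the
published tables column for column. The zero-concentration row is included
in the chlorambucil fit — the law passes through the origin exactly.

## Synthetic dose-response generator

`generate_synthetic_curve` draws curves from a known law over a caller
chosen design with multiplicative Gaussian noise y(1 + sigma z), clipped
at zero, deterministic per seed. The default study uses the published
7-point concentration design and sigma = 5%, the level at which median
parameter recovery within 10% is verified over replicated fits. The
generator emulates measurement-scale noise only: it does not model assay
censoring, between-batch effects, or design sparsity beyond the given
grid, so recovery results say nothing about those failure modes in real
assay data.

## Dose delivery semantics

Protocols schedule CAR-T doses (cells) and chlorambucil doses (mg;
converted to molecules via sigma = Avogadro / molecular weight =
1.97958685e18 molecules/mg). A CAR-T dose at day 0 enters through the
initial condition. Every later dose is delivered as a constant-rate
infusion pulse of duration 1 day (rate = amount/duration) through the
model's infusion terms.

The pulse width matters and was the one genuinely open design choice. An
instantaneous bolus interacts badly with the quadratic fratricide term: at
2e8 cells the initial self-kill rate is ~25/d, so most of a bolus burns
itself within hours and the integrated tumor kill per dose saturates
logarithmically in the dose. Under bolus delivery the weekly protocol
bottoms out near 2.5e3 live cells and never crosses the one-cell
threshold. One-day pulses (with the first dose as initial condition)
reproduce all published eradication and depletion times to ~0.01 days
(25.95, 47.15, 38.87, 40.18; CAR-T wash-out 207.32 and 228.34), so 1 day
is the default `DoseEvent.duration`; `duration=0` selects an impulse for
sensitivity analysis.

Each chlorambucil dose also updates the cytotoxicity parameters: mu_AC is
evaluated from the fitted concentration-response law at that dose's blood
concentration, with mu_TC = 0.054 mu_AC (chemotherapy damages CAR-T cells
at 5.4% of its tumor cytotoxicity) and the consumption couplings
mu_CA = 10 mu_AC, mu_CT = 10 mu_TC. This reproduces the tabulated
per-dose cytotoxicities to within 5e-4.

One bookkeeping note: the increasing-dose protocol's schedule
(40+48+48+56+56+64 mg) totals 312 mg; a figure caption in the source
reports 336 mg for the same schedule while the accompanying text says
312 mg. The preset stores the explicit schedule, so its total is 312 mg.

## Numerical integration and events

The default engine is `scipy.integrate.solve_ivp` with LSODA,
rtol = 1e-9 and atol = 1e-3. The absolute tolerance is deliberately in
cells/molecules: populations span 1 to ~1e20, and 1e-3 resolves the
one-cell eradication threshold while rtol carries accuracy for the large
pools. Integration restarts at every pulse edge so the solver never steps
across a discontinuity in the infusion terms.

The <1 clamp is applied outside the vector field, as terminal root-located
events (one per component, direction down): at the first crossing the
component is set to exactly 0 and integration resumes. Zero is invariant
for A and T (every term carries the population as a factor), so the clamp
is absorbing unless a later dose re-seeds the pool; A_d and C are also
clamped, though those constraints rarely bind before A. Tie-break: the
clamp is strict (<1); a component exactly at 1 is untouched.

A fixed-step explicit Euler engine is kept as a cross-validation
reference; it is first-order (verified by step-halving) and agrees with
the adaptive engine to 0.1% on the untreated dynamics at dt = 2.5e-4 d.
The published computations used explicit Euler with dt = 1e-7 d, which is
~2.5e9 steps per 250-day run; this package's scenario suite instead runs
in about a second with the adaptive engine, and the published event times
are matched within the ±0.5-day comparison bands rather than bit-exactly.

Problem sizes used by the test suite and the acceptance script: scenario
horizons of 250 d (immunotherapy protocols), 60 d (chemoimmunotherapy),
500 d (untreated and single-dose scenarios) and 3000 d for confirming the
coexistence steady state by integration (its slowest eigenvalue has a time
constant of hundreds of days); 100–200 replicates for the noisy-recovery
study.

## Analytic layer

Threshold doses are implemented in the nested-product form
phi = (rho_A/alpha_T)[(rho_A/alpha_T)(alpha_T − rho_T) + mu_T (+ mu_TC)],
the unique reading that reproduces all published threshold values
(320,252 through 348,821, matched within 0.1%; the residual ~0.02%
discrepancy traces to the 4-digit rounding of alpha_T). For comparisons
against bolus protocols, a dose in cells is compared against phi in
cells/day directly, following the source's own convention — a convention,
not a unit identity.

The localizing-domain bound A_sup is returned signed: a negative value is
exactly the nonexistence condition for a living tumor, so clamping it
would hide the eradication criterion. C_inf is floored at zero (negative
drug has no meaning) with the unfloored positivity recorded as a separate
condition flag. Eigenvalues are returned as complex numbers; stability
classification uses real parts with tolerance 1e-12. The closed-form
eigenvalues are verified against finite-difference Jacobians on randomized
parameter draws to 1e-6 relative.

The coexistence equilibrium is found by a bracketed scalar root-solve on
the live-cell nullcline — the bracket (mu_T/rho_T, mu_d/mu_A) is forced
by positivity of T and A_d — then polished by a 3-D Newton solve; an empty
or invalid bracket (the depletion regime) returns none.

## Limitations

* The model is mean-field and well-mixed: no spatial or compartmental
  structure, no stochastic extinction (the one-cell clamp is a
  deterministic surrogate for it), and no resistance evolution.
* Drug pharmacokinetics is a single compartment with first-order decay;
  infusion pulses stand in for unmodeled absorption.
* The CAR-T efficacy law is calibrated to six trial-derived rate
  combinations; outside that range it is an extrapolation, and its
  published inputs are treated as exact observations (no measurement
  error model).
* Alternative dose-response forms (Hill, Emax) are not implemented.
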