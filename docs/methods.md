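# Methods

This note documents the models implemented in `uratetrial`, the default
parameter values and why they were chosen, the numerical schemes, and what
the synthetic defaults do and do not represent.

## 1. PK/PD model (`uratetrial.pkpd`)

### Drug kinetics

Both drugs use linear compartmental PK with first-order oral absorption,
solved analytically: a single oral dose produces a two-exponential (one
compartment; the Bateman function) or three-exponential (two compartments)
concentration profile, and a dosing history is the superposition of the
taken doses. The degenerate case of coinciding absorption and disposition
rate constants is handled by nudging the absorption rate by 1e-7 relative,
which perturbs the profile by a comparable (negligible) amount. Multi-dose
profiles on the integration grid use a per-day amplitude recursion per
exponential term — exact for exponentials and linear in trial duration.

### Urate turnover and drug effect

Serum uric acid responds to drug through a three-state indirect-response
chain in concentrations (mg/L), with volumes `v_*` (L), renal clearances
`clr_*` (L/day), oxidase rate constants `k_hx_x`, `k_x_ua` (1/day), and
zero-order production `kin` (mg/day):

    hx' = kin/v_hx           − (k_hx_x·(1−I) + clr_hx/v_hx)·hx
    x'  = k_hx_x·(1−I)·hx·v_hx/v_x − (k_x_ua·(1−I) + clr_x·(1+S)/v_x)·x
    ua' = k_x_ua·(1−I)·x·v_x/v_ua  − (clr_ua/v_ua)·ua

with `I(C) = Imax·C/(IC50 + C)` applied to both oxidase steps and
`S(C) = Emax_x·C/(EC50_x + C)` (febuxostat only) stimulating xanthine renal
excretion. This is the minimal chain consistent with xanthine-oxidase
inhibition: blocking the oxidase diverts purine flux to renal excretion of
the precursors, lowering urate. The steady state has the closed form

    ua_ss = kin · f1 · f2 / clr_ua,
    f1 = k(1−I)v / (k(1−I)v + clr_hx),   f2 analogous with clr_x(1+S),

used as an independent oracle for the integrator and for per-subject
baseline calibration: `kin` is rescaled in closed form so the drug-free
steady state equals the subject's observed baseline sUA (the steady state
is linear in `kin`).

### Covariates and interindividual variability

Individual parameters are population value x covariate multiplier x
exp(eta). Clearances scale with (weight/70)^0.75, volumes with weight/70,
and renal clearances carry a log-linear age effect (−0.004/year around age
50) — standard pharmacometric conventions, all config-overridable. Random
effects eta are mean-zero normal on the log scale with SDs (omega) given in
the population spec; `Imax` is excluded from both perturbation and IIV to
respect its [0, 1] bound. Intra-individual (residual) variability is not
simulated: the endpoint is a deterministic function of the individual
parameters and dosing history.

### Numerics

The chain is integrated with classical RK4 at a fixed step of 0.1 day
(concentration sampled on the half-step grid), starting from the drug-free
steady state. The two concentration-driven forcing grids (oxidase
inhibition, xanthine-excretion stimulation) are precomputed in single
precision — they modulate rates of order 1/day, so the ~1e-7 relative
rounding is far below the verification tolerances — while all state
arithmetic is double precision. Verified accuracy: terminal sUA under
constant exposure agrees with the analytic steady state to ~3e-4 relative;
drug-free simulations hold the baseline exactly. Daily troughs are reported
at t = 1..duration, immediately before the next scheduled dose (the dose is
administered right after trough sampling). Units: concentrations mg/L
internally; sUA mg/dL at the interface (1 mg/dL = 10 mg/L, defined once).

### Default drug parameters

Defaults are chosen to be pharmacologically plausible and to produce the
qualitative ordering expected of the two drugs; they are placeholders for
estimated parameter sets, which can be dropped in via the configuration.

| Parameter | Allopurinol | Febuxostat | Rationale |
|---|---|---|---|
| PK | 1-comp, ka 20/d, CL 25 L/d, V 40 L, F 0.8 | 2-comp, ka 25/d, CL 250 L/d, V1 35 L, Q 100 L/d, V2 40 L, F 0.85 | allopurinol's exposure profile stands in for its slowly eliminated active metabolite; febuxostat has fast clearance with a distribution phase |
| Imax / IC50 | 0.85 / 9 mg/L | 0.95 / 0.05 mg/L | weak vs. potent oxidase inhibition |
| Emax_x / EC50_x | — | 1.0 / 0.05 mg/L | febuxostat's stimulatory effect on xanthine excretion |

System chain: k_hx_x = k_x_ua = 3/day, clr_hx = clr_x = 50 L/day,
clr_ua = 13 L/day (≈9 mL/min, typical urate renal clearance), volumes
50/50/40 L. With a 9 mg/dL baseline this implies a purine production of
~2 g/day entering the chain and an urate half-life of ~2.1 days — the
slowest timescale, so trials reach pharmacodynamic steady state well within
the 182-day duration.

## 2. Trial execution (`uratetrial.trial`)

Cohorts are sampled from lognormal baseline sUA (median 8.6 mg/dL, log-SD
0.16, giving a 2.5–97.5% range of ~6.3–11.8) and weight (median 85 kg,
log-SD 0.18) and clipped-normal age (52 ± 11 y) — plausible for a gout
trial population. Inclusion keeps subjects with baseline **strictly above**
the threshold (6 or 8 mg/dL); the boundary is assigned to exclusion.

Adherence has three components. All patients initiate treatment. Dose
implementation is a per-day Bernoulli with a subject-specific probability,
logit-normal across subjects with the location solved numerically
(Gauss–Hermite + Brent) so the population mean is exactly 0.9 (dispersion
1.0 on the logit scale — the mean is specified, the dispersion is a
modelling choice). Discontinuation follows a Weibull hazard with shape 0.5
(falling risk) and scale 2000 days, giving ~26% discontinuation over a
26-week trial; the first missed-for-good day is the smallest integer d with
(d/scale)^shape exceeding a unit-exponential draw, so the discrete-day
survival matches the continuous Weibull at integer days exactly.
Subjects who discontinue revert to their baseline sUA exactly (and are
responders only if their baseline was already < 6 mg/dL). The endpoint is
the proportion with final trough sUA strictly < 6 mg/dL.

Both arms share the cohort (common random numbers) but draw dosing
histories from independent seed streams keyed by arm index, so either arm
is reproducible in isolation.

## 3. Uncertainty propagation and priors (`uratetrial.cts`)

Population parameters listed in the uncertainty spec are multiplied by
exp(eta), eta ~ N(0, log(1+CV²)), so the lognormal factor's coefficient of
variation equals the configured CV exactly. Defaults: CV 0.25 (base case)
and 0.10 (reduced) on absorption, clearances, volumes, potency (IC50,
Emax_x) and the chain's rate constants and clearances. Each replicate
perturbs the parameters, resamples the cohort (a config switch fixes one
cohort instead), applies inclusion, and simulates both arms; the replicate
response-rate pairs are the Monte Carlo sample of θ. Both arms share the
perturbed chain (the population physiology) within a replicate; drug
parameters are perturbed per drug.

Summaries report mean, SD (ddof = 1) and empirical 2.5/97.5 percentiles
(linear interpolation), then the method-of-moments Beta fit
ν = m(1−m)/s² − 1, α = mν, β = (1−m)ν, which reproduces the input moments
exactly. A zero-variance sample (possible in fully degenerate settings) is
reported as degenerate rather than fitted.

Scaled-down defaults are 200 replicates x 200 subjects (full-fidelity
10,000 x 1,000 behind `full_fidelity`); the scaled setting keeps the
four-stage run to a few minutes on one CPU while leaving Monte Carlo error
in the prior SD at the few-percent level. Replicates own seed-sequence
children of the master seed, so results are independent of batch size and
worker count (batching only stacks subjects for the vectorised integrator,
which is elementwise).

## 4. Economic model (`uratetrial.econ`)

A transparent default cohort model stands in for a published
gout cost-effectiveness model: states <6, 6–8, >8 mg/dL and dead; 3-month
cycles over 50 years; 3.5%/year discounting of both costs and QALYs; no
half-cycle correction (payoffs valued at cycle starts). Trial responders
enter the <6 band; non-responders split 50/50 between 6–8 and >8
(configurable). Band-specific annual flare rates (0.35, 1.2, 2.5), flare
cost £250, utilities (0.88, 0.83, 0.78), flare disutility 0.015
QALY/flare, management costs £(120, 250, 400)/year, background mortality
2%/year. Discontinuation reuses the trial's Weibull hazard; discontinued
responders are reassigned to the non-responder band mix (reverting to
baseline), and no other band transitions occur — natural-history movement
between bands is deliberately omitted for transparency. The standard-of-care
strategy carries a generic drug cost of £30/year while alive.

Expected persistence t₂ integrates the Weibull on-treatment survival times
the continuous discount factor over the horizon (composite Simpson, ~1e-10
relative accuracy; ≈4.8 discounted years at the defaults). The maximum
reimbursement price P₂ = [C₁ − C̄₂ + λ(Q₂−Q₁)]/t₂ makes the incremental
net monetary benefit exactly zero when the new drug's cost is C̄₂ + P₂t₂.
λ defaults to £20,000/QALY (the conservative end of the usual UK range;
switchable to £30,000). All economic inputs other than the treatment
response rates are held at their expected values: the payer is assumed to
decide on expectations.

## 5. ROI and sample-size choice (`uratetrial.roi`)

Expected ROI per (design, n) is a preposterior Monte Carlo: θ_j from the
prior, m_j ~ Bin(n, θ_j), conjugate update, posterior **mean** into the
economic model (a config switch samples the posterior instead — an
uncertainty-averse payer), price P₂, then

    ROI = (P₂ − C_PM)·t₂·S(H) − C_trial   if P₂ ≥ P_min,   else 0.

Trial cost is C_TF + C_TV·2n with C_TF = £5,000,000 and C_TV = £20,000 per
subject (per-subject is the conventional reading and is what makes ROI
depend on n). The market S(H) = incidence x uptake x horizon
(15,000/year x 0.5 x 10 years by default), halved for designs restricting
treatment to baseline sUA > 8 mg/dL. The termination branch returns exactly
zero — no sunk trial cost — which is economically debatable but keeps the
payoff rule as specified; ties in expected ROI resolve to the smallest n
(the cheaper trial). Because the cohort trace is linear in its initial
occupancy, per-state basis values are precomputed once and each replicate's
Q and C are dot products, making stage 4 negligible in cost.

## 6. Reproducibility contract (`uratetrial.pipeline`)

All randomness descends from one master seed through explicit
`SeedSequence(entropy=seed, spawn_key=(stage, design, ...))` children.
Stage outputs are CSVs with the configuration hash and seed in a comment
header; the hash excludes execution-only settings (output directory, worker
count, batch size), so identical configurations produce byte-identical
outputs anywhere. Stages are cached keyed by the relevant configuration
subset chained with the upstream stage key: changing the payer threshold
re-runs pricing and ROI but reuses the trial simulation.

## 7. What the synthetic defaults do and do not show

The default parameter set is synthetic: it reproduces the qualitative
structure of the case study (a potent new inhibitor vs. a weaker standard
of care, response rates more sensitive to inclusion threshold and dose for
the weaker drug, narrower priors under reduced input uncertainty, ROI of
order £10⁸ for value-dominant designs) but not any estimated model's
numbers. Passing tests therefore demonstrate correctness of the machinery —
closed forms, conjugacy, price inversion, payoff rules, reproducibility —
and the direction of the framework's comparative statics, not predictions
about febuxostat. Likewise the cohort model is a transparent stand-in, not
a published model's replica: absolute QALY/cost levels, and hence absolute
prices and ROI, move with its placeholder inputs.

Other known limitations: no intra-individual variability or measurement
error in sUA; dose implementation is memoryless (no habit structure); no
titration, interim analyses, safety outcomes, or regulatory-approval
modelling; a single payer and market; parameter uncertainties are
uncorrelated; and the economic model omits natural-history transitions
between sUA bands.
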