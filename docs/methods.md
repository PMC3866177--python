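# Methods

## Model structure and assumptions

The model is a deterministic compartmental ODE system in the system-dynamics
tradition: two closed age groups (adults, children), each split into
normal-weight, overweight and obese stocks held as proportions that sum to 1
per group. There is no demography — no births, deaths, or aging between the
child and adult groups — so the two simplex constraints are exact invariants
of the dynamics, and the integrator enforces them to 1e-8 at every step.

Behavioral contagion is modeled with homogeneous mixing: the flow of
normal-weight individuals into the overweight stock is proportional to their
contact with overweight/obese individuals, `β·N·(S+O)`. Because stocks are
proportions, these mass-action terms are already frequency-normalized.
Children are exposed to overweight/obese peers (β_CC) and adults (β_AC);
adults are exposed only to adults (β_AA) — child-to-adult transmission is
assumed negligible, and the adult equations contain no child stock anywhere
(a structural property the tests assert exactly). Overweight individuals
progress to obesity at constant per-week rates γ. Recovery (overweight →
normal, obese → overweight) happens only through weight-loss behaviors: the
engaged fraction (ρ for overweight, ε for obese) of a stock recovers with
average transition time p weeks, giving outflows of the form `ρ·S/p`.
Consequences: an all-normal-weight population is a fixed point (no source of
unhealthy behavior), and prevalence is weakly monotone in every transmission
rate.

## Interventions

Prevention reduces transmission rates; treatment increases the engagement
proportions. Direct impacts η (one per targetable subgroup) are coupled
across age groups additively: each total impact is the direct impact plus the
other group's corresponding impact scaled by that group's carry-over factor
(ψ_A adult→child, ψ_C child→adult), e.g. `h_NC = η_NC + ψ_A·η_NA`. The
additive form is the simplest consistent with "a proportion of" the other
group's impact; it makes totals monotone in every η and ψ and at least the
direct η, which drives the dominance properties below. Child prevention also
reduces the adult-to-child rate, attenuated by a discount factor (default
0.5, a configurable midpoint placeholder — no published value is available)
reflecting children's limited control over parental provisioning.

Effects ramp linearly: with r(t) = min(t/ramp_horizon, 1), transmission
rates scale by (1 − h·r) and engagement proportions by (1 + h·r), capped at
1 since they are proportions. Exactly seven parameters respond (β_AA, β_CC,
β_AC, ρ_AWL, ε_AWL, ρ_CWL, ε_CWL); progression rates and transition times
never do — treatment recruits more people into weight-loss behaviors rather
than making weight loss faster. A total impact that would drive a rate
negative raises an error rather than being silently clamped. The default
magnitude of 0.5 means each directly targeted parameter has changed by
exactly 50% when the ramp completes at the 10-year horizon.

The catalogs are fixed: 15 alternatives (every meaningful combination of
adult/child prevention/treatment, "ALL" being all four) and 6 scenarios
(ψ_A ∈ {0.25, 0.50, 0.75} × ψ_C ∈ {0.10, 0.25}). Two component descriptions
in the published alternative table contradict the treatment definition
(treatment described as a *decrease* in engagement, and child treatment
applied to *adults*); both are implemented per the treatment definition —
AT raises adult engagement, CT raises child engagement.

## Parameters

| parameter | meaning | default | origin |
|---|---|---|---|
| β_AA, β_CC | adult-adult / child-child transmission (wk⁻¹) | 0.0015 | midpoint of the sensitivity range 0.0011–0.0019 |
| β_AC | adult-child transmission (wk⁻¹) | 0.00225 | assumed 50% above β_CC (parental food-intake influence) |
| γ_A | overweight→obese, adults (wk⁻¹) | 0.000769 | 16% four-year cohort incidence / 208 wk |
| γ_C | overweight→obese, children (wk⁻¹) | 0.000354 | 4.3% incidence / 28 months·4.333 wk |
| ρ_AWL, ε_AWL | adult engagement proportions | 0.10 | survey-scale placeholder (see calibration) |
| ρ_CWL, ε_CWL | child engagement proportions | 0.06 | survey-scale placeholder (see calibration) |
| p_SA, p_OA | adult transition times (wk) | 56.73, 122.91 | (6.0 / 5.5)·52 and (13.0 / 5.5)·52 kg at 5.5 kg/yr |
| p_SC, p_OC | child transition times (wk) | 52, 104 | (1.7 / 1.7)·52 and (3.4 / 1.7)·52 BMI units at 1.7/yr |
| initial stocks | adults .31/.33/.36, children .665/.17/.165 | | US 2009–2010 survey-scale prevalences |
| discount | child-prevention effect on β_AC | 0.5 | placeholder midpoint |
| magnitude | ramp-complete relative change | 0.5 | the designs' stated 50% change |

Published baseline values for the engagement proportions, transition-time
inputs and initial stocks were not available, so they are placeholders in
the realistic survey range, fixed by a single calibration: the
no-intervention 10-year run must reproduce the observed US pattern of
childhood overweight+obesity prevalence growing by a factor of roughly 1.5–2.
The defaults give a growth factor of 1.956 (33.5% → 65.5%), and the baseline
end state matches the ~66% scale of the published scenario figures. Because
the exact published baselines are unknown, the sweep's absolute final
prevalences (here 47.4–61.7% across Scenario 6) are comparable in scale but
not digit-for-digit with the published ranking table, and near-ties at the
top of that table (AP vs AT as worst alternative, 65.01 vs 64.60 in the
published run) can resolve in either order. All structural conclusions —
every alternative beats baseline, supersets beat subsets, ALL is best
everywhere, child-only alternatives are invariant to ψ_A and adult-only
child outcomes to ψ_C, and adult-containing alternatives improve as ψ_A
rises — are parameter-independent consequences of the model algebra and are
what the test suite asserts.

## Parameter estimation and synthetic records

`progression_rate` is incidence/horizon; the transition times scale a
one-year treatment effect (5.5 kg for adults, 1.7 BMI units for children) by
the change needed. The child formula consumes an already growth-chart-
adjusted summary BMI decrease; BMI-percentile machinery is out of scope.
Engagement is estimated from individual survey-style records with a strict
conjunction: on a weight-loss diet AND ≥ 250 weekly minutes of moderate plus
vigorous recreational activity (days/week × minutes/day, summed across both
intensities).

The synthetic-record generator emulates only the features this estimator
reads: group membership, a diet flag, and the four activity fields. Exactly
⌊target·n⌋ records per group qualify by construction; non-qualifying records
fail the diet criterion, the activity criterion, or both. It does not
emulate survey weights, item nonresponse, measurement error, or correlation
between diet and activity — so passing estimation tests demonstrates the
estimator's arithmetic on clean records, not robustness to real survey
artifacts. Generation is deterministic given a seed.

## Numerical choices

Fixed-step forward Euler with dt = 0.25 weeks is the default integrator,
matching the convention of the desktop system-dynamics tool the model
family is normally built in and making runs bit-for-bit reproducible;
classical RK4 is available and agrees with Euler to < 1e-4 at the horizon
on default parameters. With transmission and progression off the system is
linear, and RK4 matches the matrix-exponential solution to 1e-6 over 520
weeks — the suite's closed-form oracle. Time-varying parameters enter
through a schedule evaluated at substep times (t, t+dt/2, t+dt for RK4).
Stocks are clipped to [0, 1] only after a tolerance check: a stock below
−1e-6 or a group sum off by more than 1e-8 aborts the run (step size too
large or invalid inputs) instead of being silently repaired. Ranking ties
break alphabetically by alternative name. Degenerate inputs are rejected at
construction: zero transition times, proportions outside [0, 1], states off
the simplex beyond 1e-9, empty estimation groups, a zero initial prevalence
in the growth factor.

Problem sizes: the default experiments are exactly the study designs — 25
sensitivity runs and 90 intervention runs plus one shared baseline, each a
520-week integration at dt = 0.25 (2080 steps), all completing in seconds.
Unit tests use shorter horizons (104–260 weeks) where only structure, not
the 10-year endpoint, is under test.

## Known limitations

Homogeneous mixing ignores network clustering; the model is deterministic
and unsuited to significance testing between alternatives; intervention
resourcing, cost, supply and demand are outside the model boundary; the
single linear ramp cannot express staged or time-varying intervention
schedules; and absolute prevalence levels inherit the uncertainty of the
placeholder baselines above.
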