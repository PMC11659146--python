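# Methods

## Model structure

A cohort of previously untreated advanced-HCC patients is followed over 120
monthly cycles (10 years) through three mutually exclusive states:
progression-free on first-line therapy, progressed disease, and death. Two
first-line strategies are compared: camrelizumab (200 mg IV every two weeks)
plus rivoceranib (250 mg orally daily), and sorafenib (400 mg orally twice
daily).

State membership is governed by the arms' overall-survival (OS) and
progression-free-survival (PFS) curves, modelled as log-logistic,
`S(t) = 1/(1 + λ t^γ)` with `t` in months. The shape/scale pairs in the
bundled input file imply medians of ≈24.2 / 15.6 months (OS) and
≈5.7 / 3.4 months (PFS) for the combination and sorafenib arms — matching
the CARES-310 trial medians, which is the check that fixes the time unit
and the `month^-γ` scale convention. The log-logistic family was chosen as
the best information-criterion fit among six candidates (Weibull,
log-normal, log-logistic, gamma, Gompertz, exponential); the `ipd` module
re-enacts and validates that selection on synthetic data (below). With
γ > 1 the family has a rising-then-falling hazard and a heavy tail —
S(120 months) is ≈8% (combination OS) and ≈3% (sorafenib OS), so tail
assumptions matter for absolute totals.

Two occupancy constructions are implemented and tested to agree within 2%:

- **partitioned survival** (default): `occ_PFS = min(S_PFS, S_OS)`,
  `occ_dead = 1 − S_OS`, progressed = remainder. If `S_PFS` exceeds `S_OS`
  by more than 1e-6 a warning reports the maximum violation (it does not for
  the bundled inputs; the clamp guarantees non-negative occupancy).
- **state transition** (semi-Markov): per-cycle conditional probabilities
  `1 − S((t+1)Δ)/S(tΔ)`, with the death hazard taken from the OS curve in
  both alive states and PFS exit from the PFS curve. Because both alive
  states share the OS hazard, overall survival reproduces `S_OS` exactly;
  the per-cycle probabilities compose back to the survival function to
  1e-12 (a tested identity).

## Accrual rules

Per cycle, at start-of-cycle occupancy (or the start/end average when the
half-cycle correction is on):

- progression-free: first-line drug acquisition cost plus routine
  follow-up ($60.98/cycle), and `u_PFS = 0.76` × 1/12 QALY;
- progressed: `u_PD = 0.68` × 1/12 QALY; the fraction of progressors who
  receive second-line therapy (33% combination arm, 48% sorafenib arm, from
  trial-reported subsequent-therapy uptake) accrues the mix-weighted
  second-line cycle cost (lenvatinib $650.76 / sintilimab+bevacizumab
  $455.56, 50/50 by default since no split is published), the rest best
  supportive care ($367.71/cycle);
- cycle 0: expected one-time management cost and a one-cycle additive
  disutility for each grade 3/4 adverse event reported at >10% frequency,
  weighted by incidence. AST/ALT elevations have no published disutility
  and default to 0 (cost only).

Drug cost per cycle: combination = 2 × $438.19 (camrelizumab 200 mg) +
`days_per_cycle` × $15.67 (rivoceranib 250 mg); sorafenib =
`days_per_cycle` × 4 × $13.36 (200 mg tablets). Discounting uses
`(1+r)^(−months/12)`, r = 3%/year (0–5% in sensitivity).

Configurable accounting flags, each defaulted and documented because the
convention is genuinely open: occupancy mode (above); half-cycle correction
(off by default, matching cycle-start cohort accounting); `days_per_cycle`
(30.4375 = 365.25/12 by default, 28 mirrors the 28-day regimen cycle);
`subsequent_duration_cycles` (second-line therapy until death by default; a
finite duration caps the recipient pool by a capped convolution of PFS-exit
inflows, ignoring differential mortality among recipients).
`engine.scan_configurations` evaluates the full flag grid and records which
configuration lands closest to any external reference totals.

## Comparative statistics

ICER = ΔC/ΔE with dominance labels for the off-diagonal sign cases and an
undefined flag at ΔE = 0; NMB = WTP·E − C; a strategy is called
cost-effective at a threshold when ICER ≤ WTP (boundary inclusive). NMB is
linear in WTP and the two arms' NMB lines cross exactly at ΔC/ΔE — the
identity behind reading the CEAC crossing against the base-case ICER.

## Sensitivity analysis

**One-way:** every input with a published range (12 costs, 2 utilities, 3
disutilities, 10 adverse-event incidences) is set to its low/high bound
(the printed ranges equal baseline ±20% up to print rounding; ±20% is used
where no range exists), plus a 0–5% discount-rate sweep — 28 parameters.
Probabilities perturbed outside [0,1] are clamped and logged. Survival
parameters carry no published range or distribution and are held fixed.
The tornado ordering is by ICER spread.

**Probabilistic:** 10,000 draws, all parameters sampled jointly
independently — costs from their gamma distributions, utilities,
disutilities and the discount rate from beta, adverse-event incidences from
the gamma distributions they were published with (fidelity over the beta
convention), clamped to [0,1] with clamps counted. Cost and utility rows
are shared between arms within a draw; incidences are arm-specific.
Survival curves stay fixed, so traces are computed once and only accrual is
re-run per draw. Acceptability at a threshold is the fraction of draws with
higher combination NMB (exact ties count 0.5); results are bit-for-bit
reproducible under a fixed seed and a fixed sampling order. Every gamma/beta
row's mean reproduces its printed baseline within 0.5%, verified
exhaustively, except three adverse-event rows whose printed parameters are
internally inconsistent with their printed baselines (combination
platelet-count 0.1089 vs 0.11, combination hand-foot syndrome 0.1152 vs
0.12, sorafenib ALT 0.0288 vs 0.03); the printed distributions are sampled
as printed and the discrepancy is asserted, not hidden.

Independent sampling is a limitation: no correlation structure (e.g. between
an event's incidence and its management cost) is imposed because none is
published.

## Pseudo-IPD pipeline (synthetic provenance loop)

The survival inputs originate from digitized trial curves turned into
hypothetical individual patient data and refitted. The `ipd` module
re-enacts that chain on synthetic data so it can be validated against known
truth: (1) event times drawn from log-logistic truth by inverse transform
`t = ((1−u)/(λu))^{1/γ}` with administrative censoring (defaults: 500
subjects/arm, 36-month cut-off — trial-scale numbers); (2) the product-limit
curve plus monthly numbers at risk, i.e. exactly what digitization yields;
(3) a Guyot-style inversion back to patient-level data — per
inter-checkpoint interval the censoring count is found iteratively so the
running at-risk count matches the risk table, censoring times are spread
uniformly, and step-wise event counts track the published curve (round-trip
sup-norm < 0.02 at n = 300, tested with and without interior dropout);
(4) censored maximum likelihood for all six families (Nelder-Mead on
log-transformed parameters; closed form for the exponential; Gompertz
fits with a survival plateau above 20% are rejected for simulation use);
(5) AIC selection (BIC available), exact ties broken by a fixed family
ordering.

What this validates — and what it does not: at n = 5,000 uncensored the
log-logistic MLE recovers (γ, λ) within 5%, and the generator, estimator
and selector are mutually consistent. At trial scale (n = 500, 36-month
censoring) the *shape and median* are recovered within 15% in essentially
every replicate, but the raw scale λ = median^(−γ) amplifies shape noise
about three-fold, and AIC cannot reliably distinguish log-logistic from
gamma or log-normal at that sample size (true-family selection ≈65–90% per
curve). Passing the synthetic loop therefore demonstrates correctness of
the machinery, not that a single trial-sized dataset pins down the family
or the tail.

## Numerical choices

Trapezoidal integration on the (optionally refined) cycle grid for
restricted means; with the half-cycle correction on, the engine's accrual
is exactly the trapezoid rule, which is the tested limit identity
(u_PD = u_PFS ⇒ total QALYs = u × discounted restricted mean OS / 12).
Occupancy conservation holds to 1e-9 per cycle; curve exhaustion (S = 0)
maps to an absorbing transition probability of 1. Monetary values are USD
throughout (inputs pre-converted at 7.05 RMB/USD, kept as metadata).

## Known limitations

- **Absolute totals are not externally reproducible from the printed
  inputs.** The published analysis this model re-implements reports
  per-arm totals whose implied discounted mean OS (≈15.5 months for
  sorafenib) is far below what its own printed log-logistic parameters
  produce (≈23.5 months); no documented accounting convention bridges that
  gap, which is why the acceptance suite's base-case comparison is expected
  to flag it. Incremental quantities — the decision-relevant ones — are
  much less affected (ΔC within ~10%, ICER within ~15% of the published
  values), and every threshold verdict and robustness conclusion
  (one-way ICERs below the low-income WTP; acceptability ≈99/100/100% at
  the three thresholds) is reproduced.
- Dosing arithmetic assumes full adherence, no dose reductions, no vial
  sharing or wastage, and body-size-independent pricing.
- Treatment is until progression (drug cost rides on PFS occupancy); no
  separate time-on-treatment curve is modelled.
- The synthetic data generator emulates administrative censoring only by
  default; real trials also have dropout (the reconstruction handles it,
  the generator adds it only on request).
- Two-strategy comparison only; no efficiency frontier, EVPI, or
  correlated/bootstrap propagation of survival-parameter uncertainty.
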