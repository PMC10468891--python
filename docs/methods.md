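# Methods

`triagecea` implements a decision-analytic cost-effectiveness analysis of
a data-driven pediatric sepsis triage program evaluated in a pre/post
trial at a Ugandan regional referral hospital.  This note documents the
model, its assumptions, the defaults, and what the synthetic data do and
do not establish.

## The decision model

Each enrolled child follows a single-episode decision tree:

1. **Triage and admission.** A child presents at the outpatient
   department and is admitted with probability `p_admit`.
2. **Inpatient episode.** Admitted children stay a mean of `mean_los`
   days and die in hospital with probability `p_inhosp_death`
   (conditional on admission).
3. **Post-discharge pathway.** Every child leaving the hospital alive —
   whether discharged after admission or never admitted — follows one of
   three pathways within seven days: readmission at any facility
   (`p_readmit`), outpatient care without admission (`p_care_no_admit`),
   or no further care.  Pathway probabilities are conditional on leaving
   alive.
4. **Seven-day mortality.** Children leaving alive die within seven days
   with probability `p_7day_death`, applied marginally and independently
   of the pathway (the trial reports both as marginal rates without a
   cross-tabulation; independence is the assumption).

The tree has 13 terminal nodes whose probabilities multiply along
branches and sum to one (enforced to 1e-12).  Each terminal carries:

- **Costs by perspective.** Every child incurs one outpatient visit;
  admission adds per-diem × stay; readmission adds per-diem × readmission
  stay; outpatient care without admission adds one further visit.
  Government and patient (out-of-pocket) unit costs are separate columns
  of the schedule.  Caregiver productivity losses — missed workdays per
  resource-use stratum × the average daily wage — sit on the patient
  side; the societal perspective is the exact sum.  Deaths are charged
  the same pathway costs as survivors (no terminal-care premium: none is
  reported).
- **Years of life lost.** Each death loses the gap between life
  expectancy `L` and mean age at death `a`, discounted annually at rate
  `r` starting one year after death:
  `YLL = Σ_{t=1..⌊T⌋} (1+r)^(-t) + frac(T)·(1+r)^(-⌈T⌉)`, `T = L − a`.
  For integer `T` this is the closed form `(1−(1+r)^(-T))/r`.  No age
  weighting.  Disability (years lived with disability) is out of scope —
  no validated sepsis disability weights exist for this setting.

The intervention arm additionally carries the per-child program cost on
the government ledger: one-off program capital (infrastructure, shared
consumables, set-up wages; UGX items converted at the 2021 average rate
of 3587.075 UGX/USD and inflated by GDP-deflator ratio) is annuitized
over the five-year program horizon at 3% and divided by the 28,000
children presenting annually.  With the default items this is
$1369.82/year ≈ $0.05 per child.

Incremental results are scaled per 1000 children:
`ΔE = 1000·(YLL_pre − YLL_post)` (YLL averted), `ΔC = 1000·(C_post −
C_pre)` per perspective, and `ICER = ΔC/ΔE`.  A negative ICER with
positive ΔE means the program is cost-saving and more effective.

### Mortality modes

The default (`observed_mortality`) uses each arm's observed mortality
probabilities directly — in the trial, total mortality improved
significantly even though the primary process outcome (timely sepsis
bundle within one hour) did not move.  A second mode (`bundle_linked`)
derives the intervention arm's mortality from the control arm's via a
literature odds ratio applied to the change in timely-bundle receipt:
`odds_post = odds_pre · OR^Δbundle`.  With the trial's observed
Δbundle = 0 this mode reproduces the control arm's mortality exactly;
it exists for projecting scenarios where the process outcome does move.

## Probabilistic sensitivity analysis

Parameter uncertainty is propagated with Monte Carlo (default 10,000
draws), using standard PSA families, sampled independently:

- **Probabilities ~ Beta(events, n − events)**, parameterized directly
  from the trial counts.  The two pathway probabilities are drawn
  independently; the rare draw whose sum exceeds one is redrawn (capped,
  counted, and reported).
- **Costs, wages, stays, missed days ~ Gamma**, moments matched to the
  mean and normal-theory 95% CI (σ = width/3.92).  A zero-width CI is a
  point mass, which is how the PSA degenerates to the deterministic
  model for testing.
- **Mean age at death ~ Normal truncated at zero**, from 2.0 (0.7–3.0)
  years; truncation lifts the mean slightly above 2.0 (immaterial at
  this σ).

Each draw evaluates the full tree for both arms (the tree arithmetic is
vectorized over draws, so 10,000 iterations take about two seconds on
one CPU).  Summaries: mean ΔE and ΔC with 2.5/97.5 percentile intervals;
the headline ICER as mean ΔC / mean ΔE — the identity the trial's
reported "average ICERs" satisfy — with the mean of per-draw ratios also
reported; cost-effectiveness plane quadrant shares (southeast = more
effective and cost-saving = economic dominance); and the CEAC, the share
of draws with non-negative net monetary benefit `λ·ΔE − ΔC` over a λ
grid of $0–1000 (step 1) always containing the two decision thresholds:
the health-opportunity-cost threshold $174.12 and the WHO 1×GDP-per-
capita threshold $883.89 (2021 USD).  The threshold report states the
probability of cost-effectiveness at both and the smallest grid λ
reaching 95%.

## Sensitivity scenarios

Each scenario transforms the base case, then reruns the full PSA:

- **Annuitization rate 0%/1%/5%** re-prices the per-child program cost
  only; YLL discounting stays at 3% (the scenario varies annuitization,
  not outcome discounting).
- **No sustainability**: the program stops at study end; full capital is
  charged un-annuitized against the study cohort (1942 intervention-
  phase children), and only study-window costs and YLL count.  The
  study-cohort denominator (not the five-year throughput) is the chosen
  reading.
- **Low-volume month exclusion**: months whose enrollment is strictly
  below 50% of the phase's median monthly count are dropped from the
  patient-level records, and the phase inputs re-aggregated.  The rule —
  not any particular month list — is the algorithm.
- **Admission penalty** 25/50/75%: the absolute reduction in the
  admission rate is shrunk by the penalty,
  `p_post' = p_pre − (1−penalty)·(p_pre − p_post)`, applied per draw;
  downstream conditional probabilities are untouched.  This probes how
  much of the admission reduction (partly attributable to pandemic-era
  care-seeking shifts) must be genuine for cost-effectiveness to hold.

Scenario ICERs (mean, 2.5/97.5 percentiles of per-draw ratios) are
collected into the table behind a tornado diagram, base case first.

## Statistical summaries of the trial

Proportions carry Wilson score 95% intervals by default
(Clopper–Pearson selectable).  Wilson was fixed after checking which
method reproduces the published intervals: reconstructing events as
round(rate × n) for every table proportion whose denominator is printed,
Wilson reproduces 9 of 10 printed intervals at one-decimal rounding;
Clopper–Pearson 7 of 10.  Contrasts report the risk ratio (Katz
log-normal CI), absolute difference in percentage points (Wald CI), and
a chi-squared test without continuity correction, replaced by Fisher's
exact test when any observed 2×2 cell is below five (an expected-count
rule is available behind a flag; the observed-cell rule is the literal
reading of the trial's description).  Continuous outcomes (stays, missed
days) use t-based intervals, degenerate-flagged at n < 2.

## Synthetic data

The generator emulates the statistical structure of the trial's tables:
phase sizes 1402/1942; admission 22.3%→13.9%; in-hospital mortality
2.9%→1.1% of admitted; 7-day mortality 0.2%→0.1% of those leaving alive;
readmission and care-seeking rates; timely bundle 0.7% in both phases;
<2% loss to follow-up; mean stays of 4 days; and the six missed-workday
strata means (4/2/12/6/6/4 days).  Default counts are reconstructed from
the printed rates (events = round(rate × n)); the published sub-rates
compose to a pre-phase total mortality of 12/1402 (0.86%, printing as
0.9%).  Day counts use a shifted Poisson `1 + Poisson(mean − 1)` —
positive, integer, mean exactly as configured; the trial prints only
means and CIs, not distributions.  Ages and enrollment months are
generated for realism (months uniform across each phase's nine-month
window) and do not enter the economic model; children lost to follow-up
retain their true trajectory and are only flagged (complete-case
default, matching the <2% loss).

What passing tests on synthetic data do **not** show: the generator
assumes marginal independence of 7-day mortality and care-seeking,
homogeneous within-phase rates over months (except when engineered),
and no seasonal or severity structure; real trial data could violate
any of these.  Parameter-recovery tests (4 standard errors at
n = 10,000) validate the pipeline's arithmetic, not the trial's data.

## Unpublished inputs and what is reproducible

The facility unit costs (from a vaccine-economics costing survey), the
ILO daily wage, the life-expectancy figure, and the literature odds
ratio behind the published analysis are not printed in it.  The shipped
configuration therefore carries a synthetic-but-plausible schedule
calibrated to published anchors: government spending of $7–12 per
pediatric pneumonia admission, out-of-pocket fees near $15 per
admission, an average monthly wage of about $57 (daily wage $3.075,
consistent with the printed productivity-cost-to-days ratios), life
expectancy 62.85 years, OR 0.64.  Consequently the package reproduces
the published *ratio identities* (ICER = ΔC/ΔE at the printed values),
the bivariate statistics, and the program-cost arithmetic exactly, and
the *qualitative* result — southeast-quadrant dominance and cost-
effectiveness far below both thresholds — robustly; the absolute
incrementals and quadrant percentages depend on the unpublished inputs
and are not numeric targets.

## Numerical choices

- Annuity factor computed with `expm1`/`log1p` (stable as r → 0⁺;
  agrees with total/n to 1e-6 at r = 1e-9).
- Terminal probabilities asserted to sum to 1 within 1e-9 at every
  evaluation (1e-12 in tests).
- All randomness flows from one root seed through `numpy`
  `SeedSequence.spawn`, one child stream per pipeline stage; reruns with
  the same config and seed are byte-identical in every CSV.
- Money is serialized at full precision in machine-readable outputs and
  two decimals in printed reports; table exports round percentages to
  one decimal to mirror the published layout.
- Degenerate inputs are flagged, not silently dropped: empty
  denominators yield `None` plus an `undefined` marker; n = 1 means get
  degenerate CIs; ICER with ΔE = 0 is flagged undefined while ΔC is
  still reported.

## Known limitations

Single-episode tree (no Markov extension, no survivor lifetime costs);
no disability weights; independence of sampled parameters (no
correlation structure); opportunity costs beyond wages (livestock, crop
losses) uncounted; costs within the seven-day episode are not
within-year discounted (episode ≪ 1 year); the unit-cost schedule is
synthetic and the absolute cost results shift with it.
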