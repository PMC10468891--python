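# triagecea

Decision-analytic cost-effectiveness analysis of a data-driven pediatric
sepsis triage program, evaluated against baseline manual triage in a
pre/post trial at a Ugandan regional referral hospital.

Early sepsis treatment saves children's lives, but in low-resource
settings triage bottlenecks delay it.  A triage platform that
risk-stratifies children and tracks treatment delivery changes both
clinical outcomes (admissions, mortality) and costs (facility resources,
out-of-pocket spending, caregiver lost wages).  This package asks the
health-economics question: per year of life lost (YLL) averted, what
does the program cost — and from whose perspective?

It is written for health economists and trialists: every stage is a
tested library function, the trial data layer is synthetic (no data
download needed), and the whole analysis reruns from one YAML config and
one seed.

## The model

A decision tree follows each presenting child: admission (probability
`p_admit`), inpatient stay with in-hospital death risk, then for every
child leaving alive a post-discharge pathway (readmission / outpatient
care / none) and an independent 7-day death risk.  Terminal nodes carry
costs by perspective — government (facility + program costs), patient
(out-of-pocket + productivity losses), societal (sum) — and discounted
YLL per death:

    YLL = (1 − (1+r)^−(L−a)) / r        (integer horizon, r = 3%)

with life expectancy *L*, mean age at death *a*.  Incrementals per 1000
children give

    ICER = ΔC / ΔE,   ΔE = 1000·(YLL_pre − YLL_post)

and a 10,000-draw Monte Carlo probabilistic sensitivity analysis (Beta
for probabilities from event counts, Gamma for costs from CIs) yields
cost-effectiveness plane quadrant shares and the acceptability curve
(CEAC): the probability that net monetary benefit `λ·ΔE − ΔC` is
non-negative at each willingness-to-pay λ, reported at the
health-opportunity-cost threshold ($174.12) and the WHO 1×GDP threshold
($883.89, 2021 USD).  Scenario analyses re-run the PSA under alternative
annuitization rates, a no-sustainability assumption, low-volume month
exclusion, and admission-reduction penalty factors.

See `docs/methods.md` for assumptions, distributions, and limitations —
including which published quantities are reproducible exactly (ratio
identities, bivariate statistics, program-cost arithmetic) and which
depend on unpublished unit costs and are matched only qualitatively.

## Worked example

The deterministic base case, from the packaged default configuration:

```sh
$ triagecea model
{
  "program_capital_usd": 6273.37,
  "annual_program_cost_usd": 1369.82,
  "program_cost_per_child_usd": 0.05,
  "delta_cost_per_1000": {
    "government": -743.05,
    "patient": -2240.45,
    "societal": -2983.5
  },
  "delta_yll_averted_per_1000": 166.5,
  "icer": {
    "government": -4.46,
    "patient": -13.46,
    "societal": -17.92
  }
}
```

Reading: one-off program capital of $6273 annuitizes to $1369.82/year at
3% over five years — $0.05 per presenting child.  Per 1000 children, the
intervention arm averts 166.5 discounted YLL and *saves* money from
every perspective (negative ΔC), so the ICERs are negative: society
saves $17.92 per YLL averted.  The full pipeline —

```sh
triagecea all --seed 1 --out results/
```

— generates the synthetic cohorts, writes the pre/post outcome tables,
the terminal-node tables, 10,000 PSA draws with CEAC curves per
perspective, all scenario summaries, a tornado table, threshold
verdicts, and a manifest; rerunning with the same seed reproduces every
CSV byte for byte.  The library surface mirrors the stages:
`generate_phase`, `summarize_phase`/`compare_phases`, `evaluate_arm`/
`incremental_results`, `run_psa`/`ceac`, `run_scenario`/`tornado_table`.

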