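# scadcost

Healthcare utilization, cost regression and lifetime cost projection for
stable coronary artery disease (SCAD) cohorts.

Patients with stable coronary artery disease — stable angina, or patients who
have stabilised after an acute coronary syndrome — generate substantial,
highly variable healthcare costs over decades: background primary-care and
drug costs, large cost spikes around non-fatal myocardial infarction (AMI)
and stroke, ongoing post-event costs, and end-of-life costs. `scadcost`
implements, as a tested reusable pipeline, the analysis a health economist
would run on a linked-EHR SCAD extract: cohort construction, first-year and
post-event cost summarisation, covariate cost regression, a 90-day panel cost
model, and a multistate Markov engine that extrapolates 5-year and lifetime
costs by cardiovascular risk decile. Because real linked-EHR extracts are
access-controlled, a first-class synthetic-data module generates the three
input tables (patient baseline, clinical events, 90-day period costs) with
the statistical structure the estimators assume, so every stage is testable
end to end.

## The models

Everything lives on a 90-day ("cycle") grid; a model year is four cycles.

**First-year cost regression** — per-patient first-year total cost `y_i > 0`
follows a gamma GLM with log link, `E[y_i] = exp(x_i'β)`, fitted on M = 5
data sets completed by chained-equation imputation (predictive mean matching
for biomarkers) and pooled with Rubin's rules,
`T = W + (1 + 1/M)·B`. Coefficients are transformed to natural-scale £
increments by recycled prediction over the cohort.

**Panel cost model** — the mean cost of patient i in cycle t is additive on
the £ scale:

```
μ_it = α + γ·(t − 1) + x_i'δ + Σ_e band_e(t − t_e) + death increment
```

with four 90-day bands after each non-fatal event (AMI, ischaemic stroke,
haemorrhagic stroke) followed by a constant long-run increment, and a
death-period increment by cause. Estimated by pooled least squares with
patient-clustered standard errors, separately for total, CVD and CHD cost
categories (CHD ⊆ CVD ⊆ total by composition).

**Multistate model** — six clinical states (Stable, post-AMI, post-ischaemic
stroke, post-haemorrhagic stroke, CVD death, non-CVD death) realised as 18
Markov states with one-cycle tunnel states carrying the cost bands. Within a
cycle, cause-specific exponential rates `h_c = exp(β_0c + x'β_c)` give
per-cycle transition probabilities `p_c = h_c/H·(1 − e^{−H})`; the
discrete-cycle competing-risk likelihood is maximised per state.

**Lifetime engine** — a deterministic cohort trace propagates occupancy,
prices every cycle with the panel model (decedents accrue their state cost
plus the death increment), and discounts at 3.5% per annum (mid-cycle
convention, configurable). 5-year risk, survival, life expectancy, and
5-year/lifetime total/CVD/CHD costs are reported per covariate profile;
an independent microsimulation oracle validates the trace. Representative
profiles are built per 5-year-risk decile (continuous covariates by mean,
binary by prevalence).

## Worked example

```python
import scadcost as sc

cfg = sc.default_config(n_patients=20000, seed=1)
tables = sc.simulate(cfg)
windows = sc.build_analysis_windows(tables["baseline"], tables["events"])

costs = sc.summarize_costs(tables["period_costs"], windows, "first_scad_year")
print(f"first-year mean total cost: £{costs.mean('total_cost'):.0f} "
      f"(CHD share {costs.shares['chd']}%, CVD share {costs.shares['cvd']}%)")

panel = sc.fit_panel_triplet(tables["period_costs"], tables["events"], tables["baseline"])
ami = panel["total"].event_increments["ami"]
print(f"90-day baseline cost £{panel['total'].baseline_cost:.0f}, "
      f"trend £{panel['total'].period_trend:.1f}/cycle")
print(f"AMI increments: event cycle £{ami.band_1:.0f}, long run £{ami.long_run:.0f}, "
      f"first year £{ami.first_year_total:.0f}")

ms = sc.MultistateModel(tables["baseline"], tables["events"]).fit()
from scadcost.reporting import build_decile_profiles, project_deciles, build_table3
profiles = build_decile_profiles(tables["baseline"], ms.transition_params)
projections = project_deciles(profiles, ms.transition_params, panel)
table3 = build_table3(profiles, projections)
print(table3[["decile", "five_year_risk_pct", "life_expectancy_years",
              "five_year_total", "lifetime_total"]].to_string(index=False))
```

prints

```
first-year mean total cost: £1959 (CHD share 56.7%, CVD share 66.9%)
90-day baseline cost £340, trend £10.0/cycle
AMI increments: event cycle £5155, long run £520, first year £7745
 decile  five_year_risk_pct  life_expectancy_years  five_year_total  lifetime_total
      1                3.48                  29.17             7332          165030
      2                5.92                  20.46             7902           97546
      3                7.72                  16.82             8224           73373
      4                9.42                  14.52             8516           59905
      5               11.24                  12.63             8705           49554
      6               13.24                  11.01             8954           41669
      7               15.65                   9.55             9181           35136
      8               18.74                   8.12             9448           29354
      9               23.25                   6.60             9796           23862
     10               33.64                   4.40            10336           17072
```

The generator's ground truth is the published 90-day cost structure (£341
baseline rising £10 per cycle, £5028 AMI event-cycle increment decaying to
£521 per cycle long-run), which the panel estimator recovers; and the decile
table reproduces the analysis' central qualitative finding: higher-risk
patients have higher 5-year costs (events are expensive) but lower lifetime
costs (they do not live long enough to accrue the background stream).

A command-line interface wraps the same pipeline:

```bash
scadcost simulate --out run/ --seed 1 --n-patients 20000
scadcost build-cohort --in run/
scadcost summarize --in run/
scadcost fit-costs --in run/ --m 5 --seed 1
scadcost fit-panel --in run/
scadcost fit-transitions --in run/
scadcost project --in run/ --profile profile.json --horizon 400 --rate 0.035
scadcost run-all --out run/ --seed 1      # everything above in one shot
```

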