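# casemix

Tools for evaluating hospital payment-policy reforms with routinely coded
discharge data.  The package targets the setting of a national payer that
reimburses contracted hospitals and monitors the complexity of the cases
they admit through a **casemix index (CMI)** — for example a
pay-for-performance reform that ties hospital reimbursement tiers to case
severity, intending to discourage unnecessary admissions of low-severity
cases.  It is written for health-systems researchers and payer analysts who
have patient-level hospitalization records (diagnosis and procedure codes,
stay lengths, charges) and want a reproducible pipeline from raw records to
impact estimates.

## What it computes

**Weights and CMI.**  Every ICD-10 discharge diagnosis *g* gets a weight
from multi-year average charges within its stay stratum (short <2 days,
medium 2–15, long >15): W_g = mean charge / reference cost, where the
reference is the grand mean charge over all medical cases in the
weight-setting window; diagnoses with fewer than 20 cases take their
stratum's case-weighted average weight.  Surgical procedures have flat
fees: W_g = fee / 1,000,000 LBP, capped at 10.00.  The monthly index for a
stratum is

```
CMI = Σ_g W_g · N_g  /  Σ_g N_g
```

with N_g the number of included cases carrying code *g* in that discharge
month.  Chemotherapy session codes (Z51.1, Z51.2) are excluded by default.

**Impact estimation.**  A single-group interrupted time series with
calendar-month seasonality adjustment,

```
Y_t = β₀ + β₁·T_t + β₂·X_t + β₃·(T_t − T_I)·X_t + Σ_m γ_m·M_mt + ε_t
```

where X_t switches on at the intervention month plus a behavioural lag
(default 2 months), so β₂ is the level change at the first post-lag month
and β₃ the change in monthly trend.  Inference uses Newey–West HAC standard
errors (Bartlett kernel, small-sample corrected); residual serial
correlation is checked with the Cumby–Huizinga test and the HAC bandwidth
escalates when it rejects.  Relative changes are reported against the
starting level β₀.

**Attribution.**  Pre/post windows (default 2013–14 vs 2015–16) are
compared code by code: WN0 and WN1 are the code's weighted case volumes in
each window, the Code Count Effect CCE = [(WN1 − WN0)(W_g − CMI_ref)]²
ranks codes by the magnitude of their impact on the CMI in either
direction, and each code's attributable share is CCE_g / ΣCCE.

**Synthetic data.**  Because real claims extracts are access-restricted, a
generator emulates their structure — seasonal monthly volumes, a
55/43/2 medical/surgical/mixed case mix, a public/private hospital split,
per-code log-normal charges — with injectable intervention effects:
diagnosis recoding (e.g. cancer codes corrected to Z51.1), declining
admissions for low-severity diagnoses, and medium-to-short stay shifting.

## Worked example

```python
import casemix as cx
from casemix import its

scenario = cx.preset_paper_like(monthly_volume=1000, seed=0)
records = cx.generate(scenario)                      # 72,209 records, 2011-2016
weights = cx.build_weight_table(records, (2011, 2016), cx.fee_schedule(scenario))
series = cx.monthly_cmi(records, weights, "medical")  # 72 monthly points

fit = its.fit(series, its.ItsConfig(intervention_month="2014-08", lag_months=2))
print(fit.summary().head(4).round(4))
```

```
              estimate  hac_se  ci_low  ci_high  p_value
level_start     1.0241  0.0090  1.0060   1.0421   0.0000
trend_pre      -0.0002  0.0002 -0.0005   0.0002   0.3317
level_change    0.0191  0.0089  0.0013   0.0370   0.0361
trend_change    0.0011  0.0006 -0.0000   0.0023   0.0556
```

The medical CMI starts near 1.02, is flat before the intervention, jumps by
+0.019 (≈1.9% of the starting level, p = 0.04) two months after the
August-2014 intervention — driven by chemotherapy recoding moving low-weight
cases out of the index — and afterwards trends upward by ≈0.001/month as
admissions for low-severity diagnoses decline.

```python
ctx = cx.AttributionContext(weights=weights, case_type="medical", stay="medium")
top = cx.top_k(cx.attribute(records, ctx), 3)
print(top[["rank", "code", "n_pre", "n_post", "change_pct", "attributable_pct"]].round(1))
```

```
   rank   code  n_pre  n_post  change_pct  attributable_pct
0     1  A41.9    313     357        14.1              92.3
1     2    I50    430     466         8.4               3.1
2     3  J18.0    761     817         7.4               0.9
```

High-weight codes dominate the squared CCE ranking: a 14% rise in
septicaemia (A41.9, weight ≈3) moves the medium-stay CMI more than larger
relative swings in codes whose weight sits near the reference.

The same stages are available from the shell:

```
casemix simulate --out records.csv --seed 4 --volume 1000
casemix weights  --records records.csv --window 2011-2016 --out weights.csv
casemix cmi      --records records.csv --weights weights.csv --out series.csv
casemix its      --series series.csv --intervention 2014-08 --lag 2 --out its/
casemix run      --seed 4        # full pipeline with the default profile
```

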