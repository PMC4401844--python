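# coldharvest

Time-series tools for asking how much of cold- and heat-related mortality is
*mortality displacement* ("harvesting"): excess deaths among frail people who
would have died within a few weeks or months anyway.

Daily and weekly regression studies reliably detect deaths on and shortly
after cold or hot days, but they cannot tell whether those deaths were merely
brought forward by a few months. `coldharvest` implements an annual
time-series design that is, by construction, blind to any displacement
shorter than about a year: if deaths associated with a cold winter were due
to occur anyway before the next autumn, a regression of *annual* death counts
on *annual* cold will see no association at all.

## The design

Daily mean temperature is summarised by **degree-days** around a common
threshold (default 18 °C, the minimum-mortality temperature): per day,
`cold = max(0, 18 − T)` and `heat = max(0, T − 18)`. Weeks of 7 days are
numbered sequentially from an early-October anchor and grouped into
**autumn-anchored analysis years** (the first week starting on or after
1 October begins a new year), so a winter's cold and its lagged deaths fall
in the same year; any 53rd week is dropped, leaving 52-week (364-day) years.

The **main model** is a quasi-Poisson regression of annual deaths
Y_t on annual mean cold C_t and heat H_t:

    log E[Y_t] = β₀ + β_c C_t + β_h H_t + s(t; 5 df) + γ F_t + Σ_j δ_j step_j(t)

with a natural cubic spline `s` for secular trend (1 df per decade), the
annual influenza death proportion F_t, and step indicators for
administrative/coding discontinuities. Standard errors are scaled by the
Pearson dispersion; effects are reported as percent increase in deaths per
°C, `100(e^β − 1)`, with Wald 95% intervals. A sensitivity grid varies the
family (Poisson / negative binomial / OLS on log counts), spline flexibility,
threshold (15/21 °C), steps, and influenza control.

A **weekly comparator** — a conditional quasi-Poisson model stratified by
year × month (equivalent to a time-stratified case-crossover), with cold
averaged over the index and previous week — estimates the conventional
short-lag association on the same data.

The **synthetic-data generator** plants known acute effects in a daily
series and displaces a tunable fraction *f* of the attributable excess over
a tunable horizon of *D* days. It is the package's test bed: with *f* = 0
both estimators should recover the acute effect; with *f* = 1 and *D* well
inside a year, the weekly estimator still sees the acute effect while the
annual estimator sees almost nothing.

## Worked example

```
coldharvest demo --seeds 1
```

simulates three 57-year scenarios (acute cold effect 0.02 log-rate/°C,
baseline 170 deaths/day, expected rates fed through both estimators) and
prints:

```
           scenario  seed     f    D  acute_truth_pct  annual_pct  ...  weekly_pct  ...
 f0_no_displacement     1 0.000   60            2.020       2.092         1.753
 f1_D60_within_year     1 1.000   60            2.020       0.159         1.897
f1_D400_beyond_year     1 1.000  400            2.020       1.203         2.034
```

Read the rows: with no displacement both designs recover ≈2% per °C of
annual cold. When every attributable death is displaced by up to 60 days,
the annual estimate collapses to 0.16% (8% of the truth) while the weekly
estimate keeps 94% of it — short-horizon displacement is invisible to the
annual design but not to the weekly one. When displacement stretches over
400 days, part of the deficit escapes the analysis year and the annual
estimate recovers part of the signal (1.20%).

The same machinery runs on real data: a daily CSV
(`date,tmean,deaths_all[,deaths_cvd,...,deaths_flu]`) goes through

```
coldharvest build --daily daily.csv            # weekly + annual tables
coldharvest fit-annual --daily daily.csv --steps 1965,1966
coldharvest fit-weekly --daily daily.csv
coldharvest sensitivity --daily daily.csv --out table.csv
coldharvest run --daily daily.csv --out-dir report   # everything + run log
```

and `fit-annual --annual annual.csv` accepts a pre-built annual table.

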