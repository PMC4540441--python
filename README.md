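# reefrisk

Expert-elicited spatial Bayesian network for multi-stressor coral-reef risk
assessment. `reefrisk` predicts, for individual Great Barrier Reef mid-shelf
reefs, the probability that hard coral cover declines below present levels
over a ten-year horizon, under combined climate-change and local-management
scenarios. It is aimed at conservation scientists and marine-park analysts
who need spatially explicit, decision-support-grade risk maps from limited
data plus structured expert judgment.

## The model

Each reef is described by nine environmental layers (temperature anomaly,
cyclone exposure, flood-plume exposure, nutrient / sediment / pollutant
loads, irradiance, crown-of-thorns outbreak history, fishing effort). All
layers except temperature are re-coded into three ordered states — ≥ 1 SD
below average, within 1 SD, ≥ 1 SD above — while temperature anomalies use a
fixed bleaching-relevant ±1 °C threshold. A discrete Bayesian network links
this evidence to the binary outcome *C* (coral-cover decline) through latent
stress events *E* ∈ {bleaching, disease, CoTS outbreak} and two weighted
composite indices (water quality, anthropogenic stress):

P(C = decline | **x**) = Σ_E P(C | E, x_cyc, A(**x**)) · Π_e P(E_e | pa(E_e))

computed by exact variable elimination (the network is tiny; nothing is
approximated). CPTs for elicited nodes come from expert judgment via the
4-point method: each expert states (lowest, best, highest, confidence) for
the node's state probabilities at the two parent-configuration extremes
("all stressors low" vs "all stressors high"); intervals are standardized to
a common credible level, best estimates are pooled across experts, and the
full table is filled by linear interpolation in the mean normalized parent
ordinal *s* ∈ [0, 1]:

p(s) = (1 − s) · p_low + s · p_high.

Three parameterizations are built per elicited quantity: the group **mean**,
and **pessimistic** / **optimistic** variants from the 25th/75th percentiles
oriented so that "pessimistic" always means the higher probability of the
adverse state. Scenarios shift the evidence (e.g. +0.2 °C anomalies, cyclone
chance ×1.3, ±1-category management shifts); change maps report the per-reef
relative change (p_b − p_a)/p_a between scenario pairs.

No reef-to-reef larval connectivity is modelled, and scenarios are fixed
what-ifs, not forecasts.

## Worked example

No external data are needed — the package generates a synthetic study region
(775 mid-shelf reefs between 15.77°S and 22.31°S, one third no-take) and a
pool of 21 simulated experts:

```bash
reefrisk simulate --out-dir fixtures --seed 7 --n-reefs 775
reefrisk run --reefs fixtures/reefs.csv \
             --responses fixtures/elicitation.csv --out-dir outputs
reefrisk report --run-dir outputs
```

which prints (abridged):

```
Mean probability of coral-cover decline (10-year horizon)
          scenario parameterization  mean_overall  mean_no_take  mean_open  difference_open_minus_no_take
          baseline             mean        0.5894        0.5811     0.5936                         0.0125
           climate             mean        0.6771        0.6690     0.6811                         0.0121
climate_management             mean        0.5911        0.5888     0.5922                         0.0034
        management             mean        0.4946        0.4921     0.4958                         0.0037

Headline relative changes (mean over reefs with defined change):
  climate_vs_baseline_mean: +15.0% (n=775)
  management_vs_baseline_mean: -15.9% (n=775)
```

Read: under current conditions the synthetic fleet's mean decline
probability is 0.59; unmitigated climate change raises it to 0.68 (a +15 %
relative change per reef on average); local management without further
climate change lowers it to 0.49. Reefs outside no-take zones carry slightly
higher risk (+1.3 percentage points at baseline) because no-take reefs are
assumed to have zero fishing effort. Per-reef probabilities land in
`outputs/predictions_<scenario>_<label>.csv` and `.geojson` (reef centroids
with `p_decline` as a feature property, ready for mapping).

The same pipeline is available as a scikit-learn-style estimator:

```python
import pandas as pd, reefrisk as rr

responses = pd.read_csv("fixtures/elicitation.csv")
reefs = rr.layers.read_reef_table("fixtures/reefs.csv")

model = rr.ReefDeclineNetwork(parameterization="mean").fit(responses)
p_decline = model.predict_proba(reefs, scenario="climate")[:, 1]
```

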