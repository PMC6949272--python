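# beecast

Forecasting hourly foraging activity of stingless bees (*Melipona
fasciculata*) from prior activity and weather, with small gated recurrent
networks and a statistically disciplined model-selection protocol.

## The problem

Colonies instrumented with RFID readers at the hive entrance produce one
timestamped record per tagged-bee passage. Aggregated hourly and divided
by the number of tagged bees, these records give the colony's **activity
level** (movements·bee⁻¹·h⁻¹, roughly 0–2), a behavioural signal that
tracks daylight, temperature and — much more weakly — barometric pressure.
`beecast` forecasts the next hour's activity level from lagged activity
and weather, answers *which* recurrent architecture, *how much* history,
and *which* environmental predictors matter, and ships a synthetic-data
generator with known causal structure so every stage is testable without
field recordings.

## The model

The forecaster is the standard recurrence h(t) = f(h(t−1), x(t); θ) with
gated cells — GRU or LSTM — stacked in N layers of M units
(the evaluated grid is {GRU, LSTM} × {2x2, 2x5, 5x2, 5x5}) and a linear
readout. Inputs are **lag windows**: named subsets of past hourly offsets

| window | lags (hours before the forecast hour) |
|--------|----------------------------------------|
| w1     | t₀ |
| w3     | t₀, t₋₂ |
| w6     | t₀, t₋₂, t₋₅ |
| w12    | t₀, t₋₂, t₋₅, t₋₁₁ |
| w24    | t₀, t₋₂, t₋₅, t₋₁₁, t₋₂₃ |
| w36–w60| … up to t₋₅₉ (8 lags) |

with t₀ the hour immediately before the +1 h target. Model quality is
RMSE = √(1/n Σ(yᵢ − ŷᵢ)²). Every candidate (architecture, window or
feature set) is trained over repeated randomized 2/3–1/3 hold-outs
(default 30 replicates); candidate distributions are gated with
Shapiro–Wilk, compared against the lowest-median candidate with the
two-sided Welch t-test, and among statistically equivalent candidates
(p > 0.05) the simplest wins. Predictor pruning uses Permutation Feature
Importance (score = E_d − E_o, the RMSE increase after shuffling a feature
column of the test set) followed by correlation thresholds: FSL0 keeps
scores strictly above 0, CORR70/CORR80 additionally drop the lower-scored
member of feature pairs with |Pearson r| above 0.70/0.80.

## Worked example

```python
from beecast import synthetic, timeseries
from beecast.rnn import NetworkTopology, TrainingConfig, persistence_rmse
from beecast.selection import run_replicates
from beecast.timeseries import build_windowed_dataset, window_spec

sim = synthetic.SimulationConfig(seed=11)            # one simulated month
weather = synthetic.simulate_weather(sim)
events, truth = synthetic.simulate_events(sim, weather)
activity = timeseries.compute_activity_level(events, sim.n_bees, weather.index)
panel = timeseries.build_panel(activity, weather)

ds = build_windowed_dataset(panel, {"activity": window_spec("w24")})
res = run_replicates(ds, NetworkTopology("gru", 2, 2), n_replicates=3,
                     base_seed=42, training=TrainingConfig(epochs=100))
print(res.rmse_values)
print(persistence_rmse(ds))
```

prints (seeds as above)

```
[0.05935739356193414, 0.05816494214835938, 0.057068790293043695]
0.19218670208432706
```

i.e. a GRU 2x2 reading the last day of activity forecasts the next hour
with a test RMSE near 0.06 movements·bee⁻¹·h⁻¹ on this synthetic month,
roughly three times better than the naive persistence forecast
ŷ(t+1) = y(t₀) — the model has learned the diurnal structure rather than
echoing the previous hour.

The full study — architecture grid, per-variable window search, predictor
combinations (A, ART, ARTP, RT, RTP) and FSL0/CORR70/CORR80 pruning —
runs from the command line:

```bash
beecast run-all --seed 7 --replicates 10 --out out/
beecast report --out out/
```

or stage by stage (`simulate`, `aggregate`, `arch-search`,
`window-search`, `combine`, `select-features`), each writing JSON/CSV
artifacts plus a `provenance.json`. Configs are YAML; see
`beecast.pipeline.PipelineConfig` for the schema.

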