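# Methods

## The forecasting task

The observable is the hourly colony **activity level**: the count of
RFID-detected hive-entrance passages in an hour divided by the number of
tagged bees alive that day, in movements·bee⁻¹·h⁻¹ (observed range
roughly 0–2). The task is one-step-ahead forecasting: given lagged
activity and/or weather values up to hour t₀, predict activity at
t₀ + 1 h. All timestamps are naive local time at a single site; no DST
handling is attempted (one tropical site, one month).

## Synthetic study conditions

The generator emulates a ~1-month field campaign at a tropical apiary.
Defaults (all in `SimulationConfig`):

| parameter | default | units | why |
|---|---|---|---|
| `n_days` | 31 | days | one August-style month |
| `n_bees` | 280 | bees | mid-range of a few hundred tagged bees per day |
| `base_rate` | 0.05 | mov/bee/h | small residual night-time activity |
| `diurnal_amplitude` | 1.6 | mov/bee/h | peak λ ≈ 1.65, inside the 0–2 band |
| `irradiance_peak` | 3400 | kJ/m²/h | ≈ 950 W/m² clear-sky noon |
| `temp_mean`, `temp_diurnal_amplitude` | 26, 4 | °C | eastern-Amazon August |
| `temp_irradiance_coupling` | 3 | °C | afternoon heating follows (lagged) sun |
| `pressure_mean` | 1010 | hPa | with a slow multi-day drift of ~1 hPa |
| noise SDs | 60 / 0.3 / 0.4 | kJ/m², °C, hPa | desk-realistic measurement noise |

The latent rate is λ(t) = base_rate + diurnal_amplitude · g(t) with
g = clip(0.8·irr_norm + 0.2·temp_norm, 0, 1): irradiance-dominant by
construction, temperature secondary, **pressure never enters λ** — it is
the designated uninformative channel, which is what lets the
feature-importance protocol be validated against known truth. Hourly
passage counts are Poisson(n_bees·λ); within-hour timestamps are uniform
because only hourly aggregates matter downstream. One global seed drives
independent named sub-streams (weather noise, Poisson counts, timestamps,
bee IDs) through `beecast.seeds.derive_seed`, so a simulation is
byte-reproducible.

With these defaults a simulated month yields ~120 000 events from 280
bees with activity peaking near 1.7 — the same order as a real
month-long, several-hive campaign.

What the generator does **not** model: individual bee trajectories,
hive-to-hive differences, tag loss or mortality (population is constant),
weather fronts, rain, or any activity dependence on pressure. Passing
tests therefore demonstrate that the pipeline recovers structure the
generator put in; they do not certify field accuracy, and absolute RMSE
values on synthetic data (≈ 0.06 for activity-driven forecasts) are
cleaner than anything field data would give.

## Windowed datasets

Canonical lag windows w1…w60 are the nested sets
{t₀}, {t₀,t₋₂}, …, {t₀,t₋₂,t₋₅,t₋₁₁,t₋₂₃,t₋₃₅,t₋₄₇,t₋₅₉}; lag L means
t₀ − L hours and the target is always t₀ + 1. A dataset built from
per-variable windows is encoded as a **masked sequence** over the union
of lags, oldest timestep first: each timestep carries one value channel
per variable plus that variable's availability flag, and masked entries
are zero after scaling. The recurrent models receive values and mask
flags as separate input channels. This preserves temporal order for the
recurrence; encoding the lags as a flat vector would have been the other
defensible reading, and the choice is an interpretation, not a contract
of the protocol being reproduced.

Min–max scaling to [0,1] is fitted **on training rows only** (per
variable, over that variable's unmasked cells; the target gets its own
range). Values outside the fitted range are deliberately not clipped. A
constant input channel is an error; a constant *target* is mapped with a
unit span so that bias-only fits remain well defined. Replicate RMSEs are
always reported on the raw activity scale (predictions are
inverse-transformed), so trained models and the persistence baseline
ŷ(t+1) = y(t₀) are compared in identical units.

The hold-out split shuffles supervised samples (⌈2n/3⌉ train), which
replicates the protocol under study but lets overlapping windows straddle
the split; `contiguous=True` provides a leakage-free block split for
sensitivity analysis. Each replicate draws a fresh split (and fresh
initialization) from its derived seed.

## Recurrent cells and training

GRU and LSTM cells, stacked up to 5 layers × 5 units with a single linear
readout from the last timestep, are implemented in numpy with analytic
backpropagation through time. The standard gate equations are used (GRU:
update/reset gates, candidate with reset-gated recurrence, h' = (1−z)h + zc;
LSTM: input/forget/output gates with a separate cell state). Weights are
seeded uniform ±1/√fan-in, biases zero.

Training minimizes mean squared error with Adam (lr 0.01, batch 32, 200
epochs by default; plain SGD and global-norm gradient clipping are
available). The per-epoch loss history records the full-training-set loss
after each epoch, so a zero learning rate yields a flat history. A
non-finite loss aborts with the epoch named.

The backward pass is verified against central finite differences over
every parameter. The oracle evaluates the perturbed losses in extended
precision (`numpy.longdouble`): in 5-layer stacks the earliest layers can
carry gradients of ~1e-9, and a float64 central difference at step 1e-6
has a cancellation floor of ~1e-10 — larger than the quantity being
measured. Step sizes: 1e-6 for the 2-layer checks, 1e-5 for the
grid-wide check (below the truncation regime, above the rounding floor of
the deepest stacks). Agreement is ≤ 1e-5 max relative deviation across
the whole canonical grid.

## Selection protocol

Each candidate is evaluated over n seeded replicates (default 30; the
desk-scale runs in the test suite and acceptance script use 10 replicates
and 100 epochs — problem sizes chosen so the full suite runs comfortably
on one CPU, with margins wide enough that the conclusions do not depend
on the budget). Distributions are tested with Shapiro–Wilk; p ≤ 0.05 sets
are flagged non-normal but still compared (the protocol proceeds with
Welch tests regardless, matching the practice being reproduced, rather
than switching to a rank test). Every candidate is Welch-compared
(two-sided, unequal variance) to the lowest-median one, and among the
equivalents (p > 0.05) plus the lowest-median candidate the simplest is
selected — fewer lags for windows, fewer total units then fewer layers
for architectures, fewer channels for combinations. No multiple-testing
correction is applied across the Welch comparisons: this mirrors the
protocol under study and is a known limitation, not an endorsement.
When candidates have a single replicate, Welch comparison is impossible;
those comparisons are recorded as unavailable and the lowest median wins.

Permutation feature importance uses one trained model — by default the
lowest-RMSE replicate of the evaluated set (averaging across replicates
is available via `n_repeats`) — and scores each (variable, lag) feature
as E_d − E_o on the replicate's test set, with a single shuffle per
feature by default. Scores are computed on the scale of the dataset
passed in (the pipeline passes normalized test sets); every ranking-based
property is scale-invariant. Pearson correlations are computed on the raw
feature columns; min–max scaling leaves Pearson r unchanged, so the
normalized-vs-raw question is immaterial. "Correlation larger than X%" is
read as |r| > X/100. Within a correlated pair the lower-scored feature is
dropped (keeping the most predictive representative); ties drop the
larger lag, then the lexicographically later name, so pruning is fully
deterministic, and tightening the threshold can only shrink the selection.

## Numerical and degenerate-input choices

- RMSE of empty or mismatched vectors: error. Welch with < 2 values per
  sample or two zero-variance samples: error. Shapiro–Wilk with < 3 or
  identical values: error (reported explicitly, not as p = NaN).
- Zero-variance feature columns are excluded from the correlation matrix
  with a warning; an all-constant matrix is an error.
- Permuting a constant column is the identity, so its PFI score is
  exactly 0 by construction — used as a correctness fixture.
- Windows larger than the panel are skipped with a warning during window
  search; an empty post-pruning feature set is an error.
- Predictions are not clamped to non-negative activity; clamping is
  presentation, not part of the model.

## Known limitations

- The randomized hold-out leaks temporal context across the split by
  design fidelity; use the contiguous split to quantify the effect.
- The statistical-equivalence rule inherits the usual caveat that a
  non-significant Welch test is evidence of indistinguishability only at
  the achieved power (n = 30 replicates).
- Synthetic pressure is pure nuisance; real pressure may carry weak
  signal, so field results for the pressure-derived features need not
  match the synthetic ranking.
- The per-day tagged-population series of a real campaign is typically
  unknown day-to-day; the generator exposes a constant population and
  makes no claim of matching any field distribution.
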