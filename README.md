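# h2020index

Composite health-index construction for country × indicator × year panels,
in the style of regional health-policy monitoring frameworks (and of
HDI-like development indices): 16 quantitative indicators of mixed
direction are rescaled against pooled goalposts, aggregated by policy
target with geometric means, and the resulting country ranking is split
into quintiles with per-indicator trend tables.

It is written for analysts who have (or simulate) a long-format indicator
panel and want a reproducible, auditable index pipeline rather than a
spreadsheet: every exclusion rule, substitution and rounding step is an
explicit, tested function.

## The index

For indicator *k* with pooled extreme raw values *worst_k* and *best_k*
(pooled over the reference years 2005/2010/2015 and the included
countries, oriented so that *best* is the healthier end), a raw value *x*
maps to the indicator index

```
I_k(x) = max(1, 100 · (x − worst_k) / (best_k − worst_k))
```

i.e. a min–max affine map to [0, 100] with scores below 1 floored at 1 so
geometric means stay defined. Each quantitative target *t* is the
geometric mean of its available indicator indices, and the overall index
is the geometric mean of the available target indices:

```
T_t = ( ∏_{k ∈ t} I_k )^{1/n_t}        H = ( ∏_t T_t )^{1/n_targets}
```

The geometric mean gives partial substitutability — an x% change in any
component moves the mean by the same factor — and aggregating by target
(not indicator) weights targets equally, so an indicator aligned to two
targets carries relatively more weight overall.

Missing-data rules: observations within ±2 years substitute for a missing
reference year (closest year wins, later year on ties) and are flagged
with an asterisk in reports; a missing indicator simply drops out of its
target's mean; a target with no indicator is excluded; countries missing
more than six quantitative indicators are excluded from the roster before
goalposts are computed.

## Worked example

The package ships a synthetic panel generator with a known latent
capacity gradient, so the whole pipeline runs without any external data:

```
h2020 simulate --out run --seed 7
h2020 compute  --input run/panel.csv --out run
h2020 report   --out run
```

The seed-7 run scores 50 countries at three reference years. The 2015
overall index ranges from 91.0 (country C04, top of the latent gradient)
down to 8.4, with a median of 47.8; `quintiles.csv` starts

```
country,rank,quintile,index
C04,1,high,90.95930176944266
C02,2,high,89.58984070950825
```

and `boundaries.json` reports the observed index range of each quintile
(the "high" group spans 69.1–91.0 here) — boundaries are descriptions of
the ranking, not fixed thresholds. `trends.csv` holds the average
relative change per indicator and quintile between the baseline year and
2015, signed so positive always means improvement; for example indicator
1 (premature mortality, lower-better) improved by +0.286 in the high
quintile (9 of its 10 members had both endpoints). `ranked_summary.csv`
shows each country's indicator indices at one-decimal display precision
with `*` marking values substituted from a neighbouring year.

The indicator/target structure (directions, target memberships,
availability windows) is editable JSON — see
`src/h2020index/data/default_registry.json` — so the engine survives
revisions of the framework's mapping.

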