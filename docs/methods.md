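# Methods

## Model and procedure

The package builds a relative composite index over a panel of country ×
indicator × year observations in two aggregation steps, preceded by
normalization and followed by classification:

1. **Reference-year resolution.** Raw observations are mapped onto the
   three reference years 2005, 2010 and 2015. An observation at the
   reference year itself is used as-is; otherwise the closest observation
   within ±2 years substitutes for it and is flagged (`substituted`),
   surfacing as an asterisk in reports. Equidistant candidates resolve to
   the **later** year — more recent data is preferred when "closest" does
   not decide. With `window=0` no substitution occurs.
2. **Country filter.** A country is excluded when more than six of the 16
   quantitative indicators have no resolved value at the roster year
   (2015). Indicators structurally unobservable at a reference year (an
   indicator first collected in 2015 has no 2005 value anywhere) do not
   count toward the missing tally; otherwise every country would be
   penalised identically and the filter would lose its meaning. The
   filter runs on the 2015 panel to fix the study roster, but takes the
   reference year as a parameter so per-year audits are possible.
3. **Goalposts and rescaling.** Each indicator's goalposts are its
   extreme raw values pooled over the three reference years and the
   *included* countries (excluded countries' sparse data should not
   anchor the scale). Values map affinely to [0, 100] on the
   direction-adjusted axis — `100·(x − worst)/(best − worst)` — and
   scores below 1 are floored at 1 (`floored` flag). The affine-to-[0,100]
   +floor form (rather than a direct map to [1,100]) is what makes
   "scores of zero or close to zero" possible pre-floor; it is isolated
   in one function (`normalize.rescale`) so the alternative
   `1 + 99·(x−min)/(max−min)` convention could be swapped in. Values
   outside the goalposts (possible only with user-frozen goalposts) are
   clipped first.
4. **Aggregation.** Target index = geometric mean (via mean of logs) of
   the target's available indicator indices; overall index = geometric
   mean of the available target indices. The GM is chosen for partial
   substitutability: multiplying one of n components by c multiplies the
   mean by c^(1/n). Aggregating by target weights targets equally, which
   implicitly up-weights indicators aligned to two targets. A target with
   fewer than `min_indicators_per_target` (default 1) available
   indicators is excluded; a country with fewer than
   `min_targets_per_country` (default 1) surviving targets is unscorable.
   The defaults are the most permissive reading — "limited data" excludes
   a target only when *no* indicator remains — and both thresholds are
   policy parameters because no quantitative bound is prescribed.
5. **Quintiles and trends.** Countries are ranked on the 2015 overall
   index (ties broken by country code) and split into five contiguous
   rank groups whose sizes differ by at most one, larger groups first;
   the observed index range of each group is an *output*. Trend cells are
   the unweighted mean, within quintile, of each country's signed
   relative change `s·(v_2015 − v_base)/|v_base|` on **raw native-unit
   values** (s = +1 higher-better, −1 lower-better, so positive always
   means improvement). Index-space changes would be goalpost-dependent,
   which is why raw values are used. Baseline is 2005, or 2010 for
   indicators first observed in 2010; 2015-only indicators emit no cells.
   Countries missing either endpoint (or with a zero baseline, which
   makes relative change undefined) drop out of their cell;
   `n_countries` records the attrition.

## The registry is data

The framework structure — 19 indicators, 6 targets, which indicators are
quantitative, their direction, target memberships and availability
windows — ships as an editable JSON file and is validated, not
hard-coded. The default encodes: qualitative indicators {11, 18, 19} and
the qualitative target 6 (out of numerical scope), 2015-only indicators
{2, 14}, 2010-onward indicators {4, 10}, and multi-target indicators
{7, 9, 10, 11}. Source descriptions of the framework are ambiguous about
indicator 10 (unemployment vs life satisfaction) and indicator 11 (GINI
vs qualitative); the default reads 10 = unemployment (quantitative,
two targets, 2010-onward), 11 = GINI (qualitative, hence excluded), and
12 = life satisfaction. The exact indicator→target assignment in the
default file is a plausible reconstruction preserving these constraints;
users with the authoritative mapping should edit the JSON — no logic
depends on the specific assignment.

## Synthetic data generator

`synthetic.generate` emulates the structural features the pipeline must
survive: ~50 countries on a latent capacity gradient (a stand-in for the
region's east–west performance gradient), 16 indicators of mixed
direction, drifts of mixed sign per decade, late-starting indicators, and
missingness concentrated in low-capacity countries (mirroring weaker
civil-registration systems). The observation model is

```
value(k, i, y) = a_k + b_k · (c_i + trend_k · (y − 2005)/10 + ε),   ε ~ N(0, noise_sd)
c_i = gradient_strength · position_i + ξ,                            ξ ~ N(0, 0.05)
```

with `b_k` sign-matched to the indicator's direction (|b_k| ~ U(10, 30),
baselines a_k ~ U(20, 80), trend_k ~ U(−0.25, 0.25) per decade unless
supplied). Placing drift and noise on the latent scale makes the panel
exactly mirror-symmetric under a direction flip, which is tested.
Missingness is Bernoulli per cell with probability
`missing_rate_base + missing_rate_slope · (1 − rank-normalized capacity)`
(defaults 0.03 and 0.12: a few percent everywhere, up to ~15% in the
least-capable countries); a `substitution_rate` fraction of observations
(default 0.1) is recorded at a year within ±2 of the reference year to
exercise the substitution path. All randomness flows from one seed
through separate per-purpose streams (latent, parameters, noise,
missingness, jitter), so changing e.g. a direction flag changes no draw.

What the generator does **not** emulate: realistic marginal distributions
of actual health indicators, spatial autocorrelation beyond the 1-D
gradient, correlated (non-ignorable) missingness within a country-year,
or measurement error that differs by data-collection system. Passing
tests therefore demonstrate the pipeline's correctness and its ordering
behaviour under a known ground truth, not calibration to real data.

`synthetic.make_fixture_roster` builds the packaged deterministic
fixture: 53 countries (internal seed 20200) of which exactly three
designated "microstates" have eight indicators deleted around 2015 —
beyond the reach of the ±2-year window — so they exceed the
more-than-six-missing cut-off and 50 countries remain; any other country
that randomly crossed the cut-off is repaired with noiseless model
values, keeping the excluded count at exactly three by construction.

## Numerical choices

- Geometric means are computed as `exp(mean(log x))`; the floor-at-1 rule
  upstream guarantees positivity, and the aggregator *refuses*
  non-positive inputs rather than flooring silently, keeping the
  responsibility boundary clean.
- Rescaled scores are clamped at 100 to absorb float overshoot at the
  best goalpost; degenerate goalposts (all values equal) and empty pools
  are errors, never silently stored.
- Display rounding to one decimal happens only in the ranked report;
  every machine-readable output keeps full precision.
- All sorts use stable (mergesort) order with explicit tie-break keys, so
  pipeline outputs are byte-identical across reruns and row permutations
  of the input.

## Problem sizes

Tests and the acceptance script run panels of 10–53 countries × 16
indicators × 3 years; randomized property suites use 100–150 cases per
invariant and the missingness calibration averages 200 generator seeds.
These sizes match the study-scale panel the generator emulates.

## Known limitations

- The qualitative indicators and target 6 are represented in the
  registry but never scored.
- Country codes must match exactly across files; no name harmonization.
- No uncertainty quantification on the index (no resampling of goalposts
  or indicator noise), and no alternative weighting schemes.
- Real-data country values (and therefore published country rankings)
  are not reproducible without the underlying indicator database; the
  pipeline is validated structurally and on synthetic ground truth.
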