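"""Synthetic indicator panels with known ground truth.

The generator emulates the structure of a WHO-European-style panel: ~50
countries ordered along a latent capacity gradient (a stand-in for the
region's east–west performance gradient), 16 quantitative indicators of
mixed direction loading on that capacity, decade-scale drifts of mixed
sign, indicators that only start being collected in 2010 or 2015, and
cell-level missingness concentrated in low-capacity countries.  Every
stage of the pipeline can therefore be tested against a known ranking
without downloading anything.

The observation model for indicator *k*, country *i*, year *y* is::

    value = a_k + b_k * (c_i + trend_k * (y - 2005)/10 + eps)

with latent capacity ``c_i = gradient_strength * position_i + xi`` and
``eps ~ N(0, noise_sd)``.  The loading ``b_k`` is positive for
higher-is-better indicators and negative for lower-is-better ones, so high
capacity means better health on every indicator; drift and noise live on
the latent scale, which makes the generated panel exactly mirror-symmetric
under a direction flip.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .errors import ConfigurationError
from .ingest import ObservationTable, apply_country_filter, resolve_reference_years
from .registry import Direction, Registry, quantitative_indicators

LATENT_JITTER_SD = 0.05  # country-level departure from the smooth gradient

# fixed internal seed and roster shape for the packaged deterministic fixture
_FIXTURE_SEED = 20200
_FIXTURE_N = 53
_FIXTURE_MICROSTATES = ("C17", "C34", "C51")
_FIXTURE_DROPPED_INDICATORS = 8  # > 6, so microstates fail the inclusion cut


class SyntheticConfig(BaseModel):
    """Generator settings; defaults emulate the study-scale panel."""

    n_countries: int = Field(default=50, ge=2)
    seed: int = 0
    gradient_strength: float = Field(default=1.0, ge=0)
    noise_sd: float = Field(default=0.1, ge=0)
    missing_rate_base: float = Field(default=0.03, ge=0, lt=1)
    missing_rate_slope: float = Field(default=0.12, ge=0)
    substitution_rate: float = Field(default=0.1, ge=0, le=1)
    year_trend: Optional[dict[int, float]] = None  # latent-scale drift per decade

    @model_validator(mode="after")
    def _rates(self) -> "SyntheticConfig":
        if self.missing_rate_base + self.missing_rate_slope >= 1:
            raise ValueError("missing_rate_base + missing_rate_slope must stay below 1")
        return self


@dataclass(frozen=True)
class SyntheticTruth:
    latent_capacity: pd.Series  # country code -> capacity
    long_table: pd.DataFrame  # raw long format: country, indicator_id, year, value
    table: ObservationTable  # resolved onto reference years
    config: SyntheticConfig

    def write(self, out_dir: Union[str, Path]) -> tuple[Path, Path]:
        """Write the ingest-ready long CSV and a truth.json (capacities + config)."""
        import json

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        csv_path = out / "panel.csv"
        self.long_table.to_csv(csv_path, index=False)
        truth_path = out / "truth.json"
        truth_path.write_text(
            json.dumps(
                {
                    "latent_capacity": {
                        k: round(float(v), 12)
                        for k, v in self.latent_capacity.items()
                    },
                    "config": self.config.model_dump(),
                },
                indent=2,
                sort_keys=True,
            )
        )
        return csv_path, truth_path


def _country_codes(n: int) -> list[str]:
    return [f"C{i + 1:02d}" for i in range(n)]


def _child_rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(stream)))


def generate(config: SyntheticConfig, registry: Registry) -> SyntheticTruth:
    """Draw one synthetic panel; deterministic for a fixed seed.

    Noise, missingness and year-substitution jitter come from separate
    seed streams, so e.g. flipping an indicator's direction in the registry
    changes no random draw — only the sign of the loading.
    """
    try:
        config = SyntheticConfig.model_validate(config)
    except ValueError as exc:
        raise ConfigurationError(str(exc)) from exc
    n = config.n_countries
    codes = _country_codes(n)
    # low-numbered codes sit at the favourable end of the gradient
    position = np.linspace(1.0, 0.0, n)
    rng_latent = _child_rng(config.seed, 0)
    capacity = config.gradient_strength * position + rng_latent.normal(
        0.0, LATENT_JITTER_SD, n
    )
    cap = pd.Series(capacity, index=codes, name="latent_capacity")
    # rank-normalised capacity in [0, 1]; 1 = most capable
    rank_norm = (cap.rank(method="average") - 1) / max(n - 1, 1)
    p_miss = np.clip(
        config.missing_rate_base + config.missing_rate_slope * (1.0 - rank_norm.values),
        0.0,
        0.95,
    )

    rows = []
    for ind in quantitative_indicators(registry):
        k = ind.indicator_id
        rng_param = _child_rng(config.seed, 1, k)
        a_k = rng_param.uniform(20.0, 80.0)
        magnitude = rng_param.uniform(10.0, 30.0)
        b_k = magnitude if ind.direction is Direction.higher_better else -magnitude
        if config.year_trend is not None and k in config.year_trend:
            g_k = float(config.year_trend[k])
        else:
            g_k = rng_param.uniform(-0.25, 0.25)
        rng_noise = _child_rng(config.seed, 2, k)
        rng_miss = _child_rng(config.seed, 3, k)
        rng_jitter = _child_rng(config.seed, 4, k)
        for year in sorted(ind.available_reference_years):
            eps = rng_noise.normal(0.0, config.noise_sd, n)
            observed = rng_miss.random(n) >= p_miss
            jitter_hits = rng_jitter.random(n) < config.substitution_rate
            deltas = rng_jitter.choice([-2, -1, 1, 2], size=n)
            for i, code in enumerate(codes):
                if not observed[i]:
                    continue
                source_year = year + (int(deltas[i]) if jitter_hits[i] else 0)
                tau = (source_year - 2005) / 10.0
                value = a_k + b_k * (capacity[i] + g_k * tau + eps[i])
                rows.append((code, k, source_year, round(float(value), 9)))
    long_table = pd.DataFrame(
        rows, columns=["country", "indicator_id", "year", "value"]
    ).sort_values(["country", "indicator_id", "year"], kind="mergesort").reset_index(
        drop=True
    )
    table = resolve_reference_years(long_table)
    return SyntheticTruth(
        latent_capacity=cap, long_table=long_table, table=table, config=config
    )


def _model_value(config: SyntheticConfig, registry: Registry,
                 capacity: float, indicator_id: int, year: int) -> float:
    """Noiseless model value, used when repairing fixture cells."""
    ind = registry.indicator(indicator_id)
    rng_param = _child_rng(config.seed, 1, indicator_id)
    a_k = rng_param.uniform(20.0, 80.0)
    magnitude = rng_param.uniform(10.0, 30.0)
    b_k = magnitude if ind.direction is Direction.higher_better else -magnitude
    if config.year_trend is not None and indicator_id in config.year_trend:
        g_k = float(config.year_trend[indicator_id])
    else:
        g_k = rng_param.uniform(-0.25, 0.25)
    tau = (year - 2005) / 10.0
    return round(float(a_k + b_k * (capacity + g_k * tau)), 9)


def make_fixture_roster(
    registry: Registry,
) -> tuple[ObservationTable, dict]:
    """Deterministic 53-country fixture in which exactly three countries fail
    the more-than-six-missing inclusion cut at 2015.

    Mirrors the study roster shape: 53 candidate countries, of which three
    data-sparse microstates fall over the cut-off and 50 remain.  The three
    synthetic microstates have eight quantitative indicators deleted around
    2015 (beyond the reach of the ±2-year substitution window); every other
    country is repaired, if necessary, to at most six missing indicators by
    inserting its noiseless model value.
    """
    config = SyntheticConfig(
        n_countries=_FIXTURE_N,
        seed=_FIXTURE_SEED,
        missing_rate_base=0.03,
        missing_rate_slope=0.12,
    )
    truth = generate(config, registry)
    long_table = truth.long_table

    q_ids = [i.indicator_id for i in quantitative_indicators(registry)]
    dropped = q_ids[:_FIXTURE_DROPPED_INDICATORS]
    micro_mask = long_table.country.isin(_FIXTURE_MICROSTATES) & long_table.indicator_id.isin(
        dropped
    ) & long_table.year.between(2013, 2017)
    long_table = long_table[~micro_mask]

    # repair: keep every non-microstate country at <= 6 missing at 2015
    table = resolve_reference_years(long_table)
    report = apply_country_filter(table, registry, 2015, max_missing=6)
    additions = []
    for country, _, n_missing in report.excluded:
        if country in _FIXTURE_MICROSTATES:
            continue
        present = set(
            table.data[
                (table.data.country == country) & (table.data.reference_year == 2015)
            ].indicator_id
        )
        capacity = float(truth.latent_capacity[country])
        for ind in quantitative_indicators(registry):
            if n_missing <= 6:
                break
            k = ind.indicator_id
            if k in present or 2015 not in ind.available_reference_years:
                continue
            additions.append(
                (country, k, 2015, _model_value(config, registry, capacity, k, 2015))
            )
            n_missing -= 1
    if additions:
        long_table = pd.concat(
            [
                long_table,
                pd.DataFrame(
                    additions, columns=["country", "indicator_id", "year", "value"]
                ),
            ],
            ignore_index=True,
        ).sort_values(
            ["country", "indicator_id", "year"], kind="mergesort"
        ).reset_index(drop=True)
        table = resolve_reference_years(long_table)

    meta = {
        "n_countries": _FIXTURE_N,
        "seed": _FIXTURE_SEED,
        "microstates": list(_FIXTURE_MICROSTATES),
        "latent_capacity": {
            k: round(float(v), 12) for k, v in truth.latent_capacity.items()
        },
        "long_table": long_table,
    }
    return table, meta
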