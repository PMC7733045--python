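"""Geometric-mean aggregation: indicator indices → target indices → overall index.

The composite is a two-level geometric mean: each quantitative target is
the GM of its available indicator indices, and the overall index is the GM
of the country's available target indices.  The GM is chosen for its
partial-substitutability property — an x% change in any component moves
the mean by the same factor — and targets (not indicators) enter the top
level with equal weight, so an indicator aligned to two targets carries
relatively more weight overall.  Missing indicators simply drop out of
their target's mean; a target with no indicator at all is excluded, and a
country keeps an overall index as long as at least one target survives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import CountryUnscorableError, ValidationError
from .ingest import InclusionReport, ObservationTable, apply_country_filter
from .normalize import Goalposts, compute_goalposts, rescale_series
from .registry import (
    REFERENCE_YEARS,
    Registry,
    indicators_for_target,
    quantitative_indicators,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AggregationPolicy:
    """Missing-data thresholds.

    Defaults make a target scorable with a single indicator and a country
    scorable with a single target — the most permissive reading, under
    which sparse countries end up scored on three of five targets rather
    than dropped.
    """

    min_indicators_per_target: int = 1
    min_targets_per_country: int = 1

    def __post_init__(self) -> None:
        if self.min_indicators_per_target < 1 or self.min_targets_per_country < 1:
            raise ValidationError("policy thresholds must be >= 1")


@dataclass(frozen=True)
class TargetIndex:
    country: str
    target_id: int
    reference_year: int
    index: Optional[float]  # None when excluded
    n_indicators_used: int
    excluded: bool


@dataclass(frozen=True)
class OverallIndex:
    country: str
    reference_year: int
    index: float
    n_targets_used: int


def geometric_mean(values: Sequence[float]) -> float:
    """GM of positive reals via the mean of logarithms."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("geometric mean of an empty collection")
    if not (arr > 0).all():
        raise ValidationError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(arr))))


def target_index(
    indices: Mapping[int, float],
    registry: Registry,
    target_id: int,
    policy: AggregationPolicy = AggregationPolicy(),
    *,
    country: str = "",
    reference_year: int = 0,
) -> TargetIndex:
    """GM of one country-year's indicator indices for one target.

    ``indices`` maps indicator id → indicator index (1–100) for whatever
    indicators the country has; indicators absent from the mapping are
    excluded from the mean.
    """
    member_ids = [i.indicator_id for i in indicators_for_target(registry, target_id)]
    available = [indices[i] for i in member_ids if i in indices]
    if len(available) < policy.min_indicators_per_target:
        return TargetIndex(country, target_id, reference_year, None, len(available), True)
    return TargetIndex(
        country,
        target_id,
        reference_year,
        geometric_mean(available),
        len(available),
        False,
    )


def overall_index(
    target_indices: Iterable[TargetIndex],
    policy: AggregationPolicy = AggregationPolicy(),
) -> OverallIndex:
    """GM of a country-year's non-excluded target indices."""
    usable = [t for t in target_indices if not t.excluded]
    if not usable or len(usable) < policy.min_targets_per_country:
        raise CountryUnscorableError(
            "no scorable target for this country-year"
            if not usable
            else f"only {len(usable)} scorable targets (< {policy.min_targets_per_country})"
        )
    country = usable[0].country
    year = usable[0].reference_year
    return OverallIndex(
        country=country,
        reference_year=year,
        index=geometric_mean([t.index for t in usable]),
        n_targets_used=len(usable),
    )


@dataclass(frozen=True)
class IndexTable:
    """Full pipeline output: indicator, target and overall indices plus audit metadata."""

    indicator_indices: pd.DataFrame  # country, indicator_id, reference_year, index, floored, substituted
    target_indices: pd.DataFrame  # country, target_id, reference_year, index, n_indicators_used, excluded
    overall: pd.DataFrame  # country, reference_year, index, n_targets_used
    goalposts: dict[int, Goalposts]
    inclusion: InclusionReport
    unscorable: tuple[tuple[str, int], ...] = field(default_factory=tuple)

    def overall_for_year(self, reference_year: int) -> dict[str, float]:
        sub = self.overall[self.overall.reference_year == reference_year]
        return dict(zip(sub.country, sub["index"]))

    def to_tidy_csv(self, path: Union[str, Path]) -> None:
        """One row per (country, year, level, id): tidy export of all three levels."""
        ind = self.indicator_indices.assign(
            level="indicator",
            id=self.indicator_indices.indicator_id,
            n_used=1,
            flags=np.select(
                [
                    self.indicator_indices.floored & self.indicator_indices.substituted,
                    self.indicator_indices.floored,
                    self.indicator_indices.substituted,
                ],
                ["floored;substituted", "floored", "substituted"],
                default="",
            ),
        )
        tgt = self.target_indices[~self.target_indices.excluded].assign(
            level="target",
            id=self.target_indices[~self.target_indices.excluded].target_id,
            n_used=self.target_indices[~self.target_indices.excluded].n_indicators_used,
            flags="",
        )
        ov = self.overall.assign(
            level="overall", id=0, n_used=self.overall.n_targets_used, flags=""
        )
        cols = ["country", "reference_year", "level", "id", "index", "n_used", "flags"]
        tidy = pd.concat([f[cols] for f in (ind, tgt, ov)], ignore_index=True)
        tidy = tidy.rename(columns={"index": "value"}).sort_values(
            ["country", "reference_year", "level", "id"], kind="mergesort"
        )
        tidy.to_csv(path, index=False)


def compute_index_table(
    table: ObservationTable,
    registry: Registry,
    policy: AggregationPolicy = AggregationPolicy(),
    *,
    max_missing: int = 6,
    goalposts: Optional[Mapping[int, Goalposts]] = None,
) -> IndexTable:
    """End-to-end index construction for all included countries and years.

    The inclusion filter runs on the 2015 panel; goalposts are then pooled
    over the included roster only (unless frozen goalposts are supplied),
    indicator values rescaled, and the two aggregation levels computed.
    Countries whose targets are all excluded at some year are flagged
    unscorable for that year and omitted from the overall table.
    """
    inclusion = apply_country_filter(table, registry, 2015, max_missing=max_missing)
    roster = list(inclusion.included)
    q_indicators = quantitative_indicators(registry)

    if goalposts is None:
        goalposts = {}
        for ind in q_indicators:
            try:
                goalposts[ind.indicator_id] = compute_goalposts(table, ind, roster)
            except ValidationError as exc:
                raise ValidationError(f"goalposts: {exc}") from exc

    obs = table.data[table.data.country.isin(roster)].copy()
    pieces = []
    for ind_id, group in obs.groupby("indicator_id"):
        scaled = rescale_series(group.value, goalposts[int(ind_id)])
        pieces.append(group.assign(index=scaled["index"], floored=scaled["floored"]))
    if not pieces:
        raise ValidationError("no observations for any included country")
    indicator_indices = (
        pd.concat(pieces)[
            ["country", "indicator_id", "reference_year", "index", "floored", "substituted"]
        ]
        .sort_values(["country", "reference_year", "indicator_id"], kind="mergesort")
        .reset_index(drop=True)
    )

    target_rows, overall_rows, unscorable = [], [], []
    q_targets = registry.quantitative_target_ids
    grouped = indicator_indices.groupby(["country", "reference_year"])
    for (country, year), group in grouped:
        idx_map = dict(zip(group.indicator_id, group["index"]))
        tlist = [
            target_index(
                idx_map, registry, t, policy, country=country, reference_year=int(year)
            )
            for t in q_targets
        ]
        target_rows.extend(tlist)
        try:
            overall_rows.append(overall_index(tlist, policy))
        except CountryUnscorableError:
            unscorable.append((country, int(year)))
            logger.debug("%s unscorable at %d", country, year)

    target_frame = pd.DataFrame(
        [
            {
                "country": t.country,
                "target_id": t.target_id,
                "reference_year": t.reference_year,
                "index": np.nan if t.index is None else t.index,
                "n_indicators_used": t.n_indicators_used,
                "excluded": t.excluded,
            }
            for t in target_rows
        ]
    )
    overall_frame = pd.DataFrame(
        [
            {
                "country": o.country,
                "reference_year": o.reference_year,
                "index": o.index,
                "n_targets_used": o.n_targets_used,
            }
            for o in overall_rows
        ]
    )
    logger.info(
        "index table: %d countries, %d overall scores, %d unscorable country-years",
        len(roster), len(overall_frame), len(unscorable),
    )
    return IndexTable(
        indicator_indices=indicator_indices,
        target_indices=target_frame.sort_values(
            ["country", "reference_year", "target_id"], kind="mergesort"
        ).reset_index(drop=True),
        overall=overall_frame.sort_values(
            ["country", "reference_year"], kind="mergesort"
        ).reset_index(drop=True),
        goalposts=dict(goalposts),
        inclusion=inclusion,
        unscorable=tuple(unscorable),
    )
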