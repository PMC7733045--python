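"""Read raw observations, resolve them onto reference years, filter countries.

Raw data arrive as a long table of (country, indicator, year, value).  The
index is evaluated at three reference years (2005, 2010, 2015); when the
reference year itself is unobserved, the closest observation within ±2
years substitutes for it and is flagged, matching the asterisk convention
of the source tables.  Countries missing more than ``max_missing``
quantitative indicators after resolution are excluded from the roster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .errors import ParseError
from .registry import REFERENCE_YEARS, Registry, quantitative_indicators

logger = logging.getLogger(__name__)

RAW_COLUMNS = ["country", "indicator_id", "year", "value"]
RESOLVED_COLUMNS = [
    "country",
    "indicator_id",
    "reference_year",
    "source_year",
    "value",
    "substituted",
]


@dataclass(frozen=True)
class ObservationTable:
    """Resolved panel: at most one observation per (country, indicator, reference year)."""

    data: pd.DataFrame  # RESOLVED_COLUMNS
    countries: tuple[str, ...]

    def __post_init__(self) -> None:
        dupes = self.data.duplicated(["country", "indicator_id", "reference_year"])
        if dupes.any():
            raise ValueError("duplicate (country, indicator, reference_year) cells")

    def value(self, country: str, indicator_id: int, reference_year: int):
        m = self.data[
            (self.data.country == country)
            & (self.data.indicator_id == indicator_id)
            & (self.data.reference_year == reference_year)
        ]
        return None if m.empty else float(m.value.iloc[0])

    def to_csv(self, path: Union[str, Path]) -> None:
        self.data.to_csv(path, index=False)


@dataclass(frozen=True)
class InclusionReport:
    included: tuple[str, ...]
    excluded: tuple[tuple[str, str, int], ...]  # (country, reason, missing count)
    missing_counts: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "included": list(self.included),
            "excluded": [
                {"country": c, "reason": r, "missing_indicator_count": n}
                for c, r, n in self.excluded
            ],
            "missing_counts": dict(self.missing_counts),
        }


def read_observations(
    file: Union[str, Path, pd.DataFrame], registry: Registry
) -> pd.DataFrame:
    """Parse a long-format CSV into a raw observation frame.

    Qualitative indicators are dropped (with a logged count); unknown
    indicator ids or non-numeric values raise :class:`ParseError` naming
    the offending row (1-based data rows, excluding the header).
    """
    if isinstance(file, pd.DataFrame):
        raw = file.copy()
    else:
        try:
            raw = pd.read_csv(file, dtype=str)
        except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise ParseError(f"cannot read {file}: {exc}") from exc
    missing_cols = [c for c in RAW_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ParseError(f"missing required columns: {missing_cols}")
    raw = raw[RAW_COLUMNS].copy()
    if raw.empty:
        raise ParseError("input contains no observation rows")

    for col, kind in (("indicator_id", "Int64"), ("year", "Int64")):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = raw.index[converted.isna()]
        if len(bad):
            raise ParseError(f"row {bad[0] + 1}: non-integer {col!r} value {raw.loc[bad[0], col]!r}")
        raw[col] = converted.astype(kind)
    values = pd.to_numeric(raw["value"], errors="coerce")
    bad = raw.index[values.isna() | ~np.isfinite(values.astype(float))]
    if len(bad):
        raise ParseError(f"row {bad[0] + 1}: non-numeric value {raw.loc[bad[0], 'value']!r}")
    raw["value"] = values.astype(float)
    raw["country"] = raw["country"].astype(str)

    known = {i.indicator_id: i for i in registry.indicators}
    unknown = sorted(set(raw.indicator_id) - set(known))
    if unknown:
        raise ParseError(f"unknown indicator ids: {unknown}")
    qualitative = {i for i, d in known.items() if not d.is_quantitative}
    n_dropped = int(raw.indicator_id.isin(qualitative).sum())
    if n_dropped:
        logger.info("dropped %d rows for qualitative indicators %s", n_dropped, sorted(qualitative))
        raw = raw[~raw.indicator_id.isin(qualitative)]
    raw = raw.astype({"indicator_id": int, "year": int}).reset_index(drop=True)
    logger.info("read %d observation rows for %d countries", len(raw), raw.country.nunique())
    return raw


def resolve_reference_years(series: pd.DataFrame, window: int = 2) -> ObservationTable:
    """Map raw observations onto the reference years 2005/2010/2015.

    For each (country, indicator, reference year): an observation at the
    reference year itself is used as-is; otherwise the closest observation
    within ``window`` years substitutes for it (``substituted=True``), with
    equidistant candidates resolved in favour of the later year.  Cells with
    no candidate are simply absent.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    pieces = []
    for ref in REFERENCE_YEARS:
        cand = series[(series.year - ref).abs() <= window].copy()
        if cand.empty:
            continue
        cand["reference_year"] = ref
        cand["distance"] = (cand.year - ref).abs()
        # later-year tie-break: sort descending year within equal distance
        cand = cand.sort_values(
            ["country", "indicator_id", "distance", "year"],
            ascending=[True, True, True, False],
            kind="mergesort",
        )
        best = cand.groupby(["country", "indicator_id"], as_index=False).first()
        pieces.append(best)
    if pieces:
        resolved = pd.concat(pieces, ignore_index=True)
        resolved = resolved.rename(columns={"year": "source_year"})
        resolved["substituted"] = resolved.source_year != resolved.reference_year
        resolved = resolved[RESOLVED_COLUMNS].sort_values(
            ["country", "indicator_id", "reference_year"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        resolved = pd.DataFrame(columns=RESOLVED_COLUMNS)
    countries = tuple(sorted(series.country.unique()))
    n_sub = int(resolved.substituted.sum()) if len(resolved) else 0
    logger.info("resolved %d cells (%d substituted within ±%d years)", len(resolved), n_sub, window)
    return ObservationTable(data=resolved, countries=countries)


def apply_country_filter(
    table: ObservationTable,
    registry: Registry,
    reference_year: int = 2015,
    max_missing: int = 6,
) -> InclusionReport:
    """Exclude countries missing more than ``max_missing`` quantitative indicators.

    Only indicators structurally observable at ``reference_year`` (per the
    registry's availability windows) count toward the missing tally, so an
    indicator first collected in 2015 does not penalise anyone at 2005.
    """
    if reference_year not in REFERENCE_YEARS:
        raise ValueError(f"reference_year must be one of {REFERENCE_YEARS}")
    countable = [
        i.indicator_id
        for i in quantitative_indicators(registry)
        if reference_year in i.available_reference_years
    ]
    at_ref = table.data[table.data.reference_year == reference_year]
    present = at_ref.groupby("country").indicator_id.apply(set).to_dict()
    included, excluded, counts = [], [], {}
    for country in table.countries:
        have = present.get(country, set())
        n_missing = sum(1 for i in countable if i not in have)
        counts[country] = n_missing
        if n_missing > max_missing:
            reason = (
                f"data absent for {n_missing} of {len(countable)} quantitative "
                f"indicators at {reference_year} (cut-off: more than {max_missing})"
            )
            excluded.append((country, reason, n_missing))
            logger.debug("excluding %s: %s", country, reason)
        else:
            included.append(country)
    logger.info(
        "country filter at %d: %d included, %d excluded",
        reference_year, len(included), len(excluded),
    )
    return InclusionReport(
        included=tuple(included), excluded=tuple(excluded), missing_counts=counts
    )
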