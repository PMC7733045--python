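"""Quintile classification of the 2015 ranking and per-quintile trend tables.

Countries are ranked on the 2015 overall index and split into five
contiguous rank groups of near-equal size (high → low); the numeric index
boundaries of each group are an *output* describing the data, not fixed
thresholds.  Trends are the average relative change of each indicator's
raw values between a baseline year and 2015, averaged within quintile and
signed so that positive always means health improvement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError, ZeroBaselineError
from .ingest import ObservationTable
from .registry import Direction, Registry, quantitative_indicators

logger = logging.getLogger(__name__)

QUINTILE_LABELS = ("high", "upper_middle", "middle", "lower_middle", "low")


@dataclass(frozen=True)
class QuintileAssignment:
    country: str
    quintile: str
    rank: int  # 1 = highest index


@dataclass(frozen=True)
class QuintileBoundaries:
    """Observed (min_index, max_index) per quintile, ordered high → low."""

    bounds: tuple[tuple[str, float, float], ...]

    def as_dict(self) -> dict:
        return {
            label: {"min_index": lo, "max_index": hi} for label, lo, hi in self.bounds
        }


def assign_quintiles(
    overall_2015: Mapping[str, float],
) -> tuple[list[QuintileAssignment], QuintileBoundaries]:
    """Rank countries (descending index, ties by country code) into 5 groups.

    Group sizes differ by at most one, with the larger groups at the top of
    the ranking (n = 52 gives sizes 11, 11, 10, 10, 10).
    """
    n = len(overall_2015)
    if n < 5:
        raise ValidationError(f"need at least 5 countries to form quintiles, got {n}")
    ranked = sorted(overall_2015.items(), key=lambda kv: (-kv[1], kv[0]))
    base, extra = divmod(n, 5)
    sizes = [base + (1 if i < extra else 0) for i in range(5)]
    assignments: list[QuintileAssignment] = []
    bounds = []
    pos = 0
    for label, size in zip(QUINTILE_LABELS, sizes):
        members = ranked[pos : pos + size]
        for offset, (country, _) in enumerate(members):
            assignments.append(
                QuintileAssignment(country=country, quintile=label, rank=pos + offset + 1)
            )
        values = [v for _, v in members]
        bounds.append((label, min(values), max(values)))
        pos += size
    return assignments, QuintileBoundaries(bounds=tuple(bounds))


def relative_change(
    value_baseline: float, value_2015: float, direction: Direction
) -> float:
    """Signed fractional change, positive = improvement.

    ``s * (v2015 - baseline) / |baseline|`` with s = +1 for higher-is-better
    indicators and -1 for lower-is-better, so a mortality drop from 10 to 8
    reads +0.20.
    """
    if not (np.isfinite(value_baseline) and np.isfinite(value_2015)):
        raise ValidationError("relative change requires finite endpoint values")
    if value_baseline == 0:
        raise ZeroBaselineError("relative change undefined for zero baseline")
    sign = 1.0 if direction is Direction.higher_better else -1.0
    return sign * (value_2015 - value_baseline) / abs(value_baseline)


def trend_table(
    table: ObservationTable,
    registry: Registry,
    assignments: Sequence[QuintileAssignment],
) -> pd.DataFrame:
    """Average relative change per indicator × quintile between baseline and 2015.

    The baseline is 2005, or 2010 for indicators first observed in 2010;
    indicators observed only in 2015 emit no rows.  Countries missing
    either endpoint (or with a zero baseline) drop out of their cell;
    ``n_countries`` records how many remained, and empty cells carry a NaN
    average with ``n_countries = 0``.
    """
    quintile_of = {a.country: a.quintile for a in assignments}
    data = table.data[table.data.country.isin(quintile_of)]
    rows = []
    for ind in quantitative_indicators(registry):
        years = ind.available_reference_years
        if years == frozenset({2015}):
            continue
        baseline_year = 2005 if 2005 in years else 2010
        sub = data[data.indicator_id == ind.indicator_id]
        base = sub[sub.reference_year == baseline_year].set_index("country").value
        end = sub[sub.reference_year == 2015].set_index("country").value
        changes: dict[str, list[float]] = {q: [] for q in QUINTILE_LABELS}
        for country in base.index.intersection(end.index):
            try:
                rc = relative_change(base[country], end[country], ind.direction)
            except ZeroBaselineError:
                logger.warning(
                    "indicator %d, %s: zero baseline at %d, cell omitted",
                    ind.indicator_id, country, baseline_year,
                )
                continue
            changes[quintile_of[country]].append(rc)
        for q in QUINTILE_LABELS:
            vals = changes[q]
            rows.append(
                {
                    "indicator_id": ind.indicator_id,
                    "quintile": q,
                    "baseline_year": baseline_year,
                    "avg_relative_change": float(np.mean(vals)) if vals else np.nan,
                    "n_countries": len(vals),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "indicator_id",
            "quintile",
            "baseline_year",
            "avg_relative_change",
            "n_countries",
        ],
    )


def assignments_frame(
    assignments: Sequence[QuintileAssignment],
    overall_2015: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    frame = pd.DataFrame(
        [
            {"country": a.country, "rank": a.rank, "quintile": a.quintile}
            for a in sorted(assignments, key=lambda a: a.rank)
        ]
    )
    if overall_2015 is not None:
        frame["index"] = frame.country.map(overall_2015)
    return frame
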