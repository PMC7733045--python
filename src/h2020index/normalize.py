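"""Goalpost computation and the 1–100 indicator rescaling.

Goalposts are the extreme raw values of an indicator pooled over the three
reference years and the included countries; they anchor a min–max affine
map to [0, 100] on the direction-adjusted axis, after which scores below 1
are floored at 1 so downstream geometric means stay positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Union

import numpy as np
import pandas as pd

from .errors import DegenerateGoalpostsError, NoDataError, ValidationError
from .ingest import ObservationTable
from .registry import Direction, IndicatorDefinition

FLOOR = 1.0


@dataclass(frozen=True)
class Goalposts:
    """Worst/best raw anchors for one indicator, in native units.

    For a higher-is-better indicator ``best > worst``; for lower-is-better
    the ordering reverses (e.g. mortality: best is the minimum).
    """

    indicator_id: int
    worst: float
    best: float
    n_values: int

    def __post_init__(self) -> None:
        if self.worst == self.best:
            raise DegenerateGoalpostsError(
                f"indicator {self.indicator_id}: worst == best == {self.worst}"
            )


class RescaledValue(NamedTuple):
    index: float
    floored: bool


def compute_goalposts(
    table: ObservationTable,
    indicator: IndicatorDefinition,
    countries: Iterable[str],
) -> Goalposts:
    """Pool an indicator's raw values over 2005/2010/2015 and the included roster.

    Raises :class:`NoDataError` with no values and
    :class:`DegenerateGoalpostsError` when all values coincide.
    """
    roster = set(countries)
    values = table.data.loc[
        (table.data.indicator_id == indicator.indicator_id)
        & table.data.country.isin(roster),
        "value",
    ].to_numpy(dtype=float)
    if values.size == 0:
        raise NoDataError(f"indicator {indicator.indicator_id}: no observed values")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise DegenerateGoalpostsError(
            f"indicator {indicator.indicator_id}: all {values.size} values equal {lo}"
        )
    if indicator.direction is Direction.higher_better:
        worst, best = lo, hi
    else:
        worst, best = hi, lo
    return Goalposts(
        indicator_id=indicator.indicator_id,
        worst=worst,
        best=best,
        n_values=int(values.size),
    )


def rescale(value: float, goalposts: Goalposts) -> RescaledValue:
    """Rescale one raw value onto the 1–100 indicator index.

    The pre-floor score is ``100 * (value - worst) / (best - worst)`` on
    the direction-adjusted axis; values outside the goalpost range are
    clipped to it first (a no-op when goalposts were computed from the same
    data).  Scores below 1 are floored at 1 and flagged.
    """
    if not np.isfinite(value):
        raise ValidationError(f"non-finite value {value!r}")
    lo = min(goalposts.worst, goalposts.best)
    hi = max(goalposts.worst, goalposts.best)
    clipped = min(max(float(value), lo), hi)
    score = 100.0 * (clipped - goalposts.worst) / (goalposts.best - goalposts.worst)
    score = min(score, 100.0)  # guard float overshoot at the best goalpost
    if score < FLOOR:
        return RescaledValue(FLOOR, True)
    return RescaledValue(score, False)


def rescale_series(values: pd.Series, goalposts: Goalposts) -> pd.DataFrame:
    """Vectorised :func:`rescale`: returns columns ``index`` and ``floored``."""
    arr = values.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValidationError("non-finite values in series")
    lo = min(goalposts.worst, goalposts.best)
    hi = max(goalposts.worst, goalposts.best)
    clipped = np.clip(arr, lo, hi)
    score = np.minimum(
        100.0 * (clipped - goalposts.worst) / (goalposts.best - goalposts.worst), 100.0
    )
    floored = score < FLOOR
    return pd.DataFrame(
        {"index": np.maximum(score, FLOOR), "floored": floored}, index=values.index
    )


def goalposts_to_csv(goalposts: Iterable[Goalposts], path: Union[str, Path]) -> None:
    pd.DataFrame(
        [
            {"indicator_id": g.indicator_id, "worst": g.worst, "best": g.best, "n_values": g.n_values}
            for g in goalposts
        ]
    ).to_csv(path, index=False)


def goalposts_from_csv(path: Union[str, Path]) -> dict[int, Goalposts]:
    frame = pd.read_csv(path)
    return {
        int(r.indicator_id): Goalposts(
            indicator_id=int(r.indicator_id),
            worst=float(r.worst),
            best=float(r.best),
            n_values=int(r.n_values),
        )
        for r in frame.itertuples(index=False)
    }
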