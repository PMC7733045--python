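"""Indicator/target registry: the monitoring framework's structure as data.

The framework monitors six policy targets through 19 indicators; 16 of the
indicators are quantitative and drive the composite index, while three
qualitative indicators (and the one qualitative target they serve) are out
of numerical scope.  Which indicator informs which target, in which
direction, and from which reference year it is observed, is configuration —
shipped as a default JSON file and overridable by the user — because the
mapping belongs to the policy framework, not to the index engine.
"""

from __future__ import annotations

import json
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Union

import pandas as pd
import pydantic
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import ConfigurationError

REFERENCE_YEARS = (2005, 2010, 2015)


class Direction(str, Enum):
    """Orientation of an indicator: whether larger raw values mean better health."""

    higher_better = "higher_better"
    lower_better = "lower_better"


class IndicatorDefinition(BaseModel):
    model_config = pydantic.ConfigDict(frozen=True)

    indicator_id: int = Field(ge=1, le=19)
    name: str
    is_quantitative: bool
    direction: Direction
    target_ids: frozenset[int]
    available_reference_years: frozenset[int]

    @field_validator("target_ids")
    @classmethod
    def _targets_in_range(cls, v: frozenset[int]) -> frozenset[int]:
        bad = [t for t in v if not 1 <= t <= 6]
        if bad:
            raise ValueError(f"target ids out of range 1-6: {sorted(bad)}")
        return v

    @field_validator("available_reference_years")
    @classmethod
    def _years_valid(cls, v: frozenset[int]) -> frozenset[int]:
        if not v:
            raise ValueError("available_reference_years must be non-empty")
        bad = sorted(set(v) - set(REFERENCE_YEARS))
        if bad:
            raise ValueError(f"unknown reference years: {bad}")
        return v

    @model_validator(mode="after")
    def _quantitative_has_targets(self) -> "IndicatorDefinition":
        if self.is_quantitative and not self.target_ids:
            raise ValueError(
                f"quantitative indicator {self.indicator_id} has no target"
            )
        return self

    @property
    def first_available_year(self) -> int:
        return min(self.available_reference_years)


class TargetDefinition(BaseModel):
    model_config = pydantic.ConfigDict(frozen=True)

    target_id: int = Field(ge=1, le=6)
    name: str
    is_quantitative: bool


class Registry(BaseModel):
    """Validated set of targets and indicators making up the framework."""

    model_config = pydantic.ConfigDict(frozen=True)

    indicators: tuple[IndicatorDefinition, ...]
    targets: tuple[TargetDefinition, ...]

    @model_validator(mode="after")
    def _structure(self) -> "Registry":
        ind_ids = [i.indicator_id for i in self.indicators]
        if len(set(ind_ids)) != len(ind_ids):
            dupes = sorted({i for i in ind_ids if ind_ids.count(i) > 1})
            raise ValueError(f"duplicate indicator ids: {dupes}")
        tgt_ids = [t.target_id for t in self.targets]
        if len(set(tgt_ids)) != len(tgt_ids):
            raise ValueError("duplicate target ids")
        if len(self.targets) != 6 or set(tgt_ids) != {1, 2, 3, 4, 5, 6}:
            raise ValueError("registry must define exactly targets 1-6")
        known = set(tgt_ids)
        for ind in self.indicators:
            unknown = sorted(set(ind.target_ids) - known)
            if unknown:
                raise ValueError(
                    f"indicator {ind.indicator_id} references unknown targets {unknown}"
                )
        return self

    def indicator(self, indicator_id: int) -> IndicatorDefinition:
        for ind in self.indicators:
            if ind.indicator_id == indicator_id:
                return ind
        raise KeyError(f"no indicator with id {indicator_id}")

    def target(self, target_id: int) -> TargetDefinition:
        for t in self.targets:
            if t.target_id == target_id:
                return t
        raise KeyError(f"no target with id {target_id}")

    @property
    def quantitative_target_ids(self) -> list[int]:
        return sorted(t.target_id for t in self.targets if t.is_quantitative)


def quantitative_indicators(registry: Registry) -> list[IndicatorDefinition]:
    """All quantitative indicators, in stable ascending id order."""
    return sorted(
        (i for i in registry.indicators if i.is_quantitative),
        key=lambda i: i.indicator_id,
    )


def indicators_for_target(
    registry: Registry, target_id: int
) -> list[IndicatorDefinition]:
    """Quantitative indicators informing one quantitative target.

    An indicator aligned to two targets appears in both targets' lists —
    this is what gives multi-target indicators relatively more weight in
    the overall index.
    """
    try:
        target = registry.target(target_id)
    except KeyError as exc:
        raise ConfigurationError(str(exc)) from exc
    if not target.is_quantitative:
        raise ConfigurationError(
            f"target {target_id} is qualitative and carries no indicator indices"
        )
    return [
        i
        for i in quantitative_indicators(registry)
        if target_id in i.target_ids
    ]


def _registry_from_dict(payload: Mapping) -> Registry:
    try:
        return Registry(
            indicators=tuple(
                IndicatorDefinition(**row) for row in payload["indicators"]
            ),
            targets=tuple(TargetDefinition(**row) for row in payload["targets"]),
        )
    except (pydantic.ValidationError, ValueError, KeyError, TypeError) as exc:
        raise ConfigurationError(f"invalid registry: {exc}") from exc


def _registry_from_csv(indicators_csv: Path, targets_csv: Path) -> Registry:
    ind = pd.read_csv(indicators_csv)
    tgt = pd.read_csv(targets_csv)
    indicators = [
        {
            "indicator_id": int(r.indicator_id),
            "name": str(r.name_),
            "is_quantitative": bool(r.is_quantitative),
            "direction": str(r.direction),
            "target_ids": [int(x) for x in str(r.target_ids).split(";")],
            "available_reference_years": [
                int(x) for x in str(r.available_reference_years).split(";")
            ],
        }
        for r in ind.rename(columns={"name": "name_"}).itertuples(index=False)
    ]
    targets = [
        {
            "target_id": int(r.target_id),
            "name": str(r.name_),
            "is_quantitative": bool(r.is_quantitative),
        }
        for r in tgt.rename(columns={"name": "name_"}).itertuples(index=False)
    ]
    return _registry_from_dict({"indicators": indicators, "targets": targets})


def load_registry(
    source: Union[str, Path, Mapping, None] = None,
    *,
    targets_csv: Union[str, Path, None] = None,
) -> Registry:
    """Load and validate a registry.

    Parameters
    ----------
    source
        ``None`` for the packaged default, a mapping with ``indicators`` and
        ``targets`` keys, a path to an equivalent JSON file, or — together
        with ``targets_csv`` — a path to an indicators CSV (``target_ids``
        and ``available_reference_years`` semicolon-separated).
    """
    if source is None:
        payload = json.loads(
            resources.files("h2020index.data")
            .joinpath("default_registry.json")
            .read_text()
        )
        return _registry_from_dict(payload)
    if isinstance(source, Mapping):
        return _registry_from_dict(source)
    path = Path(source)
    if targets_csv is not None:
        try:
            return _registry_from_csv(path, Path(targets_csv))
        except (OSError, ValueError, KeyError, AttributeError) as exc:
            raise ConfigurationError(f"cannot read registry CSVs: {exc}") from exc
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfigurationError(f"cannot read registry {path}: {exc}") from exc
    return _registry_from_dict(payload)
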