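"""Core domain types for per-fruit emergence data.

The unit of observation is a single collected fruit: for each fruit we
record how many adult flies of each species emerged from it.  Fruits are
grouped by host plant species and assigned to one of two study periods
("before" / "after" an invasion year), which is all the downstream
analysis needs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

BEFORE = "before"
AFTER = "after"
PERIODS = (BEFORE, AFTER)

GUILDS = ("generalist", "specialist", "invader", "unknown")


class ValidationError(ValueError):
    """Raised when input data violate a structural invariant."""


@dataclass(frozen=True)
class FlySpecies:
    fly_id: str
    name: str = ""
    guild: str = "unknown"

    def __post_init__(self) -> None:
        if self.guild not in GUILDS:
            raise ValidationError(
                f"fly {self.fly_id!r}: guild {self.guild!r} not in {GUILDS}"
            )


@dataclass(frozen=True)
class PlantSpecies:
    plant_id: str
    name: str = ""
    family: str = ""
    tree_tip_label: str | None = None

    @property
    def tip_label(self) -> str:
        """Tip label used to match the phylogeny (defaults to plant_id)."""
        return self.tree_tip_label if self.tree_tip_label else self.plant_id


@dataclass(frozen=True)
class FruitSample:
    """One fruit with per-fly-species emergence counts."""

    sample_id: str
    plant_id: str
    period: str
    counts: Mapping[str, int]
    site_id: str | None = None
    weight_g: float | None = None

    def __post_init__(self) -> None:
        if self.period not in PERIODS:
            raise ValidationError(
                f"sample {self.sample_id!r}: period {self.period!r} "
                f"must be one of {PERIODS}"
            )
        for fly_id, c in self.counts.items():
            if c < 0:
                raise ValidationError(
                    f"sample {self.sample_id!r}: negative count {c} "
                    f"for fly {fly_id!r}"
                )
        if self.weight_g is not None and self.weight_g <= 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: weight_g must be positive"
            )

    def total(self) -> int:
        return int(sum(self.counts.values()))


@dataclass
class Dataset:
    """A registry-validated collection of fruit samples.

    Registries fix a deterministic ordering of plants and flies that every
    matrix built downstream inherits.
    """

    flies: list[FlySpecies]
    plants: list[PlantSpecies]
    samples: list[FruitSample]
    invasion_year: int = 2000

    def __post_init__(self) -> None:
        self.validate()

    # -- registry lookups ------------------------------------------------
    @property
    def fly_ids(self) -> list[str]:
        return [f.fly_id for f in self.flies]

    @property
    def plant_ids(self) -> list[str]:
        return [p.plant_id for p in self.plants]

    def fly(self, fly_id: str) -> FlySpecies:
        return self._fly_index[fly_id]

    def plant(self, plant_id: str) -> PlantSpecies:
        return self._plant_index[plant_id]

    def validate(self) -> None:
        fly_ids = self.fly_ids
        if len(set(fly_ids)) != len(fly_ids):
            raise ValidationError("duplicate fly_id in registry")
        plant_ids = self.plant_ids
        if len(set(plant_ids)) != len(plant_ids):
            raise ValidationError("duplicate plant_id in registry")
        self._fly_index = {f.fly_id: f for f in self.flies}
        self._plant_index = {p.plant_id: p for p in self.plants}
        seen: set[str] = set()
        for s in self.samples:
            if s.sample_id in seen:
                raise ValidationError(f"duplicate sample_id {s.sample_id!r}")
            seen.add(s.sample_id)
            if s.plant_id not in self._plant_index:
                raise ValidationError(
                    f"sample {s.sample_id!r}: unknown plant {s.plant_id!r}"
                )
            for fly_id in s.counts:
                if fly_id not in self._fly_index:
                    raise ValidationError(
                        f"sample {s.sample_id!r}: unknown fly {fly_id!r}"
                    )

    # -- derived views ---------------------------------------------------
    def samples_for(self, plant_id: str, period: str) -> list[FruitSample]:
        return [
            s
            for s in self.samples
            if s.plant_id == plant_id and s.period == period
        ]

    def sample_counts_per_plant(self) -> pd.DataFrame:
        """Number of fruits per plant and period (plants x {before, after})."""
        out = pd.DataFrame(
            0, index=self.plant_ids, columns=list(PERIODS), dtype=int
        )
        for s in self.samples:
            out.loc[s.plant_id, s.period] += 1
        return out

    def count_matrix(self, plant_id: str, period: str) -> np.ndarray:
        """(n_fruits x n_flies) integer count matrix for one plant/period."""
        flies = self.fly_ids
        rows = [
            [s.counts.get(f, 0) for f in flies]
            for s in self.samples_for(plant_id, period)
        ]
        return np.asarray(rows, dtype=float).reshape(len(rows), len(flies))

    def to_frame(self) -> pd.DataFrame:
        """Wide per-sample table: one row per fruit, one column per fly."""
        flies = self.fly_ids
        records = []
        for s in self.samples:
            rec = {
                "sample_id": s.sample_id,
                "plant_id": s.plant_id,
                "period": s.period,
                "site_id": s.site_id if s.site_id is not None else "",
                "weight_g": s.weight_g if s.weight_g is not None else "",
            }
            for f in flies:
                rec[f] = int(s.counts.get(f, 0))
            records.append(rec)
        cols = ["sample_id", "plant_id", "period", "site_id", "weight_g"] + flies
        return pd.DataFrame.from_records(records, columns=cols)

    def restrict_plants(self, keep: Iterable[str]) -> "Dataset":
        keep_set = set(keep)
        plants = [p for p in self.plants if p.plant_id in keep_set]
        samples = [s for s in self.samples if s.plant_id in keep_set]
        return Dataset(
            flies=list(self.flies),
            plants=plants,
            samples=samples,
            invasion_year=self.invasion_year,
        )

    def flies_present(self, period: str) -> list[str]:
        """Fly ids with at least one emerged individual in the period."""
        totals = {f: 0 for f in self.fly_ids}
        for s in self.samples:
            if s.period != period:
                continue
            for f, c in s.counts.items():
                totals[f] += c
        return [f for f in self.fly_ids if totals[f] > 0]


@dataclass(frozen=True)
class RunConfig:
    """Analysis constants.

    Defaults mirror the study design: plants kept only if sampled at least
    four times in each period, 10,000 bootstrap matrices, 95% percentile
    intervals, a QIC gap of 10 for decisive model selection, and a 0.10
    drop in interaction proportion to flag a weakened link.
    """

    invasion_year: int = 2000
    min_samples_before: int = 4
    min_samples_after: int = 4
    bootstrap_reps: int = 10_000
    ci_quantiles: tuple[float, float] = (0.025, 0.975)
    presence_threshold: int = 1
    qic_delta: float = 10.0
    decrease_threshold: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.ci_quantiles
        if not (0.0 < lo < hi < 1.0):
            raise ValidationError("ci_quantiles must be ordered within (0,1)")
        if not (0.0 < self.decrease_threshold < 1.0):
            raise ValidationError("decrease_threshold must be in (0,1)")
        for name in (
            "min_samples_before",
            "min_samples_after",
            "bootstrap_reps",
            "presence_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.qic_delta <= 0:
            raise ValidationError("qic_delta must be positive")

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "ci_quantiles" in raw:
            raw["ci_quantiles"] = tuple(raw["ci_quantiles"])
        return cls(**raw)

    def to_json(self, path: str) -> None:
        d = self.__dict__.copy()
        d["ci_quantiles"] = list(self.ci_quantiles)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)

    def with_(self, **kw) -> "RunConfig":
        return replace(self, **kw)


def period_from_year(year: int, invasion_year: int) -> str:
    """Samples from the invasion year itself count as post-invasion."""
    return BEFORE if year < invasion_year else AFTER
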