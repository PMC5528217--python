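"""Sample filtering and plants-x-flies occurrence / capacity summaries."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import BEFORE, AFTER, PERIODS, Dataset, RunConfig, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PresenceMatrix:
    """Binary plants-x-flies occurrence table for one period.

    A cell is 1 when the total number of flies of that species emerged
    over all of the plant's fruits in the period reaches the presence
    threshold (default: a single fly).
    """

    period: str
    table: pd.DataFrame  # index: plant_ids, columns: fly_ids, values 0/1

    @property
    def plant_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def fly_ids(self) -> list[str]:
        return list(self.table.columns)

    def values(self) -> np.ndarray:
        return self.table.to_numpy(dtype=float)


@dataclass
class BioticCapacity:
    """Mean total fly yield per fruit, per plant, pooled over both periods.

    Used to weight raw per-fruit counts so that exploiting a plant whose
    fruits carry many flies of any species does not inflate apparent
    specialization on that plant.
    """

    w: pd.Series  # index plant_id -> mean flies per fruit

    def __getitem__(self, plant_id: str) -> float:
        return float(self.w[plant_id])

    def as_array(self, plant_ids: list[str]) -> np.ndarray:
        return self.w.reindex(plant_ids).to_numpy(dtype=float)


@dataclass
class FilterResult:
    dataset: Dataset
    excluded: pd.DataFrame = field(default_factory=pd.DataFrame)


def filter_plants(dataset: Dataset, config: RunConfig) -> FilterResult:
    """Keep plants sampled at least ``min_samples_before`` times before AND
    ``min_samples_after`` times after the invasion, regardless of how many
    flies emerged; drop every sample of an excluded plant."""
    counts = dataset.sample_counts_per_plant()
    keep_mask = (counts[BEFORE] >= config.min_samples_before) & (
        counts[AFTER] >= config.min_samples_after
    )
    kept = [p for p in dataset.plant_ids if keep_mask[p]]
    excluded = counts.loc[~keep_mask].copy()
    excluded.index.name = "plant_id"
    if not kept:
        raise ValidationError(
            "no plant satisfies the sampling thresholds "
            f"({config.min_samples_before} before / {config.min_samples_after} after); "
            "review min_samples_before/min_samples_after"
        )
    if len(excluded):
        logger.info(
            "excluded %d plants below sampling thresholds: %s",
            len(excluded),
            list(excluded.index),
        )
    return FilterResult(dataset=dataset.restrict_plants(kept), excluded=excluded)


def build_presence(dataset: Dataset, period: str, config: RunConfig) -> PresenceMatrix:
    if period not in PERIODS:
        raise ValidationError(f"unknown period {period!r}")
    flies = dataset.flies_present(period)
    totals = pd.DataFrame(0, index=dataset.plant_ids, columns=flies, dtype=int)
    for s in dataset.samples:
        if s.period != period:
            continue
        for f, c in s.counts.items():
            if f in totals.columns:
                totals.loc[s.plant_id, f] += c
    table = (totals >= config.presence_threshold).astype(int)
    return PresenceMatrix(period=period, table=table)


def biotic_capacity(dataset: Dataset) -> BioticCapacity:
    """w_j: mean over every fruit of plant j (both periods pooled) of the
    total flies of any species emerged from that fruit."""
    sums: dict[str, list[int]] = {p: [] for p in dataset.plant_ids}
    for s in dataset.samples:
        sums[s.plant_id].append(s.total())
    w = {}
    for p, totals in sums.items():
        if not totals:
            raise ValidationError(f"plant {p!r} has no samples; filter first")
        w[p] = float(np.mean(totals))
        if w[p] == 0.0:
            logger.warning("plant %r yielded zero flies in every fruit", p)
    return BioticCapacity(w=pd.Series(w).reindex(dataset.plant_ids))


def host_richness(dataset: Dataset, period: str, config: RunConfig) -> pd.Series:
    """Number of host plants per fly species (column sums of presence)."""
    presence = build_presence(dataset, period, config)
    return presence.table.sum(axis=0)


def interaction_change(
    before_means: pd.DataFrame,
    after_means: pd.DataFrame,
    config: RunConfig,
    before_ci: dict | None = None,
    after_ci: dict | None = None,
) -> pd.DataFrame:
    """Flag (fly, plant) interactions whose mean proportion dropped by at
    least ``decrease_threshold`` between periods.

    Inputs are the bootstrap-mean interaction matrices (plants x flies).
    Flies absent from one period (e.g. the invader before it arrived) are
    skipped.  When per-cell bootstrap CIs are supplied, each flagged pair
    additionally reports whether the two intervals are disjoint.
    """
    shared_flies = [f for f in before_means.columns if f in after_means.columns]
    shared_plants = [p for p in before_means.index if p in after_means.index]
    rows = []
    for f in shared_flies:
        for p in shared_plants:
            b = float(before_means.loc[p, f])
            a = float(after_means.loc[p, f])
            drop = b - a
            if drop >= config.decrease_threshold:
                rec = {
                    "fly_id": f,
                    "plant_id": p,
                    "mean_before": b,
                    "mean_after": a,
                    "decrease": drop,
                }
                if before_ci is not None and after_ci is not None:
                    lo_b, hi_b = before_ci[(p, f)]
                    lo_a, hi_a = after_ci[(p, f)]
                    rec["ci_disjoint"] = bool(hi_a < lo_b or hi_b < lo_a)
                rows.append(rec)
    cols = ["fly_id", "plant_id", "mean_before", "mean_after", "decrease"]
    if before_ci is not None and after_ci is not None:
        cols.append("ci_disjoint")
    return pd.DataFrame(rows, columns=cols)
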