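"""Readers and writers: sample tables (CSV), phylogenies (newick), reports.

Two sample-table dialects are accepted and produce identical datasets:

wide
    ``sample_id,plant_id,date|period,site_id,weight_g,<fly_id>...`` with one
    count column per fly species.
long
    ``sample_id,plant_id,date|period,site_id,weight_g,fly_id,count`` with one
    row per (fruit, fly) pair; omitted pairs count as zero.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .data import (
    Dataset,
    FlySpecies,
    PlantSpecies,
    FruitSample,
    PERIODS,
    ValidationError,
    period_from_year,
)

_META_COLS = {"sample_id", "plant_id", "date", "period", "site_id", "weight_g"}


def _period_of(row: pd.Series, invasion_year: int) -> str:
    if "period" in row.index and isinstance(row["period"], str) and row["period"]:
        period = row["period"].strip().lower()
        if period not in PERIODS:
            raise ValidationError(
                f"sample {row['sample_id']!r}: period {period!r} "
                f"must be one of {PERIODS}"
            )
        return period
    if "date" not in row.index or pd.isna(row["date"]):
        raise ValidationError(
            f"sample {row['sample_id']!r}: neither period nor date given"
        )
    ts = pd.to_datetime(str(row["date"]), errors="coerce")
    if pd.isna(ts):
        raise ValidationError(
            f"sample {row['sample_id']!r}: unparseable date {row['date']!r}"
        )
    return period_from_year(int(ts.year), invasion_year)


def _opt_str(v) -> str | None:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    s = str(v).strip()
    return s or None


def _opt_float(v) -> float | None:
    if v is None or v == "" or (isinstance(v, float) and np.isnan(v)):
        return None
    return float(v)


def read_samples(
    path: str | Path,
    fly_registry_policy: str = "infer",
    flies: list[FlySpecies] | None = None,
    plants: list[PlantSpecies] | None = None,
    invasion_year: int = 2000,
) -> Dataset:
    """Read a fruit-sample table (wide or long CSV) into a :class:`Dataset`.

    Under ``fly_registry_policy="strict"`` every fly (and plant, if a plant
    registry is supplied) must already be registered; under ``"infer"``
    unknown species are appended to the registry in order of appearance.
    """
    if fly_registry_policy not in ("strict", "infer"):
        raise ValueError("fly_registry_policy must be 'strict' or 'infer'")
    df = pd.read_csv(path, dtype={"sample_id": str, "plant_id": str})
    is_long = "fly_id" in df.columns and "count" in df.columns

    known_flies = {f.fly_id for f in flies} if flies else set()
    known_plants = {p.plant_id for p in plants} if plants else set()
    fly_registry = list(flies) if flies else []
    plant_registry = list(plants) if plants else []

    def _touch_fly(fly_id: str) -> None:
        if fly_id in known_flies:
            return
        if fly_registry_policy == "strict":
            raise ValidationError(f"unknown fly {fly_id!r} under strict policy")
        known_flies.add(fly_id)
        fly_registry.append(FlySpecies(fly_id=fly_id))

    def _touch_plant(plant_id: str) -> None:
        if plant_id in known_plants:
            return
        if fly_registry_policy == "strict" and plants is not None:
            raise ValidationError(
                f"unknown plant {plant_id!r} under strict policy"
            )
        known_plants.add(plant_id)
        plant_registry.append(PlantSpecies(plant_id=plant_id))

    samples: list[FruitSample] = []
    if is_long:
        key_cols = [c for c in df.columns if c in _META_COLS]
        grouped = df.groupby("sample_id", sort=False)
        for sample_id, grp in grouped:
            head = grp.iloc[0]
            plant_id = str(head["plant_id"])
            _touch_plant(plant_id)
            counts: dict[str, int] = {}
            for _, r in grp.iterrows():
                fly_id = str(r["fly_id"])
                _touch_fly(fly_id)
                c = int(r["count"])
                if c < 0:
                    raise ValidationError(
                        f"sample {sample_id!r}: negative count for {fly_id!r}"
                    )
                counts[fly_id] = counts.get(fly_id, 0) + c
            samples.append(
                FruitSample(
                    sample_id=str(sample_id),
                    plant_id=plant_id,
                    period=_period_of(head[key_cols], invasion_year),
                    counts=counts,
                    site_id=_opt_str(head.get("site_id")),
                    weight_g=_opt_float(head.get("weight_g")),
                )
            )
    else:
        count_cols = [c for c in df.columns if c not in _META_COLS]
        if not count_cols:
            raise ValidationError("wide table has no fly count columns")
        for c in count_cols:
            _touch_fly(str(c))
        for _, r in df.iterrows():
            plant_id = str(r["plant_id"])
            _touch_plant(plant_id)
            counts = {}
            for c in count_cols:
                v = int(r[c])
                if v < 0:
                    raise ValidationError(
                        f"sample {r['sample_id']!r}: negative count for {c!r}"
                    )
                if v:
                    counts[str(c)] = v
            samples.append(
                FruitSample(
                    sample_id=str(r["sample_id"]),
                    plant_id=plant_id,
                    period=_period_of(r, invasion_year),
                    counts=counts,
                    site_id=_opt_str(r.get("site_id")),
                    weight_g=_opt_float(r.get("weight_g")),
                )
            )

    return Dataset(
        flies=fly_registry,
        plants=plant_registry,
        samples=samples,
        invasion_year=invasion_year,
    )


def write_samples(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset as a wide CSV (the canonical on-disk form)."""
    dataset.to_frame().to_csv(path, index=False)


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a single rooted newick tree with branch lengths.

    Trees tagged ``[&U]`` (explicitly unrooted), files with several trees,
    and trees with missing branch lengths are rejected: the downstream
    Brownian-motion correlation needs root-to-tip path lengths as given.
    """
    trees = dendropy.TreeList.get(
        path=str(path),
        schema="newick",
        rooting="default-rooted",
        suppress_internal_node_taxa=True,
    )
    if len(trees) == 0:
        raise ValidationError(f"no tree found in {path}")
    if len(trees) > 1:
        raise ValidationError(f"{path} contains {len(trees)} trees; expected 1")
    tree = trees[0]
    if not tree.is_rooted:
        raise ValidationError(f"{path}: tree is explicitly unrooted")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue  # the root edge may legitimately lack a length
        if edge.length is None:
            raise ValidationError(
                f"{path}: missing branch length above node "
                f"{edge.head_node.taxon.label if edge.head_node.taxon else '<internal>'}"
            )
        if edge.length < 0:
            raise ValidationError(f"{path}: negative branch length")
    return tree


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def write_report(report, path: str | Path) -> None:
    """Serialize a report object (anything exposing ``to_frame``/``to_dict``).

    ``path`` ending in ``.json`` gets the full JSON document; any other
    suffix gets the flat CSV view.  Confidence intervals occupy explicit
    ``ci_low``/``ci_high`` columns.
    """
    path = Path(path)
    os.makedirs(path.parent or Path("."), exist_ok=True)
    if path.suffix == ".json":
        with open(path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    else:
        report.to_frame().to_csv(path, index=False)


def read_report_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
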