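"""Shared fixtures and deterministic hypothesis configuration."""

from __future__ import annotations

import logging

import pytest
from hypothesis import HealthCheck, settings

from flyrange.data import AFTER, BEFORE, Dataset, FlySpecies, FruitSample, PlantSpecies

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

logging.disable(logging.WARNING)


def make_dataset(
    plant_fruits: dict[str, dict[str, list[dict[str, int]]]],
    flies: list[str],
    guilds: dict[str, str] | None = None,
) -> Dataset:
    """Build a dataset from nested literals.

    ``plant_fruits[plant_id][period]`` is a list of per-fruit count dicts.
    """
    guilds = guilds or {}
    counter = 0
    samples = []
    for plant_id, periods in plant_fruits.items():
        for period, fruit_list in periods.items():
            for counts in fruit_list:
                counter += 1
                samples.append(
                    FruitSample(
                        sample_id=f"S{counter:04d}",
                        plant_id=plant_id,
                        period=period,
                        counts=counts,
                    )
                )
    return Dataset(
        flies=[FlySpecies(fly_id=f, guild=guilds.get(f, "unknown")) for f in flies],
        plants=[PlantSpecies(plant_id=p) for p in plant_fruits],
        samples=samples,
    )


@pytest.fixture(scope="session")
def scenario_run():
    """One simulated study (seed 1), filtered, with aligned correlation."""
    from flyrange.data import RunConfig
    from flyrange.matrices import filter_plants
    from flyrange.phylo import align_to_registry, correlation_from_tree
    from flyrange.synthetic import ScenarioConfig, simulate_scenario

    config = RunConfig(bootstrap_reps=500)
    dataset, tree, truth = simulate_scenario(ScenarioConfig(seed=1))
    dataset = filter_plants(dataset, config).dataset
    corr = align_to_registry(correlation_from_tree(tree), dataset.plants)
    return dict(
        dataset=dataset, tree=tree, truth=truth, corr=corr, config=config
    )
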