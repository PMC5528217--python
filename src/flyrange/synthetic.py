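"""Synthetic fruit-fly community generator.

Emulates the statistical shape of a long-term per-fruit emergence
database: ~36 host plants in ~15 families on a Yule phylogeny, a fly
community of broad generalists, specialists confined to two separate
host clades (cucurbit-like and solanum-like), and a late-arriving
generalist invader.  After the invasion, generalist host-use
distributions contract smoothly toward their top hosts (an elementwise
power transform), while specialist diets stay put — the qualitative
pattern the analysis pipeline is meant to detect.

Per fruit, emergence counts are conditionally independent across fly
species given the host plant, Poisson (or negative binomial) with mean
proportional to the fly's preference for the plant, scaled so the most
preferred host carries the fly's ``mean_load``.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .data import AFTER, BEFORE, Dataset, FlySpecies, FruitSample, PlantSpecies, ValidationError
from .diversity import alpha_diversity, beta_turnover

CUCURBIT = "cucurbit"
SOLANUM = "solanum"


@dataclass(frozen=True)
class FlySpec:
    fly_id: str
    guild: str  # generalist | specialist | invader
    clade: str | None = None  # specialist clade restriction
    mean_load: float = 4.0
    after_only: bool = False


DEFAULT_FLIES = (
    FlySpec("GEN1", "generalist", mean_load=4.0),
    FlySpec("GEN2", "generalist", mean_load=4.0),
    FlySpec("GEN3", "generalist", mean_load=3.0),
    FlySpec("CUC1", "specialist", clade=CUCURBIT, mean_load=6.0),
    FlySpec("CUC2", "specialist", clade=CUCURBIT, mean_load=5.0),
    FlySpec("CUC3", "specialist", clade=CUCURBIT, mean_load=5.0),
    FlySpec("SOL1", "specialist", clade=SOLANUM, mean_load=6.0),
    FlySpec("INV1", "invader", mean_load=6.0, after_only=True),
)


@dataclass
class ScenarioConfig:
    """Study-condition knobs for the generator.

    Defaults reproduce the database shape the analysis expects: 36 plants
    in 15 families, seven resident flies plus one post-invasion arrival,
    heterogeneous sampling depth, and a post-invasion contraction of
    generalist diets (``contraction_factor`` < 1 concentrates preference
    mass on each generalist's top hosts; 1 means no change).
    """

    n_plants: int = 36
    n_families: int = 15
    flies: tuple[FlySpec, ...] = DEFAULT_FLIES
    samples_per_plant: tuple[int, int] = (5, 30)  # inclusive range per period
    contraction_factor: float = 0.5
    count_model: str = "poisson"  # or "negbinom"
    negbinom_dispersion: float = 1.0  # gamma shape; smaller = more overdispersed
    generalist_support: tuple[int, int] = (12, 20)
    invader_support: tuple[int, int] = (8, 12)
    invader_concentration: float = 0.25  # Dirichlet-like skew; small = narrow use
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plants < 2:
            raise ValidationError("n_plants must be >= 2")
        if not (0.0 < self.contraction_factor <= 1.0):
            raise ValidationError("contraction_factor must be in (0, 1]")
        if self.count_model not in ("poisson", "negbinom"):
            raise ValidationError("count_model must be poisson or negbinom")
        lo, hi = self.samples_per_plant
        if lo < 1 or hi < lo:
            raise ValidationError("samples_per_plant range invalid")


@dataclass
class NicheProfile:
    """True host-exploitation distribution of one fly in one period."""

    fly_id: str
    preference: pd.Series  # plant_id -> weight, sums to 1
    mean_load: float

    def __post_init__(self) -> None:
        s = float(self.preference.sum())
        if abs(s - 1.0) > 1e-12:
            raise ValidationError(f"{self.fly_id}: preference sums to {s}")
        if not (self.preference > 0).any():
            raise ValidationError(f"{self.fly_id}: empty support")
        if self.mean_load <= 0:
            raise ValidationError(f"{self.fly_id}: mean_load must be positive")

    def contracted(self, factor: float) -> "NicheProfile":
        """Raise preferences to 1/factor and renormalize (factor<1 sharpens)."""
        w = self.preference.to_numpy(dtype=float) ** (1.0 / factor)
        w = w / w.sum()
        return NicheProfile(
            fly_id=self.fly_id,
            preference=pd.Series(w, index=self.preference.index),
            mean_load=self.mean_load,
        )


def simulate_yule_tree(
    n_tips: int, birth_rate: float = 1.0, seed: int = 0
) -> dendropy.Tree:
    """Pure-birth tree with ``n_tips`` extant tips labeled P01, P02, ...

    Reproducible under a fixed seed; branch lengths strictly positive.
    """
    if n_tips < 1:
        raise ValidationError("n_tips must be >= 1")
    if birth_rate <= 0:
        raise ValidationError("birth_rate must be positive")
    rng = random.Random(seed)
    labels = [f"P{i + 1:02d}" for i in range(n_tips)]
    if n_tips == 1:
        t = rng.expovariate(birth_rate)
        tree = dendropy.Tree()
        tree.is_rooted = True
        taxon = tree.taxon_namespace.new_taxon(label=labels[0])
        child = tree.seed_node.new_child(taxon=taxon, edge_length=t)
        del child
        return tree
    from dendropy.model import birthdeath

    tree = birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
    )
    tree.is_rooted = True
    leaves = list(tree.leaf_node_iter())
    for leaf, label in zip(leaves, labels):
        leaf.taxon.label = label
    # guard against zero-length edges from simultaneous events
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None or edge.length <= 0:
            edge.length = 1e-9
    return tree


def _clade_tips(tree: dendropy.Tree) -> list[list[str]]:
    """Tip-label sets of all internal nodes, postorder."""
    out = []
    for node in tree.postorder_internal_node_iter():
        out.append([lf.taxon.label for lf in node.leaf_iter()])
    return out


def pick_specialist_clades(
    tree: dendropy.Tree, min_size: int = 4, max_size: int = 7
) -> dict[str, list[str]]:
    """Choose two disjoint clades to host the specialist guilds."""
    candidates = [c for c in _clade_tips(tree) if min_size <= len(c) <= max_size]
    candidates.sort(key=len, reverse=True)
    for a_i, a in enumerate(candidates):
        a_set = set(a)
        for b in candidates[a_i + 1:]:
            if a_set.isdisjoint(b):
                return {CUCURBIT: sorted(a), SOLANUM: sorted(b)}
    raise ValidationError(
        f"tree has no two disjoint clades of {min_size}-{max_size} tips; "
        "try another seed or more tips"
    )


def make_plants(
    tree: dendropy.Tree, scenario: ScenarioConfig
) -> tuple[list[PlantSpecies], dict[str, list[str]]]:
    """Plant registry with family labels; specialist clades get their own
    families, remaining tips are chunked into the other families in tree
    (traversal) order, approximating phylogenetically coherent families."""
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    clades = pick_specialist_clades(tree)
    in_clade = {t: CUCURBIT for t in clades[CUCURBIT]}
    in_clade.update({t: SOLANUM for t in clades[SOLANUM]})
    others = [t for t in tips if t not in in_clade]
    n_other_fam = max(scenario.n_families - 2, 1)
    plants = []
    fam_names = {CUCURBIT: "Cucurbitaceae-like", SOLANUM: "Solanaceae-like"}
    chunk = max(1, round(len(others) / n_other_fam))
    for t in tips:
        if t in in_clade:
            fam = fam_names[in_clade[t]]
        else:
            fam = f"Family{others.index(t) // chunk + 1:02d}"
        plants.append(PlantSpecies(plant_id=t, name=t, family=fam))
    return plants, clades


def make_niches(
    tree: dendropy.Tree,
    scenario: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, dict[str, NicheProfile]]:
    """True host-use profiles per period.

    Specialists are confined to their clade's tips in both periods;
    generalists (and the invader) live outside the specialist clades, and
    generalist profiles contract after the invasion.  The invader's
    support is drawn from the generalists' preferred hosts, so it
    genuinely competes with them and shares nothing with specialists.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    plants, clades = make_plants(tree, scenario)
    plant_ids = [p.plant_id for p in plants]
    clade_set = {t for tips in clades.values() for t in tips}
    open_hosts = [p for p in plant_ids if p not in clade_set]
    if len(open_hosts) < 3:
        raise ValidationError("too few non-specialist hosts for generalists")

    before: dict[str, NicheProfile] = {}
    generalist_tops: list[str] = []
    for spec in scenario.flies:
        if spec.guild == "specialist":
            tips = clades[spec.clade]
            w = rng.gamma(2.0, 1.0, size=len(tips))
            pref = pd.Series(0.0, index=plant_ids)
            pref.loc[tips] = w / w.sum()
        elif spec.guild == "generalist":
            lo, hi = scenario.generalist_support
            k = int(rng.integers(lo, min(hi, len(open_hosts)) + 1))
            support = list(rng.choice(open_hosts, size=k, replace=False))
            w = rng.gamma(1.0, 1.0, size=k)
            pref = pd.Series(0.0, index=plant_ids)
            pref.loc[support] = w / w.sum()
            generalist_tops.extend(
                pref.sort_values(ascending=False).index[: max(3, k // 3)]
            )
        else:  # invader: narrow, skewed use of generalist-favoured hosts
            pool = sorted(set(generalist_tops)) or open_hosts
            lo, hi = scenario.invader_support
            k = int(min(rng.integers(lo, hi + 1), len(pool)))
            support = list(rng.choice(pool, size=k, replace=False))
            w = rng.gamma(scenario.invader_concentration, 1.0, size=k) + 1e-9
            pref = pd.Series(0.0, index=plant_ids)
            pref.loc[support] = w / w.sum()
        before[spec.fly_id] = NicheProfile(
            fly_id=spec.fly_id, preference=pref, mean_load=spec.mean_load
        )

    after: dict[str, NicheProfile] = {}
    for spec in scenario.flies:
        prof = before[spec.fly_id]
        if spec.guild == "generalist":
            after[spec.fly_id] = prof.contracted(scenario.contraction_factor)
        else:
            after[spec.fly_id] = prof
    # the invader is not part of the community before its arrival
    before = {
        fid: prof
        for fid, prof in before.items()
        if not next(s for s in scenario.flies if s.fly_id == fid).after_only
    }
    return {BEFORE: before, AFTER: after}


def simulate_samples(
    niches: dict[str, dict[str, NicheProfile]],
    scenario: ScenarioConfig,
    seed: int | None = None,
    tree: dendropy.Tree | None = None,
) -> Dataset:
    """Draw per-fruit emergence counts for both periods.

    Fruits per plant and period are drawn uniformly from the configured
    range (heterogeneous depth); counts per fly are Poisson (or gamma-
    mixed Poisson) with mean ``mean_load * pref / max(pref)``, independent
    across flies given the fruit.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    any_period = niches[AFTER]
    plant_ids = list(next(iter(any_period.values())).preference.index)
    if tree is not None:
        plants, _ = make_plants(tree, scenario)
    else:
        plants = [PlantSpecies(plant_id=p, name=p) for p in plant_ids]
    guild_of = {s.fly_id: s.guild for s in scenario.flies}
    fly_ids = [s.fly_id for s in scenario.flies]
    flies = [
        FlySpecies(fly_id=f, name=f, guild="invader" if guild_of[f] == "invader" else guild_of[f])
        for f in fly_ids
    ]

    lo, hi = scenario.samples_per_plant
    samples: list[FruitSample] = []
    counter = 0
    for period in (BEFORE, AFTER):
        profiles = niches[period]
        present = [f for f in fly_ids if f in profiles]
        # per-fly per-plant expected load
        mean = np.zeros((len(plant_ids), len(present)))
        for i, f in enumerate(present):
            pref = profiles[f].preference.to_numpy(dtype=float)
            mean[:, i] = profiles[f].mean_load * pref / pref.max()
        for j, plant in enumerate(plant_ids):
            n_fruits = int(rng.integers(lo, hi + 1))
            for _ in range(n_fruits):
                counter += 1
                if scenario.count_model == "poisson":
                    lam = mean[j]
                else:
                    shape = scenario.negbinom_dispersion
                    lam = mean[j] * rng.gamma(shape, 1.0 / shape, size=len(present))
                c = rng.poisson(lam)
                counts = {f: int(c[i]) for i, f in enumerate(present) if c[i] > 0}
                samples.append(
                    FruitSample(
                        sample_id=f"S{counter:06d}",
                        plant_id=plant,
                        period=period,
                        counts=counts,
                    )
                )
    return Dataset(flies=flies, plants=plants, samples=samples)


def true_indices(
    niches: dict[str, dict[str, NicheProfile]],
) -> dict[str, dict]:
    """Ground-truth D_alpha per fly and turnover per pair, per period."""
    out: dict[str, dict] = {}
    for period, profiles in niches.items():
        fly_ids = list(profiles)
        d_alpha = {
            f: alpha_diversity(profiles[f].preference.to_numpy()) for f in fly_ids
        }
        turnover = {}
        for a_i, a in enumerate(fly_ids):
            for b in fly_ids[a_i + 1:]:
                turnover[(a, b)] = beta_turnover(
                    profiles[a].preference.to_numpy(),
                    profiles[b].preference.to_numpy(),
                )
        out[period] = {"d_alpha": d_alpha, "turnover": turnover}
    return out


def simulate_scenario(
    scenario: ScenarioConfig | None = None, seed: int | None = None
) -> tuple[Dataset, dendropy.Tree, dict]:
    """One-call generator: tree, niches, dataset and ground truth."""
    if scenario is None:
        scenario = ScenarioConfig()
    if seed is not None:
        scenario = ScenarioConfig(**{**scenario.__dict__, "seed": seed})
    tree = simulate_yule_tree(scenario.n_plants, seed=scenario.seed)
    rng = np.random.default_rng(scenario.seed)
    niches = make_niches(tree, scenario, rng=rng)
    dataset = simulate_samples(niches, scenario, seed=scenario.seed + 1, tree=tree)
    truth = true_indices(niches)
    return dataset, tree, truth
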