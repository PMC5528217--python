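"""End-to-end orchestration of the before/after host-range analysis."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as fio
from .data import AFTER, BEFORE, Dataset, RunConfig, ValidationError
from .diversity import bootstrap_indices, compare_periods
from .gee import fit_model_suite
from .matrices import biotic_capacity, build_presence, filter_plants, interaction_change
from .phylo import align_to_registry, correlation_from_tree

logger = logging.getLogger(__name__)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    seed: int
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    version: str = ""

    def to_dict(self) -> dict:
        return self.__dict__.copy()

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def run_all(
    samples_path: str | Path,
    tree_path: str | Path,
    config: RunConfig | str | Path,
    out_dir: str | Path,
) -> RunManifest:
    """Full analysis: filter, community-structure model selection on the
    pre-invasion presence matrix, bootstrap diversity for both periods,
    the before/after change table, and flagged weakened interactions.

    Writes qic_table, diversity_before, diversity_after, changes and
    interaction_changes (CSV + JSON each) plus a manifest with digests.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.from_json(str(config))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__

    manifest = RunManifest(
        config=config.__dict__.copy(), seed=config.seed, version=__version__
    )
    manifest.config["ci_quantiles"] = list(config.ci_quantiles)
    for key, p in (("samples", Path(samples_path)), ("tree", Path(tree_path))):
        manifest.inputs[key] = _digest(p)

    def _stage(name):
        logger.info("stage: %s", name)
        return time.perf_counter()

    stage = "read"
    try:
        t0 = _stage(stage)
        dataset = fio.read_samples(samples_path, invasion_year=config.invasion_year)
        tree = fio.read_tree(tree_path)
        manifest.timings[stage] = time.perf_counter() - t0

        stage = "filter"
        t0 = _stage(stage)
        fres = filter_plants(dataset, config)
        dataset = fres.dataset
        if len(fres.excluded):
            manifest.warnings.append(
                f"excluded {len(fres.excluded)} plants below sampling thresholds"
            )
        manifest.timings[stage] = time.perf_counter() - t0

        stage = "phylo"
        t0 = _stage(stage)
        corr = align_to_registry(correlation_from_tree(tree), dataset.plants)
        manifest.timings[stage] = time.perf_counter() - t0

        stage = "structure"
        t0 = _stage(stage)
        presence = build_presence(dataset, BEFORE, config)
        qic_table = fit_model_suite(presence, corr, config, dataset=dataset)
        for note in qic_table.rows["note"]:
            if "ridge" in str(note):
                manifest.warnings.append(f"ridge-stabilized fit: {note}")
                break
        fio.write_report(qic_table, out / "qic_table.csv")
        fio.write_report(qic_table, out / "qic_table.json")
        manifest.timings[stage] = time.perf_counter() - t0

        stage = "diversity"
        t0 = _stage(stage)
        w = biotic_capacity(dataset)
        rng = np.random.default_rng(config.seed)
        rep_before = bootstrap_indices(dataset, BEFORE, w, config, rng=rng)
        rep_after = bootstrap_indices(dataset, AFTER, w, config, rng=rng)
        for rep in (rep_before, rep_after):
            bad = rep.per_fly[rep.per_fly["n_valid_reps"] < config.bootstrap_reps]
            for _, r in bad.iterrows():
                manifest.warnings.append(
                    f"{r['fly_id']} ({rep.period}): {int(r['n_valid_reps'])}"
                    f"/{config.bootstrap_reps} valid replicates"
                )
        fio.write_report(rep_before, out / "diversity_before.csv")
        fio.write_report(rep_before, out / "diversity_before.json")
        fio.write_report(rep_after, out / "diversity_after.csv")
        fio.write_report(rep_after, out / "diversity_after.json")
        manifest.timings[stage] = time.perf_counter() - t0

        stage = "compare"
        t0 = _stage(stage)
        changes = compare_periods(rep_before, rep_after)
        fio.write_report(changes, out / "changes.csv")
        fio.write_report(changes, out / "changes.json")
        flagged = interaction_change(
            rep_before.mean_matrix,
            rep_after.mean_matrix,
            config,
            before_ci=rep_before.cell_ci,
            after_ci=rep_after.cell_ci,
        )
        flagged.to_csv(out / "interaction_changes.csv", index=False)
        manifest.timings[stage] = time.perf_counter() - t0
    except Exception as err:
        manifest.warnings.append(f"aborted in stage {stage!r}: {err}")
        manifest.write(out / "manifest.json")
        raise

    for p in sorted(out.glob("*.csv")) + sorted(out.glob("*.json")):
        if p.name != "manifest.json":
            manifest.outputs[p.name] = _digest(p)
    manifest.write(out / "manifest.json")
    return manifest


@dataclass
class Diagnostics:
    findings: list  # (severity, message)

    @property
    def fatal(self) -> bool:
        return any(sev == "fatal" for sev, _ in self.findings)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.findings, columns=["severity", "message"])


def validate(
    samples_path: str | Path,
    tree_path: str | Path,
    config: RunConfig | str | Path,
) -> Diagnostics:
    """Pre-flight diagnostics: per-plant sampling vs thresholds, tree
    coverage, and fly registry summary.  Never raises for data findings."""
    if not isinstance(config, RunConfig):
        config = RunConfig.from_json(str(config))
    findings: list[tuple[str, str]] = []
    try:
        dataset = fio.read_samples(samples_path, invasion_year=config.invasion_year)
    except (ValidationError, OSError) as err:
        return Diagnostics(findings=[("fatal", f"samples unreadable: {err}")])
    counts = dataset.sample_counts_per_plant()
    would_drop = counts[
        (counts[BEFORE] < config.min_samples_before)
        | (counts[AFTER] < config.min_samples_after)
    ]
    for plant_id, row in would_drop.iterrows():
        findings.append(
            (
                "info",
                f"plant {plant_id} would be excluded "
                f"({row[BEFORE]} before / {row[AFTER]} after)",
            )
        )
    if len(would_drop) == len(counts):
        findings.append(("fatal", "no plant passes the sampling thresholds"))

    try:
        tree = fio.read_tree(tree_path)
        tips = set(fio.tip_labels(tree))
        kept = [p for p in dataset.plants if p.plant_id not in set(would_drop.index)]
        missing = [p.plant_id for p in kept if p.tip_label not in tips]
        if missing:
            findings.append(
                ("fatal", f"retained plants missing from tree: {missing}")
            )
    except (ValidationError, OSError) as err:
        findings.append(("fatal", f"tree unreadable: {err}"))

    before_flies = set(dataset.flies_present(BEFORE))
    for f in dataset.fly_ids:
        if f in set(dataset.flies_present(AFTER)) and f not in before_flies:
            findings.append(("info", f"fly {f} present only after invasion (invader-like)"))
        elif f not in before_flies and f not in set(dataset.flies_present(AFTER)):
            findings.append(("warning", f"fly {f} never observed"))
    return Diagnostics(findings=findings)
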