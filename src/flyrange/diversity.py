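"""Niche breadth and overlap via Hill numbers, with a one-fruit bootstrap.

Niche breadth of fly species *i* is the Shannon number equivalent of its
host-use distribution p_i over plants,

    D_alpha(i) = exp( -sum_j p_ij ln p_ij ),

the count of equally-used host plants that would give the same entropy
(1 = strict monophagy, n_plants = perfectly even use of every plant).

Niche overlap between flies *i* and *k* uses Jost's multiplicative Shannon
decomposition with equal community weights: D_beta = exp(H_gamma - H_alpha),
rescaled to the turnover index T = (D_beta - 1)/(N - 1) with N = 2
communities, so T = 0 for identical diets and T = 1 for disjoint diets.

Sampling uncertainty is propagated by rebuilding the interaction matrix
many times, each time drawing a single fruit uniformly at random per plant
(a deliberately conservative scheme that is robust to the very uneven
sampling depth across plants), normalizing by biotic capacity and then by
column totals, and recomputing every index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .data import Dataset, RunConfig, ValidationError
from .matrices import BioticCapacity, host_richness

__all__ = [
    "alpha_diversity",
    "beta_turnover",
    "shannon",
    "InteractionMatrix",
    "DiversityReport",
    "ChangeTable",
    "resample_one_fruit",
    "normalize_matrix",
    "bootstrap_indices",
    "compare_periods",
]


def shannon(p: np.ndarray) -> float:
    """Shannon entropy (natural log) with the 0*log(0) = 0 convention."""
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def alpha_diversity(p: np.ndarray) -> float:
    """Number equivalent exp(H) of a host-use distribution."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValidationError("distribution has negative entries")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"distribution sums to {p.sum()!r}, not 1")
    return float(np.exp(shannon(p)))


def beta_turnover(p: np.ndarray, q: np.ndarray) -> float:
    """Pairwise Shannon turnover with equal community weights.

    H_alpha = (H(p)+H(q))/2, H_gamma = H((p+q)/2),
    D_beta = exp(H_gamma - H_alpha), T = D_beta - 1 (since N = 2).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValidationError("distributions must share the same plant order")
    for name, v in (("p", p), ("q", q)):
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValidationError(f"{name} sums to {v.sum()!r}, not 1")
    h_alpha = 0.5 * (shannon(p) + shannon(q))
    h_gamma = shannon(0.5 * (p + q))
    d_beta = np.exp(h_gamma - h_alpha)
    # exact endpoints can drift by float error; D_beta is in [1, 2] by theory
    return float(min(max(d_beta - 1.0, 0.0), 1.0))


@dataclass
class InteractionMatrix:
    """Column-normalized plants-x-flies proportions for one period.

    Every valid (non-all-zero) column sums to 1: p_ij is the share of
    plant j in the biotic-capacity-weighted diet of fly i.
    """

    period: str
    table: pd.DataFrame  # index plant_ids, columns fly_ids
    valid: pd.Series  # per fly: column had any flies this replicate

    def __post_init__(self) -> None:
        sums = self.table.to_numpy(dtype=float).sum(axis=0)
        ok = self.valid.to_numpy(dtype=bool)
        if np.any(np.abs(sums[ok] - 1.0) > 1e-12):
            raise ValidationError("valid columns must sum to 1")


def resample_one_fruit(
    dataset: Dataset, period: str, rng: np.random.Generator
) -> pd.DataFrame:
    """Raw count matrix from one uniformly chosen fruit per plant.

    Draws are taken in registry plant order, so a seeded generator yields
    a reproducible sequence of matrices.
    """
    flies = dataset.flies_present(period)
    fly_pos = {f: i for i, f in enumerate(dataset.fly_ids)}
    rows = []
    for plant_id in dataset.plant_ids:
        counts = dataset.count_matrix(plant_id, period)
        if counts.shape[0] == 0:
            raise ValidationError(
                f"plant {plant_id!r} has no samples in period {period!r}"
            )
        pick = int(rng.integers(0, counts.shape[0]))
        rows.append(counts[pick, [fly_pos[f] for f in flies]])
    return pd.DataFrame(np.vstack(rows), index=dataset.plant_ids, columns=flies)


def normalize_matrix(raw: pd.DataFrame, w: BioticCapacity, period: str = "") -> InteractionMatrix:
    """Biotic-capacity row scaling followed by column normalization."""
    x = raw.to_numpy(dtype=float)
    wj = w.as_array(list(raw.index))
    zero_w = wj <= 0
    if np.any(zero_w & (x.sum(axis=1) > 0)):
        bad = [raw.index[i] for i in np.flatnonzero(zero_w & (x.sum(axis=1) > 0))]
        raise ValidationError(f"zero biotic capacity with nonzero counts: {bad}")
    safe_w = np.where(zero_w, 1.0, wj)
    x = x / safe_w[:, None]
    colsum = x.sum(axis=0)
    valid = colsum > 0
    p = np.zeros_like(x)
    p[:, valid] = x[:, valid] / colsum[valid]
    return InteractionMatrix(
        period=period,
        table=pd.DataFrame(p, index=raw.index, columns=raw.columns),
        valid=pd.Series(valid, index=raw.columns),
    )


@dataclass
class DiversityReport:
    """Per-period niche breadth and overlap summary with bootstrap CIs."""

    period: str
    per_fly: pd.DataFrame  # fly_id, period, richness, d_alpha_mean, ci_low, ci_high, n_valid_reps
    per_pair: pd.DataFrame  # fly_a, fly_b, period, turnover_mean, ci_low, ci_high, n_valid_reps
    mean_matrix: pd.DataFrame  # plants x flies, bootstrap mean of valid p_ij
    cell_ci: dict = field(default_factory=dict)  # (plant_id, fly_id) -> (lo, hi)

    def to_frame(self) -> pd.DataFrame:
        return self.per_fly

    def to_dict(self) -> dict:
        return {
            "period": self.period,
            "per_fly": self.per_fly.to_dict(orient="records"),
            "per_pair": self.per_pair.to_dict(orient="records"),
            "mean_matrix": {
                "plants": list(self.mean_matrix.index),
                "flies": list(self.mean_matrix.columns),
                "values": self.mean_matrix.to_numpy().tolist(),
            },
        }


def _stacked_counts(
    dataset: Dataset, period: str, flies: list[str]
) -> list[np.ndarray]:
    """Per plant (registry order): (n_fruits x n_flies) count array."""
    fly_pos = {f: i for i, f in enumerate(dataset.fly_ids)}
    cols = [fly_pos[f] for f in flies]
    out = []
    for plant_id in dataset.plant_ids:
        counts = dataset.count_matrix(plant_id, period)
        if counts.shape[0] == 0:
            raise ValidationError(
                f"plant {plant_id!r} has no samples in period {period!r}"
            )
        out.append(counts[:, cols])
    return out


def bootstrap_indices(
    dataset: Dataset,
    period: str,
    w: BioticCapacity,
    config: RunConfig,
    rng: np.random.Generator | None = None,
) -> DiversityReport:
    """Bootstrap D_alpha per fly and turnover T per fly pair for a period.

    Each replicate resamples one fruit per plant, normalizes, and evaluates
    every index on the same matrix.  A fly whose resampled column is all
    zeros contributes nothing to its index pools that replicate (reported
    through ``n_valid_reps``) rather than being imputed as monophagous.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    reps = config.bootstrap_reps
    flies = dataset.flies_present(period)
    plants = dataset.plant_ids
    n_j, n_i = len(plants), len(flies)
    per_plant = _stacked_counts(dataset, period, flies)

    # draw fruit indices plant-by-plant in registry order (streamed rng)
    raw = np.empty((reps, n_j, n_i))
    for j, counts in enumerate(per_plant):
        idx = rng.integers(0, counts.shape[0], size=reps)
        raw[:, j, :] = counts[idx]

    wj = w.as_array(plants)
    safe_w = np.where(wj <= 0, 1.0, wj)
    x = raw / safe_w[None, :, None]
    colsum = x.sum(axis=1)  # reps x flies
    valid = colsum > 0
    p = np.zeros_like(x)
    np.divide(x, colsum[:, None, :], out=p, where=valid[:, None, :])

    # entropies per (rep, fly)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    h = -plogp.sum(axis=1)
    d_alpha = np.exp(h)

    lo_q, hi_q = config.ci_quantiles
    fly_rows = []
    richness = host_richness(dataset, period, config)
    for i, f in enumerate(flies):
        ok = valid[:, i]
        n_ok = int(ok.sum())
        if n_ok == 0:
            fly_rows.append(
                dict(
                    fly_id=f, period=period, richness=int(richness.get(f, 0)),
                    d_alpha_mean=np.nan, ci_low=np.nan, ci_high=np.nan,
                    n_valid_reps=0,
                )
            )
            continue
        vals = d_alpha[ok, i]
        fly_rows.append(
            dict(
                fly_id=f,
                period=period,
                richness=int(richness.get(f, 0)),
                d_alpha_mean=float(vals.mean()),
                ci_low=float(np.quantile(vals, lo_q)),
                ci_high=float(np.quantile(vals, hi_q)),
                n_valid_reps=n_ok,
            )
        )
    per_fly = pd.DataFrame(fly_rows)

    pair_rows = []
    for a, b in combinations(range(n_i), 2):
        ok = valid[:, a] & valid[:, b]
        n_ok = int(ok.sum())
        if n_ok == 0:
            pair_rows.append(
                dict(
                    fly_a=flies[a], fly_b=flies[b], period=period,
                    turnover_mean=np.nan, ci_low=np.nan, ci_high=np.nan,
                    n_valid_reps=0,
                )
            )
            continue
        m = 0.5 * (p[ok, :, a] + p[ok, :, b])
        with np.errstate(divide="ignore", invalid="ignore"):
            mlogm = np.where(m > 0, m * np.log(m), 0.0)
        h_gamma = -mlogm.sum(axis=1)
        h_alpha = 0.5 * (h[ok, a] + h[ok, b])
        t = np.clip(np.exp(h_gamma - h_alpha) - 1.0, 0.0, 1.0)
        pair_rows.append(
            dict(
                fly_a=flies[a],
                fly_b=flies[b],
                period=period,
                turnover_mean=float(t.mean()),
                ci_low=float(np.quantile(t, lo_q)),
                ci_high=float(np.quantile(t, hi_q)),
                n_valid_reps=n_ok,
            )
        )
    per_pair = pd.DataFrame(
        pair_rows,
        columns=["fly_a", "fly_b", "period", "turnover_mean", "ci_low",
                 "ci_high", "n_valid_reps"],
    )

    # bootstrap-mean matrix over valid replicates, with per-cell CIs
    mean_mat = np.zeros((n_j, n_i))
    cell_ci: dict = {}
    for i, f in enumerate(flies):
        ok = valid[:, i]
        if ok.any():
            cells = p[ok, :, i]
            mean_mat[:, i] = cells.mean(axis=0)
            lo = np.quantile(cells, lo_q, axis=0)
            hi = np.quantile(cells, hi_q, axis=0)
        else:
            lo = hi = np.zeros(n_j)
        for j, plant in enumerate(plants):
            cell_ci[(plant, f)] = (float(lo[j]), float(hi[j]))
    mean_matrix = pd.DataFrame(mean_mat, index=plants, columns=flies)

    return DiversityReport(
        period=period,
        per_fly=per_fly,
        per_pair=per_pair,
        mean_matrix=mean_matrix,
        cell_ci=cell_ci,
    )


@dataclass
class ChangeTable:
    """Before/after differences in breadth and overlap."""

    per_fly: pd.DataFrame
    per_pair: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.per_fly

    def to_dict(self) -> dict:
        return {
            "per_fly": self.per_fly.to_dict(orient="records"),
            "per_pair": self.per_pair.to_dict(orient="records"),
        }


def _disjoint(lo_a, hi_a, lo_b, hi_b) -> bool:
    return bool(hi_b < lo_a or hi_a < lo_b)


def compare_periods(before: DiversityReport, after: DiversityReport) -> ChangeTable:
    """Per-fly change in D_alpha and per-pair change in turnover.

    A change is flagged when the two bootstrap intervals do not overlap,
    the only notion of significance the bootstrap design supports.
    """
    b = before.per_fly.set_index("fly_id")
    a = after.per_fly.set_index("fly_id")
    rows = []
    for f in b.index:
        if f not in a.index:
            continue
        rows.append(
            dict(
                fly_id=f,
                richness_before=int(b.loc[f, "richness"]),
                richness_after=int(a.loc[f, "richness"]),
                d_alpha_before=float(b.loc[f, "d_alpha_mean"]),
                d_alpha_after=float(a.loc[f, "d_alpha_mean"]),
                delta_d_alpha=float(a.loc[f, "d_alpha_mean"] - b.loc[f, "d_alpha_mean"]),
                ci_disjoint=_disjoint(
                    b.loc[f, "ci_low"], b.loc[f, "ci_high"],
                    a.loc[f, "ci_low"], a.loc[f, "ci_high"],
                ),
            )
        )
    per_fly = pd.DataFrame(
        rows,
        columns=["fly_id", "richness_before", "richness_after",
                 "d_alpha_before", "d_alpha_after", "delta_d_alpha",
                 "ci_disjoint"],
    )

    def _key(r):
        return tuple(sorted((r["fly_a"], r["fly_b"])))

    b_pairs = {_key(r): r for _, r in before.per_pair.iterrows()}
    rows = []
    for _, r in after.per_pair.iterrows():
        k = _key(r)
        if k not in b_pairs:
            continue
        rb = b_pairs[k]
        rows.append(
            dict(
                fly_a=k[0],
                fly_b=k[1],
                turnover_before=float(rb["turnover_mean"]),
                turnover_after=float(r["turnover_mean"]),
                delta_turnover=float(r["turnover_mean"] - rb["turnover_mean"]),
                ci_disjoint=_disjoint(
                    rb["ci_low"], rb["ci_high"], r["ci_low"], r["ci_high"]
                ),
            )
        )
    per_pair = pd.DataFrame(
        rows,
        columns=["fly_a", "fly_b", "turnover_before", "turnover_after",
                 "delta_turnover", "ci_disjoint"],
    )
    return ChangeTable(per_fly=per_fly, per_pair=per_pair)
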