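"""Hill-number analytics, normalization, and the one-fruit bootstrap."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from flyrange.data import BEFORE, AFTER, RunConfig, ValidationError
from flyrange.diversity import (
    DiversityReport,
    alpha_diversity,
    beta_turnover,
    bootstrap_indices,
    compare_periods,
    normalize_matrix,
    resample_one_fruit,
    shannon,
)
from flyrange.matrices import BioticCapacity, biotic_capacity

from conftest import make_dataset


# ---------------------------------------------------------------------------
# alpha diversity (number equivalents)
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("k", range(1, 37))
def test_alpha_uniform_equals_richness(k):
    p = np.full(k, 1.0 / k)
    assert alpha_diversity(p) == pytest.approx(k, abs=1e-9)


def test_alpha_skewed_closed_form():
    assert alpha_diversity([0.5, 0.25, 0.25]) == pytest.approx(2.0**1.5, abs=1e-9)


def test_alpha_monophagy_is_one():
    assert alpha_diversity([1.0, 0.0, 0.0]) == pytest.approx(1.0, abs=1e-12)


def test_alpha_rejects_unnormalized_and_negative():
    with pytest.raises(ValidationError):
        alpha_diversity([0.5, 0.4])
    with pytest.raises(ValidationError):
        alpha_diversity([1.5, -0.5])


def test_shannon_zero_times_log_zero_convention():
    assert shannon([1.0, 0.0]) == 0.0


def test_alpha_increases_under_robin_hood_transfer():
    """D_alpha is Schur-concave: moving mass from a richer to a poorer
    category (toward uniformity) never decreases it."""
    rng = np.random.default_rng(11)
    for _ in range(50):
        p = rng.dirichlet(np.ones(6))
        i, j = int(np.argmax(p)), int(np.argmin(p))
        eps = 0.25 * (p[i] - p[j])
        q = p.copy()
        q[i] -= eps
        q[j] += eps
        assert alpha_diversity(q) >= alpha_diversity(p) - 1e-12


# ---------------------------------------------------------------------------
# pairwise turnover
# ---------------------------------------------------------------------------


def test_turnover_identical_diets_zero():
    p = np.array([0.2, 0.3, 0.5])
    assert beta_turnover(p, p) == 0.0


def test_turnover_disjoint_diets_one():
    p = np.array([0.6, 0.4, 0.0, 0.0])
    q = np.array([0.0, 0.0, 0.3, 0.7])
    assert beta_turnover(p, q) == pytest.approx(1.0, abs=1e-12)


def test_turnover_worked_example():
    assert beta_turnover([1.0, 0.0], [0.5, 0.5]) == pytest.approx(0.240806, abs=1e-6)


def test_turnover_random_pairs_bounded():
    rng = np.random.default_rng(5)
    p = rng.dirichlet(np.ones(8), size=10_000)
    q = rng.dirichlet(np.ones(8), size=10_000)
    t = np.array([beta_turnover(a, b) for a, b in zip(p, q)])
    assert np.all(t >= 0.0) and np.all(t <= 1.0)


@given(st.integers(0, 2**31 - 1))
def test_turnover_symmetric(seed):
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.ones(5))
    q = rng.dirichlet(np.ones(5))
    assert beta_turnover(p, q) == pytest.approx(beta_turnover(q, p), abs=1e-12)


def test_turnover_shape_mismatch():
    with pytest.raises(ValidationError):
        beta_turnover([1.0], [0.5, 0.5])


# ---------------------------------------------------------------------------
# matrix normalization
# ---------------------------------------------------------------------------


def test_normalize_single_fly_capacity_weighting():
    raw = pd.DataFrame({"F1": [6.0, 0.0]}, index=["PA", "PB"])
    w = BioticCapacity(w=pd.Series({"PA": 3.0, "PB": 2.0}))
    m = normalize_matrix(raw, w)
    assert m.table["F1"].tolist() == pytest.approx([1.0, 0.0])


def test_normalize_two_rows_example():
    raw = pd.DataFrame({"F1": [2.0, 2.0]}, index=["PA", "PB"])
    w = BioticCapacity(w=pd.Series({"PA": 1.0, "PB": 2.0}))
    m = normalize_matrix(raw, w)
    assert m.table["F1"].tolist() == pytest.approx([2.0 / 3.0, 1.0 / 3.0])


def test_normalize_all_zero_column_invalid_not_divided():
    raw = pd.DataFrame({"F1": [1.0, 1.0], "F2": [0.0, 0.0]}, index=["PA", "PB"])
    w = BioticCapacity(w=pd.Series({"PA": 1.0, "PB": 1.0}))
    m = normalize_matrix(raw, w)
    assert not bool(m.valid["F2"])
    assert bool(m.valid["F1"])
    assert m.table["F2"].tolist() == [0.0, 0.0]


def test_normalize_zero_capacity_with_counts_errors():
    raw = pd.DataFrame({"F1": [1.0]}, index=["PA"])
    w = BioticCapacity(w=pd.Series({"PA": 0.0}))
    with pytest.raises(ValidationError):
        normalize_matrix(raw, w)


# ---------------------------------------------------------------------------
# one-fruit resampling
# ---------------------------------------------------------------------------


def _two_plant_dataset():
    return make_dataset(
        {
            "PA": {BEFORE: [{"F1": 2}, {"F1": 4}], AFTER: [{"F1": 1}]},
            "PB": {BEFORE: [{"F2": 3}], AFTER: [{"F2": 1}]},
        },
        flies=["F1", "F2"],
    )


def test_resample_single_fruit_plant_is_deterministic():
    ds = _two_plant_dataset()
    rng = np.random.default_rng(0)
    for _ in range(20):
        m = resample_one_fruit(ds, BEFORE, rng)
        assert m.loc["PB", "F2"] == 3  # only one fruit to choose from


def test_resample_seeded_sequence_reproducible():
    ds = _two_plant_dataset()
    seq1 = [resample_one_fruit(ds, BEFORE, np.random.default_rng(7)) for _ in range(1)]
    seq2 = [resample_one_fruit(ds, BEFORE, np.random.default_rng(7)) for _ in range(1)]
    assert seq1[0].equals(seq2[0])


def test_resample_uniform_over_fruits():
    ds = _two_plant_dataset()
    rng = np.random.default_rng(123)
    picks = [resample_one_fruit(ds, BEFORE, rng).loc["PA", "F1"] for _ in range(10_000)]
    frac_first = np.mean(np.asarray(picks) == 2)
    # binomial(10^4, 1/2): 3 sigma = 0.015
    assert abs(frac_first - 0.5) < 0.015


def test_resample_missing_period_errors():
    ds = make_dataset(
        {"PA": {BEFORE: [{"F1": 1}]}},
        flies=["F1"],
    )
    with pytest.raises(ValidationError):
        resample_one_fruit(ds, AFTER, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# bootstrap indices
# ---------------------------------------------------------------------------


def test_bootstrap_degenerate_one_fruit_per_plant():
    """With a single fruit per plant every replicate is identical: the CI
    collapses onto the exact index value."""
    ds = make_dataset(
        {
            "PA": {BEFORE: [{"F1": 2}]},
            "PB": {BEFORE: [{"F1": 2}]},
        },
        flies=["F1"],
    )
    w = biotic_capacity(ds)
    cfg = RunConfig(bootstrap_reps=200)
    rep = bootstrap_indices(ds, BEFORE, w, cfg, rng=np.random.default_rng(0))
    row = rep.per_fly.iloc[0]
    assert row["d_alpha_mean"] == pytest.approx(2.0, abs=1e-12)
    assert row["ci_low"] == pytest.approx(row["ci_high"], abs=1e-12)
    assert row["n_valid_reps"] == 200


def _enumerate_alpha(ds, period, w, fly):
    """Exact distribution of D_alpha(fly) over all one-fruit selections."""
    per_plant = [ds.count_matrix(p, period) for p in ds.plant_ids]
    fly_pos = {f: i for i, f in enumerate(ds.fly_ids)}
    flies = ds.flies_present(period)
    cols = [fly_pos[f] for f in flies]
    values = []
    for combo in itertools.product(*[range(c.shape[0]) for c in per_plant]):
        raw = pd.DataFrame(
            np.vstack([per_plant[j][i][cols] for j, i in enumerate(combo)]),
            index=ds.plant_ids,
            columns=flies,
        )
        m = normalize_matrix(raw, w)
        if bool(m.valid[fly]):
            values.append(alpha_diversity(m.table[fly].to_numpy()))
    return np.asarray(values)


def test_bootstrap_matches_exhaustive_enumeration():
    ds = make_dataset(
        {
            "PA": {BEFORE: [{"F1": 2}, {"F1": 1, "F2": 1}]},
            "PB": {BEFORE: [{"F1": 1}, {"F2": 2}, {"F1": 3, "F2": 1}]},
            "PC": {BEFORE: [{"F2": 2}, {"F1": 1}]},
        },
        flies=["F1", "F2"],
    )
    w = biotic_capacity(ds)
    reps = 100_000
    cfg = RunConfig(bootstrap_reps=reps)
    rep = bootstrap_indices(ds, BEFORE, w, cfg, rng=np.random.default_rng(99))
    for fly in ("F1", "F2"):
        exact = _enumerate_alpha(ds, BEFORE, w, fly)
        row = rep.per_fly.set_index("fly_id").loc[fly]
        sigma = exact.std() / np.sqrt(reps)
        assert row["d_alpha_mean"] == pytest.approx(exact.mean(), abs=4 * sigma + 1e-12)
        # quantiles of a small discrete distribution: the bootstrap quantile
        # converges to a population atom; allow the Monte-Carlo margin of
        # +/- 0.005 in cumulative probability around the target
        for q, got in ((0.025, row["ci_low"]), (0.975, row["ci_high"])):
            lo = np.quantile(exact, max(q - 0.005, 0.0), method="inverted_cdf")
            hi = np.quantile(exact, min(q + 0.005, 1.0), method="inverted_cdf")
            assert lo - 1e-9 <= got <= hi + 1e-9


def test_bootstrap_alpha_within_bounds(scenario_run):
    ds, cfg = scenario_run["dataset"], scenario_run["config"]
    w = biotic_capacity(ds)
    rep = bootstrap_indices(ds, BEFORE, w, cfg, rng=np.random.default_rng(2))
    n_plants = len(ds.plant_ids)
    valid = rep.per_fly[rep.per_fly["n_valid_reps"] > 0]
    assert (valid["d_alpha_mean"] >= 1.0 - 1e-9).all()
    assert (valid["d_alpha_mean"] <= n_plants + 1e-9).all()
    assert (valid["ci_low"] <= valid["d_alpha_mean"] + 1e-12).all()
    assert (valid["d_alpha_mean"] <= valid["ci_high"] + 1e-12).all()
    assert (rep.per_pair["turnover_mean"].dropna() >= 0.0).all()
    assert (rep.per_pair["turnover_mean"].dropna() <= 1.0).all()


def test_bootstrap_deterministic_under_seed(scenario_run):
    ds, cfg = scenario_run["dataset"], scenario_run["config"]
    w = biotic_capacity(ds)
    r1 = bootstrap_indices(ds, BEFORE, w, cfg, rng=np.random.default_rng(3))
    r2 = bootstrap_indices(ds, BEFORE, w, cfg, rng=np.random.default_rng(3))
    pd.testing.assert_frame_equal(r1.per_fly, r2.per_fly)
    pd.testing.assert_frame_equal(r1.per_pair, r2.per_pair)


# ---------------------------------------------------------------------------
# before/after comparison
# ---------------------------------------------------------------------------


def _report(period, rows, pairs=()):
    per_fly = pd.DataFrame(
        [
            dict(
                fly_id=f, period=period, richness=r, d_alpha_mean=m,
                ci_low=lo, ci_high=hi, n_valid_reps=100,
            )
            for f, r, m, lo, hi in rows
        ]
    )
    per_pair = pd.DataFrame(
        [
            dict(
                fly_a=a, fly_b=b, period=period, turnover_mean=t,
                ci_low=lo, ci_high=hi, n_valid_reps=100,
            )
            for a, b, t, lo, hi in pairs
        ],
        columns=["fly_a", "fly_b", "period", "turnover_mean", "ci_low",
                 "ci_high", "n_valid_reps"],
    )
    return DiversityReport(
        period=period, per_fly=per_fly, per_pair=per_pair,
        mean_matrix=pd.DataFrame(),
    )


def test_compare_periods_flags_disjoint_intervals():
    before = _report(BEFORE, [("F1", 12, 10.4, 7.5, 13.3), ("F2", 4, 4.0, 3.0, 5.0)])
    after = _report(AFTER, [("F1", 8, 5.2, 2.9, 7.4), ("F2", 4, 4.1, 3.1, 5.1)])
    table = compare_periods(before, after).per_fly.set_index("fly_id")
    assert table.loc["F1", "delta_d_alpha"] == pytest.approx(-5.2, abs=1e-9)
    assert bool(table.loc["F1", "ci_disjoint"])
    assert not bool(table.loc["F2", "ci_disjoint"])


def test_compare_periods_skips_invader_without_before_row():
    before = _report(BEFORE, [("F1", 5, 5.0, 4.0, 6.0)])
    after = _report(AFTER, [("F1", 5, 5.0, 4.0, 6.0), ("INV", 3, 2.0, 1.5, 2.5)])
    table = compare_periods(before, after)
    assert table.per_fly["fly_id"].tolist() == ["F1"]


def test_compare_periods_pairs_symmetric_keying():
    before = _report(
        BEFORE, [("F1", 5, 5.0, 4, 6), ("F2", 5, 5.0, 4, 6)],
        pairs=[("F1", "F2", 0.2, 0.1, 0.3)],
    )
    after = _report(
        AFTER, [("F1", 5, 5.0, 4, 6), ("F2", 5, 5.0, 4, 6)],
        pairs=[("F2", "F1", 0.6, 0.5, 0.7)],
    )
    table = compare_periods(before, after).per_pair
    assert len(table) == 1
    assert table.iloc[0]["delta_turnover"] == pytest.approx(0.4, abs=1e-9)
    assert bool(table.iloc[0]["ci_disjoint"])
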