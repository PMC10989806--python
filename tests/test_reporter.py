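"""Reporter-score core: transform, aggregation, background, invariances."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from reporterscore import (
    KOStat,
    PathwaySet,
    aggregate_z,
    background_stats,
    corrected_score,
    p_to_z,
    run_reporter,
    score_to_p,
    split_directional,
)
from reporterscore.errors import ValidationError
from reporterscore.reporter import build_background, rows_to_frame


# ------------------------------------------------------------ elementary ops

@pytest.mark.parametrize(
    "p, z_expect",
    [(0.5, 0.0), (0.05, 1.64), (0.95, -1.64)],
)
def test_p_to_z_anchors(p, z_expect):
    assert round(p_to_z(p), 2) == z_expect


def test_p_to_z_clipping_and_validation():
    assert np.isfinite(p_to_z(0.0)) and p_to_z(0.0) > 7
    assert np.isfinite(p_to_z(1.0)) and p_to_z(1.0) < -7
    for bad in (-0.1, 1.1, float("nan")):
        with pytest.raises(ValidationError):
            p_to_z(bad)


@given(st.floats(1e-12, 1 - 1e-12), st.floats(1e-12, 1 - 1e-12))
def test_p_to_z_strictly_decreasing(p1, p2):
    if p1 != p2:
        lo, hi = sorted((p1, p2))
        assert p_to_z(lo) > p_to_z(hi)


@pytest.mark.parametrize(
    "zs, expect",
    [([1.0], 1.0), ([1, 1, 1, 1], 2.0), ([0, 1, 2], 1.7321)],
)
def test_aggregate_z_examples(zs, expect):
    assert aggregate_z(zs) == pytest.approx(expect, abs=1e-4)


def test_aggregate_z_empty_is_error():
    with pytest.raises(ValidationError):
        aggregate_z([])


@pytest.mark.parametrize(
    "zp, mu, sigma, expect",
    [(3.3, 3.3, 0.7, 0.0), (2.5, 0.5, 1.0, 2.0), (2.1213, 1.4142, 0.5774, 1.2247)],
)
def test_corrected_score(zp, mu, sigma, expect):
    assert corrected_score(zp, mu, sigma) == pytest.approx(expect, abs=1e-4)


def test_corrected_score_degenerate_sigma_raises():
    with pytest.raises(ValidationError):
        corrected_score(1.0, 0.0, 0.0)


def test_score_to_p_anchors_and_roundtrip():
    assert score_to_p(0.0) == 0.5
    assert round(score_to_p(1.6449), 2) == 0.05
    for z in np.linspace(-6, 6, 25):
        # double precision of 1 - Phi limits the deep-left tail to ~1e-8
        assert p_to_z(score_to_p(z)) == pytest.approx(z, abs=1e-6)


@pytest.mark.parametrize(
    "p, sign, expect",
    [
        (0.04, +1, (0.02, 0.98)),
        (0.04, -1, (0.98, 0.02)),
        (1.0, +1, (0.5, 0.5)),
        (0.3, 0, (0.5, 0.5)),
    ],
)
def test_split_directional_examples(p, sign, expect):
    assert split_directional(p, sign) == pytest.approx(expect)


@given(st.floats(0, 1), st.sampled_from([-1, 0, 1]))
def test_split_directional_sums_to_one(p, sign):
    up, down = split_directional(p, sign)
    assert up + down == pytest.approx(1.0)
    assert 0.0 <= up <= 1.0


# ------------------------------------------------------------ background

def test_background_exhaustive_worked_example():
    """Enumerating {0,1},{0,2},{1,2} at k=2: aggregates 1/sqrt(2)*{1,2,3}."""
    bg = background_stats([0.0, 1.0, 2.0], k=2)
    assert bg.method == "exhaustive" and bg.n_samples == 3
    assert bg.mu_k == pytest.approx(1.4142, abs=1e-4)
    assert bg.sigma_k == pytest.approx(0.5774, abs=1e-4)


def test_background_constant_universe():
    c, k = 0.73, 4
    bg = background_stats([c] * 9, k=k)
    assert bg.mu_k == pytest.approx(c * math.sqrt(k))
    assert bg.sigma_k == 0.0


def test_background_seeded_determinism():
    z = np.random.default_rng(0).normal(size=50)
    a = background_stats(z, k=5, n_samples=500, seed=11, exhaustive_cap=10)
    b = background_stats(z, k=5, n_samples=500, seed=11, exhaustive_cap=10)
    assert a == b and a.method == "monte_carlo"


def test_background_monte_carlo_matches_exhaustive():
    """MC moments converge to the exhaustive enumeration (3 SE band)."""
    rng = np.random.default_rng(3)
    z = p_to_z(rng.uniform(size=10))
    k = 5  # C(10,5) = 252 <= 500
    ex = background_stats(z, k=k)
    assert ex.method == "exhaustive"
    n_mc = 20_000
    mc = background_stats(z, k=k, n_samples=n_mc, seed=5, exhaustive_cap=1)
    se_mu = ex.sigma_k / math.sqrt(n_mc)
    se_sigma = ex.sigma_k / math.sqrt(2 * n_mc)
    assert abs(mc.mu_k - ex.mu_k) <= 3 * se_mu
    assert abs(mc.sigma_k - ex.sigma_k) <= 3 * se_sigma


def test_background_order_independence():
    """Per-k draws happen in sorted-k order: result ignores pathway order."""
    z = np.random.default_rng(1).normal(size=100)
    a = build_background(z, [12, 5, 9], n_samples=300, seed=4, exhaustive_cap=1)
    b = build_background(z, [9, 12, 5], n_samples=300, seed=4, exhaustive_cap=1)
    assert a.entries == b.entries


# ------------------------------------------------------------ run_reporter

def _stats_from(pvals, signs=None):
    signs = signs if signs is not None else [1] * len(pvals)
    return [
        KOStat(f"K{i:05d}", float(p), float(s), "unit")
        for i, (p, s) in enumerate(zip(pvals, signs))
    ]


def test_all_half_pvalues_score_zero():
    """All P = 0.5: every Z is 0, aggregates 0, background 0 -> score 0."""
    stats = _stats_from([0.5] * 30)
    sets = PathwaySet({"pw1": frozenset(s.ko_id for s in stats[:5]),
                       "pw2": frozenset(s.ko_id for s in stats[5:12])})
    rows = run_reporter(stats, sets, seed=0)
    assert len(rows) == 2
    for r in rows:
        assert r.z_corrected == pytest.approx(0.0)
        assert not r.significant


def test_sign_flip_leaves_undirected_rows_identical(replica):
    """The headline correction: the score is a function of P values only."""
    ko_stats, sets, _ = replica
    flipped = [dataclasses.replace(s, statistic=-s.statistic) for s in ko_stats]
    rng = np.random.default_rng(99)
    randomized = [
        dataclasses.replace(s, statistic=float(sg) * abs(s.statistic))
        for s, sg in zip(ko_stats, rng.choice([-1.0, 1.0], size=len(ko_stats)))
    ]
    base = run_reporter(ko_stats, sets, seed=7)
    assert run_reporter(flipped, sets, seed=7) == base
    assert run_reporter(randomized, sets, seed=7) == base


def test_least_significant_pathway_attains_minimum(replica):
    ko_stats, sets, truth = replica
    rows = run_reporter(ko_stats, sets, seed=7)
    least = truth.loc[truth.least_significant, "pathway"].item()
    assert rows[-1].pathway_id == least
    assert rows[-1].z_corrected == min(r.z_corrected for r in rows)
    # strongly negative, i.e. the naive reading would call it "downregulated"
    assert rows[-1].z_corrected < -1.64


def test_monotonicity_in_member_pvalues():
    rng = np.random.default_rng(12)
    pvals = rng.uniform(size=40)
    stats = _stats_from(pvals)
    members = frozenset(s.ko_id for s in stats[:8])
    sets = PathwaySet({"pw": members})
    base = run_reporter(stats, sets, seed=3)[0]
    lowered = list(pvals)
    for i in range(8):
        lowered[i] = pvals[i] * 0.3
    better = run_reporter(_stats_from(lowered), sets, seed=3)[0]
    assert better.z_pathway >= base.z_pathway


def test_directed_mode_two_rows_and_complement():
    """All-positive-sign pathway with small P values scores up >> down."""
    rng = np.random.default_rng(5)
    pvals = np.concatenate([rng.uniform(0.001, 0.05, 10), rng.uniform(size=30)])
    stats = _stats_from(pvals, signs=[1] * 40)
    sets = PathwaySet({"pw_up": frozenset(s.ko_id for s in stats[:10]),
                       "pw_bg": frozenset(s.ko_id for s in stats[20:30])})
    rows = run_reporter(stats, sets, seed=2, mode="directed")
    assert len(rows) == 4
    by = {(r.pathway_id, r.mode): r for r in rows}
    assert by[("pw_up", "up")].z_corrected > by[("pw_up", "down")].z_corrected
    # per-KO one-tailed P values are complementary
    for p, sg in zip(pvals, [1] * 40):
        up, down = split_directional(float(p), sg)
        assert up + down == pytest.approx(1.0)


def test_output_sorted_and_min_k_filter():
    rng = np.random.default_rng(8)
    stats = _stats_from(rng.uniform(size=30))
    ids = [s.ko_id for s in stats]
    sets = PathwaySet({
        "small": frozenset(ids[:2]),          # below min_k = 3, dropped
        "a": frozenset(ids[:6]),
        "b": frozenset(ids[6:14]),
        "c": frozenset(ids[14:20]),
    })
    rows = run_reporter(stats, sets, seed=1)
    assert {r.pathway_id for r in rows} == {"a", "b", "c"}
    scores = [r.z_corrected for r in rows]
    assert scores == sorted(scores, reverse=True)


def test_run_reporter_validation():
    stats = _stats_from([0.1, 0.2, 0.3])
    sets = PathwaySet({"pw": frozenset(s.ko_id for s in stats)})
    with pytest.raises(ValidationError):
        run_reporter([], sets)
    with pytest.raises(ValidationError):
        run_reporter(stats, sets, mode="sideways")
    with pytest.raises(ValidationError):
        PathwaySet({"pw": frozenset()})


def test_rows_frame_columns(replica):
    ko_stats, sets, _ = replica
    df = rows_to_frame(run_reporter(ko_stats, sets, seed=7))
    assert list(df.columns) == [
        "pathway", "mode", "k", "z_pathway", "mu_k", "sigma_k",
        "reporter_score", "p_equiv", "q_value", "significant",
    ]
    assert df["q_value"].between(0, 1).all()
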