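"""Correction arithmetic, degree classification, the empirical error model
and kin-group construction."""

import numpy as np
import pandas as pd
import pytest

from correctkin.correct_filter import (
    HARD_THRESHOLD_DEFAULT,
    classify_degree,
    correct_kinship,
    filter_relatives,
    fit_error_model,
    kin_groups,
)
from correctkin.overlap import OverlapMatrix
from correctkin.validation import reference_tables


def test_published_correction_arithmetic():
    """uncorrected / overlap-fraction reproduces every printed corrected
    coefficient of the two published worked-example tables, within the
    tolerance implied by the printed 5-decimal rounding of both inputs."""
    for row in reference_tables().itertuples(index=False):
        got = row.uncorrected / row.f
        tol = max(1e-4, 0.5e-5 / row.f + 0.5e-5)
        assert got == pytest.approx(row.corrected, abs=tol), (row.sample1, row.sample2)


def test_correction_identity_and_zero_overlap():
    phi = np.array([[1.0, 0.2], [0.2, 1.0]])
    f = np.array([[1.0, 1.0], [1.0, 1.0]])
    out = correct_kinship(phi, f)
    assert out[0, 1] == 0.2  # f=1 -> identity
    assert np.isnan(out[0, 0])  # diagonal excluded
    f0 = np.array([[1.0, 0.0], [0.0, 1.0]])
    out0 = correct_kinship(phi, f0)
    assert np.isnan(out0[0, 1])  # f=0 -> NA, never silently zero


@pytest.mark.parametrize(
    "phi_star, degree",
    [
        (0.5, "sample_match"),
        (0.26006, "first"),
        (0.15700, "second"),
        (0.08123, "third"),
        (0.375, "sample_match"),  # boundary is lower-inclusive
        (0.046875, "third"),
        (0.04, "fourth"),
        (0.0234375, "fourth"),
        (0.02, "distant"),
    ],
)
def test_degree_classification_midpoints(phi_star, degree):
    assert classify_degree(phi_star) == degree


def test_hard_threshold_is_third_fourth_midpoint():
    assert HARD_THRESHOLD_DEFAULT == (0.0625 + 0.03125) / 2 == 0.046875


def _synthetic_unrelated(seed, n_pairs=5000, b=1.2, a=0.0, n_lo=200, n_hi=100_000):
    rng = np.random.default_rng(seed)
    n = np.exp(rng.uniform(np.log(n_lo), np.log(n_hi), size=n_pairs))
    sd = a + b / np.sqrt(n)
    phi = rng.normal(0.0, sd)
    return phi, n


def test_error_model_recovers_inverse_sqrt_noise():
    """phi* noise ~ b/sqrt(n): the fitted b lands within 20% of truth and
    the fitted floor a stays near zero."""
    phi, n = _synthetic_unrelated(seed=0, b=1.2)
    model = fit_error_model(phi, n)
    assert model.b == pytest.approx(1.2, rel=0.2)
    assert abs(model.a) < 0.01
    # sd curve non-increasing in n
    grid = np.geomspace(300, 90_000, 10)
    sd = model.sd_curve(grid)
    assert np.all(np.diff(sd) <= 1e-12)
    assert np.all(sd > 0)


def test_error_model_degenerate_single_overlap_level():
    rng = np.random.default_rng(1)
    phi = rng.normal(0, 0.01, size=400)
    n = np.full(400, 5000.0)
    model = fit_error_model(phi, n)
    sd = float(model.sd_curve(5000.0))
    assert sd == pytest.approx(phi.std(), rel=0.15)
    assert float(model.sd_curve(100.0)) == sd  # constant curve


def test_error_model_robust_to_planted_relatives():
    """Five 1st-degree pairs among 1000 unrelated shift the fitted spread
    by less than 10% at every overlap level."""
    phi, n = _synthetic_unrelated(seed=2, n_pairs=1000, b=1.0)
    model_clean = fit_error_model(phi, n)
    phi_dirty = np.concatenate([phi, np.full(5, 0.25)])
    n_dirty = np.concatenate([n, np.full(5, 50_000.0)])
    model_dirty = fit_error_model(phi_dirty, n_dirty)
    grid = np.geomspace(500, 80_000, 8)
    ratio = model_dirty.sd_curve(grid) / model_clean.sd_curve(grid)
    assert np.all(np.abs(ratio - 1) < 0.10)


def test_error_model_needs_enough_pairs():
    with pytest.raises(ValueError, match="50"):
        fit_error_model(np.zeros(10), np.full(10, 100.0))


def _toy_overlap(n, panel_size=1000, count=500):
    counts = np.full((n, n), count, dtype=np.int64)
    np.fill_diagonal(counts, panel_size)
    return OverlapMatrix([f"s{i}" for i in range(n)], panel_size, counts)


def test_filter_reports_obvious_pair_and_criterion():
    n = 30
    rng = np.random.default_rng(3)
    corrected = rng.normal(0, 0.005, size=(n, n))
    corrected = (corrected + corrected.T) / 2
    corrected[0, 1] = corrected[1, 0] = 0.5
    np.fill_diagonal(corrected, np.nan)
    om = _toy_overlap(n, panel_size=100_000, count=50_000)
    raw = np.nan_to_num(corrected) * 0.5
    calls = filter_relatives(raw, corrected, om, hard_threshold=0.046875)
    assert len(calls) == 1
    call = calls.iloc[0]
    assert {call["sample1"], call["sample2"]} == {"s0", "s1"}
    assert call["degree"] == "sample_match"
    assert call["criterion"] == "hard"
    assert not call["low_confidence"]
    # below-threshold pairs are absent
    assert not ((calls["sample1"] == "s2") & (calls["sample2"] == "s3")).any()


def test_filter_sorts_by_corrected_descending_and_flags_low_overlap():
    n = 4
    corrected = np.full((n, n), np.nan)
    corrected[0, 1] = corrected[1, 0] = 0.1
    corrected[2, 3] = corrected[3, 2] = 0.3
    om = _toy_overlap(n, panel_size=100_000, count=10_000)
    calls = filter_relatives(corrected * 0.1, corrected, om, hard_threshold=0.05)
    assert calls["corrected_kin"].tolist() == [0.3, 0.1]
    assert calls["low_confidence"].all()  # 10k < 17k overlapping markers


def test_kin_groups_connected_components():
    calls = pd.DataFrame(
        {"sample1": ["A", "B", "D"], "sample2": ["B", "C", "E"]}
    )
    grouped = kin_groups(calls)
    assert grouped.loc[0, "kin_group"] == grouped.loc[1, "kin_group"] == 1
    assert grouped.loc[2, "kin_group"] == 2
    empty = kin_groups(calls.iloc[0:0])
    assert len(empty) == 0


def test_kin_groups_match_union_find_oracle():
    rng = np.random.default_rng(7)
    nodes = [f"n{i}" for i in range(30)]
    edges = [
        (nodes[a], nodes[b])
        for a, b in rng.integers(0, 30, size=(40, 2))
        if a != b
    ]
    calls = pd.DataFrame(edges, columns=["sample1", "sample2"])
    grouped = kin_groups(calls)
    # brute-force transitive closure
    comp = {n: {n} for n in set(calls["sample1"]) | set(calls["sample2"])}
    changed = True
    while changed:
        changed = False
        for a, b in edges:
            merged = comp[a] | comp[b]
            if merged != comp[a] or merged != comp[b]:
                for x in merged:
                    comp[x] = merged
                changed = True
    expect_groups = {frozenset(v) for v in comp.values()}
    got = {}
    for row in grouped.itertuples(index=False):
        got.setdefault(row.kin_group, set()).update((row.sample1, row.sample2))
    assert {frozenset(v) for v in got.values()} == expect_groups


def test_filter_invariant_under_sample_permutation():
    rng = np.random.default_rng(5)
    n = 40
    corrected = rng.normal(0, 0.004, size=(n, n))
    corrected = (corrected + corrected.T) / 2
    corrected[4, 17] = corrected[17, 4] = 0.24
    corrected[8, 9] = corrected[9, 8] = 0.12
    np.fill_diagonal(corrected, np.nan)
    om = _toy_overlap(n, panel_size=50_000, count=30_000)
    base = filter_relatives(corrected * 0.6, corrected, om, hard_threshold=0.05)
    base_pairs = {frozenset(p) for p in zip(base["sample1"], base["sample2"])}
    perm = rng.permutation(n)
    corrected_p = corrected[np.ix_(perm, perm)]
    ids_p = [f"s{i}" for i in perm]
    om_p = OverlapMatrix(ids_p, om.panel_size, om.counts[np.ix_(perm, perm)])
    permuted = filter_relatives(corrected_p * 0.6, corrected_p, om_p, hard_threshold=0.05)
    perm_pairs = {frozenset(p) for p in zip(permuted["sample1"], permuted["sample2"])}
    assert base_pairs == perm_pairs
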