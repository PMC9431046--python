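"""Diversity primitives, rarefaction, PERMANOVA and PCoA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from phyllocore import (
    AsvTable,
    bray_curtis,
    bray_curtis_matrix,
    inverse_simpson,
    mean_pairwise_dissimilarity,
    pcoa,
    permanova,
    rarefy,
)
from phyllocore.diversity import UndefinedDiversityError

from conftest import random_table


# ---------------------------------------------------------------------------
# inverse Simpson
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "counts,expected",
    [
        ([10, 10, 10, 10], 4.0),
        ([100], 1.0),
        ([5, 3, 2], 1 / (0.25 + 0.09 + 0.04)),
    ],
)
def test_inverse_simpson_values(counts, expected):
    assert inverse_simpson(counts) == pytest.approx(expected, rel=1e-12)


def test_inverse_simpson_bounds_and_uniform_maximum():
    rng = np.random.default_rng(5)
    for _ in range(20):
        v = rng.integers(1, 100, size=rng.integers(1, 10))
        d = inverse_simpson(v)
        assert 1.0 <= d <= len(v) + 1e-9
    with pytest.raises(UndefinedDiversityError):
        inverse_simpson([0, 0])


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------


def test_bray_curtis_limits_and_hand_value():
    assert bray_curtis([3, 1, 4], [3, 1, 4]) == 0.0
    assert bray_curtis([5, 0], [0, 9]) == 1.0
    assert bray_curtis([6, 0, 2], [2, 2, 0]) == pytest.approx(1 - 4 / 12)


def test_bray_curtis_matches_scipy_and_is_symmetric():
    rng = np.random.default_rng(11)
    for _ in range(25):
        x = rng.integers(0, 30, size=8)
        y = rng.integers(0, 30, size=8)
        if x.sum() + y.sum() == 0:
            continue
        got = bray_curtis(x, y)
        assert got == pytest.approx(scipy_braycurtis(x, y))
        assert got == pytest.approx(bray_curtis(y, x))
        assert 0.0 <= got <= 1.0


def test_bray_curtis_undefined_for_empty_pair():
    with pytest.raises(UndefinedDiversityError):
        bray_curtis([0, 0], [0, 0])


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------


def test_rarefy_depth_drop_and_determinism():
    rng = np.random.default_rng(1)
    t = random_table(rng, 6, 20, max_count=80)
    # sample totals straddle the depth
    depth = int(t.sample_totals().median())
    out = rarefy(t, depth, seed=3)
    assert (out.sample_totals() == depth).all()
    kept = {s for s in t.sample_ids if t.sample_totals()[s] >= depth}
    assert set(out.sample_ids) == kept
    again = rarefy(t, depth, seed=3)
    assert again == out
    assert rarefy(t, depth, seed=4) != out or out.n_samples == 0


def test_rarefy_is_subsample_without_replacement():
    t = AsvTable(pd.DataFrame([[3, 2, 0]], index=["s"], columns=list("abc")))
    out = rarefy(t, 4, seed=0)
    assert (out.counts.loc["s"] <= t.counts.loc["s"].drop(labels=set(t.asv_ids) - set(out.asv_ids), errors="ignore")).all()


def test_rarefy_preserves_expected_proportions():
    """A 50% taxon stays at 50% on average across seeds."""
    t = AsvTable(pd.DataFrame([[500, 300, 200]], index=["s"], columns=list("abc")))
    props = [
        rarefy(t, 100, seed=s).counts.loc["s", "a"] / 100 for s in range(200)
    ]
    se = np.std(props, ddof=1) / np.sqrt(len(props))
    assert abs(np.mean(props) - 0.5) < 3 * se + 1e-12


# ---------------------------------------------------------------------------
# Mean pairwise dissimilarity (core-set contribution primitive)
# ---------------------------------------------------------------------------


def brute_force_subset_mean_bc(table: AsvTable, subset) -> float:
    """Oracle: direct iteration over pairs, |x-y| restricted to the subset,
    divided by the pair's FULL read total."""
    vals = []
    for i, j in itertools.combinations(range(table.n_samples), 2):
        x, y = table.counts.iloc[i], table.counts.iloc[j]
        vals.append(sum(abs(x[a] - y[a]) for a in subset) / (x.sum() + y.sum()))
    return float(np.mean(vals))


def test_subset_dissimilarity_matches_brute_force(toy_table):
    subset = ["a1", "a4"]
    assert mean_pairwise_dissimilarity(toy_table, subset) == pytest.approx(
        brute_force_subset_mean_bc(toy_table, subset)
    )


def test_full_subset_equals_full_matrix_mean(toy_table):
    dm = bray_curtis_matrix(toy_table, relative=False)
    full_mean = dm.condensed_form().mean()
    assert mean_pairwise_dissimilarity(toy_table) == pytest.approx(full_mean)
    assert mean_pairwise_dissimilarity(toy_table, toy_table.asv_ids) == pytest.approx(full_mean)


def test_identical_samples_give_zero_for_any_subset():
    t = AsvTable(pd.DataFrame([[4, 6], [4, 6]], index=["x", "y"], columns=["a", "b"]))
    assert mean_pairwise_dissimilarity(t, ["a"]) == 0.0
    with pytest.raises(ValueError):
        mean_pairwise_dissimilarity(t.select_samples(["x"]))


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def _labelled_distance(seed=0, n=6, spread=0.0):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3))
    labels = ["g1"] * (n // 2) + ["g2"] * (n - n // 2)
    pts[np.array(labels) == "g2"] += spread
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    return DistanceMatrix(d, ids=[f"s{i}" for i in range(n)]), labels


def brute_force_exact_p(dm, labels):
    """Oracle: enumerate all distinct label arrangements, F computed from
    first principles (among/within squared-distance sums)."""
    sq = dm.data**2
    n = len(labels)

    def f_stat(lab):
        lab = np.asarray(lab)
        groups = sorted(set(lab))
        ss_tot = sq[np.triu_indices(n, 1)].sum() / n
        ss_w = 0.0
        for g in groups:
            idx = np.flatnonzero(lab == g)
            if len(idx) > 1:
                ss_w += sq[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)].sum() / len(idx)
        ss_a = ss_tot - ss_w
        return (ss_a / (len(groups) - 1)) / (ss_w / (n - len(groups)))

    f_obs = f_stat(labels)
    arrangements = set(itertools.permutations(labels))
    hits = sum(f_stat(a) >= f_obs for a in arrangements)
    return hits / len(arrangements), len(arrangements)


def test_permanova_exact_matches_enumeration_oracle():
    dm, labels = _labelled_distance(seed=2, n=6, spread=2.0)
    res = permanova(dm, labels, exact=True)
    p_oracle, n_arr = brute_force_exact_p(dm, labels)
    assert n_arr == 20  # C(6,3)
    assert res.n_permutations == 20
    assert res.p_value == pytest.approx(p_oracle)


def test_permanova_r2_one_when_within_groups_identical():
    d = np.array(
        [
            [0, 0, 1, 1],
            [0, 0, 1, 1],
            [1, 1, 0, 0],
            [1, 1, 0, 0],
        ],
        dtype=float,
    )
    dm = DistanceMatrix(d, ids=list("abcd"))
    res = permanova(dm, ["g1", "g1", "g2", "g2"], n_permutations=99, seed=0)
    assert res.r_squared == pytest.approx(1.0)


def test_permanova_agrees_with_skbio():
    dm, labels = _labelled_distance(seed=9, n=12, spread=1.0)
    mine = permanova(dm, labels, n_permutations=999, seed=1)
    ref = skbio_permanova(dm, grouping=labels, permutations=999)
    assert mine.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-9)
    assert abs(mine.p_value - ref["p-value"]) < 0.05  # same null distribution


def test_permanova_invariant_to_relabeling_and_reordering():
    dm, labels = _labelled_distance(seed=4, n=8, spread=1.0)
    base = permanova(dm, labels, n_permutations=99, seed=0)
    renamed = permanova(dm, ["B" if l == "g2" else "A" for l in labels], n_permutations=99, seed=0)
    assert renamed.r_squared == pytest.approx(base.r_squared)
    order = np.random.default_rng(0).permutation(len(labels))
    dm2 = DistanceMatrix(dm.data[np.ix_(order, order)], ids=[dm.ids[i] for i in order])
    shuffled = permanova(dm2, [labels[i] for i in order], n_permutations=99, seed=0)
    assert shuffled.r_squared == pytest.approx(base.r_squared)


def test_permanova_null_p_value_is_uniform():
    """Structure-free data: p over replicates is ~Uniform(0,1] (KS check)."""
    from scipy.stats import kstest

    rng = np.random.default_rng(12)
    pvals = []
    for _ in range(300):
        pts = rng.normal(size=(8, 3))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(8)])
        res = permanova(dm, ["a"] * 4 + ["b"] * 4, n_permutations=99, seed=int(rng.integers(2**31)))
        pvals.append(res.p_value)
    assert kstest(pvals, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------


def test_pcoa_recovers_planar_configuration():
    pts = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0], [3.0, 4.0]])
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    dm = DistanceMatrix(d, ids=list("abcd"))
    res = pcoa(dm, n_axes=2)
    coords = res.samples.to_numpy()
    rec = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
    np.testing.assert_allclose(rec, d, atol=1e-8)


def test_pcoa_two_samples_single_axis():
    dm = DistanceMatrix([[0, 0.8], [0.8, 0]], ids=["x", "y"])
    res = pcoa(dm)
    axis = res.samples.iloc[:, 0]
    assert abs(axis["x"] - axis["y"]) == pytest.approx(0.8)


def test_pcoa_eigenvalue_sum_equals_centered_trace():
    rng = np.random.default_rng(8)
    t = random_table(rng, 5, 12)
    dm = bray_curtis_matrix(t)
    sq = dm.data**2
    n = sq.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    centered = -0.5 * J @ sq @ J
    res = pcoa(dm)
    assert res.eigvals.sum() == pytest.approx(np.trace(centered), abs=1e-10)
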