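"""Occupancy/consistency ranking, contribution curve, elbow and lastcall."""

import itertools

import numpy as np
import pandas as pd
import pytest

from phyllocore import (
    AsvTable,
    SampleMetadata,
    cumulative_contribution,
    elbow_rank,
    find_core,
    lastcall_rank,
    occupancy_abundance,
    rank_by_occupancy,
)
from phyllocore.diversity import mean_pairwise_dissimilarity


# ---------------------------------------------------------------------------
# occupancy_abundance
# ---------------------------------------------------------------------------


def test_occupancy_abundance_hand_arithmetic():
    t = AsvTable(
        pd.DataFrame(
            {"v": [5, 0, 5], "w": [5, 10, 5]},
            index=["s1", "s2", "s3"],
        )
    )
    recs = {r.asv_id: r for r in occupancy_abundance(t)}
    assert recs["v"].occupancy == pytest.approx(2 / 3)
    assert recs["v"].mean_relative_abundance == pytest.approx((0.5 + 0 + 0.5) / 3)
    assert recs["w"].occupancy == 1.0
    assert recs["w"].log10_mean_abundance == pytest.approx(np.log10(recs["w"].mean_relative_abundance))


def test_single_sample_occupancy_is_binary():
    t = AsvTable(pd.DataFrame([[3, 0]], index=["s"], columns=["a", "b"]))
    occ = {r.asv_id: r.occupancy for r in occupancy_abundance(t)}
    assert occ == {"a": 1.0, "b": 0.0}


# ---------------------------------------------------------------------------
# rank_by_occupancy
# ---------------------------------------------------------------------------


def _cells_fixture():
    """Two (department, week) cells of two samples each."""
    t = AsvTable(
        pd.DataFrame(
            {
                "full": [5, 5, 5, 5],  # in every sample of every cell
                "half": [5, 5, 5, 0],  # fills cell A, half of cell B
                "none": [0, 0, 0, 0],
            },
            index=["a1", "a2", "b1", "b2"],
        )
    )
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": ["a1", "a2", "b1", "b2"],
                "sample_type": ["plant"] * 4,
                "crop": ["tomato"] * 4,
                "department": ["DA", "DA", "DB", "DB"],
                "week": [1, 1, 1, 1],
                "run": ["run1"] * 4,
            }
        )
    )
    return t, meta


def test_ranking_index_formula():
    t, meta = _cells_fixture()
    index = dict(rank_by_occupancy(t, meta))
    assert index["full"] == pytest.approx(1.0)
    # mean occupancy (1 + 0.5)/2, fully-occupied cells 1 of 2
    assert index["half"] == pytest.approx(0.5 * ((1 + 0.5) / 2 + 1 / 2))
    assert index["none"] == 0.0


def test_ranking_invariant_to_sample_order_and_label_names():
    t, meta = _cells_fixture()
    base = rank_by_occupancy(t, meta)
    order = ["b2", "a1", "b1", "a2"]
    shuffled = rank_by_occupancy(t.select_samples(order), meta)
    assert shuffled == base
    renamed_frame = meta.frame.copy()
    renamed_frame["department"] = renamed_frame["department"].map({"DA": "x9", "DB": "zz"})
    renamed = rank_by_occupancy(t, SampleMetadata(renamed_frame.reset_index(names="sample_id")))
    assert renamed == base


def test_ranking_requires_factors():
    t, meta = _cells_fixture()
    broken = meta.frame.copy()
    broken.loc["a1", "week"] = pd.NA
    with pytest.raises(Exception, match="a1"):
        rank_by_occupancy(t, SampleMetadata(broken.reset_index(names="sample_id")))


# ---------------------------------------------------------------------------
# cumulative_contribution
# ---------------------------------------------------------------------------


def test_contribution_reaches_one_and_matches_pair_enumeration():
    rng = np.random.default_rng(21)
    t = AsvTable(
        pd.DataFrame(
            rng.integers(0, 40, size=(4, 5)),
            index=[f"s{i}" for i in range(4)],
            columns=[f"a{j}" for j in range(5)],
        )
    )
    ranked = list(t.asv_ids)
    curve = cumulative_contribution(t, ranked)
    assert curve["contribution"].iloc[-1] == pytest.approx(1.0)
    full = mean_pairwise_dissimilarity(t)
    for k in range(1, 6):
        vals = []
        for i, j in itertools.combinations(range(4), 2):
            x, y = t.counts.iloc[i], t.counts.iloc[j]
            vals.append(sum(abs(x[a] - y[a]) for a in ranked[:k]) / (x.sum() + y.sum()))
        assert curve["contribution"].iloc[k - 1] == pytest.approx(np.mean(vals) / full)


def test_single_discriminating_asv_contributes_everything():
    t = AsvTable(
        pd.DataFrame(
            {"diff": [10, 0], "same": [10, 10]}, index=["x", "y"]
        )
    )
    curve = cumulative_contribution(t, ["diff", "same"])
    assert curve["contribution"].iloc[0] == pytest.approx(1.0)


def test_contribution_requires_complete_ranking(toy_table):
    with pytest.raises(ValueError):
        cumulative_contribution(toy_table, toy_table.asv_ids[:-1])


# ---------------------------------------------------------------------------
# elbow / lastcall
# ---------------------------------------------------------------------------


def brute_force_elbow(curve):
    c = np.asarray(curve, float)
    n = len(c)
    stats = [
        (c[p - 1] - c[0]) / p - (c[-1] - c[p - 1]) / (n - p) for p in range(1, n)
    ]
    return int(np.argmax(stats)) + 1


def test_elbow_hand_examples():
    assert elbow_rank([0.2, 0.8, 0.85, 0.9, 1.0]) == 2
    # steep rise to position 3, flat after
    assert elbow_rank([0.3, 0.6, 0.9, 0.92, 0.94, 0.96, 0.98, 1.0]) == 3
    # strictly linear curve: the split statistic −slope/p increases with p,
    # so the formula puts the elbow at the last split position
    assert elbow_rank(np.linspace(0.1, 1.0, 10)) == 9
    # exact ties: first maximizer wins
    assert elbow_rank([1.0, 1.0, 1.0, 1.0]) == 1
    with pytest.raises(ValueError):
        elbow_rank([0.5, 1.0])


def test_elbow_matches_exhaustive_search_on_random_curves():
    rng = np.random.default_rng(99)
    for _ in range(200):
        n = int(rng.integers(3, 40))
        curve = np.sort(rng.uniform(size=n))
        curve[-1] = 1.0
        assert elbow_rank(curve) == brute_force_elbow(curve)


def test_lastcall_scan_and_fallback():
    curve = [0.5, 0.75, 0.7725, 0.780225, 0.780225]
    increases = [0.5, 1.5, 1.03, 1.01, 1.00]
    assert lastcall_rank(curve, 1.02, increases) == 3
    # nothing qualifies -> falls back to the elbow
    flat = np.array([0.97, 0.98, 0.99, 0.995, 1.0])
    assert lastcall_rank(flat, 1.02) == elbow_rank(flat)
    # monotone 5% gains throughout -> lastcall = n
    gains = 0.5 * 1.05 ** np.arange(6)
    assert lastcall_rank(gains / gains[-1] * 1.0, 1.02) == 6


# ---------------------------------------------------------------------------
# find_core end-to-end
# ---------------------------------------------------------------------------


def test_find_core_recovers_planted_taxa(default_dataset):
    """Three planted ubiquitous, dissimilarity-dominant taxa are exactly the
    elbow core; the lastcall core is a superset."""
    from phyllocore import filter_min_reads, merge_runs, remove_nonbacterial
    from phyllocore.diversity import rarefy

    ds = default_dataset
    merged = merge_runs(list(ds.tables.values()), ds.metadata, ds.taxonomy)
    bacterial, _ = remove_nonbacterial(merged, ds.taxonomy)
    plants = ds.metadata.subset(bacterial.sample_ids).samples_of_type("plant")
    plant_table = filter_min_reads(bacterial.select_samples(plants), 100)
    rarefied = rarefy(plant_table, 500, seed=0)
    ranking = find_core(rarefied, ds.metadata)
    assert ranking.core_elbow == ds.truth.planted_core
    assert ranking.core_elbow <= ranking.core_lastcall
    ranks = ranking.table["rank"].tolist()
    assert ranks == list(range(1, len(ranks) + 1))
    assert (np.diff(ranking.table["index"].to_numpy()) <= 1e-12).all()


def test_single_dominant_asv_gives_core_of_one():
    rng = np.random.default_rng(2)
    n = 6
    counts = pd.DataFrame(
        {"dom": rng.integers(200, 1000, n), "b1": 1, "b2": 1, "b3": 1},
        index=[f"s{i}" for i in range(n)],
    )
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": counts.index,
                "sample_type": "plant",
                "crop": "tomato",
                "department": ["D1"] * 3 + ["D2"] * 3,
                "week": [1, 2, 3, 1, 2, 3],
                "run": "run1",
            }
        )
    )
    ranking = find_core(AsvTable(counts), meta)
    assert ranking.core_elbow == {"dom"}
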