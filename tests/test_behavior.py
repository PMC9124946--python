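"""Behavioral scoring, indices, z-scores and clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fairgame import behavior as beh


# ---------------------------------------------------------------- trial sets

# independent truth table transcribed directly from the set definitions
DG_TRUTH = {
    (90, "accepted"): "DG_selfish", (80, "accepted"): "DG_selfish",
    (60, "refused"): "DG_selfish", (50, "refused"): "DG_selfish",
    (60, "accepted"): "DG_fair", (50, "accepted"): "DG_fair",
    (90, "refused"): "DG_fair", (80, "refused"): "DG_fair",
    (70, "accepted"): "DG_neutral", (70, "refused"): "DG_neutral",
}
UG_TRUTH = {
    (10, "accepted"): "UG_altruistic", (20, "accepted"): "UG_altruistic",
    (40, "refused"): "UG_altruistic", (50, "refused"): "UG_altruistic",
    (40, "accepted"): "UG_conceit", (50, "accepted"): "UG_conceit",
    (10, "refused"): "UG_conceit", (20, "refused"): "UG_conceit",
    (30, "accepted"): "UG_neutral", (30, "refused"): "UG_neutral",
}


@pytest.mark.parametrize("game,truth", [("DG", DG_TRUTH), ("UG", UG_TRUTH)])
def test_trial_set_labels_match_truth_table(game, truth):
    for (share, resp), label in truth.items():
        assert beh.trial_set_label(game, share, resp) == label


def test_every_valid_trial_gets_exactly_one_label():
    for game, shares in (("DG", (50, 60, 70, 80, 90)), ("UG", (10, 20, 30, 40, 50))):
        for share, resp in itertools.product(shares, ("accepted", "refused")):
            label = beh.trial_set_label(game, share, resp)
            assert label in beh.TRIAL_SETS


def test_classify_rejects_invalid_trials_and_unknown_allocations():
    with pytest.raises(ValueError):
        beh.trial_set_label("DG", 90, "omitted")
    with pytest.raises(ValueError):
        beh.trial_set_label("DG", 85, "accepted")
    with pytest.raises(ValueError):
        beh.classify_trial({"game": "DG", "allocation_self_share": 90,
                            "response": "accepted", "valid": False})


# ---------------------------------------------------------------- index

@pytest.mark.parametrize("pro,anti,expected", [
    (79.2, 0.8, 0.98),    # selfish group, allocator role
    (3.1, 77.0, -0.92),   # fair group
    (45.0, 34.9, 0.13),   # heterogeneous group
    (1.3, 78.7, -0.97),   # selfish group, responder role
    (23.9, 56.1, -0.40),  # low-conceit group
    (65.0, 16.4, 0.60),   # intermediate group
])
def test_index_reproduces_published_group_medians(pro, anti, expected):
    assert round(beh.compute_index(pro, anti), 2) == expected


def test_index_edge_cases():
    assert beh.compute_index(5, 5) == 0.0
    assert beh.compute_index(0, 7) == -1.0
    assert np.isnan(beh.compute_index(0, 0))
    with pytest.raises(ValueError):
        beh.compute_index(-1, 2)


@settings(max_examples=100, deadline=None)
@given(st.floats(0, 1e6), st.floats(0, 1e6))
def test_index_antisymmetric_and_bounded(a, b):
    x = beh.compute_index(a, b)
    if a + b == 0:
        assert np.isnan(x)
    else:
        assert -1.0 <= x <= 1.0
        assert x == pytest.approx(-beh.compute_index(b, a), abs=1e-12)


# ---------------------------------------------------------------- profiles

def _trials(rows):
    return pd.DataFrame(rows, columns=["participant", "game",
                                       "allocation_self_share", "response",
                                       "valid", "rt_ms"])


def test_profile_all_neutral_gives_undefined_index():
    rows = [("P01", "DG", 70, "accepted", True, 400.0)] * 240
    p = beh.build_profile(_trials(rows))
    assert np.isnan(p["dg_selfishness"])
    assert p["counts"]["DG_neutral"] == 240


def test_profile_is_permutation_invariant(behavioral_cohort):
    sub = behavioral_cohort[behavioral_cohort["participant"] == "P01"]
    p1 = beh.build_profile(sub)
    p2 = beh.build_profile(sub.sample(frac=1.0, random_state=0))
    assert p1 == p2


def test_profile_counts_sum_to_valid_trials(behavioral_cohort):
    prof = beh.build_profiles(behavioral_cohort)
    for _, row in prof.iterrows():
        dg = sum(row[f"n_{s}"] for s in beh.TRIAL_SETS if s.startswith("DG"))
        assert dg == row["n_valid_dg"]


# ---------------------------------------------------------------- z-scores

def test_zscore_hand_example():
    t = _trials([("P01", "DG", 70, "accepted", True, rt)
                 for rt in (400.0, 500.0, 600.0)])
    z = beh.zscore_rt(t)
    assert np.allclose(z.to_numpy(), [-1.0, 0.0, 1.0])


def test_zscore_constant_rts_error():
    t = _trials([("P01", "DG", 70, "accepted", True, 500.0)] * 5)
    with pytest.raises(ValueError, match="P01"):
        beh.zscore_rt(t)


def test_zscore_cell_mean_zero_sd_one(behavioral_cohort):
    sub = behavioral_cohort[behavioral_cohort["valid"]].copy()
    z = beh.zscore_rt(sub)
    for (_, _), idx in sub.groupby(["participant", "game"]).groups.items():
        vals = z.loc[idx].dropna()
        assert abs(vals.mean()) < 1e-9
        assert vals.std(ddof=1) == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------- clustering

def _profiles(points, ids=None):
    ids = ids or [f"P{i:02d}" for i in range(1, len(points) + 1)]
    return pd.DataFrame({"participant": ids,
                         "ug_altruism": [p[0] for p in points],
                         "dg_selfishness": [p[1] for p in points]})


def brute_force_complete_linkage(points, k):
    """Naive O(n^3) agglomerative complete-linkage clustering."""
    clusters = [frozenset([i]) for i in range(len(points))]
    pts = np.asarray(points, float)

    def dist(a, b):
        return max(np.linalg.norm(pts[i] - pts[j]) for i in a for j in b)

    while len(clusters) > k:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = dist(clusters[i], clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        _, i, j = best
        merged = clusters[i] | clusters[j]
        clusters = [c for idx, c in enumerate(clusters) if idx not in (i, j)]
        clusters.append(merged)
    labels = np.empty(len(points), dtype=int)
    for ci, c in enumerate(clusters):
        for i in c:
            labels[i] = ci
    return labels


def _same_partition(a, b):
    a, b = np.asarray(a), np.asarray(b)
    return len({(x, y) for x, y in zip(a, b)}) == len(set(a)) == len(set(b))


def test_two_points_form_two_singletons():
    res = beh.cluster_cohort(_profiles([(0.0, 0.0), (1.0, 1.0)]))
    assert res.k == 2
    assert sorted(res.labels.to_numpy()) == [1, 2]


@pytest.mark.parametrize("n,k", [(5, 2), (6, 2), (7, 3), (8, 3), (8, 4)])
def test_clustering_matches_bruteforce_oracle(n, k, rng):
    for _ in range(8):
        pts = rng.normal(size=(n, 2))
        res = beh.cluster_cohort(_profiles([tuple(p) for p in pts]),
                                 beh.ClusterConfig(k=k))
        oracle = brute_force_complete_linkage(pts, k)
        assert _same_partition(res.labels.to_numpy(), oracle)


def test_undefined_indices_are_excluded():
    prof = _profiles([(0, 0), (1, 1), (np.nan, 0.5)])
    res = beh.cluster_cohort(prof)
    assert res.excluded == ["P03"]
    with pytest.raises(ValueError):
        beh.cluster_cohort(_profiles([(0, 0), (np.nan, 1)]))


def test_group_naming_on_published_centroids():
    # cluster centroids at the published median index pairs
    pts, ids = [], []
    centroids = {"GrpS": (-0.97, 0.98), "GrpA": (-0.69, 0.60),
                 "GrpB": (-0.40, 0.73), "GrpC": (-0.29, 0.13),
                 "GrpF": (-0.97, -0.92)}
    truth = []
    i = 0
    for name, (ug, dg) in centroids.items():
        for d in (-0.012, 0.0, 0.012):
            i += 1
            ids.append(f"P{i:02d}")
            pts.append((ug + d, dg + d))
            truth.append(name)
    prof = _profiles(pts, ids)
    res = beh.assess_stability(prof, beh.ClusterConfig(k=5, jitter_eps=0.0))
    named = prof["participant"].map(res.group_names)
    assert list(named) == truth
    assert res.stability.all()


def test_borderline_participant_flagged_unstable():
    tight_a = [(-0.95 + d, 0.95 + d) for d in (-0.01, 0.0, 0.01)] * 2
    tight_b = [(-0.40 + d, 0.70 + d) for d in (-0.01, 0.0, 0.01)] * 2
    border = [(-0.675, 0.825)]  # exactly midway between the two centroids
    prof = _profiles(tight_a + tight_b + border)
    res = beh.assess_stability(prof, beh.ClusterConfig(
        k=2, jitter_eps=0.02, stability_replicates=50, seed=1))
    assert not res.stability.loc["P13"]
    assert res.group_names.loc["P13"] == "GrpA"
    assert res.stability.drop("P13").all()


def test_zero_jitter_replicates_are_all_stable():
    prof = _profiles([(-0.9, 0.9), (-0.88, 0.95), (-0.4, 0.7), (-0.38, 0.72)])
    res = beh.assess_stability(prof, beh.ClusterConfig(k=2, jitter_eps=0.0))
    assert res.stability.all()
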