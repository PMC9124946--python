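"""Behavioral scoring and phenotyping.

Valid trials of each game fall into exactly one of three sets.  In the
dictator game (the participant allocates): *selfish* trials endorse the
most favorable splits for the allocator (self-share 90 or 80) or refuse the
least favorable ones (60 or 50); *fair* trials do the opposite; 70:30 trials
are *neutral* regardless of response.  In the ultimatum game (the
participant responds): *altruistic* trials accept the least favorable offers
(self-share 10 or 20) or reject the equitable ones (40 or 50); *conceit*
trials do the opposite; 30:70 offers are neutral.

Two indices in [-1, 1] contrast the opposed sets:

    DG_selfishness = (Nb_selfish - Nb_fair) / (Nb_selfish + Nb_fair)
    UG_altruism    = (Nb_altruistic - Nb_conceit) / (Nb_altruistic + Nb_conceit)

Participants are phenotyped by complete-linkage agglomerative clustering of
the (UG_altruism, DG_selfishness) points, with a jitter/shuffle perturbation
scheme that flags participants whose assignment is unstable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment

__all__ = [
    "TRIAL_SETS", "trial_set_label", "classify_trial", "compute_index",
    "build_profile", "build_profiles", "zscore_rt",
    "ClusterConfig", "ClusterResult", "cluster_cohort", "assess_stability",
]

TRIAL_SETS = ("DG_selfish", "DG_neutral", "DG_fair",
              "UG_altruistic", "UG_neutral", "UG_conceit")

_DG_PRO = frozenset({80, 90})     # most favorable to the allocator
_DG_ANTI = frozenset({50, 60})
_UG_LEAST = frozenset({10, 20})   # least favorable offers to the responder
_UG_EQUIT = frozenset({40, 50})


def trial_set_label(game: str, self_share: int, response: str) -> str:
    """Trial-set label of one valid trial."""
    if response not in ("accepted", "refused"):
        raise ValueError(f"invalid or omitted trial (response={response!r})")
    acc = response == "accepted"
    if game == "DG":
        if self_share == 70:
            return "DG_neutral"
        if self_share in _DG_PRO:
            return "DG_selfish" if acc else "DG_fair"
        if self_share in _DG_ANTI:
            return "DG_fair" if acc else "DG_selfish"
    elif game == "UG":
        if self_share == 30:
            return "UG_neutral"
        if self_share in _UG_LEAST:
            return "UG_altruistic" if acc else "UG_conceit"
        if self_share in _UG_EQUIT:
            return "UG_conceit" if acc else "UG_altruistic"
    else:
        raise ValueError(f"unknown game {game!r}")
    raise ValueError(f"unknown allocation self-share {self_share} for {game}")


# spec-level alias taking a trial record (mapping or namedtuple-like row)
def classify_trial(trial) -> str:
    """Label a single trial record (needs game, allocation, response)."""
    get = trial.get if hasattr(trial, "get") else trial.__getitem__
    if not get("valid"):
        raise ValueError("cannot classify an invalid (omitted) trial")
    return trial_set_label(get("game"), int(get("allocation_self_share")),
                           get("response"))


def compute_index(n_pro: float, n_anti: float) -> float:
    """Normalized contrast (n_pro - n_anti) / (n_pro + n_anti).

    Accepts counts or percent frequencies (the scale cancels).  Returns NaN
    (undefined) when both inputs are zero; raises on negative input.
    """
    if n_pro < 0 or n_anti < 0:
        raise ValueError("set counts must be nonnegative")
    tot = n_pro + n_anti
    if tot == 0:
        return float("nan")
    return (n_pro - n_anti) / tot


def build_profile(trials: pd.DataFrame) -> dict:
    """Per-participant set counts, relative frequencies and both indices.

    ``trials`` holds one participant's trials (either or both games).
    Frequencies are percentages of the game's valid trials.  Order of rows
    is irrelevant.
    """
    counts = {s: 0 for s in TRIAL_SETS}
    valid = trials[trials["valid"].astype(bool)]
    for game, s, r in zip(valid["game"], valid["allocation_self_share"],
                          valid["response"]):
        counts[trial_set_label(game, int(s), r)] += 1
    n_dg = sum(counts[s] for s in TRIAL_SETS if s.startswith("DG"))
    n_ug = sum(counts[s] for s in TRIAL_SETS if s.startswith("UG"))
    freq = {}
    for s in TRIAL_SETS:
        n_game = n_dg if s.startswith("DG") else n_ug
        freq[s] = 100.0 * counts[s] / n_game if n_game else float("nan")
    return {
        "counts": counts,
        "frequencies_pct": freq,
        "n_valid_dg": n_dg,
        "n_valid_ug": n_ug,
        "dg_selfishness": compute_index(counts["DG_selfish"], counts["DG_fair"]),
        "ug_altruism": compute_index(counts["UG_altruistic"], counts["UG_conceit"]),
    }


def build_profiles(behavior: pd.DataFrame) -> pd.DataFrame:
    """Tidy profile table, one row per participant."""
    rows = []
    for pid, sub in behavior.groupby("participant", sort=True):
        p = build_profile(sub)
        row = {"participant": pid,
               "dg_selfishness": p["dg_selfishness"],
               "ug_altruism": p["ug_altruism"],
               "n_valid_dg": p["n_valid_dg"], "n_valid_ug": p["n_valid_ug"]}
        row.update({f"n_{s}": p["counts"][s] for s in TRIAL_SETS})
        row.update({f"pct_{s}": p["frequencies_pct"][s] for s in TRIAL_SETS})
        if "group_truth" in sub.columns:
            row["group_truth"] = sub["group_truth"].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


def zscore_rt(trials: pd.DataFrame) -> pd.Series:
    """Within-(participant, game) z-scores of RTs over valid trials.

    Invalid trials get NaN.  Raises if any cell has zero RT variance or
    fewer than two valid trials.
    """
    rt = pd.to_numeric(trials["rt_ms"])
    out = pd.Series(np.nan, index=trials.index, dtype=float)
    valid = trials["valid"].astype(bool) & rt.notna()
    for (pid, game), idx in trials[valid].groupby(
            ["participant", "game"], sort=False).groups.items():
        x = rt.loc[idx]
        if len(x) < 2:
            raise ValueError(f"cell ({pid}, {game}) has fewer than 2 valid trials")
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError(f"cell ({pid}, {game}) has zero RT variance")
        out.loc[idx] = (x - x.mean()) / sd
    return out


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterConfig:
    k: int | None = None          # fixed k, or None -> gap criterion
    k_range: tuple[int, int] = (2, 6)
    stability_replicates: int = 50
    jitter_eps: float = 0.01
    seed: int = 0


@dataclass
class ClusterResult:
    labels: pd.Series             # participant -> integer cluster id
    k: int
    merge_heights: np.ndarray
    linkage_matrix: np.ndarray
    excluded: list                # participants with undefined indices
    stability: pd.Series | None = None   # participant -> bool (stable)
    group_names: pd.Series | None = None


def _complete_linkage_labels(points: np.ndarray, k: int) -> np.ndarray:
    Z = linkage(points, method="complete", metric="euclidean")
    return fcluster(Z, t=k, criterion="maxclust")


def _choose_k(heights: np.ndarray, k_range: tuple[int, int]) -> int:
    """Largest relative gap in merge heights over the admissible k."""
    n = heights.size + 1
    best_k, best_gap = k_range[0], -np.inf
    for k in range(k_range[0], min(k_range[1], n - 1) + 1):
        low = heights[n - 1 - k]        # last merge while >= k clusters remain
        high = heights[n - k]           # merge that reduces to k-1 clusters
        gap = high / low if low > 0 else np.inf
        if gap > best_gap:
            best_k, best_gap = k, gap
    return best_k


def cluster_cohort(profiles: pd.DataFrame,
                   config: ClusterConfig = ClusterConfig()) -> ClusterResult:
    """Complete-linkage clustering of (UG_altruism, DG_selfishness) points.

    Participants with an undefined index are excluded and reported.  k is
    fixed by config or chosen by the largest relative merge-height gap.
    """
    pts = profiles[["ug_altruism", "dg_selfishness"]].to_numpy(dtype=float)
    ok = np.isfinite(pts).all(axis=1)
    excluded = list(profiles.loc[~ok, "participant"])
    usable = profiles.loc[ok]
    if len(usable) < 2:
        raise ValueError("need at least 2 participants with defined indices")
    X = pts[ok]
    Z = linkage(X, method="complete", metric="euclidean")
    heights = Z[:, 2]
    k = config.k if config.k is not None else _choose_k(heights, config.k_range)
    k = min(k, len(usable))
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(
        labels=pd.Series(labels, index=usable["participant"].to_numpy()),
        k=k, merge_heights=heights, linkage_matrix=Z, excluded=excluded)


def _match_labels(ref: np.ndarray, new: np.ndarray) -> np.ndarray:
    """Relabel ``new`` to maximize overlap with ``ref`` (Hungarian)."""
    ref_ids, new_ids = np.unique(ref), np.unique(new)
    cost = np.zeros((new_ids.size, ref_ids.size))
    for i, a in enumerate(new_ids):
        for j, b in enumerate(ref_ids):
            cost[i, j] = -np.sum((new == a) & (ref == b))
    ri, ci = linear_sum_assignment(cost)
    mapping = {new_ids[i]: ref_ids[j] for i, j in zip(ri, ci)}
    return np.array([mapping.get(x, -x) for x in new])


_MIDDLE_NAMES = {1: ["GrpB"], 2: ["GrpC", "GrpB"], 3: ["GrpC", "GrpB", "GrpA"]}


def _name_groups(labels: pd.Series, profiles: pd.DataFrame) -> pd.Series:
    """Map cluster ids to group names by centroid position.

    Highest DG_selfishness centroid -> GrpS, lowest -> GrpF; the remaining
    clusters, in descending UG_altruism, take GrpC/GrpB/GrpA.
    """
    prof = profiles.set_index("participant")
    cents = {}
    for cid in np.unique(labels.to_numpy()):
        pids = labels.index[labels.to_numpy() == cid]
        cents[cid] = (prof.loc[pids, "dg_selfishness"].mean(),
                      prof.loc[pids, "ug_altruism"].mean())
    by_selfish = sorted(cents, key=lambda c: cents[c][0])
    names = {by_selfish[-1]: "GrpS", by_selfish[0]: "GrpF"}
    middle = [c for c in cents if c not in names]
    middle.sort(key=lambda c: cents[c][1], reverse=True)
    pool = _MIDDLE_NAMES.get(len(middle),
                             [f"Grp{i}" for i in range(len(middle))])
    for cid, nm in zip(middle, pool):
        names[cid] = nm
    return labels.map(names)


def assess_stability(profiles: pd.DataFrame,
                     config: ClusterConfig = ClusterConfig(),
                     base: ClusterResult | None = None) -> ClusterResult:
    """Perturbation replicates: jitter the indices and shuffle the input
    order; participants whose (matched) label ever changes are unstable and
    form an extra group ("GrpA" analogue).  Stable clusters are named by
    centroid position.
    """
    base = base or cluster_cohort(profiles, config)
    pids = base.labels.index.to_numpy()
    usable = profiles[profiles["participant"].isin(pids)].set_index(
        "participant").loc[pids].reset_index()
    X = usable[["ug_altruism", "dg_selfishness"]].to_numpy(dtype=float)
    ref = base.labels.to_numpy()
    rng = np.random.default_rng(config.seed)
    stable = np.ones(ref.size, dtype=bool)
    for _ in range(config.stability_replicates):
        order = rng.permutation(ref.size)
        Xp = X[order] + rng.normal(0.0, config.jitter_eps, size=X.shape)
        lab_p = _complete_linkage_labels(Xp, base.k)
        lab = np.empty_like(lab_p)
        lab[order] = lab_p
        stable &= _match_labels(ref, lab) == ref
    names = _name_groups(base.labels, usable)
    names = names.where(pd.Series(stable, index=names.index), "GrpA")
    return ClusterResult(labels=base.labels, k=base.k,
                         merge_heights=base.merge_heights,
                         linkage_matrix=base.linkage_matrix,
                         excluded=base.excluded,
                         stability=pd.Series(stable, index=base.labels.index),
                         group_names=names)
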