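"""Pipeline orchestration: simulate -> classify -> erp -> stats -> report.

Stages communicate only through documented on-disk files so that any stage
can be re-run in isolation or fed real data in the same schema:

    simulate : behavior.tsv, events.tsv, epochs.h5, ledger.json
    classify : profiles.csv, clusters.json, scatter.csv
    erp      : measurements.csv, grand_averages.csv
    stats    : stats.csv
    report   : report.md

A manifest (manifest.json) records the config hash, which stages ran, a
checksum for every output file and the accumulated warnings.  With
``resume=True`` a stage is skipped when its outputs exist and no upstream
stage had to run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .behavior import (ClusterConfig, assess_stability, build_profiles,
                       cluster_cohort, trial_set_label, zscore_rt)
from .erp import (EpochSpec, FilterSpec, bandpass, baseline_correct,
                  default_times_ms, measure_components, reject_artifacts)
from .lmm import anova_like, fit_lmm
from .stats import test_means
from .synthetic import CohortSpec, NoiseModel, iter_participants

STAGES = ("simulate", "classify", "erp", "stats", "report")

STAGE_OUTPUTS = {
    "simulate": ["behavior.tsv", "events.tsv", "epochs.h5", "ledger.json"],
    "classify": ["profiles.csv", "clusters.json", "scatter.csv"],
    "erp": ["measurements.csv", "grand_averages.csv"],
    "stats": ["stats.csv"],
    "report": ["report.md"],
}


@dataclass
class RunConfig:
    seed: int = 0
    group_sizes: dict = field(default_factory=lambda: {"GrpS": 8, "GrpB": 10,
                                                       "GrpF": 10})
    games: list = field(default_factory=lambda: ["DG", "UG"])
    eeg_games: list = field(default_factory=lambda: ["DG", "UG"])
    channels: list = field(default_factory=lambda: ["Fz", "FCz", "Pz", "CPz"])
    n_blocks: int = 5
    block_size: int = 48
    noise_rms_uv: float = 10.0
    noise_exponent: float = 1.0
    blink_rate: float = 0.0
    replicates: int = 3
    reject_threshold_uv: float = 100.0
    smoothing_ms: float = 8.0
    cluster_k: int | None = None
    stability_replicates: int = 50
    jitter_eps: float = 0.01
    designs: list = field(default_factory=lambda: [
        "response_by_group", "game_by_group", "response_by_behavior"])

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(group_sizes=dict(self.group_sizes), seed=self.seed,
                          channels=tuple(self.channels),
                          noise=NoiseModel(self.noise_rms_uv, self.noise_exponent),
                          games=tuple(self.games),
                          eeg_games=tuple(self.eeg_games),
                          n_blocks=self.n_blocks, block_size=self.block_size,
                          blink_rate=self.blink_rate)

    def cluster_config(self) -> ClusterConfig:
        return ClusterConfig(k=self.cluster_k,
                             stability_replicates=self.stability_replicates,
                             jitter_eps=self.jitter_eps, seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig, out: Path, warnings: list) -> None:
    spec = config.cohort_spec()
    times = default_times_ms(spec.sfreq)
    frames, ledger = [], {"participants": {}, "seed": spec.seed,
                          "sfreq": spec.sfreq, "channels": list(spec.channels)}

    def produce():
        for pid, group, behavior, epochs_by_game, truth in iter_participants(spec):
            frames.append(behavior)
            ledger["participants"][pid] = truth
            for game, pack in epochs_by_game.items():
                yield pid, game, pack["data"], pack["trials"]

    fio.write_epochs_h5(out / "epochs.h5", produce(), times, spec.channels,
                        spec.sfreq)
    behavior = pd.concat(frames, ignore_index=True)
    fio.write_behavior_tsv(behavior, out / "behavior.tsv")
    fio.write_events_tsv(behavior, out / "events.tsv")
    fio.write_ledger_json(ledger, out / "ledger.json")
    n_omitted = int((~behavior["valid"]).sum())
    warnings.append(f"simulate: {len(behavior)} trials, {n_omitted} omitted")


def stage_classify(config: RunConfig, out: Path, warnings: list) -> None:
    behavior = fio.read_behavior_tsv(out / "behavior.tsv")
    profiles = build_profiles(behavior)
    ccfg = config.cluster_config()
    base = cluster_cohort(profiles, ccfg)
    res = assess_stability(profiles, ccfg, base)
    profiles["group"] = profiles["participant"].map(res.group_names)
    profiles.to_csv(out / "profiles.csv", index=False)
    clusters = {
        "k": int(res.k),
        "merge_heights": [float(h) for h in res.merge_heights],
        "excluded": list(res.excluded),
        "groups": {str(p): str(g) for p, g in res.group_names.items()},
        "stable": {str(p): bool(s) for p, s in res.stability.items()},
    }
    (out / "clusters.json").write_text(json.dumps(clusters, indent=1,
                                                  sort_keys=True))
    profiles[["participant", "ug_altruism", "dg_selfishness", "group"]].to_csv(
        out / "scatter.csv", index=False)
    unstable = [p for p, s in res.stability.items() if not s]
    if unstable:
        warnings.append(f"classify: unstable participants {unstable}")
    if res.excluded:
        warnings.append(f"classify: excluded (undefined index) {res.excluded}")


def stage_erp(config: RunConfig, out: Path, warnings: list) -> None:
    behavior = fio.read_behavior_tsv(out / "behavior.tsv")
    groups = json.loads((out / "clusters.json").read_text())["groups"]
    times, channels, sfreq = fio.read_epochs_meta(out / "epochs.h5")
    fspec, espec = FilterSpec(), EpochSpec(
        reject_threshold_uv=config.reject_threshold_uv)
    meas_frames, ga_acc = [], {}
    n_rejected = 0
    for pid, game, data, trials in fio.iter_epochs_h5(out / "epochs.h5"):
        data = bandpass(data, sfreq, fspec)
        data = baseline_correct(data, times, espec.baseline_ms)
        data, kept, log = reject_artifacts(data, espec.reject_threshold_uv,
                                           channels)
        n_rejected += len(log)
        sub = behavior[(behavior["participant"] == pid)
                       & (behavior["game"] == game)
                       & behavior["valid"]].set_index("trial").loc[trials]
        sub = sub.iloc[kept]
        labels = np.array([trial_set_label(game, int(s), r) for s, r in
                           zip(sub["allocation_self_share"], sub["response"])])
        conds = {f"{game}|all": data}
        for lbl in np.unique(labels):
            if "neutral" in lbl:
                continue
            family = lbl.split("_", 1)[1]
            for resp in ("accepted", "refused"):
                m = (labels == lbl) & (sub["response"].to_numpy() == resp)
                if m.any():
                    conds[f"{game}|{family}|{resp}"] = data[m]
        meas = measure_components(
            conds, times, channels, replicates=config.replicates,
            seed=np.random.SeedSequence([config.seed, int(pid.lstrip("P"))]),
            smoothing_ms=config.smoothing_ms, participant=pid)
        meas["game"] = game
        meas["group"] = groups.get(pid, "")
        meas_frames.append(meas)
        key = (groups.get(pid, ""), game)
        ga_acc.setdefault(key, []).append(data.mean(axis=0))
    meas = pd.concat(meas_frames, ignore_index=True)
    parts = meas["condition"].str.split("|", expand=True)
    meas["set"] = parts[1].where(parts[1] != "all", "all")
    meas["response"] = parts[2] if parts.shape[1] > 2 else None
    meas.to_csv(out / "measurements.csv", index=False)

    rows = []
    for (group, game), avgs in sorted(ga_acc.items()):
        ga = np.mean(avgs, axis=0)
        for ci, ch in enumerate(channels):
            rows.append(pd.DataFrame({
                "group": group, "game": game, "channel": ch,
                "time_ms": times, "amplitude_uv": ga[ci]}))
    pd.concat(rows, ignore_index=True).to_csv(out / "grand_averages.csv",
                                              index=False)
    n_unid = int((~meas["identified"].astype(bool)).sum())
    warnings.append(f"erp: {n_rejected} epochs rejected, "
                    f"{n_unid} unidentified peak measurements")


def _rt_design(behavior: pd.DataFrame, groups: dict, game: str):
    sub = behavior[(behavior["game"] == game) & behavior["valid"]].copy()
    sub["z_rt"] = zscore_rt(sub)
    sub["group"] = sub["participant"].map(groups)
    sub = sub[sub["group"].isin(["GrpS", "GrpB", "GrpF"])]
    cells = (sub.groupby(["participant", "group", "response"], observed=True)
             ["z_rt"].mean().reset_index())
    return cells


def stage_stats(config: RunConfig, out: Path, warnings: list) -> None:
    behavior = fio.read_behavior_tsv(out / "behavior.tsv")
    groups = json.loads((out / "clusters.json").read_text())["groups"]
    meas = pd.read_csv(out / "measurements.csv")
    meas = meas[meas["identified"].astype(bool)]
    rows = []

    def add_anova(design, game, component, measure, table, fixed):
        try:
            fit = fit_lmm(table, measure, fixed)
        except Exception as exc:  # degenerate designs on tiny demo runs
            warnings.append(f"stats: {design}/{game}/{component}/{measure}: {exc}")
            return
        for _, r in anova_like(fit).iterrows():
            rows.append({"design": design, "game": game,
                         "component": component, "measure": measure,
                         "effect": r["effect"], "kind": "anova_like",
                         "statistic": r["F"], "df1": r["df1"], "df2": r["df2"],
                         "p": r["p"], "eta_g2": r.get("eta_g2", np.nan),
                         "n": len(table)})

    if "response_by_group" in config.designs:
        for game in config.games:
            try:
                cells = _rt_design(behavior, groups, game)
            except ValueError as exc:
                warnings.append(f"stats: rt design {game}: {exc}")
                continue
            if cells["group"].nunique() >= 2:
                add_anova("response_by_group", game, "RT", "z_rt", cells,
                          ["response", "group"])

    erp_groups = meas[meas["group"].isin(["GrpS", "GrpB", "GrpF"])]
    if "game_by_group" in config.designs and len(config.eeg_games) > 1:
        pooled = erp_groups[erp_groups["set"] == "all"]
        for component, sub in pooled.groupby("component"):
            for measure in ("latency_ms", "amplitude_uv"):
                if sub["group"].nunique() >= 2 and sub["game"].nunique() == 2:
                    add_anova("game_by_group", "both", component, measure,
                              sub, ["game", "group"])
                    f = sub[sub["group"] == "GrpF"][measure]
                    s = sub[sub["group"] == "GrpS"][measure]
                    for game in config.eeg_games:
                        fg = sub[(sub["group"] == "GrpF") & (sub["game"] == game)][measure]
                        sg = sub[(sub["group"] == "GrpS") & (sub["game"] == game)][measure]
                        if len(fg) >= 2 and len(sg) >= 2:
                            t = test_means(fg, sg, m_comparisons=2)
                            rows.append({"design": "game_by_group", "game": game,
                                         "component": component,
                                         "measure": measure,
                                         "effect": "GrpF_vs_GrpS",
                                         "kind": f"t_{t.variant}",
                                         "statistic": t.t, "df1": 1,
                                         "df2": t.df, "p": t.p,
                                         "p_adjusted": t.p_adjusted,
                                         "cohens_d": t.d,
                                         "d_category": t.d_category,
                                         "n": t.n1 + t.n2})
    if "response_by_behavior" in config.designs:
        sets = erp_groups[erp_groups["set"] != "all"].copy()
        sets["behavior_set"] = sets["set"]
        for (game, component), sub in sets.groupby(["game", "component"]):
            for measure in ("latency_ms", "amplitude_uv"):
                if (sub["behavior_set"].nunique() == 2
                        and sub["response"].nunique() == 2):
                    add_anova("response_by_behavior", game, component, measure,
                              sub, ["response", "behavior_set"])
    pd.DataFrame(rows).to_csv(out / "stats.csv", index=False)


def _fmt_mean_sem(x) -> str:
    x = np.asarray(x, float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return "-"
    sem = x.std(ddof=1) / np.sqrt(x.size) if x.size > 1 else 0.0
    return f"{np.median(x):.1f}, {x.mean():.1f} ± {sem:.1f}"


def stage_report(config: RunConfig, out: Path, warnings: list) -> None:
    lines = ["# Pipeline report", ""]
    prof_path = out / "profiles.csv"
    if prof_path.exists():
        prof = pd.read_csv(prof_path)
        lines += ["## Behavioral groups (median, mean ± SEM of % frequencies)", ""]
        cols = ["pct_DG_selfish", "pct_DG_fair", "dg_selfishness",
                "pct_UG_altruistic", "pct_UG_conceit", "ug_altruism"]
        header = "| group | n | " + " | ".join(cols) + " |"
        lines += [header, "|" + "---|" * (len(cols) + 2)]
        for group, sub in prof.groupby("group"):
            cells = [_fmt_mean_sem(sub[c]) for c in cols]
            lines.append(f"| {group} | {len(sub)} | " + " | ".join(cells) + " |")
        lines.append("")
    else:
        lines += ["## Behavioral groups", "", "*absent*", ""]

    beh_path = out / "behavior.tsv"
    if beh_path.exists():
        behavior = fio.read_behavior_tsv(beh_path)
        lines += ["## Reaction times (ms; median, mean ± SEM per response)", ""]
        lines += ["| game | response | summary |", "|---|---|---|"]
        for (game, resp), sub in behavior[behavior["valid"]].groupby(
                ["game", "response"]):
            lines.append(f"| {game} | {resp} | {_fmt_mean_sem(sub['rt_ms'])} |")
        lines.append("")

    meas_path = out / "measurements.csv"
    if meas_path.exists():
        meas = pd.read_csv(meas_path)
        meas = meas[meas["identified"].astype(bool)]
        lines += ["## ERP components (mean latency ms / amplitude uV)", ""]
        lines += ["| component | game | group | latency | amplitude | n |",
                  "|---|---|---|---|---|---|"]
        pooled = meas[meas["set"] == "all"]
        for (comp, game, group), sub in pooled.groupby(
                ["component", "game", "group"]):
            lines.append(f"| {comp} | {game} | {group} | "
                         f"{sub['latency_ms'].mean():.1f} | "
                         f"{sub['amplitude_uv'].mean():.2f} | {len(sub)} |")
        lines.append("")
        ledger_path = out / "ledger.json"
        if ledger_path.exists():
            ledger = fio.read_ledger_json(ledger_path)
            lines += ["## Recovery vs planted ground truth (N1 latency, ms)", ""]
            lines += ["| group | game | planted | recovered |", "|---|---|---|---|"]
            rec = meas[(meas["set"] == "all") & (meas["component"] == "N1")]
            for (group, game), sub in rec.groupby(["group", "game"]):
                planted = []
                for pid, entry in ledger["participants"].items():
                    if entry["group"] != group or game not in entry["erp"]:
                        continue
                    for resp in entry["erp"][game].values():
                        planted.append(resp["N1"]["FCz"]["latency_ms"])
                if planted:
                    lines.append(f"| {group} | {game} | {np.mean(planted):.1f} "
                                 f"| {sub['latency_ms'].mean():.1f} |")
            lines.append("")

    stats_path = out / "stats.csv"
    if stats_path.exists():
        stats = pd.read_csv(stats_path)
        lines += ["## Statistical tests", ""]
        if len(stats):
            lines += ["| design | game | component | measure | effect | stat | df | p |",
                      "|---|---|---|---|---|---|---|---|"]
            for _, r in stats.iterrows():
                lines.append(
                    f"| {r['design']} | {r['game']} | {r['component']} | "
                    f"{r['measure']} | {r['effect']} | {r['statistic']:.3f} | "
                    f"({r['df1']:.0f}, {r['df2']:.1f}) | {r['p']:.4g} |")
        lines.append("")
    else:
        lines += ["## Statistical tests", "", "*absent*", ""]
    if warnings:
        lines += ["## Warnings", ""] + [f"- {w}" for w in warnings] + [""]
    (out / "report.md").write_text("\n".join(lines))


_STAGE_FUNCS = {"simulate": stage_simulate, "classify": stage_classify,
                "erp": stage_erp, "stats": stage_stats, "report": stage_report}


def run_all(config: RunConfig, out_dir, resume: bool = False,
            stages=STAGES) -> dict:
    """Execute the pipeline; returns (and writes) the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    warnings: list[str] = []
    manifest = {"config_hash": config.digest(), "stages_run": [], "files": {},
                "warnings": warnings}
    upstream_ran = False
    try:
        for stage in STAGES:
            if stage not in stages:
                continue
            outputs = [out / f for f in STAGE_OUTPUTS[stage]]
            if resume and not upstream_ran and all(p.exists() for p in outputs):
                continue
            _STAGE_FUNCS[stage](config, out, warnings)
            manifest["stages_run"].append(stage)
            upstream_ran = True
    finally:
        for stage in STAGES:
            for f in STAGE_OUTPUTS[stage]:
                p = out / f
                if p.exists():
                    manifest["files"][f] = fio.sha256_of(p)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))
    return manifest
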