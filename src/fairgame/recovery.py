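"""Ground-truth recovery studies on synthetic cohorts.

Two study designs back the package's validation claims:

* :func:`component_recovery` — per-participant condition averages are
  measured with the ERP chain and compared against the ledgered planted
  peaks, quantifying latency/amplitude bias of the whole measurement path.
* :func:`direction_study` — a full simulate -> cluster -> measure pass on
  one cohort, returning the signed group/condition contrasts that
  characterize the reference cohort (N1 latency GrpS vs GrpF, posterior LPC
  amplitude GrpS vs GrpF, MFN latency by response).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import calibration as cal
from .behavior import ClusterConfig, assess_stability, build_profiles, trial_set_label
from .erp import (COMPONENT_WINDOWS, EpochSpec, FilterSpec, bandpass,
                  baseline_correct, default_times_ms, detect_peak,
                  measure_components, reject_artifacts)
from .synthetic import (CohortSpec, NoiseModel, _condition_targets,
                        _epoch_batch, calibrate_condition, iter_participants,
                        planted_truth)

FC = ("Fz", "FCz")
PP = ("Pz", "CPz")
ALL_CH = FC + PP


def _participant_traits(rng, spec_like=None):
    lat_sd = getattr(spec_like, "erp_latency_participant_sd_ms", 3.0)
    amp_sd = getattr(spec_like, "erp_amplitude_participant_sd_uv", 0.3)
    lat = {c: rng.normal(0.0, lat_sd) for c in cal.COMPONENT_WIDTHS_MS}
    amp = {c: rng.normal(0.0, amp_sd) for c in cal.COMPONENT_WIDTHS_MS}
    return lat, amp


def _measure_average(avg, times, channels, participant, condition,
                     smoothing_ms=8.0):
    rows = []
    for comp, win in COMPONENT_WINDOWS.items():
        for el in win.electrodes:
            if el not in channels:
                continue
            m = detect_peak(avg[channels.index(el)], times, win,
                            smoothing_ms=smoothing_ms,
                            participant=participant, condition=condition,
                            electrode=el)
            rows.append(m.as_dict())
    return rows


def component_recovery(seed: int, n_participants: int = 39,
                       trials_per_set: int = 200,
                       noise: NoiseModel = NoiseModel(),
                       group_sizes: dict | None = None) -> pd.DataFrame:
    """Measure planted components back from per-set averages.

    Each participant contributes one average per (game, response) set built
    from ``trials_per_set`` single trials at default SNR; the ERP chain
    (band-pass, baseline, average, windowed peak pick) runs exactly as on
    pipeline data.  Returns one row per measured peak joined with its
    planted (ledger) latency/amplitude.
    """
    group_sizes = group_sizes or dict(cal.GROUP_SIZES)
    assert sum(group_sizes.values()) == n_participants
    times = default_times_ms()
    master = np.random.SeedSequence([seed, 20_05])
    rows = []
    pid = 0
    for group, n in group_sizes.items():
        for ss in master.spawn(n):
            pid += 1
            rng = np.random.default_rng(ss)
            lat_shift, amp_shift = _participant_traits(rng)
            for game in ("DG", "UG"):
                for resp in ("accepted", "refused"):
                    targets = _condition_targets(cal.erp_targets(group), game,
                                                 resp, lat_shift, amp_shift)
                    specs = calibrate_condition(targets)
                    truth = planted_truth(specs, ALL_CH, times)
                    epochs = _epoch_batch(specs, noise, ALL_CH,
                                          trials_per_set, rng, times, 1024.0)
                    epochs = bandpass(epochs, 1024.0, FilterSpec())
                    epochs = baseline_correct(epochs, times)
                    avg = epochs.mean(axis=0)
                    for m in _measure_average(avg, times, list(ALL_CH),
                                              f"P{pid:02d}",
                                              f"{game}|{resp}"):
                        comp, el = m["component"], m["electrode"]
                        t = truth[comp][el]
                        m.update(group=group, game=game, response=resp,
                                 planted_latency_ms=t["latency_ms"],
                                 planted_amplitude_uv=t["amplitude_uv"])
                        rows.append(m)
    return pd.DataFrame(rows)


def recovery_summary(measured: pd.DataFrame) -> pd.DataFrame:
    """Per-component bias of identified measurements vs the ledger.

    Latency bias is the mean signed error (ms).  Amplitude bias is the mean
    signed error normalized by the mean planted magnitude, so components
    whose planted amplitude changes sign across conditions (the MFN) get a
    well-posed relative bias.
    """
    ok = measured[measured["identified"]]
    out = []
    for comp, sub in ok.groupby("component"):
        lat_bias = (sub["latency_ms"] - sub["planted_latency_ms"]).mean()
        amp_err = (sub["amplitude_uv"] - sub["planted_amplitude_uv"]).mean()
        scale = sub["planted_amplitude_uv"].abs().mean()
        out.append({"component": comp,
                    "n_identified": len(sub),
                    "n_total": int((measured["component"] == comp).sum()),
                    "latency_bias_ms": float(lat_bias),
                    "amplitude_bias_rel": float(abs(amp_err) / scale)})
    return pd.DataFrame(out)


def cohort_measurements(spec: CohortSpec, replicates: int = 3,
                        filter_spec: FilterSpec = FilterSpec(),
                        epoch_spec: EpochSpec = EpochSpec(),
                        smoothing_ms: float = 8.0):
    """Run simulate -> ERP measurement in memory, participant by participant.

    Returns ``(behavior, measurements)``; measurements carry condition keys
    ``{game}|all`` and ``{game}|{family}|{response}``.
    """
    behav_frames, meas_frames = [], []
    times = default_times_ms(spec.sfreq)
    channels = list(spec.channels)
    for pid, group, behavior, epochs_by_game, _ in iter_participants(spec):
        behav_frames.append(behavior)
        for game, pack in epochs_by_game.items():
            data = pack["data"].astype(np.float64)
            data = bandpass(data, spec.sfreq, filter_spec)
            data = baseline_correct(data, times, epoch_spec.baseline_ms)
            data, kept, _ = reject_artifacts(
                data, epoch_spec.reject_threshold_uv, channels)
            sub = behavior[(behavior["game"] == game) & behavior["valid"]]
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
                conds, times, channels, replicates=replicates,
                seed=np.random.SeedSequence([spec.seed, int(pid.lstrip("P"))]),
                smoothing_ms=smoothing_ms, participant=pid)
            meas["group_truth"] = group
            meas["game"] = game
            meas_frames.append(meas)
    behavior = pd.concat(behav_frames, ignore_index=True)
    meas = pd.concat(meas_frames, ignore_index=True)
    return behavior, meas


def direction_study(seed: int, game: str = "UG",
                    group_sizes: dict | None = None) -> dict:
    """One full pipeline pass; returns the headline signed contrasts.

    Contrasts (identified measurements only):

    * ``n1_latency_S_minus_F`` — fronto-central N1 latency, GrpS - GrpF,
      all trials pooled (expected negative: shorter in selfish group).
    * ``lpc_amplitude_S_minus_F`` — posterior-parietal LPC amplitude,
      GrpS - GrpF (expected positive).
    * ``mfn_latency_rej_minus_acc`` — fronto-central MFN latency,
      refusals minus acceptances across trial sets (expected negative
      during UG).

    Groups come from the behavioral clustering, not the planted labels.
    """
    group_sizes = group_sizes or {"GrpS": 8, "GrpB": 10, "GrpF": 10}
    spec = CohortSpec(group_sizes=group_sizes, seed=seed, eeg_games=(game,))
    behavior, meas = cohort_measurements(spec)
    profiles = build_profiles(behavior)
    res = assess_stability(profiles, ClusterConfig(seed=seed))
    names = res.group_names
    meas = meas[meas["identified"]].copy()
    meas["group"] = meas["participant"].map(names)

    def pooled(component, field, electrodes):
        sub = meas[(meas["component"] == component)
                   & meas["electrode"].isin(electrodes)
                   & (meas["condition"] == f"{game}|all")]
        return sub.groupby("group")[field].mean()

    out = {}
    n1 = pooled("N1", "latency_ms", FC)
    lpc = pooled("LPC", "amplitude_uv", PP)
    out["n1_latency_S_minus_F"] = float(n1.get("GrpS", np.nan) - n1.get("GrpF", np.nan))
    out["lpc_amplitude_S_minus_F"] = float(lpc.get("GrpS", np.nan) - lpc.get("GrpF", np.nan))
    mfn = meas[(meas["component"] == "MFN") & meas["electrode"].isin(FC)
               & meas["condition"].str.contains(r"\|accepted|\|refused")]
    resp_means = mfn.groupby(mfn["condition"].str.rsplit("|", n=1).str[-1])[
        "latency_ms"].mean()
    out["mfn_latency_rej_minus_acc"] = float(
        resp_means.get("refused", np.nan) - resp_means.get("accepted", np.nan))

    # t test for the N1 group contrast at measurement level
    from .stats import test_means
    a = meas[(meas["component"] == "N1") & meas["electrode"].isin(FC)
             & (meas["condition"] == f"{game}|all") & (meas["group"] == "GrpF")]
    b = meas[(meas["component"] == "N1") & meas["electrode"].isin(FC)
             & (meas["condition"] == f"{game}|all") & (meas["group"] == "GrpS")]
    if len(a) >= 2 and len(b) >= 2:
        t = test_means(a["latency_ms"], b["latency_ms"])
        out["n1_latency_F_vs_S_t"] = t.t
        out["n1_latency_F_vs_S_p"] = t.p
    return out
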