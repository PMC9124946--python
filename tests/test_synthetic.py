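"""Generator tests: schedules, decisions, RTs, planted EEG components."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fairgame import calibration as cal
from fairgame import synthetic as syn
from fairgame.behavior import build_profiles
from fairgame.erp import default_times_ms


# ---------------------------------------------------------------------- schedules

@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2 ** 31 - 1), st.sampled_from(["DG", "UG"]))
def test_schedule_balanced_for_any_seed(seed, game):
    s = syn.make_schedule(game, seed)
    assert len(s) == 240
    counts = s["allocation_self_share"].value_counts()
    assert sorted(counts.index) == sorted(syn._shares(game))
    assert (counts == 48).all()


def test_schedule_deterministic_and_blocks_unbalanced():
    a = syn.make_schedule("DG", 7)
    b = syn.make_schedule("DG", 7)
    pd.testing.assert_frame_equal(a, b)
    # single blocks need not be balanced: over many seeds at least one block
    # deviates from 48/5 per allocation
    unbalanced = False
    for seed in range(10):
        s = syn.make_schedule("DG", seed)
        per_block = s.groupby("block")["allocation_self_share"].value_counts()
        if (per_block != 48 // 5).any():
            unbalanced = True
    assert unbalanced


def test_schedule_counts_match_independent_tally():
    # brute-force tally with a plain dict counter, 20 seeds
    for seed in range(20):
        s = syn.make_schedule("UG", seed)
        tally = {}
        for v in s["allocation_self_share"]:
            tally[v] = tally.get(v, 0) + 1
        assert all(tally[share] == 48 for share in syn.UG_SHARES)


# ---------------------------------------------------------------------- decisions

def test_all_accept_policy_accepts_everything():
    sched = syn.make_schedule("DG", 0)
    pol = syn.DecisionPolicy("DG", {s: 1.0 for s in syn.DG_SHARES},
                             omission_probability=0.0)
    out = syn.simulate_decisions(sched, pol, 1)
    assert (out["response"] == "accepted").all()
    assert out["valid"].all()


def test_missing_policy_entry_is_named():
    sched = syn.make_schedule("DG", 0)
    pol = syn.DecisionPolicy("DG", {90: 1.0})
    with pytest.raises(KeyError, match="self-share 50|self-share 60|self-share 70|self-share 80"):
        syn.simulate_decisions(sched, pol, 1)


def test_accept_rate_matches_policy_within_3se(rng):
    pol = syn.default_policy("GrpS", "DG")
    p = pol.accept[90]
    n = 10_000
    sched = pd.DataFrame({"game": "DG", "block": 1,
                          "trial": np.arange(n) + 1,
                          "allocation_self_share": 90})
    out = syn.simulate_decisions(sched, syn.DecisionPolicy("DG", {90: p}, 0.0), 42)
    rate = (out["response"] == "accepted").mean()
    se = np.sqrt(p * (1 - p) / n)
    assert abs(rate - p) < 3 * se


def test_simulated_index_matches_closed_form_expectation():
    """Mean simulated DG_selfishness over many participants stays within
    3 SE of the policy's closed-form expected index."""
    pol = syn.default_policy("GrpF", "DG")
    expected = syn.expected_index_from_policy(pol)
    spec = syn.CohortSpec(group_sizes={"GrpF": 40}, seed=5, eeg_games=(),
                          games=("DG",), q_jitter_sd=0.0)
    frames = [b for _, _, b, _, _ in syn.iter_participants(spec)]
    prof = build_profiles(pd.concat(frames))
    idx = prof["dg_selfishness"].to_numpy()
    se = idx.std(ddof=1) / np.sqrt(len(idx))
    assert abs(idx.mean() - expected) < 3 * max(se, 1e-3)


def test_grpf_planted_indices_strongly_negative():
    hits = 0
    for seed in range(5):
        spec = syn.CohortSpec(group_sizes={"GrpF": 10}, seed=seed,
                              eeg_games=(), games=("DG",))
        frames = [b for _, _, b, _, _ in syn.iter_participants(spec)]
        prof = build_profiles(pd.concat(frames))
        hits += int((prof["dg_selfishness"] < -0.5).sum() >= 9)
    assert hits >= 4


# ---------------------------------------------------------------------- reaction times

def test_rt_degenerate_sigma_equals_median(rng):
    model = syn.RtModel(medians_ms={("DG", "accepted"): 400.0}, log_sigma=0.0,
                        set_offsets_ms={})
    rt = model.draw("DG", "accepted", None, rng)
    assert rt == pytest.approx(400.0)


def test_rt_accepted_faster_than_refused_in_every_group(rng):
    for group in cal.GROUPS:
        model = syn.default_rt_model(group)
        for game in ("DG", "UG"):
            acc = model.draw(game, "accepted", None, rng, size=10_000)
            ref = model.draw(game, "refused", None, rng, size=10_000)
            assert np.median(acc) < np.median(ref)


def test_rt_positive_skew_and_bounds(rng):
    model = syn.default_rt_model("GrpB")
    x = model.draw("DG", "accepted", None, rng, size=10_000)
    assert x.max() <= 3000.0 and x.min() > 0
    from scipy.stats import skew
    assert skew(x) > 0


def test_omitted_trial_has_no_rt():
    with pytest.raises(ValueError):
        syn.simulate_rt("DG", "omitted", None, syn.default_rt_model("GrpB"), 0)


# ---------------------------------------------------------------------- epochs

def _n1_spec(a=4.0, jitter=0.0, cv=0.0, w=1.0):
    return syn.ErpComponentSpec("N1", "negative", 130.0, a, 16.0,
                                latency_jitter_sd_ms=jitter, amplitude_cv=cv,
                                weights={"FCz": w})


def test_single_noiseless_n1_has_minimum_at_planted_peak():
    times = default_times_ms()
    y = syn.simulate_epoch([_n1_spec()], syn.NoiseModel(0.0), "FCz", 0, times)
    i = int(np.argmin(y))
    assert abs(times[i] - 130.0) < 1.0
    assert y[i] == pytest.approx(-4.0, abs=1e-3)  # grid quantization


def test_zero_weights_give_flat_trace():
    times = default_times_ms()
    y = syn.simulate_epoch([_n1_spec(w=0.0)], syn.NoiseModel(0.0), "FCz", 0, times)
    assert np.allclose(y, 0.0)


def test_component_latency_outside_epoch_raises():
    spec = syn.ErpComponentSpec("N1", "negative", 900.0, 4.0, 16.0,
                                weights={"FCz": 1.0})
    with pytest.raises(ValueError, match="outside epoch"):
        syn.simulate_epoch([spec], syn.NoiseModel(0.0), "FCz", 0)


def test_noiseless_waveform_is_linear_in_amplitudes():
    times = default_times_ms()
    y1 = syn.simulate_epoch([_n1_spec(a=2.0)], syn.NoiseModel(0.0), "FCz", 3, times)
    y2 = syn.simulate_epoch([_n1_spec(a=4.0)], syn.NoiseModel(0.0), "FCz", 3, times)
    assert np.allclose(2.0 * y1, y2)


def test_average_rmse_shrinks_like_sqrt_n(rng):
    """Monte-Carlo noise scaling: RMSE of the n-trial average against the
    expected template halves when n quadruples."""
    times = default_times_ms()
    specs = [_n1_spec(jitter=10.0, cv=0.3)]
    template = syn.expected_average(specs, "FCz", times)
    noise = syn.NoiseModel(rms_uv=10.0)

    def rmse(n):
        ep = syn._epoch_batch(specs, noise, ["FCz"], n, rng, times, 1024.0)
        return np.sqrt(((ep.mean(axis=0)[0] - template) ** 2).mean())

    r50 = np.mean([rmse(50) for _ in range(6)])
    r200 = np.mean([rmse(200) for _ in range(6)])
    assert r50 / r200 == pytest.approx(2.0, rel=0.3)


def test_pink_noise_spectral_slope(rng):
    noise = syn.NoiseModel(rms_uv=10.0, exponent=1.0)
    x = syn.pink_noise(rng, (100, 1024), noise, 1024.0)
    freqs = np.fft.rfftfreq(1024, 1 / 1024.0)
    psd = (np.abs(np.fft.rfft(x, axis=-1)) ** 2).mean(axis=0)
    band = (freqs >= 2) & (freqs <= 100)
    slope = np.polyfit(np.log(freqs[band]), np.log(psd[band]), 1)[0]
    assert slope == pytest.approx(-1.0, abs=0.2)


def test_calibrated_templates_hit_group_targets():
    times = default_times_ms()
    for group in ("GrpS", "GrpB", "GrpF"):
        for game in ("DG", "UG"):
            targets = {c: cal.erp_targets(group)[game][c]
                       for c in ("N1", "P2", "MFN", "LPC")}
            specs = syn.calibrate_condition(targets)
            truth = syn.planted_truth(specs, ("FCz", "Pz"), times)
            for comp, (lat, amp) in targets.items():
                got = truth[comp][cal.REFERENCE_ELECTRODE[comp]]
                assert got["latency_ms"] == pytest.approx(lat, abs=1.0)
                assert got["amplitude_uv"] == pytest.approx(amp, abs=0.05)


# ---------------------------------------------------------------------- cohort

def test_cohort_shapes_and_determinism():
    spec = syn.CohortSpec(group_sizes={"GrpS": 2, "GrpB": 3, "GrpF": 3},
                          seed=9, n_blocks=2, block_size=40,
                          eeg_games=("UG",))
    c1 = syn.simulate_cohort(spec)
    c2 = syn.simulate_cohort(spec)
    assert c1.behavior["participant"].nunique() == 8
    per = c1.behavior.groupby("participant").size()
    assert (per <= 480).all()
    pd.testing.assert_frame_equal(c1.behavior, c2.behavior)
    for key in c1.epochs:
        assert np.array_equal(c1.epochs[key]["data"], c2.epochs[key]["data"])
    assert c1.ledger == c2.ledger


def test_cohort_ledger_records_planted_parameters(tiny_cohort_spec):
    cohort = syn.simulate_cohort(tiny_cohort_spec)
    entry = cohort.ledger["participants"]["P01"]
    assert entry["group"] == "GrpS"
    assert set(entry["erp"]) == {"DG", "UG"}
    truth = entry["erp"]["DG"]["accepted"]
    assert set(truth) == {"N1", "P2", "MFN", "LPC"}
    assert set(truth["N1"]) >= {"Fz", "FCz"}
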