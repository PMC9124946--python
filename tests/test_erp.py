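"""Filtering, epoching, artifact rejection and peak detection."""

import numpy as np
import pytest

from fairgame import erp
from fairgame import synthetic as syn

SF = 1024.0


# ---------------------------------------------------------------- filtering

def test_midband_sinusoid_amplitude_preserved():
    # long record with generous interior: the 0.1 Hz pole settles slowly
    t = np.arange(0, 30, 1 / SF)
    x = np.sin(2 * np.pi * 10 * t)
    y = erp.bandpass(x, SF)
    core = slice(10 * 1024, 20 * 1024)
    assert np.abs(y[core]).max() == pytest.approx(1.0, rel=0.01)


def test_stopband_attenuation_at_one_octave():
    t = np.arange(0, 30, 1 / SF)
    x = np.sin(2 * np.pi * 64 * t)
    y = erp.bandpass(x, SF)
    atten_db = 20 * np.log10(np.abs(y[10 * 1024:20 * 1024]).max())
    assert atten_db <= -24.0  # >= 12 dB per pass, doubled forward-backward


def test_zero_phase_impulse_response_is_symmetric():
    # odd length so sample reversal preserves the center; the production
    # 0.1 Hz corner limits float accuracy to ~1e-5, a 4 Hz corner is exact
    n = 16 * 1024 + 1
    x = np.zeros(n)
    x[n // 2] = 1.0
    y = erp.bandpass(x, SF)
    assert np.abs(y - y[::-1]).max() < 1e-5
    y4 = erp.bandpass(x, SF, erp.FilterSpec(low_hz=4.0))
    assert np.abs(y4 - y4[::-1]).max() < 1e-9


def test_zero_phase_time_reversal_symmetry():
    # tapered edges keep the slow-pole edge transients out of the comparison
    from scipy.signal.windows import tukey
    rng = np.random.default_rng(0)
    n = 16 * 1024 + 1
    x = rng.normal(size=n) * tukey(n, 0.2)
    spec = erp.FilterSpec(low_hz=4.0)
    y1 = erp.bandpass(x, SF, spec)
    y2 = erp.bandpass(x[::-1], SF, spec)[::-1]
    assert np.allclose(y1, y2, atol=1e-9)


def test_inband_pulse_latency_unshifted():
    t = np.arange(0, 2, 1 / SF)
    x = np.exp(-0.5 * ((t - 1.0) / 0.02) ** 2)
    y = erp.bandpass(x, SF)
    assert abs(int(np.argmax(y)) - int(np.argmax(x))) <= 1


def test_cutoff_above_nyquist_raises():
    with pytest.raises(ValueError, match="Nyquist"):
        erp.bandpass(np.zeros(1024), 60.0, erp.FilterSpec(high_hz=32.0))
    with pytest.raises(ValueError):
        erp.bandpass(np.zeros(1024), 200.0)


# ---------------------------------------------------------------- epoching

def test_constant_trace_epochs_to_zero():
    cont = np.full((1, 10240), 5.0)
    events = np.array([2048, 4096, 6144])
    epochs, times, dropped = erp.epoch_and_baseline(cont, SF,
                                                    event_samples=events)
    assert epochs.shape[0] == 3 and not dropped
    assert np.allclose(epochs, 0.0)


def test_edge_events_dropped_with_log():
    cont = np.zeros((1, 3000))
    events = np.array([50, 1500, 2950])
    eps, kept, dropped = erp.extract_epochs(cont, events, SF)
    assert kept == [1500]
    assert dropped == [50, 2950]


def test_baseline_mean_zero_and_idempotent(rng):
    times = erp.default_times_ms()
    epochs = rng.normal(size=(7, 2, times.size))
    out = erp.baseline_correct(epochs, times)
    base = out[..., times < 0]
    assert np.abs(base.mean(axis=-1)).max() < 1e-9
    again = erp.baseline_correct(out, times)
    assert np.allclose(out, again, atol=1e-12)


# ---------------------------------------------------------------- rejection

def test_clean_epochs_not_rejected(rng):
    epochs = rng.normal(scale=10.0, size=(20, 2, 512)).clip(-99, 99)
    clean, kept, log = erp.reject_artifacts(epochs, 100.0)
    assert clean.shape[0] == 20 and not log


def test_planted_blinks_rejected_exactly(tiny_cohort_spec):
    import dataclasses
    spec = dataclasses.replace(tiny_cohort_spec, blink_rate=0.1, seed=77,
                               eeg_games=("UG",))
    cohort = syn.simulate_cohort(spec)
    for (pid, game), pack in cohort.epochs.items():
        planted = set(cohort.ledger["participants"][pid]["blink_trials"][game])
        data = erp.baseline_correct(pack["data"].astype(float), cohort.times_ms)
        _, kept, log = erp.reject_artifacts(data, 100.0, list(spec.channels))
        rejected = {int(pack["trials"][i]) for i in
                    set(range(data.shape[0])) - set(kept)}
        # every planted blink is rejected; spurious rejections are rare but
        # possible when 1/f noise alone crosses the threshold
        assert planted <= rejected
        assert len(rejected - planted) <= 2


def test_rejection_count_matches_bruteforce_scan(rng):
    epochs = rng.normal(scale=45.0, size=(50, 3, 256))
    clean, kept, log = erp.reject_artifacts(epochs, 100.0)
    expected = sum(1 for tr in epochs if np.abs(tr).max() > 100.0)
    assert len(log) == expected
    assert clean.shape[0] == 50 - expected


# ---------------------------------------------------------------- averaging

def test_average_identical_and_opposite_epochs(rng):
    e = rng.normal(size=(1, 2, 128))
    two = np.concatenate([e, e])
    avg, n, usable = erp.average_condition(two, n_min=2)
    assert np.allclose(avg, e[0]) and n == 2 and usable
    opp = np.concatenate([e, -e])
    avg, _, _ = erp.average_condition(opp, n_min=2)
    assert np.allclose(avg, 0.0)
    none, n, usable = erp.average_condition(np.empty((0, 2, 128)))
    assert none is None and n == 0 and not usable


# ---------------------------------------------------------------- peak detection

def _gauss(times, mu, sigma, amp):
    return amp * np.exp(-0.5 * ((times - mu) / sigma) ** 2)


def test_noiseless_gaussian_negativity_detected_exactly():
    times = erp.default_times_ms()
    y = _gauss(times, 130.0, 12.0, -4.0)
    m = erp.detect_peak(y, times, erp.COMPONENT_WINDOWS["N1"], smoothing_ms=0)
    assert m.identified
    assert m.latency_ms == pytest.approx(130.0, abs=1.0)
    assert m.amplitude_uv == pytest.approx(-4.0, abs=1e-3)  # grid quantization


def test_monotonic_segment_is_not_identified():
    times = erp.default_times_ms()
    y = times * 0.01  # strictly increasing
    m = erp.detect_peak(y, times, erp.COMPONENT_WINDOWS["N1"], smoothing_ms=0)
    assert not m.identified
    assert m.latency_ms is None and m.amplitude_uv is None


def test_lpc_tie_breaks_to_later_peak_and_early_components_to_earlier():
    times = erp.default_times_ms()
    # centers on the sampling grid so both peak samples are exactly equal
    t1 = times[np.argmin(np.abs(times - 470.0))]
    t2 = times[np.argmin(np.abs(times - 560.0))]
    y = _gauss(times, t1, 20.0, 3.0) + _gauss(times, t2, 20.0, 3.0)
    m = erp.detect_peak(y, times, erp.COMPONENT_WINDOWS["LPC"], smoothing_ms=0)
    assert m.latency_ms == pytest.approx(t2, abs=0.5)
    t3 = times[np.argmin(np.abs(times - 290.0))]
    t4 = times[np.argmin(np.abs(times - 370.0))]
    y2 = -(_gauss(times, t3, 15.0, 2.0) + _gauss(times, t4, 15.0, 2.0))
    m2 = erp.detect_peak(y2, times, erp.COMPONENT_WINDOWS["MFN"], smoothing_ms=0)
    assert m2.latency_ms == pytest.approx(t3, abs=0.5)


def test_window_outside_waveform_raises():
    times = erp.default_times_ms()[:200]
    with pytest.raises(ValueError, match="window"):
        erp.detect_peak(np.zeros(200), times, erp.COMPONENT_WINDOWS["LPC"])


def test_prominence_gate_uses_baseline_sd(rng):
    times = erp.default_times_ms()
    noise = rng.normal(scale=2.0, size=times.size)
    y = noise + _gauss(times, 130.0, 12.0, -0.1)  # peak buried in noise
    m = erp.detect_peak(y, times, erp.COMPONENT_WINDOWS["N1"],
                        smoothing_ms=0, prominence_factor=50.0)
    assert not m.identified


# ---------------------------------------------------------------- measurement table

def test_capacity_formula():
    assert erp.measurement_capacity(28, 4, 2, 3) == 672


def test_r1_no_bootstrap_equals_plain_average_measurement(rng):
    times = erp.default_times_ms()
    epochs = np.stack([
        np.stack([_gauss(times, 130.0, 12.0, -4.0) + rng.normal(scale=0.2, size=times.size),
                  np.zeros(times.size)])
        for _ in range(20)])
    table = erp.measure_components({"c": epochs}, times, ["FCz", "Pz"],
                                   replicates=1, bootstrap=False, seed=0)
    n1 = table[(table.component == "N1") & (table.electrode == "FCz")].iloc[0]
    direct = erp.detect_peak(epochs.mean(axis=0)[0], times,
                             erp.COMPONENT_WINDOWS["N1"])
    assert n1["latency_ms"] == direct.latency_ms
    assert n1["amplitude_uv"] == direct.amplitude_uv


def test_replicate_rows_and_seeded_determinism(rng):
    times = erp.default_times_ms()
    epochs = rng.normal(size=(30, 2, times.size))
    t1 = erp.measure_components({"a": epochs}, times, ["FCz", "Pz"],
                                replicates=3, seed=5)
    t2 = erp.measure_components({"a": epochs}, times, ["FCz", "Pz"],
                                replicates=3, seed=5)
    # 4 components, each measured at the one available site-group electrode
    assert len(t1) == 3 * 4
    assert t1.equals(t2)
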