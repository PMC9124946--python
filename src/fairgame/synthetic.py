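"""Synthetic dictator/ultimatum-game cohorts with stimulus-locked EEG.

Every downstream stage of the pipeline (behavioral phenotyping, ERP peak
extraction, statistics) is validated against data from this generator, which
plants known decision policies, reaction-time distributions and ERP
components and records them in a ground-truth ledger.

The behavioral model is deliberately transparent: each group carries an
explicit accept-probability table per allocation, calibrated so that the
expected behavioral indices reproduce the reference cohort's group medians.
Reaction times are shifted log-normals per (group, game, response) cell.

The EEG model is a sum of Gaussian component bumps (N1, P2, MFN, LPC, plus a
broad late P3 pedestal that is not itself measured) with per-trial latency
jitter and amplitude variability, fixed channel topography weights, and 1/f
background noise.  Component coefficients are calibrated numerically so the
*expected average* waveform hits prescribed windowed peak targets; those
composite-template extrema are what the ledger records as planted truth,
because overlapping components make raw bump coefficients unmeasurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import calibration as cal
from .behavior import trial_set_label
from .erp import COMPONENT_WINDOWS, default_times_ms

__all__ = [
    "DG_SHARES", "UG_SHARES", "RESPONSES",
    "DecisionPolicy", "RtModel", "ErpComponentSpec", "NoiseModel",
    "CohortSpec", "Cohort",
    "make_schedule", "simulate_decisions", "simulate_rt", "simulate_epoch",
    "simulate_cohort", "iter_participants",
    "default_policy", "default_rt_model", "expected_set_counts",
    "expected_index_from_policy", "calibrate_condition",
    "expected_average", "pink_noise", "planted_truth",
]

#: Admissible allocator self-shares (DG) and responder self-shares (UG).
DG_SHARES = (50, 60, 70, 80, 90)
UG_SHARES = (10, 20, 30, 40, 50)
RESPONSES = ("accepted", "refused", "omitted")

SFREQ = 1024.0


def _shares(game: str):
    if game == "DG":
        return DG_SHARES
    if game == "UG":
        return UG_SHARES
    raise ValueError(f"game must be 'DG' or 'UG', got {game!r}")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecisionPolicy:
    """Accept probability per allocation plus a per-trial omission rate."""

    game: str
    accept: dict[int, float]
    omission_probability: float = cal.OMISSION_PROBABILITY

    def __post_init__(self):
        for s, p in self.accept.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"accept probability for share {s} not in [0,1]")
        if not 0.0 <= self.omission_probability <= 1.0:
            raise ValueError("omission probability not in [0,1]")

    def require(self, share: int) -> float:
        if share not in self.accept:
            raise KeyError(
                f"decision policy for game {self.game} has no entry for "
                f"allocation self-share {share}")
        return self.accept[share]


@dataclass(frozen=True)
class RtModel:
    """Shifted log-normal reaction times.

    ``medians_ms`` maps (game, response) to the median RT of that cell;
    ``set_offsets_ms`` adds a trial-set-dependent shift (slower deliberation
    on counter-normative trials).  ``log_sigma = 0`` degenerates to the exact
    median.  Draws are redrawn (then clamped) to stay within (0, deadline].
    """

    medians_ms: dict[tuple[str, str], float]
    set_offsets_ms: dict[str, float] = field(
        default_factory=lambda: dict(cal.RT_SET_OFFSETS_MS))
    log_sigma: float = cal.RT_LOG_SIGMA
    shift_ms: float = cal.RT_SHIFT_MS
    deadline_ms: float = 3000.0

    def draw(self, game: str, response: str, set_label: str | None,
             rng: np.random.Generator, size: int | None = None) -> np.ndarray:
        med = self.medians_ms[(game, response)]
        if set_label is not None:
            med = med + self.set_offsets_ms.get(set_label, 0.0)
        scale = max(med - self.shift_ms, 1.0)
        n = 1 if size is None else size
        draws = self.shift_ms + scale * np.exp(
            rng.normal(0.0, self.log_sigma, size=n))
        for _ in range(100):
            bad = draws > self.deadline_ms
            if not bad.any():
                break
            draws[bad] = self.shift_ms + scale * np.exp(
                rng.normal(0.0, self.log_sigma, size=int(bad.sum())))
        draws = np.clip(draws, 1e-6, self.deadline_ms)
        return float(draws[0]) if size is None else draws


@dataclass(frozen=True)
class ErpComponentSpec:
    """One planted component with trial-level variability.

    Measured components (N1/P2/MFN/LPC) are unit-peak Gaussian bumps;
    ``shape="plateau"`` gives a smooth sigmoidal plateau (used for the broad
    late positivity that is planted as background but never measured).

    ``amplitude_uv`` is the single-trial peak magnitude in the direction of
    ``polarity`` (the waveform contribution is ``sign(polarity) * amplitude``
    at the bump center); a negative amplitude flips the bump against its
    nominal polarity, which happens when a nominally negative component rides
    on a large positive pedestal.
    """

    name: str
    polarity: str
    mean_latency_ms: float
    amplitude_uv: float
    width_ms: float
    latency_jitter_sd_ms: float = cal.LATENCY_JITTER_SD_MS
    amplitude_cv: float = cal.AMPLITUDE_CV
    weights: dict[str, float] = field(default_factory=dict)
    shape: str = "gaussian"
    onset_ms: float = 0.0      # plateau only: sigmoid rise center / scale
    offset_ms: float = 0.0
    rise_ms: float = 15.0
    fall_ms: float = 50.0

    @property
    def sign(self) -> float:
        return -1.0 if self.polarity == "negative" else 1.0

    @property
    def smeared_width_ms(self) -> float:
        return float(np.hypot(self.width_ms, self.latency_jitter_sd_ms))

    def weight(self, channel: str) -> float:
        return self.weights.get(channel, 0.0)

    def shape_fn(self, times_ms: np.ndarray, center_shift: float = 0.0,
                 smeared: bool = False) -> np.ndarray:
        """Unit-peak shape evaluated on ``times_ms``.

        ``smeared=True`` returns the (approximate) expectation over latency
        jitter: Gaussians widen exactly; sigmoid edges widen by variance
        matching of the logistic scale.
        """
        t = times_ms - center_shift
        if self.shape == "gaussian":
            s = self.smeared_width_ms if smeared else self.width_ms
            peak = (self.width_ms / s) if smeared else 1.0
            return peak * np.exp(-0.5 * ((t - self.mean_latency_ms) / s) ** 2)
        j2 = 3.0 * self.latency_jitter_sd_ms ** 2 / np.pi ** 2
        rise = np.sqrt(self.rise_ms ** 2 + j2) if smeared else self.rise_ms
        fall = np.sqrt(self.fall_ms ** 2 + j2) if smeared else self.fall_ms
        from scipy.special import expit
        return expit((t - self.onset_ms) / rise) * expit((self.offset_ms - t) / fall)


@dataclass(frozen=True)
class NoiseModel:
    """1/f^exponent background noise, scaled to a target RMS per channel."""

    rms_uv: float = cal.NOISE_RMS_UV
    exponent: float = cal.NOISE_EXPONENT


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate one cohort deterministically."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"GrpS": 8, "GrpB": 10, "GrpF": 10})
    seed: int = 0
    sfreq: float = SFREQ
    channels: tuple[str, ...] = ("Fz", "FCz", "Pz", "CPz")
    noise: NoiseModel = field(default_factory=NoiseModel)
    games: tuple[str, ...] = ("DG", "UG")
    eeg_games: tuple[str, ...] = ("DG", "UG")
    n_blocks: int = 5
    block_size: int = 48
    q_jitter_sd: float = 0.04
    rt_participant_sd_ms: float = 15.0
    erp_latency_participant_sd_ms: float = 3.0
    erp_amplitude_participant_sd_uv: float = 0.3
    blink_rate: float = 0.0
    blink_amplitude_uv: float = 150.0

    def __post_init__(self):
        for g, n in self.group_sizes.items():
            if g not in cal.GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 1:
                raise ValueError("group sizes must be >= 1")


@dataclass
class Cohort:
    spec: CohortSpec
    behavior: pd.DataFrame
    epochs: dict          # (participant, game) -> {"data", "trials"}
    times_ms: np.ndarray
    channels: tuple[str, ...]
    ledger: dict


# ---------------------------------------------------------------------------
# behavioral generation
# ---------------------------------------------------------------------------

def make_schedule(game: str, seed, n_blocks: int = 5,
                  block_size: int = 48) -> pd.DataFrame:
    """Seeded trial schedule: every allocation equally often over the session.

    Individual blocks are *not* balanced; the full session is a seeded
    permutation of the balanced multiset.
    """
    shares = _shares(game)
    n_trials = n_blocks * block_size
    if n_trials % len(shares):
        raise ValueError("trial count must be a multiple of the allocation count")
    rng = np.random.default_rng(seed)
    alloc = np.repeat(shares, n_trials // len(shares))
    alloc = rng.permutation(alloc)
    return pd.DataFrame({
        "game": game,
        "block": np.arange(n_trials) // block_size + 1,
        "trial": np.arange(n_trials) + 1,
        "allocation_self_share": alloc,
    })


def default_policy(group: str, game: str) -> DecisionPolicy:
    accept = (cal.dg_accept_probabilities(group) if game == "DG"
              else cal.ug_accept_probabilities(group))
    return DecisionPolicy(game=game, accept=accept)


def default_rt_model(group: str) -> RtModel:
    medians = {(g, r): cal.RT_MEDIANS_MS[(group, g, r)]
               for g in ("DG", "UG") for r in ("accepted", "refused")}
    return RtModel(medians_ms=medians)


def simulate_decisions(schedule: pd.DataFrame, policy: DecisionPolicy,
                       seed) -> pd.DataFrame:
    """Draw accept/refuse/omit for every scheduled trial."""
    rng = np.random.default_rng(seed)
    shares = schedule["allocation_self_share"].to_numpy()
    p_accept = np.array([policy.require(int(s)) for s in shares])
    omitted = rng.random(len(shares)) < policy.omission_probability
    accepted = rng.random(len(shares)) < p_accept
    response = np.where(omitted, "omitted",
                        np.where(accepted, "accepted", "refused"))
    out = schedule.copy()
    out["response"] = response
    out["valid"] = ~omitted
    return out


def simulate_rt(game: str, response: str, set_label: str | None,
                rt_model: RtModel, seed) -> float:
    """Single-trial RT; the trial must not be omitted."""
    if response == "omitted":
        raise ValueError("omitted trials have no reaction time")
    return rt_model.draw(game, response, set_label, np.random.default_rng(seed))


def expected_set_counts(policy: DecisionPolicy, n_trials: int = 240) -> dict:
    """Closed-form expected trial-set counts under a policy (valid trials)."""
    shares = _shares(policy.game)
    per = n_trials / len(shares) * (1.0 - policy.omission_probability)
    counts: dict[str, float] = {}
    for s in shares:
        p = policy.require(s)
        for resp, prob in (("accepted", p), ("refused", 1.0 - p)):
            lbl = trial_set_label(policy.game, s, resp)
            counts[lbl] = counts.get(lbl, 0.0) + per * prob
    return counts


def expected_index_from_policy(policy: DecisionPolicy) -> float:
    """Expected behavioral index implied by a policy (ratio of expectations)."""
    c = expected_set_counts(policy)
    if policy.game == "DG":
        pro, anti = c.get("DG_selfish", 0.0), c.get("DG_fair", 0.0)
    else:
        pro, anti = c.get("UG_altruistic", 0.0), c.get("UG_conceit", 0.0)
    return (pro - anti) / (pro + anti)


# ---------------------------------------------------------------------------
# EEG generation
# ---------------------------------------------------------------------------

#: Broad late positive pedestal (putative P3 / slow positivity).  Constant
#: across groups and conditions and excluded from quantitative measurement;
#: it supplies the flat positive background on which the MFN dip rides, so
#: shallow (even net-positive) MFN minima remain strict local extrema.
P3_PEDESTAL = ErpComponentSpec(
    name="P3", polarity="positive", mean_latency_ms=420.0, amplitude_uv=4.0,
    width_ms=200.0, shape="plateau", onset_ms=220.0, offset_ms=620.0,
    rise_ms=15.0, fall_ms=50.0,
    weights={"Fz": 0.95, "FCz": 1.0, "Pz": 0.15, "CPz": 0.17})


def pink_noise(rng: np.random.Generator, shape: tuple[int, ...],
               noise: NoiseModel, sfreq: float = SFREQ) -> np.ndarray:
    """1/f^exponent noise along the last axis, RMS-normalized per trace."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-noise.exponent / 2.0)
    spec_shape = shape[:-1] + (freqs.size,)
    phase = rng.normal(size=spec_shape) + 1j * rng.normal(size=spec_shape)
    x = np.fft.irfft(phase * amp, n=n, axis=-1)
    rms = np.sqrt((x ** 2).mean(axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return x / rms * noise.rms_uv


def expected_average(specs, channel: str, times_ms: np.ndarray) -> np.ndarray:
    """Analytic expected average waveform (jitter-smeared, noise-free)."""
    out = np.zeros_like(times_ms, dtype=float)
    for c in specs:
        w = c.weight(channel)
        if w == 0.0:
            continue
        out += w * c.sign * c.amplitude_uv * c.shape_fn(times_ms, smeared=True)
    return out


def simulate_epoch(component_specs, noise_model: NoiseModel, channel: str,
                   seed, times_ms: np.ndarray | None = None,
                   sfreq: float = SFREQ) -> np.ndarray:
    """One single-trial waveform on ``channel`` (uV)."""
    if times_ms is None:
        times_ms = default_times_ms(sfreq)
    for c in component_specs:
        if not times_ms[0] < c.mean_latency_ms < times_ms[-1]:
            raise ValueError(
                f"component {c.name} latency {c.mean_latency_ms} ms outside epoch")
    rng = np.random.default_rng(seed)
    y = np.zeros_like(times_ms, dtype=float)
    for c in component_specs:
        jitter = rng.normal(0.0, c.latency_jitter_sd_ms) if c.latency_jitter_sd_ms else 0.0
        a = c.amplitude_uv * _amp_factor(rng, c.amplitude_cv)
        y += c.sign * a * c.weight(channel) * c.shape_fn(times_ms, center_shift=jitter)
    if noise_model.rms_uv > 0:
        y = y + pink_noise(rng, times_ms.shape, noise_model, sfreq)
    return y


def _amp_factor(rng, cv: float, size=None):
    """Unit-mean log-normal multiplicative amplitude variability."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    s = np.sqrt(np.log1p(cv ** 2))
    return np.exp(rng.normal(-s ** 2 / 2.0, s, size=size))


def _epoch_batch(specs, noise_model, channels, n_trials, rng, times_ms, sfreq):
    """(n_trials, n_channels, n_samples) single-trial epochs, vectorized."""
    t = times_ms[None, :]
    parts = np.zeros((n_trials, len(specs), times_ms.size))
    for k, c in enumerate(specs):
        jit = rng.normal(0.0, c.latency_jitter_sd_ms, size=(n_trials, 1))
        amp = _amp_factor(rng, c.amplitude_cv, size=(n_trials, 1))
        if c.shape == "gaussian":
            shapes = np.exp(-0.5 * ((t - c.mean_latency_ms - jit) / c.width_ms) ** 2)
        else:
            from scipy.special import expit
            shapes = (expit((t - jit - c.onset_ms) / c.rise_ms)
                      * expit((c.offset_ms - t + jit) / c.fall_ms))
        parts[:, k, :] = c.sign * c.amplitude_uv * amp * shapes
    w = np.array([[c.weight(ch) for ch in channels] for c in specs])
    epochs = np.einsum("nkt,kc->nct", parts, w)
    if noise_model.rms_uv > 0:
        epochs += pink_noise(rng, epochs.shape, noise_model, sfreq)
    return epochs


# -- calibration of component coefficients to peak targets -------------------

def calibrate_condition(targets: dict[str, tuple[float, float]],
                        jitter_sd_ms: float = cal.LATENCY_JITTER_SD_MS,
                        amplitude_cv: float = cal.AMPLITUDE_CV,
                        pedestal: ErpComponentSpec | None = P3_PEDESTAL,
                        max_iter: int = 80, damp: float = 0.7,
                        ) -> list[ErpComponentSpec]:
    """Solve for component specs whose expected average hits ``targets``.

    ``targets`` maps component name -> (latency_ms, amplitude_uv) of the
    windowed extremum at the component's reference electrode.  Overlapping
    bumps are handled by damped fixed-point iteration: each step re-sets a
    component's coefficient from the residual between the composite extremum
    and its target, and nudges its center latency likewise.
    """
    times = default_times_ms()
    grid = times[times >= 0.0]
    comps: dict[str, dict] = {}
    for name, (lat, amp) in targets.items():
        win = COMPONENT_WINDOWS[name]
        comps[name] = {"mu": float(lat), "coef": 0.0, "win": win,
                       "sigma_avg": float(np.hypot(cal.COMPONENT_WIDTHS_MS[name],
                                                   jitter_sd_ms)),
                       "ref": cal.REFERENCE_ELECTRODE[name],
                       "target": (float(lat), float(amp))}

    def bump(mu, sigma, coef):
        return coef * np.exp(-0.5 * ((grid - mu) / sigma) ** 2)

    def composite(channel, skip=None):
        out = np.zeros_like(grid)
        if pedestal is not None:
            out += expected_average([pedestal], channel, grid)
        for nm, c in comps.items():
            if nm == skip:
                continue
            out += cal.TOPOGRAPHY[nm][channel] * bump(c["mu"], c["sigma_avg"], c["coef"])
        return out

    # initialize coefficients against the pedestal background
    for nm, c in comps.items():
        i0 = int(np.argmin(np.abs(grid - c["mu"])))
        c["coef"] = c["target"][1] - composite(c["ref"], skip=nm)[i0]

    for _ in range(max_iter):
        err = 0.0
        for nm, c in comps.items():
            win, (t_lat, t_amp) = c["win"], c["target"]
            ref, w = c["ref"], cal.TOPOGRAPHY[nm][c["ref"]]
            full = composite(ref)
            m = (grid >= win.tmin_ms) & (grid <= win.tmax_ms)
            seg = full[m]
            i_ext = int(np.argmin(seg) if win.polarity == "negative" else np.argmax(seg))
            lat_now = float(grid[m][i_ext])
            amp_now = float(seg[i_ext])
            c["coef"] += damp * (t_amp - amp_now) / w
            c["mu"] += damp * (t_lat - lat_now)
            c["mu"] = float(np.clip(c["mu"], win.tmin_ms + 1.0, win.tmax_ms - 1.0))
            err = max(err, abs(t_amp - amp_now), abs(t_lat - lat_now) / 10.0)
        if err < 1e-4:
            break

    specs = []
    for nm, c in comps.items():
        win = c["win"]
        sigma_single = cal.COMPONENT_WIDTHS_MS[nm]
        coef_single = c["coef"] * (c["sigma_avg"] / sigma_single)
        sign = -1.0 if win.polarity == "negative" else 1.0
        specs.append(ErpComponentSpec(
            name=nm, polarity=win.polarity, mean_latency_ms=c["mu"],
            amplitude_uv=sign * coef_single, width_ms=sigma_single,
            latency_jitter_sd_ms=jitter_sd_ms, amplitude_cv=amplitude_cv,
            weights=dict(cal.TOPOGRAPHY[nm])))
    if pedestal is not None:
        specs.append(pedestal)
    return specs


def planted_truth(specs, channels, times_ms: np.ndarray | None = None) -> dict:
    """Windowed extrema of the expected average composite, per channel.

    This is the measurable ground truth the recovery suite compares against.
    """
    if times_ms is None:
        times_ms = default_times_ms()
    truth: dict[str, dict] = {}
    for name, win in COMPONENT_WINDOWS.items():
        if not any(c.name == name for c in specs):
            continue
        truth[name] = {}
        m = (times_ms >= win.tmin_ms) & (times_ms <= win.tmax_ms)
        for ch in channels:
            comp = expected_average(specs, ch, times_ms)[m]
            i = int(np.argmin(comp) if win.polarity == "negative" else np.argmax(comp))
            truth[name][ch] = {"latency_ms": float(times_ms[m][i]),
                               "amplitude_uv": float(comp[i])}
    return truth


def _condition_targets(group_targets: dict, game: str, response: str,
                       lat_shift: dict, amp_shift: dict) -> dict:
    """Per-(game, response) targets = group/game base + response offsets
    + participant-level trait shifts."""
    out = {}
    for comp, (lat, amp) in group_targets[game].items():
        off_l = cal.RESPONSE_OFFSETS.get((game, comp, "latency"), {}).get(response, 0.0)
        off_a = cal.RESPONSE_OFFSETS.get((game, comp, "amplitude"), {}).get(response, 0.0)
        out[comp] = (lat + off_l + lat_shift.get(comp, 0.0),
                     amp + off_a + amp_shift.get(comp, 0.0))
    return out


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _participant_ids(group_sizes: dict[str, int]):
    pid = 0
    for group, n in group_sizes.items():
        for _ in range(n):
            pid += 1
            yield f"P{pid:02d}", group


def iter_participants(spec: CohortSpec):
    """Yield per-participant products without holding the cohort in memory.

    Yields ``(pid, group, behavior_df, epochs_by_game, truth_entry)`` where
    ``epochs_by_game`` maps game -> {"data": float32 (n_valid, n_ch, n_samp),
    "trials": trial indices} for games with EEG enabled.
    """
    times = default_times_ms(spec.sfreq)
    master = np.random.SeedSequence(spec.seed)
    children = master.spawn(sum(spec.group_sizes.values()))
    for (pid, group), ss in zip(_participant_ids(spec.group_sizes), children):
        rng = np.random.default_rng(ss)

        # --- participant-level traits ---------------------------------
        delta_q = rng.normal(0.0, spec.q_jitter_sd)
        policies = {}
        for game in spec.games:
            base = default_policy(group, game)
            accept = {s: float(np.clip(p + delta_q if p not in (0.0, 1.0) else p,
                                       0.005, 0.995))
                      for s, p in base.accept.items()}
            policies[game] = replace(base, accept=accept)
        rt_shift = rng.normal(0.0, spec.rt_participant_sd_ms)
        base_rt = default_rt_model(group)
        rt_model = replace(base_rt, medians_ms={
            k: v + rt_shift for k, v in base_rt.medians_ms.items()})
        lat_shift = {c: rng.normal(0.0, spec.erp_latency_participant_sd_ms)
                     for c in cal.COMPONENT_WIDTHS_MS}
        amp_shift = {c: rng.normal(0.0, spec.erp_amplitude_participant_sd_uv)
                     for c in cal.COMPONENT_WIDTHS_MS}

        truth_entry = {
            "group": group,
            "accept_probabilities": {g: policies[g].accept for g in spec.games},
            "rt_medians_ms": {f"{g}/{r}": m for (g, r), m in rt_model.medians_ms.items()},
            "erp": {}, "blink_trials": {},
        }

        # --- behavior ---------------------------------------------------
        frames = []
        epochs_by_game = {}
        for game in spec.games:
            sched = make_schedule(game, rng.integers(2 ** 31),
                                  spec.n_blocks, spec.block_size)
            trials = simulate_decisions(sched, policies[game], rng.integers(2 ** 31))
            labels = [trial_set_label(game, int(s), r) if r != "omitted" else None
                      for s, r in zip(trials["allocation_self_share"],
                                      trials["response"])]
            rts = np.full(len(trials), np.nan)
            for resp in ("accepted", "refused"):
                for lbl in set(l for l, r in zip(labels, trials["response"]) if r == resp):
                    m = (trials["response"].to_numpy() == resp) & \
                        np.array([l == lbl for l in labels])
                    if m.any():
                        rts[m] = rt_model.draw(game, resp, lbl, rng, size=int(m.sum()))
            trials = trials.assign(participant=pid, group_truth=group,
                                   rt_ms=np.round(rts, 3))
            frames.append(trials)

            # --- EEG ----------------------------------------------------
            if game in spec.eeg_games:
                valid_idx = np.where(trials["valid"].to_numpy())[0]
                n_valid = valid_idx.size
                data = np.empty((n_valid, len(spec.channels), times.size),
                                dtype=np.float32)
                truth_entry["erp"][game] = {}
                for resp in ("accepted", "refused"):
                    targets = _condition_targets(cal.erp_targets(group), game,
                                                 resp, lat_shift, amp_shift)
                    specs = calibrate_condition(targets)
                    truth_entry["erp"][game][resp] = planted_truth(
                        specs, spec.channels, times)
                    rows = np.where(trials["response"].to_numpy()[valid_idx] == resp)[0]
                    if rows.size:
                        data[rows] = _epoch_batch(
                            specs, spec.noise, spec.channels, rows.size,
                            rng, times, spec.sfreq)
                if spec.blink_rate > 0:
                    blink = np.where(rng.random(n_valid) < spec.blink_rate)[0]
                    if blink.size:
                        t0 = rng.uniform(0.0, 600.0, size=blink.size)
                        wts = np.array([{"Fz": 1.0, "FCz": 0.8, "Pz": 0.2,
                                         "CPz": 0.25}.get(ch, 0.3)
                                        for ch in spec.channels])
                        shape = np.exp(-0.5 * ((times[None, :] - t0[:, None]) / 50.0) ** 2)
                        data[blink] += (spec.blink_amplitude_uv
                                        * wts[None, :, None]
                                        * shape[:, None, :]).astype(np.float32)
                    truth_entry["blink_trials"][game] = [
                        int(trials["trial"].to_numpy()[valid_idx[i]]) for i in blink]
                epochs_by_game[game] = {
                    "data": data,
                    "trials": trials["trial"].to_numpy()[valid_idx].copy(),
                }
        behavior = pd.concat(frames, ignore_index=True)
        cols = ["participant", "group_truth", "game", "block", "trial",
                "allocation_self_share", "response", "rt_ms", "valid"]
        yield pid, group, behavior[cols], epochs_by_game, truth_entry


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Materialize a full cohort (behavior tables, epochs, ground truth)."""
    times = default_times_ms(spec.sfreq)
    frames, epochs, ledger = [], {}, {"participants": {}, "seed": spec.seed,
                                      "sfreq": spec.sfreq,
                                      "channels": list(spec.channels)}
    for pid, group, behavior, epochs_by_game, truth in iter_participants(spec):
        frames.append(behavior)
        for game, pack in epochs_by_game.items():
            epochs[(pid, game)] = pack
        ledger["participants"][pid] = truth
    return Cohort(spec=spec, behavior=pd.concat(frames, ignore_index=True),
                  epochs=epochs, times_ms=times, channels=spec.channels,
                  ledger=ledger)
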