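"""Default calibration tables for the synthetic cohort generator.

These numbers describe the behavioral and electrophysiological phenotypes of
the five participant groups seen in the original dictator-game (DG) /
ultimatum-game (UG) cohort: the group-level accept probabilities that
reproduce the published median behavioral indices, reaction-time medians per
response, and ERP component peak targets (latency in ms, amplitude in uV)
per group and game.  They are *calibration*, i.e. one of many generator
settings consistent with the published group summaries, not ground truth
about any individual.
"""

from __future__ import annotations

GROUPS = ("GrpS", "GrpA", "GrpB", "GrpC", "GrpF")

#: Group sizes of the reference cohort (N = 39).
GROUP_SIZES = {"GrpS": 8, "GrpA": 3, "GrpB": 10, "GrpC": 8, "GrpF": 10}

#: Median behavioral indices per group: (DG_selfishness, UG_altruism).
GROUP_INDICES = {
    "GrpS": (0.98, -0.97),
    "GrpA": (0.60, -0.69),
    "GrpB": (0.73, -0.40),
    "GrpC": (0.13, -0.29),
    "GrpF": (-0.92, -0.97),
}

# Accept probability at the "neutral" 70:30 split (does not enter either
# index); chosen so selfish-leaning allocators keep favorable splits.
DG_NEUTRAL_ACCEPT = {"GrpS": 0.90, "GrpA": 0.85, "GrpB": 0.85, "GrpC": 0.50, "GrpF": 0.20}
UG_NEUTRAL_ACCEPT = {"GrpS": 0.70, "GrpA": 0.75, "GrpB": 0.80, "GrpC": 0.70, "GrpF": 0.70}


def dg_accept_probabilities(group: str) -> dict[int, float]:
    """Accept probability per DG allocation (keyed by allocator self-share).

    Calibrated so the expected DG_selfishness equals the group's median
    index: with symmetric behavior q at the pro-self allocations {90, 80}
    (accept) and {60, 50} (refuse), the expected index is 2q - 1.
    """
    idx, _ = GROUP_INDICES[group]
    q = (1.0 + idx) / 2.0
    return {90: q, 80: q, 70: DG_NEUTRAL_ACCEPT[group], 60: 1.0 - q, 50: 1.0 - q}


def ug_accept_probabilities(group: str) -> dict[int, float]:
    """Accept probability per UG offer (keyed by responder self-share).

    Altruistic behavior = accepting the least favorable offers {10, 20} and
    rejecting the equitable ones {40, 50}; expected UG_altruism = 2q - 1
    with q the accept probability at {10, 20}.
    """
    _, idx = GROUP_INDICES[group]
    q = (1.0 + idx) / 2.0
    return {10: q, 20: q, 30: UG_NEUTRAL_ACCEPT[group], 40: 1.0 - q, 50: 1.0 - q}


#: Default per-trial probability that no response arrives within the 3 s
#: deadline (approximately 237.3 of 240 trials completed).
OMISSION_PROBABILITY = 0.011

#: Reaction-time medians (ms) per (group, game, response).  The lognormal
#: cells reproduce these medians after adding the shift.  The GrpS/UG
#: rejected cell is set above the accepted one so that every group obeys the
#: global "responses endorsing the split are faster" direction the generator
#: guarantees by contract.
RT_MEDIANS_MS = {
    ("GrpS", "DG", "accepted"): 391.0,
    ("GrpS", "DG", "refused"): 415.0,
    ("GrpS", "UG", "accepted"): 440.0,
    ("GrpS", "UG", "refused"): 450.0,
    ("GrpA", "DG", "accepted"): 373.0,
    ("GrpA", "DG", "refused"): 395.0,
    ("GrpA", "UG", "accepted"): 415.0,
    ("GrpA", "UG", "refused"): 440.0,
    ("GrpB", "DG", "accepted"): 355.0,
    ("GrpB", "DG", "refused"): 373.5,
    ("GrpB", "UG", "accepted"): 390.0,
    ("GrpB", "UG", "refused"): 409.0,
    ("GrpC", "DG", "accepted"): 380.0,
    ("GrpC", "DG", "refused"): 405.0,
    ("GrpC", "UG", "accepted"): 410.0,
    ("GrpC", "UG", "refused"): 435.0,
    ("GrpF", "DG", "accepted"): 398.0,
    ("GrpF", "DG", "refused"): 432.0,
    ("GrpF", "UG", "accepted"): 400.0,
    ("GrpF", "UG", "refused"): 430.0,
}

#: Additive RT offsets (ms) per trial-set family: altruistic UG trials are
#: markedly slower than conceit ones; fair DG trials slightly slower than
#: selfish ones.
RT_SET_OFFSETS_MS = {
    "DG_selfish": 0.0,
    "DG_neutral": 10.0,
    "DG_fair": 20.0,
    "UG_conceit": 0.0,
    "UG_neutral": 20.0,
    "UG_altruistic": 80.0,
}

#: Lognormal shape (sigma of log) and shift (ms) shared by all RT cells.
RT_LOG_SIGMA = 0.85
RT_SHIFT_MS = 200.0

# ---------------------------------------------------------------------------
# ERP peak targets: (latency ms, amplitude uV) of the windowed extremum of
# the expected average waveform at the component's reference electrode
# (FCz for fronto-central N1/P2/MFN, Pz for posterior-parietal LPC).
# ---------------------------------------------------------------------------

_ERP_SBF = {
    # group: {game: {component: (latency_ms, amplitude_uV)}}
    "GrpB": {
        "DG": {"N1": (139.1, -4.04), "P2": (222.1, 5.01), "MFN": (326.5, -2.23), "LPC": (524.3, 5.12)},
        "UG": {"N1": (130.8, -3.94), "P2": (222.7, 4.72), "MFN": (328.1, 1.07), "LPC": (531.1, 3.66)},
    },
    "GrpF": {
        "DG": {"N1": (138.4, -2.83), "P2": (201.3, 4.40), "MFN": (314.6, 1.26), "LPC": (520.6, 4.19)},
        "UG": {"N1": (140.7, -3.53), "P2": (226.0, 4.83), "MFN": (338.1, 0.62), "LPC": (581.0, 2.14)},
    },
    "GrpS": {
        "DG": {"N1": (128.2, -1.66), "P2": (205.9, 3.31), "MFN": (292.4, -2.13), "LPC": (551.4, 4.96)},
        "UG": {"N1": (127.8, -2.33), "P2": (211.3, 3.74), "MFN": (318.3, 0.68), "LPC": (530.5, 5.75)},
    },
}


def _midpoint(a, b):
    return {
        game: {c: ((a[game][c][0] + b[game][c][0]) / 2.0, (a[game][c][1] + b[game][c][1]) / 2.0)
               for c in a[game]}
        for game in a
    }


def erp_targets(group: str) -> dict:
    """Peak targets per game and component for ``group``.

    GrpA and GrpC were not characterized electrophysiologically at the group
    level; they receive the midpoints of their behavioral neighbors
    (S--B and B--F respectively).
    """
    if group in _ERP_SBF:
        return _ERP_SBF[group]
    if group == "GrpA":
        return _midpoint(_ERP_SBF["GrpS"], _ERP_SBF["GrpB"])
    if group == "GrpC":
        return _midpoint(_ERP_SBF["GrpB"], _ERP_SBF["GrpF"])
    raise KeyError(f"unknown group {group!r}")


#: Response-dependent additive offsets to the peak targets, keyed by
#: (game, component, field) -> {response: offset}.  field is "latency"
#: (ms) or "amplitude" (uV).  Directions: DG refusals delay the MFN and
#: shrink the LPC; UG rejections shorten the MFN and deepen it slightly.
RESPONSE_OFFSETS = {
    ("DG", "MFN", "latency"): {"accepted": -16.0, "refused": +16.0},
    ("DG", "LPC", "amplitude"): {"accepted": +0.86, "refused": -0.86},
    ("UG", "MFN", "latency"): {"accepted": +10.0, "refused": -10.0},
    ("UG", "MFN", "amplitude"): {"accepted": +0.33, "refused": -0.33},
}

#: Channel topography weights per component family.  Fronto-central
#: components are maximal at FCz, the late positivity at Pz.
TOPOGRAPHY = {
    "N1":  {"Fz": 0.95, "FCz": 1.00, "Pz": 0.30, "CPz": 0.35},
    "P2":  {"Fz": 0.95, "FCz": 1.00, "Pz": 0.30, "CPz": 0.35},
    "MFN": {"Fz": 0.95, "FCz": 1.00, "Pz": 0.30, "CPz": 0.35},
    "LPC": {"Fz": 0.40, "FCz": 0.45, "Pz": 1.00, "CPz": 0.95},
}

#: Single-trial component widths (Gaussian sigma, ms).  Together with the
#: 10 ms latency jitter these set the width of the expected average bump.
COMPONENT_WIDTHS_MS = {"N1": 16.0, "P2": 24.0, "MFN": 42.0, "LPC": 65.0}

#: Reference electrode at which each component's targets are calibrated.
REFERENCE_ELECTRODE = {"N1": "FCz", "P2": "FCz", "MFN": "FCz", "LPC": "Pz"}

#: Default single-trial stochastic settings.
LATENCY_JITTER_SD_MS = 10.0
AMPLITUDE_CV = 0.3
NOISE_RMS_UV = 10.0
NOISE_EXPONENT = 1.0
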