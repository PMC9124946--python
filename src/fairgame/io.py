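"""On-disk formats: behavioral TSV, HDF5 epoch container, events TSV,
ground-truth ledger JSON, and checksum helpers.

The HDF5 container stores float32 epochs per participant and game under
``/<participant>/<game>/epochs`` with shape (trial, channel, sample), the
originating trial indices alongside, and sampling metadata as root
attributes.  Events are exported as a BIDS-style TSV (onset, duration,
trial_type) with participant/game columns.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

BEHAVIOR_COLUMNS = ["participant", "group_truth", "game", "block", "trial",
                    "allocation_self_share", "response", "rt_ms", "valid"]

#: Nominal trial spacing (s) used to place stimulus onsets on a virtual
#: session clock in the events file.
TRIAL_SPACING_S = 5.0
STIMULUS_DURATION_S = 1.2


def write_behavior_tsv(behavior: pd.DataFrame, path) -> Path:
    path = Path(path)
    behavior.to_csv(path, sep="\t", index=False)
    return path


def read_behavior_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(BEHAVIOR_COLUMNS) - {"group_truth"} - set(df.columns)
    if missing:
        raise ValueError(f"behavior table missing columns: {sorted(missing)}")
    df["valid"] = df["valid"].astype(bool)
    return df


def write_events_tsv(behavior: pd.DataFrame, path) -> Path:
    """BIDS-style events: one row per trial on a virtual session clock."""
    ev = behavior.copy()
    ev["onset"] = (ev["trial"] - 1) * TRIAL_SPACING_S
    ev["duration"] = STIMULUS_DURATION_S
    ev["trial_type"] = (ev["game"] + "/" +
                        ev["allocation_self_share"].astype(str) + "/" +
                        ev["response"])
    cols = ["onset", "duration", "trial_type", "participant", "game", "trial"]
    path = Path(path)
    ev[cols].to_csv(path, sep="\t", index=False)
    return path


def write_epochs_h5(path, participant_epochs, times_ms, channels,
                    sfreq: float) -> Path:
    """``participant_epochs`` iterates (pid, game, data, trial_index)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["sfreq"] = float(sfreq)
        f.attrs["channels"] = [str(c) for c in channels]
        f.create_dataset("times_ms", data=np.asarray(times_ms, dtype=np.float64))
        for pid, game, data, trials in participant_epochs:
            grp = f.require_group(f"{pid}/{game}")
            grp.create_dataset("epochs", data=np.asarray(data, dtype=np.float32))
            grp.create_dataset("trials", data=np.asarray(trials, dtype=np.int64))
    return path


def iter_epochs_h5(path):
    """Yield (pid, game, epochs float64 uV, trial_index) lazily."""
    with h5py.File(path, "r") as f:
        for pid in sorted(k for k in f.keys() if k != "times_ms"):
            for game in sorted(f[pid].keys()):
                grp = f[pid][game]
                yield (pid, game, grp["epochs"][()].astype(np.float64),
                       grp["trials"][()])


def read_epochs_meta(path):
    with h5py.File(path, "r") as f:
        return (f["times_ms"][()], [str(c) for c in f.attrs["channels"]],
                float(f.attrs["sfreq"]))


def write_ledger_json(ledger: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(ledger, indent=1, sort_keys=True))
    return path


def read_ledger_json(path) -> dict:
    return json.loads(Path(path).read_text())


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
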