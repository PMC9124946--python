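#!/usr/bin/env python
"""Step 3 — ERP preprocessing and peak measurement.

Band-pass filters (0.1--32 Hz, zero phase), baseline-corrects, rejects
over-threshold epochs, averages each behavioral trial set, and takes three
bootstrap-replicate peak measurements per component and electrode
(N1/P2/MFN at Fz+FCz, LPC at Pz+CPz).  Prints identification rates and the
group-level component table.
"""

import pandas as pd

from analysis_config import CONFIG, OUT
from fairgame.pipeline import run_all


def main() -> None:
    run_all(CONFIG, OUT, stages=("erp",))
    meas = pd.read_csv(OUT / "measurements.csv")
    ident = meas.groupby("component")["identified"].mean()
    print("peak identification rate per component:")
    print(ident.round(3).to_string())
    pooled = meas[meas["identified"] & (meas["set"] == "all")]
    table = (pooled.groupby(["component", "game", "group"])
             [["latency_ms", "amplitude_uv"]].mean().round(1))
    print(table.to_string())


if __name__ == "__main__":
    main()
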