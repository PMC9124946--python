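#!/usr/bin/env python
"""Step 4 — statistical battery and report.

Runs the mixed-model ANOVA-like tables (Satterthwaite df), the Levene-gated
group t-tests with Bonferroni adjustment, and renders the markdown report.
Prints the tests significant at alpha = 0.05.
"""

import pandas as pd

from analysis_config import CONFIG, OUT
from fairgame.pipeline import run_all


def main() -> None:
    run_all(CONFIG, OUT, stages=("stats", "report"))
    stats = pd.read_csv(OUT / "stats.csv")
    sig = stats[stats["p"] < 0.05]
    cols = ["design", "game", "component", "measure", "effect",
            "statistic", "df2", "p"]
    print(f"{len(sig)} of {len(stats)} tests significant at alpha=0.05:")
    print(sig[cols].round(4).to_string(index=False))
    print(f"\nreport: {OUT / 'report.md'}")


if __name__ == "__main__":
    main()
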