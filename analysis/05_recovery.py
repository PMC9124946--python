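#!/usr/bin/env python
"""Step 5 — ground-truth recovery validation.

Runs the two validation studies behind the pipeline's claims: (a) peak
recovery bias of the full measurement chain against the planted ledger on a
39-participant, 200-trials-per-set cohort; (b) a full pipeline pass on a
fresh responder-game cohort checking the headline group/condition contrast
directions.  Writes results/recovery_summary.csv and prints both outcomes.
"""

from pathlib import Path

from fairgame.recovery import component_recovery, direction_study, recovery_summary

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    measured = component_recovery(seed=1)
    summary = recovery_summary(measured)
    RESULTS.mkdir(exist_ok=True)
    summary.to_csv(RESULTS / "recovery_summary.csv", index=False)
    print("peak recovery vs planted ground truth (39 participants, "
          "200 trials/set):")
    print(summary.round(3).to_string(index=False))

    out = direction_study(seed=1, game="UG")
    print("\nheadline contrasts on a fresh responder-game cohort:")
    print(f"  N1 latency, selfish - fair group:   "
          f"{out['n1_latency_S_minus_F']:+.1f} ms (expected < 0)")
    print(f"  LPC amplitude, selfish - fair group: "
          f"{out['lpc_amplitude_S_minus_F']:+.2f} uV (expected > 0)")
    print(f"  MFN latency, rejected - accepted:    "
          f"{out['mfn_latency_rej_minus_acc']:+.1f} ms (expected < 0)")


if __name__ == "__main__":
    main()
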