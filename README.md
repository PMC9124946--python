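# fairgame

Behavioral phenotyping and ERP analysis for a combined dictator-game (DG) /
ultimatum-game (UG) experiment, driven by a fully synthetic, ground-truthed
cohort generator.

In this paradigm a participant sees one of five endowment splits —
self-shares {50, 60, 70, 80, 90}% as DG allocator, {50, 40, 30, 20, 10}% as
UG responder — and accepts or refuses it within 3 s while 1024-Hz EEG is
recorded.  Valid trials fall into behaviorally opposed sets (selfish/fair
in DG, altruistic/conceit in UG), summarized per participant by two indices
in [−1, 1]:

    DG_selfishness = (N_selfish − N_fair) / (N_selfish + N_fair)
    UG_altruism    = (N_altruistic − N_conceit) / (N_altruistic + N_conceit)

Participants are phenotyped by complete-linkage clustering of the 2-D index
points (with a jitter/shuffle stability rule that isolates borderline
participants), stimulus-locked epochs are filtered (0.1–32 Hz zero-phase
Butterworth), baseline-corrected, artifact-rejected and averaged per trial
set, and four components are measured as windowed extrema — N1 (110–160 ms)
/ P2 (180–240 ms) / MFN (260–400 ms) at Fz+FCz and LPC (430–630 ms) at
Pz+CPz — with three bootstrap-replicate measurements standing in for
independent human observers.  The statistical battery comprises Levene-gated
Student/Welch t-tests with Bonferroni adjustment, Cohen's d and generalized
η² with verbal categories, random-intercept mixed models with Type-III
ANOVA-like tables and Satterthwaite denominator df, polynomial regressions,
and noncentral-F power for within–between interactions.

Because no recordings are deposited for this paradigm, every stage is
validated against the synthetic generator's ledger of planted parameters:
decision policies calibrated to the published group median indices,
condition-ordered log-normal reaction times, and Gaussian ERP components
(plus a late positive pedestal and 1/f noise) calibrated so that the
expected average waveform hits the published group × game × response peak
values.  See `docs/methods.md` for the model and its assumptions.

## Worked example

The numbered scripts under `analysis/` run the full study into
`results/run/`:

```
cd analysis
python 01_simulate.py    # cohort: 8 selfish / 10 low-conceit / 10 fair
python 02_phenotype.py
python 03_erp.py
python 04_stats.py
python 05_recovery.py
```

Step 2 prints the recovered phenotypes:

```
      dg_selfishness             ug_altruism
              median  mean count      median  mean count
group
GrpB            0.74  0.72    10       -0.39 -0.39    10
GrpF           -0.92 -0.91    10       -0.96 -0.95    10
GrpS            0.95  0.95     8       -0.96 -0.95     8
recovered group label agrees with planted group for 100% of participants
```

i.e. clustering the behavioral indices alone re-identifies all three
planted phenotypes; the group medians sit at the calibration targets
(selfish group ≈ +0.95 DG_selfishness, fair group ≈ −0.92).  Step 5 prints
the validation of the ERP chain against the ground-truth ledger:

```
component  n_identified  n_total  latency_bias_ms  amplitude_bias_rel
      LPC           312      312           -1.565               0.052
      MFN           312      312           -0.839               0.035
       N1           312      312           -0.376               0.084
       P2           305      312            0.211               0.001

headline contrasts on a fresh responder-game cohort:
  N1 latency, selfish - fair group:   -15.0 ms (expected < 0)
  LPC amplitude, selfish - fair group: +3.46 uV (expected > 0)
  MFN latency, rejected - accepted:    -14.3 ms (expected < 0)
```

Peak latencies are recovered with < 2 ms bias and amplitudes within a few
percent of the planted magnitudes, and the pipeline reproduces the signed
group/condition contrasts that characterize the reference cohort: the
selfish group shows an earlier fronto-central N1 and a larger
posterior-parietal late positivity than the fair group, and rejections
shorten the medial frontal negativity.

The same stages are available as a CLI
(`fairgame {simulate|classify|erp|stats|report|all} --config cfg.yaml
--seed N --out DIR [--resume]`); stages communicate only through documented
on-disk files (TSV/CSV/HDF5/JSON), so real data in the same schemas can be
substituted at any boundary.

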