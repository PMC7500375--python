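# liftlab

Simulation and analysis pipeline for grasp-and-lift force-scaling and
weight-perception experiments.

The package covers five stages:

1. **Session design** (`liftlab.session_design`) — pseudorandom trial
   sequences of light/heavy target objects with medium-weight dummy trials.
   Each previous×current order pair (LL, HL, LH, HH) occurs exactly
   `n_reps_per_cell` times per stimulation condition (dynamic, static,
   none); dummies are never first, last, or adjacent.  The reference design
   (10 reps/cell) yields 149 trials: 120 analyzable, 14 dummies, 14
   post-dummy trials and the first trial.
2. **Lift simulation** (`liftlab.lift_simulator`) — synthetic two-sensor,
   three-axis force traces at 1 kHz plus raw weight reports.  Load-force
   rate follows minimum-jerk pulses scaled to the *expected* weight
   (sensorimotor memory of the previous lift); under-scaled lifts get a
   larger corrective second rate peak; grip force leads and tracks load
   force with a safety margin; reports are biased by the previous weight
   and carry participant-specific affine scales.  Stimulation effects and
   artifact trials (drops, multiple lifts, failed stimulation) are
   injectable.
3. **Metric extraction** (`liftlab.trace_metrics`) — zero-phase 2nd-order
   Butterworth filtering at 15 Hz, grip/load composition, 0.1 N onsets,
   0.4 N contact trigger, liftoff detection, force rates, peak and
   first-peak extraction (first peak ≥ 30% of maximum) in the grip-onset →
   liftoff+50 ms window, static grip force 600–800 ms post liftoff, burst
   scheduling (3 pulses at 10 Hz), and the two-stage exclusion rule.
4. **Perception pipeline** (`liftlab.perception_pipeline`) — per-participant
   z-scoring of reports, participant×order-pair×condition cell means,
   previous-weight and stimulation difference scores, percent-bias.
5. **Inference protocol** (`liftlab.inference_protocol`) — mixed 2×3×2×2
   split-plot ANOVA with Mauchly's test and Greenhouse–Geisser correction,
   Bonferroni post hocs, the location-split rule, AR(1)
   maximum-likelihood regressions relating force covariates to perceptual
   differences, and Fisher-z Pearson confidence intervals.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes unit tests per module, property tests (hypothesis), and
`tests/test_acceptance.py` with the design-arithmetic, oracle-equivalence,
event-recovery, type-I-calibration and parameter-recovery criteria.

## Command line

```bash
liftlab design   --seed 1 --reps 10 --out design.csv
liftlab simulate --seed 1 --n-per-group 2 --reps 2 --out simdir/
liftlab extract  --in simdir/traces --out metrics.csv
liftlab perceive --metrics metrics.csv --out cells.csv
liftlab infer    --cells cells.csv --out results/
liftlab run      --config examples/config.yaml --out results/
liftlab fixtures --seed 0 --out fixtures/
```

`liftlab run` executes the whole pipeline from a YAML configuration (see
`examples/config.yaml`) and writes `metrics.csv`, `cells.csv`,
`results.json`, `correlations.csv` and a reproducibility `manifest.json`
carrying the master seed and package version.  Traces are stored as
per-trial CSV files with JSON metadata sidecars.

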