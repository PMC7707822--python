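# locoresp

Analysis pipeline for locomotor-respiratory coupling in running rodents:

- **EMG processing** — centered moving-RMS integration of a raw diaphragm
  EMG trace, threshold burst detection with hysteresis, and per-cycle
  respiratory parameters (Ti, Te, instantaneous frequency, normalized
  amplitude) averaged over deterministic 6-s measurement windows.
- **Gait kinematics** — cleaning of pose-estimation tracks (likelihood
  gating, interpolation, running median), velocity-threshold stance/swing
  segmentation with sub-frame footfall refinement, trot/gallop
  classification from inter-limb relative phases, stable-epoch selection
  from the head trace, and open-field mobility metrics.
- **Coupling statistics** — inspiration phase within the stride cycle
  (0 at the preceding footfall, 1 at the next), circular mean and
  concentration R with the fixed R < 0.3 orientation criterion,
  phase histograms, surrogate-calibrated cross-correlograms, and
  Mann-Whitney U condition comparisons (exact for small samples).
- **Session pipeline** — end-to-end orchestration of one recording and
  aggregation across animals/conditions.
- **Synthetic data** — a generator of limb pose tracks and diaphragm EMG
  with full ground truth: gait-specific inter-limb phases, duty-cycled
  sawtooth paw trajectories with tracking noise and dropouts, and
  inspiration onsets from a refractory hazard process that is either
  independent of the stride cycle (kappa = 0) or von-Mises coupled to a
  preferred stride phase.

## Command-line interface

```sh
# generate a synthetic session (EMG text file, pose CSV, ground truth)
locoresp simulate --scenario scenario.yaml --seed 1 --outdir session1/

# analyze one session end-to-end (result tables, optional figures)
locoresp analyze --emg session1/emg.txt --pose session1/pose.csv \
    --config session1/config.yaml --outdir out1/ --figures

# aggregate per-session summaries and compare two conditions
locoresp summarize --indir condA/ --label A
locoresp compare --a condA/ --b condB/ --param freq
```

Exit code 0 on success, 2 on validation/configuration errors. All
analysis parameters (thresholds, window lengths, seeds) live in the YAML
config under `params:` and have documented defaults in
`locoresp.session_pipeline.DEFAULT_PARAMS`.

File formats: pose tables use the common 3-header-row CSV export of
pose-estimation tools (scorer / bodyparts / coords rows; x, y, likelihood
per bodypart); EMG is plain one-column (or two-column time,value) numeric
text; result tables are CSV with fixed column order; configuration and
simulation scenarios are YAML.

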