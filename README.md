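# lfpdecode

Decoding bilateral hindlimb joint angles from intraspinal local field
potentials (LFP), rebuilt as a tested, reusable Python pipeline and exercised
end to end on a synthetic-session generator with known ground truth.

The pipeline covers:

- **Synthetic sessions** (`lfpdecode.synth`) — gait-periodic joint angles at a
  configurable cadence; 8-channel LFP built from six band-limited noise
  carriers whose envelopes are modulated by gait phase with per-channel
  coupling depth/phase; 50/100/150 Hz line interference, pink and white
  noise; optional theta-power/cadence linkage. Deterministic under a seed.
- **Preprocessing** (`lfpdecode.preprocess`) — Butterworth notch filters at
  50/100/150 Hz; a six-band filter bank (delta 0.5–4, theta 6–12, beta 15–30,
  gamma 40–80, high-gamma 80–120, ripple 150–210 Hz); band envelopes
  (rectify, 4 Hz low-pass, resample to 10 Hz); windowed mean LFP amplitude
  (200 ms window, 100 ms step); lagged 8 x 10 x 7 feature tensors
  (channel x lag x feature, 100 ms lag step); kinematic targets aligned to
  the shared 10 Hz grid. All filtering is zero-phase.
- **Decoding** (`lfpdecode.decode`, `lfpdecode.cnn`) — a single-output 3-D
  CNN (70 filters of 7 x 6 x 8, stride 1, same padding; 2 x 2 x 2 max-pool,
  stride 1; one hidden fully connected layer; trained with SGD + momentum,
  MSE + L2 penalty), implemented directly on NumPy; PLS and Lasso baselines
  with inner-CV hyperparameter selection; threefold cross-validation over
  contiguous temporal blocks; the percent coefficient of determination;
  electrode subsets (lateral 1/4/5/8, dorsal 2/3/6/7, left 3/4/7/8,
  right 1/2/5/6).
- **Analyses** (`lfpdecode.analysis`) — gait-cycle segmentation and
  cycle-averaged ERD/ERS maps (percent change per phase bin, with
  phase-shuffled surrogate bounds); mutual information by adaptive
  partitioning of the rank space (bits); per-session MI matrices
  (channel x feature x joint) and their aggregates; one-/two-way ANOVA with
  Tukey HSD; cadence-group comparison (lower < 0.67, higher > 0.73 steps/s)
  with per-band Welch t-tests.
- **I/O and CLI** (`lfpdecode.session`, `lfpdecode.pipeline`,
  `lfpdecode.cli`) — HDF5 session/feature containers and a `lfpdecode`
  command with `simulate`, `preprocess`, `decode`, `analyze` and `run`
  subcommands; full runs write CSV tables plus a manifest with checksums.

## CLI example

```bash
lfpdecode simulate --seed 1 --out session.h5
lfpdecode preprocess --in session.h5 --out features.h5
lfpdecode decode --features features.h5 --decoder pls --subset lateral --out decode.csv
lfpdecode analyze tfmap --in session.h5 --out tfmap.csv
lfpdecode run --seed 1 --out-dir run_output
```

## Acceptance

Acceptance is property-based (filter attenuation, envelope analytics, the
R^2 scorer against a literal oracle, the feature-tensor lag contract, MI
against the bivariate-Gaussian closed form, MI band-ranking recovery,
decoding parameter recovery with CNN >= PLS, ERD/ERS phase recovery, cadence
effect recovery, and the channel-subset groupings); every criterion lives in
`tests/test_acceptance.py`. There are no numeric targets to recompute from
the study (its recordings are not deposited), so

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs an end-to-end smoke check and writes an empty JSON report.
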