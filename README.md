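# perturbreach

Synthetic single-unit recording sessions for an orientation-perturbation
reach-to-grasp task, plus the analysis pipeline that goes with them:

- **`perturbreach.simulate`** — generates complete sessions with known ground
  truth: a 240-trial block (4 sets: 90 unperturbed, 90 randomly perturbed,
  2 x 30 repeat-perturbed), hand-orientation trajectories at 100 Hz built from
  minimum-jerk segments with corrective submovements and over-rotation, and
  spike trains drawn from inhomogeneous Poisson intensities (baseline,
  movement bump, corrective burst, anticipatory ramp, orientation tuning) via
  Lewis–Shedler thinning.
- **`perturbreach.epochs`** — trial epoch windows (CHT/RTc/MT/PD/PR/THT),
  epoch firing rates, baseline-stability screening, the 2-SD task-related
  rule, perturbation-response and anticipatory t-tests, and a 2x3
  direction-by-orientation ANOVA; population category fractions.
- **`perturbreach.kinematics`** — perturbation reaction time (RTp) from
  trajectory deviations against a 95% band built from unperturbed trials,
  and RTp adaptation series with prediction flags.
- **`perturbreach.psth`** — perievent rasters and 20 ms histograms for any
  alignment event.
- **`perturbreach.decode`** — single-unit condition decoding with a
  two-layer backprop network (tanh hidden layer, linear output, −1/0/+1
  targets, ±0.6 threshold rule), including the random-trial cross-test and
  prediction-rate clustering.
- **`perturbreach.report`** — orchestrates all stages into a reproducible
  report bundle (TSV + JSON + plots) from a single config + seed.

## CLI

```bash
perturbreach simulate --seed 1 --neurons 20 --out session/
perturbreach analyze epochs --in session/ --alpha 0.05 --out results/
perturbreach analyze rtp   --in session/ --band normal --k 3 --out results/
perturbreach analyze psth  --in session/ --align center_release --bin 0.020 --out results/
perturbreach decode --in session/ --task condition --seed 0 --out results/
perturbreach run --config config.yaml
```

All session data are plain tab-separated text (`trials.tsv`, `spikes.tsv`,
`traj.tsv`, `ground_truth.tsv`); times in seconds from central-pad hit,
angles in degrees.

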