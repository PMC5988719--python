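# ornpulse

Quantification pipeline for larval olfactory-receptor-neuron (ORN)
calcium recordings and optogenetic choice-assay behavior, with a
synthetic-data module so that every analysis stage carries a
parameter-recovery test.

## What it does

**Imaging** (`ornpulse.imaging_io`, `ornpulse.trace_analysis`)

- ΔF/F0 normalization in two baselining modes: mean of the lowest
  quartile of samples (spontaneous "prior" activity) or the mean of the
  nine frames from stimulation onset (optical-stimulation experiments).
- Event detection as threshold-crossing runs at *baseline + 2σ*
  (baseline = series median, σ = series standard deviation; MAD option),
  event frequency in events/s, and the prior-to-evoked amplitude ratio.
- One-sided periodograms (Parseval-exact normalization) with cross-trace
  mean ± SEM averaging.
- Stimulus-response metrics: ΔF/F0max in the stimulation windows,
  post-offset undershoot relative to the pre-stimulus baseline, and
  return-to-baseline time.
- Preprocessing per the imaging protocol: per-frame disk mean filter
  (radius in pixels) followed by rolling-ball background subtraction,
  implemented as grayscale opening with a spherical-cap structuring
  element; ROI mean-intensity extraction from multi-page TIFF stacks.

**Behavior** (`ornpulse.behavior`)

- Quadrant assignment on a circular four-quadrant plate (two diagonal
  quadrants lit), performance index
  PI = (lit positions − dark positions) / total classified positions,
- boundary-approach events via a hysteresis band around the quadrant
  lines with cross / turn-back outcomes, and entry / turn-back
  probabilities with raw counts ready for Fisher testing.

**Statistics** (`ornpulse.stats`)

- Wilcoxon rank-sum with an exact permutation mode (mid-ranks, subset-sum
  dynamic programming) and a tie/continuity-corrected normal mode,
- two-sided Fisher's exact test (probability-mass rule),
- Bonferroni and Benjamini–Hochberg adjustment, box-plot summaries.

**Synthetic data** (`ornpulse.synthetic`)

- Calcium traces: Poisson events × difference-of-exponentials kernel
  (+ optional sinusoidal rate modulation for rhythmicity), log-normal
  amplitudes, drift and Gaussian noise — with ground-truth event times.
- Stimulus responses: sustained/fluctuating mode with post-offset
  undershoot vs exponentially adapting mode with slow recovery.
- Image stacks with traces painted into disjoint ROI footprints.
- Larval trajectories: persistent random walks in the arena with one
  Bernoulli boundary decision per approach, ground truth attached.

All generators are pure functions of their parameters including the
seed.

## Command line

```sh
ornpulse --version
ornpulse simulate traces --seed 1 --n 20 --out out/sim
ornpulse simulate trajectories --seed 1 --out out/traj
ornpulse traces extract --stack s.tif --roi mask.tif --mean-radius 2 --ball-radius 50 --out traces.tsv
ornpulse traces analyze --in traces.tsv --out metrics.tsv
ornpulse behavior --in out/traj/trajectories.tsv --out out/beh
ornpulse stats --in metrics.tsv --groups group --value frequency_hz --adjust bonferroni --out stats.tsv
ornpulse run --config config.yaml --seed 1 --out out/run
```

`ornpulse run` drives a whole experiment (simulate → analyze → test →
report) from one YAML config, e.g.

```yaml
experiment: prior_activity
groups:
  wt:     {event_rate: 0.9,  noise_sigma: 2.0}
  mutant: {event_rate: 0.06, noise_sigma: 2.0}
n_per_group: 20
seed: 7
out_dir: out/prior
```

Experiments: `prior_activity`, `pulse_response`, `continuous_response`,
`choice_assay`. Identical configs produce byte-identical outputs; one
top-level seed is expanded into per-stage child seeds.

## Data formats

Everything tabular is plain text (TSV/CSV): trace tables
(`time_s` + one column per trace), trajectory tables
(`larva_id, frame, x_cm, y_cm`), metric and stats tables. Image stacks
are multi-page TIFF; ROI masks are images with nonzero member pixels;
ground truth is JSON.
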