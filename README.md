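# trialprep

Trial-based preprocessing and GLM evaluation for awake non-human-primate
(NHP) fMRI at high field.

Awake-monkey experiments structure scanning into short behavioural
trials: the animal holds still during a trial and moves (jaw, body)
between trials for its reward. At 7 T those movements perturb the B0
field and, with segmented EPI, produce N/2 ghosts, apparent shifts along
the phase-encode (A–P) axis, and between-trial changes of brain position
and apparent shape. Standard single-subject fMRI pipelines assume one
continuous, mostly-still time series and handle none of this well.
`trialprep` implements the trial-aware alternative, for methods-minded
fMRI researchers and for anyone who needs a fully synthetic, ground-truth
testbed for such pipelines:

- **QC & trial selection** — per-volume ghost ratio
  (mean brain ROI / mean N/2-ghost ROI) and centre-of-mass shift,
  semi-automatic flagging with manual overrides, whole-trial rejection.
- **Concatenation** — keep only accepted-trial volumes, with full gap
  bookkeeping (`ConcatIndex`).
- **2-step realignment** — 1-DOF phase-axis registration of each volume
  to its trial's first volume, composed with a per-trial 12-parameter
  affine (T·R·Z·S: translations, rotations, scales, shears) of trial
  means to the first trial's mean, applied in a **single** reslice.
- **Gap-interpolated high-pass filtering** — linearly interpolate removed
  epochs between two-volume anchor averages, DCT high-pass each run
  (cutoff 96 s, K = ⌊2·N·TR/cutoff⌋ components), then discard the
  interpolated samples.
- **Adaptive brain extraction** — Gaussian radial weighting
  w(x) = exp(−(d/σ)²), σ = d_max/(1+strength), relative thresholding,
  morphological fill; the mask is applied to the *original* data.
- **GLM evaluation** — canonical double-gamma HRF regressors built before
  concatenation and row-selected with the data, runs modelled as
  sessions, voxelwise OLS with grand-mean scaling, and t-maps summarized
  by suprathreshold voxel counts at T = 3.11 (p < 0.001 unc.).
- **Method comparison harness** — five analysis strategies (standard
  realignment, + artefact regressors, concatenated + standard,
  concatenated + 2-step, + gap-filtered high-pass) scored on identical
  simulated sessions.
- **Synthetic sessions** — a seeded simulator of multi-run awake-NHP
  sessions (ghosts, within-trial respiratory shifts, between-trial
  affine jitter, drifts, run steps, coil bias field) that records
  everything it injects, so every stage is testable without any data
  download.

## Worked example

Simulate a corrupted two-run session (one trial seeded with in-trial
ghosts) and compare the five analysis strategies on it:

```python
from trialprep.synthetic import SimConfig
from trialprep.glm_eval import compare_methods

cfg = SimConfig.small(seed=0).replace(bad_trial_ids=(2,))
table = compare_methods(cfg, methods=(1, 2, 3, 4, 5), seeds=(0,))
print(table.to_string(index=False))
```

```
 method  seed  count  proportion
      1     0     59    0.045315
      2     0     85    0.065284
      3     0     99    0.076744
      4     0    107    0.082625
      5     0    127    0.098145
```

`count` is the number of brain-mask voxels whose stimulation-vs-fixation
t-statistic exceeds 3.11, `proportion` that count over the mask size.
The standard analysis (method 1) recovers the least activation because
ghosted inter-trial volumes and uncorrected between-trial distortion
inflate the residual variance; artefact regressors (2) and trial
concatenation (3, 4) each recover part of it, and the full pipeline with
2-step realignment plus gap-interpolated filtering (5) yields the
largest activated fraction — here roughly twice method 1.

The same stages are available as subcommands of the `trialprep` CLI
(`simulate`, `qc`, `select`, `concat`, `realign`, `tfilter`, `extract`,
`glm`, `compare`), and `trialprep pipeline --config pipeline.yaml --out
dir/` runs the whole chain from one YAML file, materializing every
intermediate (NIfTI/TSV/JSON) plus an append-only step log.

```bash
trialprep simulate --out session/ --seed 7
trialprep qc --in session/series.nii.gz --trials session/trials.tsv \
    --brain-mask session/truth_brain_mask.nii.gz --out qc.tsv
```

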