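# dediff

Paired-associate fMRI analysis pipeline with a planted-effect BOLD
simulator.  The package implements, end to end:

- **Experimental design** (`dediff.design`): an 8-picture
  category/subcategory/exemplar stimulus hierarchy, balanced 64-item study
  lists with intact/recombined test pairings (counterbalanced, derangement
  re-pairing), and constraint-satisfying trial sequencing by rejection
  sampling.
- **Synthetic data** (`dediff.simulate`): multi-subject 4D BOLD runs
  (NIfTI + BIDS-style events TSV) with planted hierarchical pattern
  geometry in a ventral-temporal region, condition-dependent regional
  activation, trial-latent hippocampal-cortical coupling, AR(1) noise and
  slow drift.  "young" and "old" presets plant the qualitative effect
  structure the analyses are meant to recover (graded pattern similarity
  SE > SS > SC > DC, dedifferentiation in the old preset, hit > CR
  activation in HIPP/ANG, young-only CR > hit effects in DLPFC and in
  HIPP-VLPFC connectivity), with behavioral hit/CR rates drawn from the
  reference per-group trial counts.
- **GLMs** (`dediff.glm`): canonical double-gamma HRF, discrete-cosine
  high-pass basis (128 s cutoff), condition and single-trial
  (least-squares-all) designs, OLS with optional pooled AR(1) prewhitening,
  percent-signal-change scaling, contrasts, Gaussian smoothing.
- **ROIs** (`dediff.roi`): mm-radius spheres by voxel-centre distance (a
  5 mm sphere on a 3 mm grid is exactly 19 voxels), localizer-defined
  category-selective cortex (Bonferroni-corrected voxelwise contrast), and
  participant-specific peak-centred hippocampal seed spheres.
- **RSA** (`dediff.rsa`): 192 x 192 trial pattern-correlation matrices,
  Fisher-z level means over across-run pairs (SE/SS/SC/DC), distinctiveness
  difference scores, and Group x Level statistics.
- **Connectivity** (`dediff.connectivity`): beta-series correlation between
  the hippocampal seed and cortical targets, separately within hit and CR
  trials, with per-target mixed ANOVAs at the 0.05/3 threshold.
- **Statistics** (`dediff.stats`): behavioral scoring (hit/CR/FA/miss/
  no-response), pooled/Welch independent t, paired t, a classical balanced
  mixed (split-plot) ANOVA, Bonferroni thresholds.
- **Pipeline + CLI** (`dediff.pipeline`, `dediff.cli`): one JSON config
  drives simulate -> analyze -> report with tidy CSV outputs, figure-analog
  PNGs and provenance.

## CLI

```sh
# simulate a 2 x 4-subject cohort dataset tree
dediff simulate --seed 1 --n-per-group 4 --out scratch/cohort

# structural checks
dediff validate --data scratch/cohort

# full analysis: behavior, RSA, ROI percent signal change, connectivity
dediff analyze --data scratch/cohort --out scratch/report

# human-readable summary
dediff report --results scratch/report
```

A JSON config (`--config`) can override grid shape, smoothing FWHM,
whitening, the RSA accuracy filter, trial-count minima and alpha levels;
`dediff simulate` writes the config it used into the dataset tree so
`analyze` picks it up automatically.

## Data formats

Simulated datasets are BIDS-like trees: per-subject
`sub-XX/func/sub-XX_task-{study,test}_run-{r}_{bold.nii,events.tsv}`,
region masks under `masks/`, `participants.tsv`, and ground-truth
parameters in `truth.json`.  User-supplied preprocessed data in the same
layout (runs already on a common grid) can be analyzed directly.
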