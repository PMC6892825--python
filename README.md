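# mslab — EEG microstate analysis with a verifiable synthetic cohort

`mslab` is a Python package for resting-state EEG **microstate analysis**:
segmentation of multichannel EEG into a small number of quasi-stable scalp
topographies (the classical maps A–D), and group-level statistics on their
temporal dynamics. It targets the kind of clinical contrast where two
groups — here adults with Down syndrome without (DS) and with
Alzheimer-type dementia (DS-AD) — are compared on microstate features
derived from short eyes-closed recordings (19-channel 10–20 montage,
1 kHz).

Because clinical EEG of this population cannot be shared, the package
ships a first-class **synthetic cohort generator** that plants known
microstate structure (template maps, semi-Markov label dynamics, group
shifts in class durations) into realistic alpha-dominated EEG, so that
every stage of the pipeline is testable against ground truth.

## The method

For each subject, after standard conditioning (1–70 Hz band-pass,
45–55 Hz band-stop, common average reference, 1-s epoching,
amplitude-based epoch screening with spherical-spline repair of up to two
bad channels, ≥30-epoch inclusion rule), the analysis band is narrowed to
2–20 Hz and the epochs concatenated. The pipeline then computes:

- **GFP peaks** — local maxima of the global field power
  GFP(t) = √(1/C · Σ_c v_c(t)²), with a 10 ms minimum separation and
  exclusion of peaks above mean + 2·SD of the peak-GFP distribution.
- **TAAHC segmentation** — peak topographies pooled across subjects (each
  subject capped at the smallest subject's peak count) are clustered
  bottom-up: every map starts as a singleton cluster, and the cluster
  contributing least global explained variance is repeatedly *atomized*
  and its members reassigned by polarity-invariant spatial correlation,
  until K = 4 template maps remain (5 and 6 are supported). Exposed as a
  scikit-learn style estimator, `MicrostateSegmentation(n_states=4)`.
- **Back-fitting** — every sample is labelled with the template of highest
  |Pearson spatial correlation| (polarity ignored); runs shorter than
  30 ms are relabelled to their runner-up class until none remain.
- **Features** — per class: mean duration (ms), occurrence (s⁻¹), coverage
  (fraction), linked by the identity duration × occurrence / 1000 =
  coverage; plus global explained variance
  GEV = Σ_t (GFP_t · r_t)² / Σ_t GFP_t².
- **Syntax analysis** — observed transition probabilities between distinct
  consecutive microstates vs those expected from occurrence alone
  (E_ij ∝ p_i p_j, i ≠ j), compared by the chi-square distance with a
  5000-repetition subject-level permutation test.
- **Group statistics** — Wilcoxon rank-sum for demographics, ANCOVA of
  log-features on group with age and gender covariates, and Spearman
  correlations between features and the DSQIID dementia-screening score.

## Worked example

```python
from mslab.pipeline import PipelineConfig, run_all, evaluate_against_truth

cfg = PipelineConfig(out_dir="mslab_run", seed=7)   # simulates a cohort
result = run_all(cfg)
metrics = evaluate_against_truth(result)
print(round(metrics["min_template_correlation"], 4))
print(round(metrics["label_accuracy"], 4))
print(result.summary.filter(regex="row|duration_ms_[AD]").round(2))
```

Output from this exact run:

```
0.9997
0.9489
       row  duration_ms_A_mean  duration_ms_A_sd  duration_ms_D_mean  duration_ms_D_sd
0       DS               88.15              5.56               99.92              2.66
1    DS-AD               96.85              4.32               96.14              3.83
2  p_value                0.00               NaN                0.13               NaN
```

The four TAAHC prototypes match the planted templates at |r| ≥ 0.9997;
94.9 % of samples receive their true microstate label after smoothing;
and the recovered group contrast shows the planted direction — DS-AD
dwell longer in map A (temporal-lobe associated) and shorter in map D
(frontal-lobe associated). The same run writes `maps.csv`,
`features.csv`, `transitions.csv`, `ancova.csv`, `summary_table.csv`,
DSQIID scatterplots and a reproducibility manifest into `mslab_run/`.

The command-line interface mirrors the stages:

```bash
mslab simulate --out data/ --seed 7
mslab preprocess --in data/ --out clean/
mslab segment --in clean/ --out seg/ --k 4
mslab backfit --in clean/ --maps seg/maps.csv --out fit/
mslab stats --features fit/features.csv --transitions fit/transitions.csv \
            --meta data/metadata.csv --out stats/
mslab groupstats --features fit/features.csv --meta data/metadata.csv --out gs/
# or everything at once:
mslab run-all --out mslab_run --seed 7
```

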