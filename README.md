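# msalpha

Resting-EEG **microstate** segmentation and **aperiodic-adjusted alpha**
analysis, with a ground-truth-known synthetic cohort generator for
validating every stage.

EEG microstates are quasi-stable scalp potential topographies that dominate
the signal for ~80–120 ms before switching. Their temporal statistics
(coverage, occurrence, duration, per-state explained variance, and
first-order Markov transition probabilities) are widely used descriptors of
large-scale brain network dynamics, including in developmental-disorder
cohorts where they are correlated with clinical instruments such as the
Autism Behavior Checklist (ABC) and Social Responsiveness Scale (SRS).
Because broadband microstates and alpha-band power share generators,
credible brain–behavior claims require separating the periodic alpha peak
from the 1/f aperiodic background and then controlling the alpha influence
on microstate parameters — which is exactly the pipeline this package
implements:

1. **preprocess** — notch → 1–45 Hz zero-phase band-pass → non-overlapping
   4 s epochs → amplitude/gradient artifact rejection → per-epoch ±200 µV
   bad-channel detection with neighbor interpolation → average reference.
2. **microstate** — global field power `GFP_t = sd_c(v_{t,c})`, constrained
   GFP-peak selection (10 ms spacing, 20 µV floor, ±1 SD band, ≤1000
   peaks/subject), polarity-invariant **modified K-means** over k = 2–8
   (50 restarts, ≤2000 iterations), model-order selection on min–max
   normalized GEV and CV, back-fitting by maximal |spatial correlation|,
   temporal parameters, and run-sequence transition probabilities.
   GEV = Σ_t (GFP_t·C_t)² / Σ_t GFP_t²; CV = σ̂²·((N−1)/(N−1−k))².
3. **spectral** — channel-averaged Welch PSD (2 s Hamming windows, 50 %
   overlap), knee-free parameterization over 1–40 Hz into
   log₁₀P(f) = offset − χ·log₁₀f + Σ Gaussians(CF, height, bandwidth),
   and extraction of the aperiodic-adjusted alpha peak in 8–12 Hz.
4. **stats** — Tukey-fence outlier screening (> 3 extreme microstate cells
   or > 4 TP cells excludes a subject), two-sample contrasts with Cohen's
   d, Pearson/Spearman correlations with Benjamini–Hochberg FDR (family
   size 6), an OLS alpha-modulation contrast, and **semi-partial
   correlations** that residualize the microstate parameter on alpha power
   before correlating with the clinical score.
5. **synth** — a semi-Markov topographic-state generator (geometric dwells,
   alpha-frequency carrier, spatially mixed 1/f background) plus a
   two-group cohort builder with configurable group effects and a linear
   clinical-score model, so every estimator above can be tested against a
   known truth.

## Worked example

```python
import numpy as np
from msalpha.config import RunConfig
from msalpha.pipeline import run_pipeline
from msalpha.microstate import match_templates
from msalpha.synth import CohortSpec, simulate_cohort

spec = CohortSpec(n_per_group=10, n_channels=32, fs=250.0,
                  duration_s=60.0, snr=4.0, seed=20)
cohort = simulate_cohort(spec, with_eeg=True)

cfg = RunConfig(seed=20)
cfg.microstate.fixed_k = 5
result = run_pipeline(cfg, cohort=cohort, out_dir="out")

truth = next(iter(cohort.ground_truth.values())).templates
perm, corr = match_templates(result.model, truth)
print(f"k={result.model.k}  GEV={result.model.gev:.3f}  "
      f"template recovery |r|={corr:.3f}")
print(result.features.filter(like="coverage").mean().round(3))
```

prints

```
k=5  GEV=0.896  template recovery |r|=1.000
coverage_A    0.226
coverage_B    0.201
coverage_C    0.198
coverage_D    0.199
coverage_E    0.177
dtype: float64
```

i.e. the five generating topographies are recovered essentially exactly
(mean absolute spatial correlation 1.000 after Hungarian matching) and the
fitted model explains 89.6 % of the GFP-weighted topographic variance of
the peak maps. Pooled mean coverages sit around the generating occupancy
of 0.2; the spread reflects the built-in group effects (+0.03 and −0.05
coverage shifts in the ASD group on two states — the pipeline labels
states A–E by descending explained variance, so the shifted states appear
here as the high and low extremes). The `out/` directory receives the full
report bundle: `features.tsv` (subject × parameter table),
`group_contrasts.tsv`, `correlations.tsv` (r and semi-r side by side),
`exclusions.tsv`, `templates.tsv`, and `manifest.json`.

A CLI mirrors the library: `msalpha init-config`, `msalpha simulate`,
`msalpha preprocess`, `msalpha run`, sharing `--config/--seed/--out`.

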