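# Methods

## The analysis model

The pipeline treats resting EEG as an alternation of a small number of
quasi-stable scalp topographies riding on a 1/f-like background. Three
estimation problems follow:

1. **Which topographies?** Maps sampled at peaks of the global field power
   (GFP, the per-sample population SD of channel voltages — the moments of
   highest topographic signal-to-noise) are clustered with a
   polarity-invariant modified K-means: each map is assigned to the
   template maximizing its squared spatial correlation (Pearson correlation
   across channels after removing each map's channel mean), and each
   template is re-estimated as the dominant eigenvector of its cluster's
   outer-product sum. Polarity is ignored by construction — both the
   squared-correlation assignment and the eigenvector update are invariant
   to the sign of any map — matching the physiology (oscillatory generators
   flip sign every half cycle while the spatial pattern persists).
2. **When is each active?** Back-fitting labels every sample with the
   template of maximal absolute spatial correlation. Temporal parameters
   are computed per state from maximal runs: coverage (fraction of assigned
   samples), occurrence (runs per second of assigned time), duration (mean
   run length, ms), mean GFP, and per-state GEV. Transition probabilities
   are estimated on the run sequence (consecutive duplicates collapsed,
   epoch boundaries never bridged), giving a zero-diagonal row-stochastic
   matrix — the first-order Markov description of state switching.
3. **How much alpha, net of the background?** The channel-averaged Welch
   spectrum is decomposed over 1–40 Hz into a knee-free aperiodic component
   `log10 P(f) = offset − exponent·log10 f` plus Gaussian peaks; the
   highest-power peak with center frequency inside 8–12 Hz provides the
   aperiodic-adjusted alpha power (log10 units above the background) and
   alpha center frequency.

Model-order selection uses the two standard criteria: GEV
(`Σ(GFP_t·C_t)²/ΣGFP_t²`, to be maximized) and the CV criterion
(`σ̂²·((N−1)/(N−1−k))²` with N channels and σ̂² the mean per-sample variance
orthogonal to the assigned template, to be minimized). Both are min–max
normalized across the candidate range k = 2…8 and the k maximizing
(normalized GEV − normalized CV) is chosen, ties toward smaller k; a
configured `fixed_k` overrides the criterion, since published work often
fixes k by judgment for comparability.

## Key parameters (defaults)

| parameter | default | unit | rationale |
|---|---|---|---|
| band-pass | 1–45 | Hz | standard broadband microstate range |
| notch | 50 | Hz | mains (configurable; 60 for the Americas) |
| epoch length | 4 | s | common resting-state segmentation |
| bad-channel threshold | ±200 (strict >) | µV | per-epoch excursion rule |
| GFP peak spacing / floor / band | 10 ms / 20 µV / ±1 SD | — | peak reliability constraints |
| peaks per subject | ≤ 1000 | — | uniform seeded subsample beyond the cap |
| k range / restarts / iterations | 2–8 / 50 / 2000 | — | clustering search effort |
| Welch window / overlap | 2 s / 50 % | — | 0.5 Hz resolution resolves 1 Hz-wide peaks |
| fit range / widths / max peaks / threshold | 1–40 Hz / [1,10] Hz / 10 / 1 SD | — | parameterization settings |
| alpha band | 8–12 | Hz | developmental alpha |
| FDR family size | 6 | — | one family per instrument's six scores |
| outlier limits | >3 MS cells, >4 TP cells | — | Tukey 1.5·IQR fences per column |

## The synthetic generator

`msalpha.synth` produces recordings whose generative structure matches what
the pipeline assumes, with every estimand known:

- **States**: k zero-mean unit-norm topographies (mutually uncorrelated by
  construction; the zero-mean subspace limits k to n_channels − 1).
- **Dynamics**: a discrete-time semi-Markov chain — successor states drawn
  from a zero-diagonal row-stochastic matrix, dwells geometric with
  per-state means. Geometric dwells are memoryless, so the first-order TP
  estimator on run sequences is unbiased; the stationary occupancy
  `occ_i ∝ π_i·d_i` (π the embedded chain's stationary vector) is available
  analytically and the cohort builder inverts it to hit target coverages
  exactly.
- **Signal**: the active template scaled by a sinusoidal envelope at the
  subject's alpha center frequency with a fresh random phase per dwell;
  the rectified envelope yields GFP peaks at twice the alpha rate, as in
  resting EEG.
- **Background**: FFT-shaped 1/f^χ Gaussian noise (band-limited to ≥ 1 Hz so
  the variance budget lives in the analysis band), spatially mixed by a
  random orthogonal matrix fixed per subject, plus a small white
  sensor-noise floor (0.1 % variance); scaled to a requested
  signal-to-noise variance ratio (default snr = 4).
- **Cohort**: two groups (default 59/group, 47 male / 12 female, 62
  channels at 1000 Hz, 80 s — configurable; validation studies use 10–50
  per group, 16–32 channels at 250 Hz, 40–60 s to keep runtimes in
  minutes). Group effects are additive shifts on occupancy, alpha center
  frequency and alpha power (defaults: −0.05 coverage on state C, +0.03 on
  state A, −0.4 Hz alpha CF in the ASD-labeled group). Clinical scores are
  linear functions of ground-truth parameters plus Gaussian noise, clipped
  to instrument ranges (ABC 0–158, SRS 0–195, clipping logged), with
  default couplings targeting zero-order |r| ≈ 0.4 for a handful of
  parameter–subscale pairs (sensory ↔ occurrence D negative,
  communication ↔ duration C positive, social motivation ↔ coverage A
  positive, restrictive/repetitive ↔ coverage E negative) and totals
  anchored near ABC 51 and SRS 101. Because subscale noise is independent,
  simulated totals have somewhat smaller SDs than the clinical anchors.

What the generator does **not** emulate: ocular/EMG artifact morphology,
volume conduction from a head model, heavy-tailed or nonstationary noise,
age-dependent spectral maturation, polarity asymmetries. Passing tests
therefore demonstrate estimator correctness under the model's own
assumptions — they are necessary, not sufficient, evidence about behavior
on real recordings.

## Numerical choices

- **Filters**: zero-phase (forward–backward) Butterworth band-pass and IIR
  notch, so microstate timing is never phase-shifted; per-edge order 6 keeps
  the 1–45 Hz passband within ~1 dB and attenuates 60 Hz by >99 %.
- **Clustering**: restarts seeded from random map selections; an emptied
  cluster is reseeded from the worst-fit map; convergence on the relative
  change of residual variance (tol 1e-8); the best restart by GEV wins.
  Template polarity is normalized (largest-|value| channel positive) so
  outputs are reproducible; assignment ties break toward the lower template
  index.
- **Peak selection**: conflicting GFP peaks within the spacing window keep
  the larger; the ±1 SD band applies to the peak-GFP distribution after the
  amplitude floor; subsampling beyond the cap is uniform with a seeded RNG.
- **Aperiodic fit**: ordinary least squares in log–log space, then a
  lower-envelope re-fit excluding points whose positive residual exceeds the
  2.5th percentile — keeps the line off oscillatory bumps; deterministic.
- **Peak fit**: iterative largest-residual extraction with half-height width
  estimates clipped to the width limits; guesses whose centers lie within
  one combined SD are merged (keeping the taller) before a joint bounded
  multi-Gaussian refinement (centers movable ≤ 2 SD) — both guards prevent
  one bump from being split into two overlapping Gaussians, which is the
  dominant failure mode of iterative peak extraction on noisy spectra. A
  1e-8 absolute height floor keeps log-power roundoff from seeding peaks.
- **Back-fitting** applies no temporal smoothing by default; a
  minimum-segment merge exists but is off, because smoothing systematically
  inflates durations and deflates occurrences.
- **Occurrence convention**: runs per second of *assigned* time, which makes
  coverage = occurrence × duration/1000 an exact identity (verified by a
  fuzz suite). Runs truncated by epoch boundaries count once.
- **Degenerate inputs** are errors, not silent results: zero-variance maps
  in correlations, all-zero GFP in GEV, constant alpha power in the
  modulation contrast, zero-variance residuals in semi-partials, fewer than
  4 subjects in the outlier screen.

## Statistical layer

Group contrasts are two-sample pooled-variance t tests with Cohen's d;
correlations are Pearson (Spearman for instrument totals, which are skewed)
with Benjamini–Hochberg adjustment at a configurable family size (default
6, one family per instrument's score set; when more tests than the nominal
family are run, the larger count is used). The semi-partial correlation
residualizes the microstate parameter on alpha power only — the stated
direction of control — and correlates that residual with the clinical
score; p is two-tailed on n − 3 df. The alpha-modulation contrast is a
deliberately simple fixed-effects OLS (parameter mean-centered within
state, stacked, regressed on alpha power + group) standing in for a
state-random-intercept mixed model: it preserves the tested contract (sign
and presence of the alpha slope) without re-implementing off-the-shelf
mixed-model machinery. The literal reading of "values beyond the
quartiles" as outliers would discard half the data; the conventional Tukey
1.5·IQR fences are used instead, with zero-width IQR flagging nothing.

## Validation design and problem sizes

- Template/coverage recovery: 20 subjects (10/group), 5 states, 32
  channels, 250 Hz, 60 s/subject, snr 4; recovered templates matched to
  truth by Hungarian assignment on |spatial correlation|. Coverage recovery
  is scored against the *realized* ground-truth label sequence: at 60 s,
  finite-dwell sampling alone caps the realized-vs-analytic-occupancy
  correlation near 0.77, so the analytic stationary vector is not the
  truth of any single recording.
- Model-order selection: 20 replicates of 4-subject pools (same signal
  conditions, 8 restarts) across k = 2…8.
- Markov recovery: ≥ 2×10⁴ transitions from a random 5-state matrix.
- Spectral recovery: exactness on noiseless spectra; 100 noisy replicates
  (log-noise SD 0.05); a 20-spectrum cross-check against an independent
  single-shot joint nonlinear fit of the full aperiodic+peak model.
- Calibration: 200 null cohorts (type-I error of the coverage contrast,
  n = 50/group) and 100 effect cohorts (power for a 0.05 coverage deficit).
  These studies measure coverage directly from simulated label sequences —
  the quantity under test is the statistical layer, not the signal path.

## Known limitations

- The artifact rejector is a plain amplitude + gradient threshold screen;
  real blink/EMG morphology requires ICA or regression methods out of scope
  here.
- Aperiodic fitting is knee-free by design; spectra with a clear knee will
  bias the exponent.
- Subjects without an 8–12 Hz peak propagate missing alpha values and are
  excluded pairwise from alpha-dependent analyses.
- Group-level clustering pools all subjects' peak maps into one template
  set; a two-level (subject-then-group) variant is not implemented.
- Canonical A–E archetype matching requires real electrode positions; on
  synthetic montages templates are ordered by descending per-state GEV, or
  matched to a supplied reference set.
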