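# Methods

This note documents the models and procedures implemented in
`vocrecall`, the parameters that matter, and the design choices made
where the underlying experimental method left details open.

## Noise-band vocoder

The vocoder simulates the spectrally degraded percept of a cochlear
implant. The signal path per channel:

1. **Analysis filtering.** The 80–8000 Hz range is split into
   `n_channels` logarithmically spaced bands (edge *k* at
   `f_lo · (f_hi/f_lo)^(k/N)`, so every channel spans an equal number of
   octaves). Each band is isolated with a 3rd-order Butterworth
   band-pass applied once (causal). A 3rd-order design has an 18
   dB/octave asymptotic rolloff per side; zero-phase two-pass filtering
   would double that, which is why single-pass filtering is used
   throughout.
2. **Envelope extraction.** Half-wave rectification followed by a
   2nd-order Butterworth low-pass at 300 Hz; residual negative
   excursions from filter ringing are clamped to zero. The rectifier
   and the envelope-filter order are conventions of the noise-band
   vocoding literature rather than uniquely determined choices, so both
   are configurable (`VocoderConfig.env_lpf_order`, `env_cutoff_hz`).
3. **Synthesis.** Fresh white Gaussian noise — one independent stream
   per band, seeded from `(rng_seed, band_index)` for bit-exact
   reproducibility — is passed through the same band-pass, multiplied by
   the band envelope, and (by default) rescaled to the RMS of its
   analysis band before summation. Per-band RMS matching preserves the
   input's spectral profile; it can be disabled
   (`per_band_rms_match=False`) to mimic pipelines that only match
   levels globally.
4. **Level matching.** The summed output is rescaled so its overall RMS
   equals the input's (relative error < 1e-3). Silent input returns
   silence rather than dividing by zero.

Numerical guards: a band whose upper edge reaches 0.95 × Nyquist is
capped there with a warning (filter stability); steady-state
measurements discard a 50 ms settling window.

`measure_rolloff` evaluates the analytic (analog-prototype) Butterworth
magnitude over one octave starting three octaves above the upper band
edge. Close to the edge the two skirts of a band-pass interact and the
slope is still curving toward its asymptote; by 8× the edge it has
settled to the nominal 6·order dB/octave. The digital (bilinear) filter
is intentionally not used for this measurement: frequency warping makes
its apparent slope steeper near Nyquist, which would misstate the
design's dB/octave figure.

## Stimulus preparation

Segmentation is text-level: boundaries are word indices meaning
"interrupt before word *k*" (0-based). Deciding where a major clause or
sentence boundary falls is linguistic annotation and is treated as
input; `heuristic_boundaries` (split at sentence-final punctuation and
comma+conjunction) exists only to build fixtures and is explicitly
non-linguistic.

The counterbalanced design assigns each participant all eight passages
(four high-, four low-predictability), one per cell of the
2 (format) × 2 (clarity) × 2 (predictability) within-subject design.
Within a block of eight participants a fixed cyclic rotation places
each passage in each format × clarity cell exactly twice; the seed only
permutes which participant receives which rotation row, so balance is a
structural property of the square and holds for every seed. Any
rotation with the equal-exposure property would do; the cyclic one was
chosen for transparency and testability.

## Propositional scoring

A proposition is a predicate with ordered arguments, each an atomic
lemma or a reference to another proposition; references must form a
DAG. Three levels are assigned with strict precedence: roots (flagged
as topic-bearing) are **main**; a non-root referencing any main
proposition is **mid**; everything else is **detail**. A proposition
referencing both a main and a detail proposition is therefore mid.

Scoring is binary with no half credit: a proposition counts as recalled
when its predicate lemma and all atomic-argument lemmas occur in the
lemmatized transcript, directly or through the bank's synonym lexicon.
Matching is bag-of-lemmas over the whole transcript — free recall is
order-free, and the convention scores content rather than order.
Propositional arguments impose no extra lexical requirement; the
referenced proposition is scored on its own.

Two deliberate simplifications:

* **Lemmatizer.** A deterministic suffix stripper (plural -s/-es,
  verbal -ed/-ing with consonant undoubling and Porter-style final-e
  restoration, plus a small irregular table). It is applied identically
  to bank lemmas and transcript tokens, so consistency matters more
  than linguistic coverage; it is swappable for anything better.
* **Synonyms.** An explicit per-bank lexicon. Human scorers' judgments
  of "close synonyms that preserve meaning" cannot be reproduced
  algorithmically; the lexicon makes the tolerance explicit and
  auditable.

## Synthetic-data generator

The generator produces datasets with the statistical structure of a
24-participant × 8-passage discourse-recall experiment so the analysis
stage can be tested for parameter recovery and error calibration.

### Recall model

Linear-probability on the percentage scale. The expected recall
percentage of a design cell is

    E[pct] = K + Lc(level)·g(pred)
           + d_pred·[high] + d_format·[selfpaced] + d_clarity·[clear]

with `Lc` the hierarchy contribution (0, d_mid_detail,
d_mid_detail + d_main_mid for detail/mid/main) **centered over the
three levels**, and the predictability-specific hierarchy gain
`g(high) = 2/(1+a)`, `g(low) = 2a/(1+a)` for attenuation
`a = interaction_atten` (mean gain 1; low/high slope ratio exactly
`a`). `K` anchors the (detail, low, vocoded, continuous) cell at
`base_pct`.

The centering is the load-bearing choice: it makes every marginal
contrast of the balanced design equal its calibration delta exactly, so
the printed effect sizes (7.85, 9.78, 5.61, 6.83, 4.78 percentage
points) are literal generator parameters and parameter-recovery tests
have exact truths. An uncentered "attenuate the level contribution
under low predictability" construction would leak the interaction into
the predictability and hierarchy marginals (e.g. the high−low marginal
would become ≈ 11 pp at the default attenuation). A linear rather than
logistic construction is used for the same reason: the published
effects are percentage points, and a linear model makes them exact by
construction. Feasibility (all 24 fixed-effect cell means inside
[0, 100]) is checked before any sampling; with random effects the
per-trial propensity is clamped into [0, 1] just before binomial
sampling, a rare event at the defaults (top cell ≈ 75% with ~10 pp of
random-effect SD).

On top of the fixed part: participant intercept (SD 8 pp), item
intercept (SD 5 pp), item-by-level random slope (SD 2 pp per level
step), optional cell-level residual (default 0), then
`n_recalled ~ Binomial(n_props, p)` with `n_props` = 10/15/20 for
main/mid/detail. The participant intercept loads on the standardized
R-span score (loading 0.5) and on the log pause tendency (0.6), with
the remainder independent; loadings must satisfy
`0.5² + 0.6² ≤ 1`.

All of base level, attenuation, random-effect SDs, loadings, and
proposition counts are invented defaults — the published summary
determines only the five marginal deltas, the attenuation's existence
and direction, and the covariate and pause moments. Every one of them
is exposed in `EffectCalibration` (packaged as
`data/default_calibration.json`).

### Participants

R-span and vocabulary are rounded truncated normals on their score
ranges ([0, 15] and [0, 20]); the truncated distribution's location is
solved numerically so its mean equals the target sample mean (9.42 and
13.00) — naive truncation at 15 would drag the R-span mean down to
~9.22. PTA is normal (6.88, 4.12). Pause tendency is lognormal with
unit median.

### Pauses

`log pause = mu0 + sigma_p·z_i + sigma_g·z_ij + sigma_e·eps`, lognormal
for positivity and the right skew implied by SD (2.71 s) exceeding the
mean (2.43 s). The total log-variance `ln(1 + (2.71/2.43)²) ≈ 0.81` is
moment-matched analytically and split into a participant component
(`sigma_p = 0.5`, the pause-tendency spread), a participant-by-passage
component (`sigma_g = 0.3`), and a residual (≈ 0.68); the split is a
package choice, constrained only to sum to the matched total. The
participant-by-passage latent `z_ij` is drawn during recall simulation
and shared with the pause generator, adding
`0.3 · sd_participant` pp per z to that passage's recall propensity —
this is what produces the within-participant "paused longer on this
passage, recalled it better" coupling, while the tendency/intercept
correlation (0.6) produces the between-participant coupling. Clarity
deliberately has no effect on pauses. One pause per segment transition;
synthetic passages default to 10–11 segments (the study-like geometry
of ~10.5 segments of ~8 words).

## Analysis stage

The response is the percentage of propositions recalled per
participant × passage × level cell — matching how such data are
conventionally summarized and reported — rather than a trial-level
binomial GLMM. Fixed factors are treatment-coded (reference levels:
detail, vocoded, continuous, low). Random structure: participant and
item intercepts plus an item-by-level slope, fitted as variance
components within a single super-group (how crossed random effects are
expressed in statsmodels' MixedLM). Estimation is ML, not REML, because
fixed effects are compared by likelihood-ratio tests.

* **LRTs.** χ² = 2·Δlog-likelihood, df = difference in fixed-parameter
  counts. Testing a main effect removes the effect together with its
  retained interactions, which is what yields 4 df for the semantic
  hierarchy (2 + 2) and 3 df for predictability (1 + 2) when the
  hierarchy × predictability interaction is retained.
* **Reverse selection** starts from all six two-way interactions among
  the four factors (optionally plus the four-way as a check) and
  repeatedly removes the least-significant non-significant interaction,
  refitting until all retained terms are significant. Main effects are
  never removed, nor is an interaction nested inside a retained
  higher-order one. Note the procedure's intrinsic false-retention
  rate: with six null interactions the last survivor tests significant
  with probability ≈ 1 − 0.95⁶ ≈ 0.26, so "everything removed" is the
  ~74% outcome, not a certainty — the tests encode that expectation.
* **Marginal effects and slopes** are computed from unweighted
  cell-mean percentages, not model coefficients, to stay model-agnostic
  (for the balanced design and additive model the two coincide to
  machine precision, which is itself a test). CIs are participant-level
  bootstrap, seeded. Because only participants are resampled, the CI
  understates uncertainty for between-item factors: predictability is
  carried by just 4 + 4 passages, so a single dataset's predictability
  estimate scatters with an item-sampling SD of ≈ 3.8 pp around the
  generating value, far more than its participant-bootstrap CI
  suggests. Across replicates the estimator is unbiased, which is what
  the recovery checks measure. The hierarchy slope is the linear
  contrast (main − detail)/2 with level spacing (−1, 0, +1).
* **Pause analyses.** Between participants: OLS of participant mean
  self-paced recall on participant mean pause, F with (1, n−2) df.
  Within participants: mixed model of per-passage recall on the
  person-centered passage mean pause with participant intercepts,
  1-df LRT. Degenerate regressors (constant pauses) raise rather than
  returning a silent zero.
* **Covariates.** Each of R-span, vocabulary, PTA is standardized and
  added to the final model as a continuous fixed effect, 1-df LRT. No
  multiple-testing correction anywhere, matching the convention of
  reporting raw LRT p-values.

Numerical choices: optimizers are tried in the order lbfgs → bfgs →
cg → nm, skipping ones that fail to converge or that land on a
variance-component boundary where the Hessian is singular; if the
item-by-level slope itself prevents convergence it is dropped with a
warning recorded in the fit diagnostics; outright non-convergence
raises, never silently degrades.

## What the synthetic data do and do not establish

The generator reproduces the design's balance, the printed marginal
effect sizes, the attenuation direction, the covariate moments, and the
pause moments and couplings. It does **not** reproduce: actual passage
content or transcripts (recall is generated at the proposition-count
level), serial-position or output-order structure in recall, floor
effects in specific cells, non-lognormal pause features (bimodality,
key-repeat artifacts), or any dependence of pauses on clarity (absent
by design). Passing recovery tests therefore shows the pipeline is
correct and calibrated for data of this structure — not that the human
data would satisfy the model's assumptions. The published test
statistics from the human sample (specific χ² and F values) are not
reproduction targets, since the raw data are not deposited; what is
checked instead is that under null settings each test's type-I error is
compatible with α = 0.05 and that real effects of the calibrated size
are detected.

Problem sizes used by the shipped checks: 200 replicates of the 24 × 8
design for recovery and type-I calibration (the replicate count that
makes the Monte-Carlo SE of the noisiest contrast, predictability at
≈ 3.8 pp per replicate, about 0.27 pp); a 2640-participant cohort
(~100k pauses) for the pause-moment check, sized so the clustered
sampling error of the mean (dominated by the participant component,
≈ 1.3/√n_participants) sits inside the ±0.05 s tolerance.

## Known limitations

* The LMM-on-proportions response is heteroscedastic by construction
  (binomial variance differs across levels and cells); the LRTs remain
  approximately calibrated at the design's size, but a trial-level
  binomial GLMM would be the stricter model.
* The lemmatizer is a heuristic; scoring real transcripts benefits from
  a curated synonym lexicon per bank.
* The vocoder models spectral degradation only — no frequency-place
  mismatch, no current-spread smearing, no sine-carrier or pulsatile
  (ACE/CIS) strategies, no loudness mapping, no intelligibility
  prediction.
* `aggregate_scores` expects a complete participant × passage score
  map; partial datasets must be filtered upstream.
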