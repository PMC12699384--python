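# Methods

This note documents the models and numerical choices behind `revaci`: what is
simulated, how the estimators are defined and solved, and what the defaults
mean.  It complements the README (user-facing) and the docstrings
(API-facing).

## 1. Stimuli and calibration

All audio lives in a `Waveform` (mono float samples, rate, dBFS reference).
Levels follow a full-scale convention: a waveform with RMS 1.0 is presented at
`dbfs_ref` dB SPL (default 100), so `set_level(w, L)` rescales to RMS
`10**((L-dbfs_ref)/20)`.  Target-in-noise mixing supports two SNR
conventions:

- `broadband_rms` — the target RMS over its own support is `snr_db` above the
  masker RMS in the same window;
- `es_over_n0` — `snr_db` is `10*log10(Es/N0)` with `Es` the target energy
  (sum of squared samples over the rate) and `N0` the masker power spectral
  density (power / Nyquist bandwidth): the classic tone-in-noise measure.

Maskers are pure functions of a `NoiseSpec` (kind, duration, rate, seed).
White and pink noise are exact (FFT amplitude shaping for pink: power
∝ 1/f, i.e. −10 dB/decade).  Bump noise multiplies the short-time
log-magnitude of a white seed by sparse 2-D Gaussian bumps (default peak gain
10 dB) and resynthesises with the original phases; MPS noise low-passes the
log short-time magnitude in the 2-D modulation domain (default temporal
cutoff 40 Hz) and reconstructs the phase with a few Griffin–Lim iterations.
Both are *property-matched approximations*: they keep a flat expected
long-term spectrum while boosting low-rate envelope fluctuations, but they do
not bit-match any particular legacy generator.  Assembled stimuli get 10-ms
raised-cosine ramps by default.

### Seeding

One master seed determines a whole session.  Derived streams use a counter
scheme on `numpy.random.SeedSequence`:

- masker `k`: `SeedSequence((master_seed, 0, k))`;
- trial scheduling: tag 1; per-trial draws (rove offset, interval order,
  responder internal noise): `SeedSequence((master_seed, 2, trial_index))`.

Because nothing carries RNG state across trials, any single waveform or trial
is regenerable in isolation, and an interrupted session resumed from an
archive is bit-identical to an uninterrupted run.

## 2. Experiment engine

`run_experiment(config, responder)` iterates the schedule (a seeded
permutation with exactly `n_presentation` trials per target), synthesises the
stimulus (optional), calls the responder, logs the trial, and updates the
adaptive track.  The experimental variable (expvar — here the mixing SNR in
dB) is governed by:

- `constant` — fixed at `startvar`;
- `transformed_updown` — move down after `n_down` consecutive correct, up
  after `n_up` consecutive incorrect, step `stepsize`;
- `weighted_updown` — 1-up/1-down with asymmetric steps: correct
  ⇒ `expvar -= stepsize`, incorrect ⇒ `expvar += stepsize * weighted_ratio`.
  Zero expected drift requires `p·S_down = (1−p)·S_up`, so the equilibrium
  percent correct is `S_up/(S_up+S_down)`; the default ratio 2.4130 targets
  70.7 %.

The step size is multiplied by `adapt_stepsize_factor` (default 0.5) every
two reversals and floored at `min_stepsize` (default 0.4144, an arbitrary
configurable floor); expvar is capped at `maxvar`.  `step_resolution`
"multiplicative" applies steps as factors instead of increments.  Each block
of `session_len` trials restarts the track at `startvar` with the starting
step size, and reversal counting restarts with it.  Probe trials (every
`probe_periodicity`-th presentation) are shown at `startvar + probe_boost`,
are excluded from the staircase and from reversal counting, and may exceed
`maxvar` — they exist to keep a participant engaged, not to track.

## 3. Artificial listener

The observer is a template-matching optimal detector.  Its front-end maps
audio to a frequency × time matrix; the default is a gammatone spectrogram:

- channel centers equally spaced on the ERB-number scale
  `E(f) = 21.4·log10(0.00437 f + 1)` (Glasberg–Moore).  The default analysis
  grid spans 45.8 Hz (1.69 ERB) to 8 kHz in 0.5-ERB steps — 64 channels, the
  highest at ERB-number 1.69 + 63·0.5 = 33.19, slightly below 8 kHz (8 kHz
  itself sits at ≈33.29; the grid point is what the axis reports);
- per channel a 4th-order gammatone magnitude response
  `[1+((f−fc)/b)²]⁻²`, `b = 1.019·ERB(fc)`, applied in the spectral domain;
- a simplified inner-hair-cell envelope: half-wave rectification followed by
  a first-order low-pass at 1 kHz (configurable), averaged into half-open
  10-ms bins.  The envelope stage is positively homogeneous of degree 1.

The template is the mean of `templ_num` (default 10) differences
frontend(target-2 stimulus) − frontend(target-1 stimulus), each on a fresh
masker mixed at the supra-threshold level `det_lev`, normalised to unit
Euclidean norm (an all-zero difference is flagged, not normalised).  The
difference-of-targets convention means a single inner product discriminates
and positive classification-image weights correspond to "response 2".

Decisions: `dv = ⟨representation, template⟩ + ε`, `ε ~ N(0, in_var)`.
Two-interval trials pick the interval with the larger dv (exact tie →
interval 1).  Yes/no trials compare dv to a criterion.  The *stateless*
`decide()` uses `thres_for_bias` directly; the session-level
`TemplateObserver` additionally centers the criterion, because the envelope
front-end is nonnegative and the masker contributes a large positive pedestal
to dv — with a fixed raw threshold the observer would answer one class
almost always.  The criterion is initialised as the mean template projection
of both targets mixed at `startvar`, then tracked as a slow exponential
moving average of observed dv (rate 0.02); `thres_for_bias` offsets it for
bias experiments.  This makes the observer approximately unbiased while
leaving its trial-to-trial decisions driven by masker fluctuations plus
internal noise — the regime reverse correlation requires.

## 4. From session to tensor

`dataload` regenerates, per trial in presentation order, the masker (default)
or the full stimulus, applies the representation (`gammatone`, plain `spect`
magnitude STFT, or `coarse_grid` band/segment energies), crops to `t_limits`
/ `f_limits`, and stacks a trials × n_f × n_t `StimulusTensor`.  The
`coarse_grid` option reproduces the classic coarse layout of early
tone-in-noise work (e.g. a 5×5 grid of 50-Hz × 100-ms cells).

Trial selection applies, in this fixed order: trial type (all / correct /
incorrect / target-1 / target-2) → staircase convergence exclusion (drop
trials of each block before its Nth reversal) → expvar window → response
balancing (`no_bias`: remove majority-response trials, most extreme
|expvar − mean| first — the mean over the trials surviving the earlier
filters — until the classes are equal).  Probes are always excluded; an empty
result raises with a per-filter attrition report.

Per-pixel z-scoring across trials (recommended, default in the model front
door) sets each pixel to mean 0, SD 1; constant pixels become 0 and are
flagged.  Z-scoring makes the correlation and weighted-sum images exactly
proportional and puts GLM weights on a common unitless "perceptual weight"
scale.

## 5. Estimators

Responses are coded `r ∈ {0,1}` with 1 = "response 2" *for every method*, and
positive weights always favour response 2.  (The probit model is often
written for P(response 1); we flip its sign so all five estimators share one
sign convention.)

- `correlation` — per-pixel Pearson correlation of pixel values with `r`;
  per-pixel t statistics and two-sided p-values are attached.
- `weighted_sum` — `E[N | r=1] − E[N | r=0]`.
- `glm` — maximum-likelihood probit, `P(r=1) = Φ(N·w + c)`, by damped
  Newton/IRLS with backtracking.  Drift toward perfect separation
  (|η| > 25) emits a warning recommending a penalized fit and returns the
  current iterate flagged unconverged; true non-convergence raises with the
  objective trace.
- `glm_L2` — adds `λ · Σ (first differences between neighbouring pixels)²`
  over both axes (a smoothness prior); solved by penalized IRLS.
- `glm_L1_GB` — probit on a Gaussian-pyramid basis with an L1 penalty
  `λ‖β‖₁`; the image is `design·β`.  Level *l* of the pyramid (default
  levels 2–5) places unit-peak 2-D Gaussians of σ = 2^(l−1) bins on a grid of
  spacing 2^(l−1), so element counts shrink as scales coarsen.  Solved by
  FISTA with an adaptive restart and a per-iteration exact Newton refinement
  of the (unpenalized) intercept; Lipschitz constant 1.1·‖Z‖₂² (the probit
  NLL curvature in η is < 1.1).  Tolerance 1e-6 relative objective, max 10⁴
  iterations (CV scoring fits use 3e3 iterations at 1e-5 — the final fit at
  λ* is always full precision).

The intercept is never penalized.  **λ is per-trial**: internally the
penalty is multiplied by the number of trials, i.e. λ weighs the penalty
against the *mean* negative log-likelihood.  This keeps λ values comparable
across dataset sizes and makes the default search start λ₀ = 5 a genuinely
over-penalized endpoint (β = 0, image flat, c = Φ⁻¹(mean r)).

### Hyperparameter search

`search_lambda` walks a geometric grid descending from λ₀ = 5 by a factor 5,
scoring each λ by 10-fold cross-validated deviance (−2·held-out
log-likelihood, probabilities clipped at 1e-12).  Folds are a seeded,
response-stratified, near-equal partition, shared with downstream validation
so the goodness-of-fit numbers are directly comparable.  The descent stops
when the deviance exceeds the running best by the precision fraction (0.05)
or after 8 factor steps; geometric bisection then refines around the minimum
until no candidate improves by the precision fraction or `maxiter` = 30 fits
have been spent.  λ* is the path's argmin; ties resolve to the smaller λ.
On simulated observer data the path is U-shaped: the large-λ endpoint
degrades toward the intercept-only deviance and the small-λ end rises with
overfitting.

## 6. Validation

- **Permutation test** — `n_perm` (default 100) random permutations of the
  response vector (class counts preserved by construction) each yield a null
  image; per pixel the [5th, 95th] null interval is formed with the
  *outward* order-statistic convention (`lower`/`higher`), which puts the
  nominal null coverage at ≈90 % for n_perm = 200 (interpolated percentiles
  under-cover slightly at small n_perm).  Pixels of the observed image
  outside the interval are flagged significant.  No multiple-testing
  correction is applied by default; a Benjamini–Hochberg helper (`fdr_mask`)
  is provided.
- **Cross-validation** — each stratified fold held out once; accuracy uses
  the 0.5-threshold rule on Φ(η), deviance is −2·held-out log-likelihood;
  the report carries per-fold values, means, and ±1.96-SE intervals.
- **Cross-prediction** — a *fixed* image (weights unchanged; intercept
  optionally refit by 1-D likelihood maximisation) evaluated on another
  dataset over the same folds as the within-dataset CV.
- **Convergence diagnostics** — partial images on the first k·block trials;
  Pearson correlation with the full-data image (the last point is exactly
  1 by construction, so the track measures stabilisation, not truth) and the
  cue-to-noise ratio: mean squared weight in a known-cue region over a
  known-irrelevant region.  A uniform-|weight| image gives exactly 1; the
  ratio is scale-invariant; a zero denominator returns +inf with a warning.

## 7. The simulation preset and what it shows

`revaci.presets` fixes the canonical study conditions used by the tests and
the worked example: a yes/no detection of a 100-ms, 500-Hz tone gated into
the middle of a 300-ms white-noise masker at 65 dB SPL (5 kHz rate), 400
trials per block, weighted 1-up/1-down staircase (steps 2 → floor 0.4144,
ratio 2.4130), template observer with a gammatone-envelope front-end
(200–2000 Hz; 0.5-ERB spacing for estimation studies, 1-ERB for quick
loops).  The observer's internal-noise variance (4e-7) is set so the
internal-noise SD is on the order of the masker-driven fluctuation of the
decision variable — a listener whose errors reflect both external and
internal noise, which is the regime in which classification images are
informative.  Under these conditions a 4,000-trial session yields a
correlation image that correlates ≈0.8 with the observer's template, and the
L1-Gaussian-basis fit at λ* ≈0.92 — the penalized estimator dominates, and
its cross-validated accuracy sits ≈19 points above chance.

What the preset does **not** emulate: human lapses and bias drift,
across-session learning, memory or attention effects, speech targets, and
any nonlinearity of real auditory processing beyond the envelope front-end.
Passing tests demonstrate internal consistency and estimator behaviour under
a known ground truth, not properties of human listeners.

## 8. Numerical details and edge cases

- Probabilities are clipped at 1e-12 before logs; deviances stay finite.
- Correlation on a constant pixel is 0 (flagged), never NaN.
- Two-interval ties break to interval 1, documented and deterministic.
- `zscore∘zscore = zscore` to 1e-10; representations of all-zero audio are
  all-zero.
- Session archives are plain JSON + CSV (floats at 17 significant digits,
  parsed with round-trip precision); waveform checksums (SHA-256 prefix)
  guard seed-based regeneration; tensors and results use HDF5.
- Problem sizes in the test-suite simulations (trial counts, channel counts,
  masker durations) are the package's chosen desk-scale study conditions;
  they trade spectral coverage for fast, fully reproducible end-to-end runs.

## 9. Known limitations

- Bump/MPS maskers approximate the intended noise statistics; their exact
  legacy synthesis is out of scope.
- Within-participant CV and permutation machinery accept any estimator, but
  GLM-based permutation tests are computationally heavy (a cost warning is
  the only guard).
- The L2 smoothness operator is the squared first-difference Laplacian-like
  penalty; other discretisations would give slightly different images.
- Only the optimal-detector back-end is implemented for the artificial
  listener; speech-oriented decision back-ends are out of scope.
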