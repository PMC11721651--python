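# Methods

`resogest` analyses whether the kinematic expressivity of a story narrator's
co-speech gestures drives emotional (electrodermal) resonance among the
participants of a conversational storytelling. This note documents the
models and procedures the package implements, the choices made where the
design was genuinely open, and what the synthetic corpus generator does and
does not emulate.

## Data model

A *recording* is a dyadic or triadic conversation; each *story* within it
has one narrator, annotated onset/offset and a manually identified climax
span. Gestures carry a phase segmentation (preparation, nucleus, hold,
retraction) and five human-coded binary parameters — Size (SZ), Force (FO),
Character viewpoint (CV), Silent gesture (SL), Multiple articulators (MA).
Two further binary parameters are derived from the segmentation:

- **HO** (hold phase): present iff any phase segment is labelled `hold`;
- **ND** (nucleus duration): yes iff the gesture's total nucleus duration
  *strictly* exceeds the arithmetic mean nucleus duration of its story.

The **Gesture Expressivity Index** is the unweighted mean of the seven
binaries, `GEI = (#yes)/7`, so its range is exactly {0/7, …, 7/7}. Missing
codings are an error — no imputation.

Contextual covariates per gesture: `G_position_rel`, the gesture's relative
position in its story — gesture *i* of *n* (sorted by onset) gets
`(i−1)/(n−1)`, a single-gesture story the midpoint 0.5 (the formula is
undefined there and the midpoint is the unbiased choice); `G_quote`, a
fuzzy co-quote flag set when any quote's start lies within ±1.5 s of the
gesture onset (symmetric distance — "within 1.5 s" is read as absolute
difference); `Sentiment`, the mean word-level composite sentiment of the
IPU with maximal temporal overlap with the gesture (ties break to the
earlier IPU; no overlapping IPU gives the neutral 0). Word-level sentiment
scores in [−1, 1] are consumed as data; any lexicon that produces composite
word scores can feed them.

All times are seconds on one shared clock per recording (annotation
sources in milliseconds are converted on read); every window in the package
is half-open `[start, end)` so a 4 Hz sample never counts twice across a
boundary.

## EDA response detection

Skin conductance is sampled at 4 Hz in 0.01–100 μS. For each gesture and
each participant, the response window spans the gesture plus a 1.5 s
post-gesture pad that absorbs typical 1–3 s SCR latency. The window's
**amplitude** is the maximal trough-to-peak rise, `max_{i<j}(x_j − x_i)`
floored at 0 — the standard SCR amplitude reading, robust to a declining
tonic baseline (a last-minus-first reading would miss transient waves). A
response is **specific** when the amplitude strictly exceeds 0.05 μS. A
gesture **resonates** when ≥ 2 participants show specific responses within
its window; the narrator counts toward the tally (an optional strict mode
additionally requires the narrator's own response). "Concurrent" is
operationalised at window level, not sample-level peak overlap, because
resonance is defined per gesture. Traces are not smoothed or detrended by
default, and overlapping gestures get independent windows.

Known interplay: with SCR latency up to 3 s and a 1.5 s pad, a *short*
gesture's window can end before a late response begins. Detection-recovery
checks therefore use a regime with well-separated (4–6 s gaps), longer
gestures (nucleus median 1.8 s), strong SCRs (0.3–0.5 μS) and quiet traces
(noise sd 0.005 μS); under those conditions window classification recovers
≥ 95% of true response indicators in both directions. At tight gesture
spacing, windows can additionally capture a *neighbouring* gesture's rise,
which couples detected responses to window length and hence weakly to the
duration-linked components (HO, ND); this is a property of the windowing
method itself, not of the implementation.

## Inter-rater reliability

For two raters on binary codes, the package reports percent agreement and
the Holley–Guilford G index, `G = (agreements − disagreements)/N =
2·p_agree − 1`. G is chance-symmetric and remains informative under the
heavy negative skew typical of rare kinematic features, where Cohen's κ
collapses. Reported values are rounded half-up to 2 d.p. Only the
two-rater case is supported.

## Inference

**Crescendo model (RQ1).** A linear mixed model of `G_expressivity` on
`G_position_rel` with a random intercept and slope per narrator ID
(narrator × recording), fitted by REML for reporting and by ML for the
likelihood-ratio test against the null without the position term. The
predictor is standardised internally before fitting and estimates are
back-transformed, which makes the whole procedure — including the
boundary-fit check — invariant to affine rescaling of the position
covariate. If the REML random-effect covariance is singular (smallest
eigenvalue ≤ 1e−6 of the largest), the model falls back to random
intercepts and records that in the result; the LRT degrees of freedom are
reported as the actual parameter-count difference of the two fitted models.
Effect size is Nakagawa's conditional pseudo-R²,
`(σ²_fixed + σ²_random)/(σ²_fixed + σ²_random + σ²_resid)` with
`σ²_random = mean_i(z_i' G z_i)`. The result also carries each narrator's
conditional-mode slope and the share of narrators with a positive slope.
statsmodels' default gradient optimizer occasionally stalls short of the
optimum on these small variance surfaces, so each fit keeps the better of
the default and a Powell run by log-likelihood.

**Arousal model (RQ2).** A mixed-effects logistic regression of the
per-(gesture, participant) specific-response indicator on
`G_expressivity`, with crossed random intercepts for participant and
recording, fitted by maximum likelihood under the Laplace approximation —
the same approximation lme4's `glmer` defaults to, and the implementation
is cross-checked against `glmer` in the test suite (coefficients, SDs and
log-likelihood agree to ~1e−3). The conditional mode is found by damped
Newton on the dense joint Hessian (adequate for the tens of random-effect
levels in this design); variance components are optimised on the log-sd
scale with box bounds so singular fits surface as σ → 0 rather than
failures. The LRT compares against the null without expressivity;
conditional pseudo-R² uses the logit-link residual variance π²/3.

A structural caveat: when cross-participant coupling is present, responses
to the same gesture are correlated across participants, a dependence that
participant and recording intercepts do not capture. For a gesture-level
predictor this inflates the LRT (we measure ~12–17% rejection at nominal
5% under a zero arousal slope with coupling on). The type-I calibration
study therefore uses the model's own null — no arousal link *and* no
coupling — where the rejection rate is nominal. Analyses of data with
strong within-gesture coupling should read the RQ2 p-value as
anticonservative.

**Resonance forest (RQ3).** A bootstrap-aggregated ensemble of CART trees
with `mtry = 3` candidate predictors per split and 1,500 trees by default —
i.e. a classical random forest, built as bagged `DecisionTreeClassifier`s
so each tree's bootstrap sample is exposed and out-of-bag (OOB)
predictions are genuine majority votes over the trees that did not see a
record (vote ties go to the training majority class). Thirteen predictors:
the seven GEI components plus `G_quote`, `Sentiment`, `protagonist`,
`group_compose`, `group_size`, `recency`. Unordered categoricals are
one-hot encoded; their columns move as one block everywhere, so importance
is always reported per original variable.

- **Fit metrics**: exact one-tailed binomial test of the OOB correct count
  against the majority-class rate; traditional R² = 1 − SSE/SST of OOB
  vote shares against the 0/1 outcome (undefined and flagged when
  SST = 0); McFadden's R² = 1 − ℓ_model/ℓ_null with Bernoulli
  log-likelihoods and vote shares clipped to [1e−6, 1−1e−6].
- **Importance**: OOB permutation importance — the mean decrease in OOB
  majority-vote accuracy over R (default 10) permutations of a predictor's
  column block. This is *marginal* permutation importance; party-style
  conditional importance is out of scope, and output metadata says so.
- **ICE curves**: per-record predicted resonance probability over a grid
  of one predictor with everything else held at observed values; the
  pointwise mean is the partial-dependence curve (verified against
  scikit-learn's brute-force partial dependence), and evaluating a curve
  at the record's own value reproduces the direct prediction exactly.

## Synthetic corpus generator

The generator emulates the statistical structure the analysis assumes and
supplies ground truth for recovery tests. Defaults mirror the study
conditions: 9 recordings of 2–3 participants, ~6 stories per recording,
4–40 gestures per story (the study's range was 4–91, mean ≈ 22), 4 Hz EDA,
SCR latency 1–3 s.

- **Expressivity stream**: the five coded components and HO are
  independent Bernoullis whose logits shift by `slope_n · (position − ½)`;
  base rates at mid-story loosely match observed marginal frequencies
  (HO ≈ .33, CV ≈ .06, MA ≈ .04, SL ≈ .02; SZ = .35 and FO = .30 are
  chosen so a typical gesture shows about two features, matching the
  observed median GEI of 2/7). Nucleus durations are log-normal (median
  1 s, log-sd 0.6) with the same position trend, so ND *emerges* from the
  durations rather than being sampled. Each narrator's crescendo slope is
  drawn `N(crescendo_slope, crescendo_slope_sd)`; the default spread
  (1.35 at mean 1.0) puts ~77% of narrators on a positive slope, the kind
  of between-narrator heterogeneity a random-slope model needs to be
  estimable. Narrators also differ in baseline expressivity (logit shift,
  sd 0.4).
- **Physiology**: each gesture triggers a narrator SCR with probability
  `logistic(arousal_intercept + arousal_slope·GEI + participant + recording
  shifts)`; recipients fire with probability `coupling` (on the logit
  scale, with the same individual shifts) given the narrator fired.
  Participant (sd 0.8) and recording (sd 0.4) arousal shifts reproduce the
  large cross-participant spread of response propensities that motivates
  the random intercepts in RQ2. SCRs are peak-normalised Bateman
  (difference-of-exponentials) kernels — the standard phasic EDA shape,
  rise 0.75 s / decay 2 s — delayed by a uniform 1–3 s latency, with
  amplitudes uniform in 0.1–0.5 μS, superimposed on a constant tonic level
  (2 μS) plus Gaussian noise (sd 0.01 μS, device-quantisation scale; iid
  noise above ~0.02 μS would cross the 0.05 μS threshold by chance in most
  windows) and clipped to the device range.
- **Speech**: IPUs tile each story with uniform word sentiments in
  [−1, 1]; quote spans are placed inside climax spans, where direct speech
  clusters.

Not emulated: tonic drift and slow EDA trends, autocorrelated sensor
noise, spontaneous (non-gesture-locked) SCRs, motion artefacts, gesture
streams by non-narrators, and any acoustic/visual signal content. Passing
recovery tests therefore shows the pipeline recovers planted structure
under the model's own assumptions — not that real EDA is this clean.

Effect-size defaults (crescendo slope 1.0, arousal intercept −1, slope 2,
coupling 0.35) are stand-ins chosen for clearly detectable structure; no
published estimates exist to calibrate them against.

## Validation study sizes

Chosen to give the checks adequate power at desk scale: sign recovery uses
20 replicates of ~40-story corpora (crescendo slope 1.5) and ~40-story
corpora at arousal slope 2; type-I control uses 100 reduced replicates
(6 recordings × 3 stories) under the full null, with the acceptance band
fixed a priori at the central 95% interval of Binomial(100, 0.05), i.e.
1–10 rejections; the planted-signal forest check runs at 300 trees. The
interaction probe (stronger kinematic ICE slopes in triads when coupling
is stronger in triads) uses 8 dyadic + 8 triadic recordings with coupling
0.1 vs 0.85 and reduced individual heterogeneity, since participant-level
arousal spread otherwise masks the group-size contrast at this scale.

## Numerical conventions

Report rounding is half-up (`decimal`-based, so 0.885 → 0.89). Pipeline
JSON output is key-sorted and reruns of the same configuration are
byte-identical. Feature tables are written with full-precision floats and
read back with round-trip float parsing. All stochastic components
(generator, forest, permutations) take explicit seeds; derived per-recording
seeds come from a `SeedSequence` spawn of the corpus seed.

## Known limitations

- The RQ2 p-value is anticonservative under strong within-gesture
  cross-participant coupling (see above).
- The 0.05 μS threshold is applied to the raw trough-to-peak rise within
  the window; no baseline re-referencing or filtering is applied, and the
  method inherits the window-length coupling described under detection.
- Random-slope structure for RQ1 is only estimable when narrators genuinely
  differ in slope; boundary fits fall back to random intercepts, and the
  per-narrator slope share then degenerates to the sign of the fixed slope.
- The EAF reader supports the package's documented tier conventions, not
  arbitrary ELAN tier hierarchies.
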