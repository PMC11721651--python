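# resogest

Does a story narrator's gestural effort move the audience — literally, in
their skin? `resogest` is an analysis pipeline for multimodal corpora of
conversational storytelling in which participants wear skin-conductance
(EDA) sensors. It is written for researchers in gesture studies,
interaction research and psychophysiology who have ELAN-style annotations
(stories, gesture phases, kinematic codings, speech units, quotes) and
per-participant EDA traces, and who want to test whether gesture
expressivity builds toward the story climax and drives shared emotional
arousal.

## What it computes

**Gesture Expressivity Index (GEI).** Each gesture is coded on seven binary
parameters — Size (SZ), Force (FO), Character viewpoint (CV), Silent
gesture (SL), Hold phase (HO), Multiple articulators (MA), Nucleus duration
(ND); HO and ND are derived from the phase segmentation. The index is the
unweighted mean, GEI = (#yes)/7. Contextual covariates: relative position
in the story ((i−1)/(n−1) over the story's n gestures), a ±1.5 s fuzzy
co-quote flag, and the mean word-sentiment of the overlapping speech unit.

**EDA responses and resonance.** For every gesture × participant, the EDA
window spans the gesture plus 1.5 s (absorbing 1–3 s response latency); its
amplitude is the maximal trough-to-peak rise max_{i<j}(x_j − x_i). A
response is *specific* if that rise exceeds 0.05 μS; a gesture *resonates*
if ≥ 2 participants respond specifically within its window.

**Inter-rater reliability.** Percent agreement and the Holley–Guilford
G index, G = 2·p_agree − 1, which stays informative under the skewed
margins typical of rare gesture features.

**Three inference stages** (statsmodels-style Model → Results objects):

1. `CrescendoModel` — linear mixed model GEI ~ position with a random
   slope per narrator, likelihood-ratio tested, with Nakagawa's conditional
   pseudo-R² and the share of narrators with positive slopes;
2. `ArousalModel` — mixed logistic regression of specific responses on
   GEI with crossed participant/recording intercepts (own Laplace-ML
   implementation, cross-validated against lme4::glmer);
3. `ResonanceForest` — a 1,500-tree random forest (mtry = 3) for
   gesture-level resonance over 13 predictors, with out-of-bag
   majority-vote accuracy, an exact binomial fit test, traditional and
   McFadden R², OOB permutation importance and ICE/partial-dependence
   curves.

A synthetic corpus generator (`resogest.simulate`) produces recordings
with the full statistical structure — position-dependent component rates,
logistic GEI → SCR link, cross-participant coupling, Bateman-kernel SCRs on
noisy tonic traces — plus ground truth, so every stage is validated by
parameter-recovery tests. See `docs/methods.md` for models, defaults and
limitations.

## Worked example

```python
from resogest.pipeline import PipelineConfig, run_pipeline
from resogest.simulate import SimConfig

cfg = PipelineConfig(
    sim=SimConfig(n_recordings=4, stories_per_recording=4,
                  gestures_per_story=(8, 20), crescendo_slope=1.2,
                  arousal_slope=2.0, seed=42),
    outdir="demo_run", forest_trees=500, importance_repeats=5, seed=42,
)
run_pipeline(cfg)
print(open("demo_run/report.txt").read())
```

prints (abridged):

```
Crescendo model: linear mixed model (REML estimates, ML LRT)
  nobs = 230, groups = 10, random structure = slopes
  Fixed effects:
    Intercept                0.0906  SE   0.0469  t   1.933  p    0.0533
    G_position_rel           0.2009  SE   0.0927  t   2.167  p    0.0302
  LRT vs null without position: chi2(1) = 4.244, p = 0.0394
  Conditional pseudo-R2 (Nakagawa): 0.436
  Share of narrators with positive slope: 80%

Arousal model: mixed logistic regression (Laplace ML)
  nobs = 581, logLik = -285.161, converged = True
  Fixed effects:
    Intercept               -1.8470  SE   0.4229  z  -4.368  p  1.26e-05
    G_expressivity           2.7336  SE   0.6478  z   4.219  p  2.45e-05
  LRT vs null without expressivity: chi2(1) = 18.209, p = 1.979e-05

Resonance forest: 500 trees, mtry = 3, seed = 42
  OOB accuracy = 0.791 (baseline 0.817), exact one-tailed binomial p = 0.866
```

Reading it: gestures later in a story are more expressive (position slope
+0.20 GEI units from onset to climax, LRT p = 0.039; 8 of 10 narrators
trend positive), and more expressive gestures make specific EDA responses
more likely (logit slope 2.73, p < 0.001 — the planted generator value was
2.0). With only 230 gestures the forest cannot beat the 82% majority-class
baseline for the rarer resonance outcome, which the honest binomial test
reports (p = 0.87); importance rankings are informative at larger corpus
sizes, as the test suite's planted-signal checks show.

The same stages run from the shell:

```sh
resogest simulate --config cfg.yaml --out corpus/
resogest all --config cfg.yaml
```

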