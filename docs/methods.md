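# Methods

## The measurement model

The package treats depression assessment as construct measurement followed by
calibration. Stage one measures 23 interpretable constructs from an
interview transcript; stage two calibrates those measurements to the PHQ-8
total score (0–24) with a linear map. The constructs come in three blocks:
the eight DSM-aligned PHQ-8 symptom criteria (Q1–Q8), five linguistic
markers with prior evidence of association with depression (Q9–Q13), and the
ten Cognitive Distortion Scale distortion types (Q14–Q23).

Each construct is scored by a single zero-shot prompt: the rendered
interview (one `Speaker: text` line per utterance, both parties, original
order) and the question are inserted into a fixed template that instructs
the backend to return only an integer 0–10. Interviewer turns are included
in the rendered body because the template frames the text as the full
interview; the rendering is configurable at the corpus layer for users who
want participant-only bodies.

### Decoding configurations

Two presets are defined. The deterministic preset (`top_p = 0`,
`temperature = 1e-4`) requests greedy decoding so that a given (transcript,
question) pair always yields the same completion; the stochastic preset
(`top_p = 0.8`, `temperature = 0.7`) is for response-variability
experiments, where extraction is repeated over distinct seeds and the spread
of downstream error is examined. The deterministic preset caps
`max_new_tokens` at 4 rather than 1: under byte-pair tokenizations the score
"10" can occupy two tokens, and a one-token cap would truncate it. The
single-score constraint is instead enforced by the parser, which accepts
only a bare base-10 integer in [0, 10] — prose, prefixes ("Score: 7") or
out-of-range integers are recorded as failures. Greedy decoding never
retries (the completion cannot change); stochastic extraction retries up to
3 times with fresh draws. Failed cells are listed in a failure report and
never imputed.

## Severity models

Predictors are z-scored with training-set statistics (sample SD, n−1; the
convention only rescales coefficients, configurable via `ddof`). The
primary model is OLS on the z-scored design with intercept. Rank-deficient
designs raise by default, naming the collinear features via pivoted QR; a
minimum-norm (`pinv`) policy exists for analyses that must tolerate exact
collinearity (ablation uses it). Predictions are raw regression output, not
clipped to [0, 24], unless `clip=True` — clipping would distort residual
diagnostics and the structure coefficients.

Two comparison families are provided. The RBF-SVR model tunes only the
penalty C, by leave-one-out cross-validation on the training set with MAE as
the criterion and ties broken toward the smallest C; the grid defaults to 16
log-spaced points 2⁻⁵…2¹⁰, epsilon to 0.1, and gamma to 1/(d · pooled
variance) of the standardized features. These defaults are stated rather
than silent because only the C-tuning procedure is part of the design; the
rest is a documented package choice. The stacking ensemble fits one linear
model per feature category, collects leave-one-out out-of-fold predictions
on the training set as a meta-design matrix, and fits an OLS meta-model with
intercept on it (the meta-learner family was an open choice; OLS keeps the
ensemble fully linear and inspectable). Base models are refit on the full
training set before prediction.

Evaluation reports MAE (primary), RMSE, and R² = 1 − SS_res/SS_tot computed
against the evaluation-set mean — the coefficient of determination, which
can be negative out of sample and is undefined (flagged `None`) for n < 2.

## Inference

Uncertainty uses a seeded percentile bootstrap: resample rows with
replacement B times (default 10,000), take the 2.5/97.5 percentiles as the
CI, and a two-sided sign-based p-value
`p = min(1, 2·(min(#{θ*≤0}, #{θ*≥0}) + 1)/(B + 1))`. The +1 continuity
correction keeps p strictly positive at finite B. Resamples on which the
statistic is undefined (e.g. a constant column under a correlation) are
dropped and counted; more than 1% undefined aborts the computation rather
than silently reporting a biased interval. Multiplicity across a feature set
is controlled by Benjamini–Hochberg step-up FDR,
`q₍ᵢ₎ = min_{j≥i} p₍ⱼ₎·m/j` capped at 1, implemented in-package and
cross-checked against `statsmodels` in the tests.

For test-set statistics (structure coefficients, ablation ΔMAE) the model is
fit once on the training rows and held fixed; the bootstrap resamples
evaluation rows only. This matches the estimand — uncertainty of the
contribution measure over the evaluation population, not refitting
variability — and guarantees train/test hygiene by construction. For
training-set statistics (univariate and multiple-regression standardized
betas) the bootstrap resamples training pairs and refits, re-standardizing
within each resample.

Structure coefficients are Pearson correlations between the *raw* feature
values and the model's predictions; standardization is affine per feature
and cannot change r, so the raw scale is used. Ablation importance refits
the model without each feature (removal, not coefficient-zeroing — zeroing a
z-scored coefficient does not correspond to any fitted model) and reports
ΔMAE against the full model on held-out data. Reports are sorted by
|estimate| descending, ties broken by the feature's bank order, and carry a
significance tier (FDR-significant / nominal / ns) at α = 0.05.

## Construct validity

Q1–Q8 are compared against their matching PHQ-8 item responses, and Q9–Q12
against lexicon metrics computed from participant tokens only: tone-positive
and tone-negative rates per 100 tokens, the first-person share of all
personal pronouns, and the present-marker share of all tense markers.
Agreement is Spearman's rank correlation (average ranks under ties),
FDR-adjusted jointly across the 12 linked features; Q13–Q23 have no
established reference and are skipped. Ratios with zero-match denominators
are flagged absent, never coerced to 0. Tokenization lowercases, keeps
apostrophe contractions whole, and normalizes curly apostrophes. "Per 100
tokens" is this package's stated normalization convention for the tone
rates.

The pronoun and tense lists are small closed classes and faithful; the tone
lists are a compact open lexicon and approximate by design — commercial
dictionary tools cover far larger vocabularies, and users can substitute
their own lexicon via YAML. Validity is computed on training-set
participants.

## Question banks

The 23-question bank ships verbatim, with machine-readable links from Q1–Q8
to PHQ-8 items 1–8 and from Q9–Q12 to the four lexicon metrics. The
control bank ("control_nq") holds ten placeholder questions on non-clinical
themes (political opinions, musical interests, food preferences and similar
everyday topics); the originally distributed control items are not publicly
printed, so users who have them should load them via `load_custom_set`,
which also supports arbitrary user-defined feature sets. The direct-severity
bank is the single question "How severe are Participant's depressive
symptoms?".

## Synthetic cohorts and the mock backend

The generator's purpose is to make every pipeline stage executable and
falsifiable offline; it emulates structure, not linguistic realism.

* **Severity**: a two-component mixture — Poisson(4) with weight 0.65 and
  8 + Poisson(6) with weight 0.35, clipped to [0, 24] — giving the
  right-skewed shape of screening cohorts (majority below the clinical
  threshold of 10, tail to the maximum).
* **Items**: the total is distributed point-by-point across the eight items,
  each point assigned uniformly among items still below the cap of 3. This
  sequential capped allocation is always feasible for totals ≤ 24 (a naive
  rejection sampler degenerates near the maximum, where only the all-3s
  allocation exists).
* **Features**: `round(clip(b_q + λ_q·10·s/24 + ε, 0, 10))` with
  `ε = σ(√ρ·z_cat + √(1−ρ)·z)`; defaults σ = 1.5, ρ = 0.3 within category.
  The strong-signal loadings λ (package default) encode the qualitative
  pattern reported for real instruments: strong positive loadings for mood,
  sleep, fatigue, negative sentiment and mental filter; a strong negative
  loading for positive sentiment; weak loadings for appetite, self-focus and
  emotion differentiation. Baselines b_q keep the severity-driven span
  inside the 0–10 scale for negative loadings.
* **Transcripts**: each participant's turns carry one distinctive cue word
  per question, planted exactly `feature` times (for self-focus and
  present-focus, v first-person/present tokens against 10−v
  third-person/past tokens, so the lexicon ratios track the planted value).
  Control-topic cues appear at severity-independent random counts, and a
  direct-severity cue tracks the normalized total. Filler tokens are chosen
  from outside every cue and lexicon class.

The mock backend parses the prompt, locates the question, counts that
question's cue word among participant-line tokens, and returns
`min(10, count)` — monotone in the planted signal and exactly reproducible;
under the stochastic preset it adds a seeded ±1 jitter. Because cue counts
equal feature values by construction, mock extraction recovers the planted
matrix, which is what lets end-to-end tests assert quantitative recovery
(model MAE far below the constant-mean baseline; depression questions
outranking control questions) rather than mere execution.

What passing these tests shows: the statistical machinery (standardization
hygiene, OLS, LOOCV, bootstrap, FDR, structure coefficients) is correct, and
the pipeline propagates a known signal faithfully. What they do not show:
that any particular language model scores real interviews accurately — that
depends on the backend and corpus, which is why the validity module exists.

## Problem sizes and numerical choices

Tests run the study at reduced scale (30–140 participants) and reduced
bootstrap B (150–500) with fixed seeds; the acceptance script runs the full
140/46/86 design with B = 2000 for the structure report. Statistical-oracle
tests compare against brute-force implementations (normal equations,
rank-then-Pearson, step-up FDR by definition) at 1e-8 or exact equality.
Bootstrap coverage was verified at 94.8% (500 replications, B = 500,
correlation statistic, n = 100) against the nominal 95%.

## Known limitations

* The shipped tone lexicon is small; tone-rate validity checks are
  approximate by construction.
* The tense-marker lists are heuristic (auxiliaries and common temporal
  adverbs), documented as such.
* Synthetic transcripts are cue-carrier dialogues; they exercise the
  pipeline but say nothing about real-language scoring quality.
* No real scoring-model backend ships with the package; plugging one in is
  a two-attribute adapter (`complete`, `deterministic`).
* Classification (screening at PHQ-8 ≥ 10), regularized or neural
  predictors, and multimodal (audio/video) features are out of scope.
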