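# depscore

Interpretable depression-severity assessment from clinical-interview
transcripts.

Automated depression screening from text usually means handing a transcript
to a large model and getting a number back — accurate, perhaps, but opaque.
`depscore` implements a two-stage alternative aimed at clinicians and
computational-psychiatry researchers: a language model is used only for
narrow, well-defined scoring tasks, and the severity prediction itself is a
transparent linear model whose feature contributions can be inspected.

**Stage 1 — feature scoring.** Each interview is scored against a bank of 23
questions on a 0–10 scale ("0 means Not at all, 10 means Extremely"), one
prompt per question, covering three domains: the eight PHQ-8 clinical
symptoms (Q1–Q8), five linguistic patterns (Q9–Q13: positive/negative
sentiment, self- vs other-focus, present- vs past/future-focus, emotion
differentiation), and the ten Cognitive Distortion Scale distortion types
(Q14–Q23: mindreading, catastrophizing, mental filter, …). The scoring
backend is pluggable: any instruction-tuned model can stand behind the
single-method contract, and a deterministic mock backend ships with the
package so that every stage runs offline.

**Stage 2 — severity regression.** The 23 scores are z-scored (training
statistics only) and mapped to the PHQ-8 total (0–24) by ordinary least
squares:

    ŷ = β₀ + Σⱼ βⱼ · (xⱼ − μⱼ) / σⱼ

Accuracy is reported as MAE (primary), RMSE and R² = 1 − SS_res/SS_tot on
held-out test sets. RBF-kernel SVR (with leave-one-out-tuned C) and a
per-category stacking ensemble are included as comparison model families.

**Interpretation and validity.** Feature contributions are quantified by
structure coefficients r_j = corr(x_j, ŷ) on held-out data — stable under the
multicollinearity that makes partial regression weights hard to read —
alongside standardized betas and ablation ΔMAE. All statistics carry 95%
percentile-bootstrap confidence intervals and Benjamini–Hochberg FDR-adjusted
q-values. Construct validity is checked by Spearman correlation of Q1–Q8
against the matching PHQ-8 item responses and of Q9–Q12 against lexicon-based
metrics (tone rates per 100 tokens; first-person/pronoun and
present/tense-marker ratios) computed from the participant's own words.

A synthetic cohort generator produces latent severities, PHQ-8 item scores,
category-correlated 0–10 feature matrices, and cue-word transcripts that the
mock backend can score, so the full pipeline — including its statistical
guarantees — is testable with no external data.

## Worked example

```python
import pandas as pd
import depscore as d
from depscore import pipeline

study = d.generate_study(seed=1)                      # 140 train / 46 + 86 test
qs = d.builtin_set("depression23")
fm = d.extract_features(study["transcripts"], qs, d.MockBackend(), seed=1)
parts = pipeline.partition_frames(fm, study["labels"], study["split"], qs.qids)
X_train, y_train = parts["train"]
model = d.LinearSeverityRegressor().fit(X_train, y_train)

for part in ("test1", "test2"):
    X, y = parts[part]
    m = d.evaluate_predictions(y, model.predict(X))
    print(f"{part}: MAE={m.mae:.2f}  RMSE={m.rmse:.2f}  R2={m.r2:.2f}  n={m.n}")

report = d.structure_report(
    model, pd.concat([parts["test1"][0], parts["test2"][0]]), B=2000, seed=1
)
print(report.head(5)[["qid", "estimate", "ci_low", "ci_high", "tier"]].to_string(index=False))
```

Output:

```
test1: MAE=1.33  RMSE=1.74  R2=0.85  n=46
test2: MAE=1.03  RMSE=1.34  R2=0.94  n=86
qid  estimate    ci_low   ci_high            tier
Q10  0.847627  0.799834  0.886960 fdr_significant
 Q2  0.841465  0.788014  0.884967 fdr_significant
 Q9 -0.840422 -0.890799 -0.778743 fdr_significant
 Q3  0.825408  0.764404  0.874729 fdr_significant
 Q7  0.816273  0.757560  0.863164 fdr_significant
```

The model recovers the planted severity signal far below the constant-mean
baseline (MAE ≈ 4.0/4.8 on the two test partitions), and the
structure-coefficient ladder surfaces negative sentiment (Q10), depressed
mood (Q2), positive sentiment (Q9, negative sign) and sleep disturbance (Q3)
as the strongest contributors — the pattern the generator's loadings encode.

The same pipeline is scriptable from the shell:

```bash
depscore simulate --out study/ --seed 1
depscore extract --transcripts study/transcripts --out features.csv
depscore fit --features features.csv --labels study/labels.csv \
             --split study/split.csv --out model.json
depscore evaluate --model model.json --features features.csv \
                  --labels study/labels.csv --split study/split.csv --partition test1
```

To score real interviews, place DAIC-WOZ-style tab-separated transcripts
(columns `start_time`, `stop_time`, `speaker`, `value`) in a directory and
implement the two-attribute backend contract around your model of choice
(see `depscore.prompting.ScoringBackend`).

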