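"""End-to-end orchestration: extract -> fit -> evaluate -> interpret -> validate.

A run is driven by a :class:`RunConfig` (loadable from YAML) and writes every
artifact — feature matrix, model, per-partition metrics, coefficient reports,
validity report — under one output directory, together with a manifest
carrying the resolved config and a content hash of each output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import corpus, interpret, lexicon, models, prompting, questions, simulate, validity

log = logging.getLogger("depscore")

MODEL_FAMILIES = ("ols", "svr_rbf", "stacking")
FEATURE_SUBSETS = ("all", "clinical", "linguistic", "distortion")

_SUBSET_TO_CATEGORY = {
    "clinical": "clinical_symptoms",
    "linguistic": "linguistic_patterns",
    "distortion": "cognitive_distortions",
}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    transcripts_dir: str
    labels_path: str
    split_path: str
    out_dir: str
    question_set: str = "depression23"  # built-in name or YAML path
    backend: str = "mock"
    decoding: str = "deterministic"  # deterministic | stochastic
    model_family: str = "ols"
    feature_subset: str | list[str] = "all"
    B: int = 10_000
    seed: int = 0
    transcript_dialect: str = "daicwoz_tsv"
    clip_predictions: bool = False

    def validate(self) -> None:
        if self.model_family not in MODEL_FAMILIES:
            raise ConfigError(f"unknown model family {self.model_family!r}")
        if isinstance(self.feature_subset, str) and self.feature_subset not in FEATURE_SUBSETS:
            raise ConfigError(f"unknown feature subset {self.feature_subset!r}")
        if self.decoding not in ("deterministic", "stochastic"):
            raise ConfigError(f"unknown decoding preset {self.decoding!r}")
        if self.B < 100:
            raise ConfigError("B must be >= 100")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def resolve_question_set(spec: str) -> questions.QuestionSet:
    if spec in ("depression23", "control_nq", "direct_dq"):
        return questions.builtin_set(spec)
    return questions.load_custom_set(spec)


def resolve_backend(name: str) -> prompting.ScoringBackend:
    if name == "mock":
        return prompting.MockBackend()
    raise ConfigError(
        f"unknown backend {name!r}; only the offline 'mock' backend ships with "
        "the package — plug in model backends via the library API"
    )


def _subset_qids(qs: questions.QuestionSet, subset: str | list[str]) -> list[str]:
    if isinstance(subset, list):
        unknown = [q for q in subset if q not in qs.qids]
        if unknown:
            raise ConfigError(f"unknown feature qids in subset: {unknown}")
        return list(subset)
    if subset == "all":
        return qs.qids
    qids = [q.qid for q in qs.by_category(_SUBSET_TO_CATEGORY[subset])]
    if not qids:
        raise ConfigError(f"subset {subset!r} matches no questions in {qs.name}")
    return qids


def build_model(family: str, qs: questions.QuestionSet, qids: list[str], clip: bool):
    if family == "ols":
        return models.LinearSeverityRegressor(clip=clip)
    if family == "svr_rbf":
        return models.SVRSeverityRegressor()
    if family == "stacking":
        cats = {
            c: [q.qid for q in qs.by_category(c) if q.qid in qids]
            for c in qs.categories()
        }
        cats = {c: qq for c, qq in cats.items() if qq}
        return models.StackingSeverityRegressor(categories=cats)
    raise ConfigError(f"unknown model family {family!r}")


def load_corpus(cfg: RunConfig):
    """Read split, labels and the transcripts the split references; apply QC
    (participants missing a party's text are excluded, with a record)."""
    split = corpus.load_split(cfg.split_path)
    labels = corpus.load_labels(cfg.labels_path)
    tdir = Path(cfg.transcripts_dir)
    suffix = ".tsv" if cfg.transcript_dialect == "daicwoz_tsv" else ".txt"
    transcripts, exclusions = {}, []
    for pid in (*split.train_ids, *split.test1_ids, *split.test2_ids):
        path = tdir / f"{pid}{suffix}"
        t, _report = corpus.read_transcript_table(path, dialect=cfg.transcript_dialect)
        flag = corpus.qc_missing_party(t)
        if flag is not corpus.QCFlag.OK:
            exclusions.append({"participant_id": pid, "reason": flag.value})
            continue
        transcripts[pid] = t
    return split, labels, transcripts, exclusions


def partition_frames(fm: prompting.FeatureMatrix, labels, split, qids):
    y = {r.participant_id: r.phq8_total for r in labels}
    out = {}
    for name, ids in (("train", split.train_ids), ("test1", split.test1_ids),
                      ("test2", split.test2_ids)):
        ids = [p for p in ids if p in fm.data.index and p in y]
        X = fm.data.loc[ids, qids].astype(float)
        out[name] = (X, np.array([y[p] for p in ids], dtype=float))
    return out


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full(cfg: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Idempotent: extraction is cached on content, and every statistic is
    seeded, so re-running an unchanged config reproduces identical outputs.
    """
    cfg.validate()
    qs = resolve_question_set(cfg.question_set)
    qids = _subset_qids(qs, cfg.feature_subset)
    backend = resolve_backend(cfg.backend)
    dec = (prompting.DecodingConfig.deterministic() if cfg.decoding == "deterministic"
           else prompting.DecodingConfig.stochastic())
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("stage=load")
    split, labels, transcripts, exclusions = load_corpus(cfg)
    (out / "exclusions.json").write_text(json.dumps(exclusions, indent=2))

    log.info("stage=extract n=%d x %d", len(transcripts), len(qs))
    fm = prompting.extract_features(
        list(transcripts.values()), qs, backend, dec, seed=cfg.seed,
        cache_dir=out / "cache",
    )
    fm.to_csv(out / "features.csv")
    if fm.failures:
        (out / "extraction_failures.jsonl").write_text(
            "\n".join(json.dumps(f) for f in fm.failures)
        )

    log.info("stage=fit family=%s", cfg.model_family)
    parts = partition_frames(fm, labels, split, qids)
    X_train, y_train = parts["train"]
    model = build_model(cfg.model_family, qs, qids, cfg.clip_predictions)
    model.fit(X_train, y_train)

    log.info("stage=evaluate")
    metric_rows = []
    for name in ("train", "test1", "test2"):
        X, y = parts[name]
        if len(y) == 0:
            continue
        m = models.evaluate_predictions(y, model.predict(X))
        metric_rows.append({"partition": name, **m.as_dict()})
        pd.DataFrame(
            {"participant_id": X.index, "y_true": y, "y_pred": model.predict(X)}
        ).to_csv(out / f"predictions_{name}.csv", index=False)
    pd.DataFrame(metric_rows).to_csv(out / "metrics.csv", index=False)

    log.info("stage=interpret B=%d", cfg.B)
    X_tests = pd.concat([parts["test1"][0], parts["test2"][0]])
    y_tests = np.concatenate([parts["test1"][1], parts["test2"][1]])
    if len(X_tests) >= 3 and cfg.model_family == "ols":
        interpret.structure_report(model, X_tests, B=cfg.B, seed=cfg.seed).to_csv(
            out / "structure_coefficients.csv", index=False
        )
        interpret.beta_report(X_train, y_train, B=cfg.B, seed=cfg.seed).to_csv(
            out / "standardized_betas.csv", index=False
        )
        interpret.ablation_report(
            X_train, y_train, X_tests, y_tests, B=cfg.B, seed=cfg.seed
        ).to_csv(out / "ablation_importance.csv", index=False)
    models.fit_univariate_models(X_train, y_train, B=cfg.B, seed=cfg.seed).to_csv(
        out / "univariate_betas.csv", index=False
    )

    log.info("stage=validate")
    lex = lexicon.default_lexicon()
    train_metrics = [
        lexicon.compute_linguistic_metrics(transcripts[pid], lex)
        for pid in split.train_ids if pid in transcripts
    ]
    train_fm = prompting.FeatureMatrix(
        data=fm.data.loc[[p for p in split.train_ids if p in fm.data.index]],
        metadata=fm.metadata,
    )
    validity.validity_report(train_fm, labels, train_metrics, qs).to_csv(
        out / "validity.csv", index=False
    )

    resolved = asdict(cfg)
    (out / "config.json").write_text(json.dumps(resolved, indent=2))
    manifest = {
        "config": resolved,
        "outputs": {
            p.name: _hash_file(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("stage=done out=%s", out)
    return out


def compare_prompting_strategies(
    transcripts: dict[str, corpus.Transcript],
    labels: list[corpus.LabelRecord],
    split: corpus.SplitAssignment,
    strategies: list[questions.QuestionSet],
    backend: prompting.ScoringBackend | None = None,
    dec: prompting.DecodingConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit one all-features linear model per question set and tabulate
    MAE/RMSE/R² on each test partition (one row per strategy x partition)."""
    if not strategies:
        raise ValueError("need at least one strategy")
    backend = backend if backend is not None else prompting.MockBackend()
    dec = dec if dec is not None else prompting.DecodingConfig.deterministic()
    rows = []
    for qs in strategies:
        fm = prompting.extract_features(
            list(transcripts.values()), qs, backend, dec, seed=seed
        )
        parts = partition_frames(fm, labels, split, qs.qids)
        X_train, y_train = parts["train"]
        model = models.LinearSeverityRegressor().fit(X_train, y_train)
        for name in ("test1", "test2"):
            X, y = parts[name]
            if len(y) == 0:
                continue
            m = models.evaluate_predictions(y, model.predict(X))
            rows.append({"strategy": qs.name, "partition": name, **m.as_dict()})
    return pd.DataFrame(rows)
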