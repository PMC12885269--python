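"""Prompt assembly and feature extraction via a pluggable scoring backend.

Each (transcript, question) pair is scored 0-10 by inserting the rendered
interview and the question into a fixed zero-shot prompt and asking a backend
for a single-integer completion.  The backend contract is minimal — a
callable from (prompt, decoding config, seed) to raw completion text plus a
determinism declaration — so a local instruction-tuned model, a remote
endpoint, or the built-in deterministic mock can all stand behind it.

Two decoding presets are provided: a deterministic greedy configuration
(top_p 0, temperature 1e-4) used for the primary analyses, and a stochastic
configuration (top_p 0.8, temperature 0.7) for response-variability
experiments.  The deterministic preset caps max_new_tokens at 4 rather than
1: a one-token cap cannot emit the two-token score "10" under some
tokenizations, so the single-score constraint is enforced by strict output
parsing instead.
"""

from __future__ import annotations

import hashlib
import json
import re
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

from .corpus import Transcript, QCFlag, qc_missing_party, render_interview_text
from .lexicon import tokenize
from .questions import QuestionSet, builtin_set

PROMPT_TEMPLATE = """The following text is a semi-structured clinical interview conducted by the virtual interviewer “Ellie” with interviewee “Participant” with varying depressive symptoms.

[Interview]

[INSERT_INTERVIEW]

[End of interview]

Based on the interview text, answer the following question.

Question: [INSERT_QUESTION]

Answer should be a score between 0 and 10, where 0 means “Not at all” and 10 means “Extremely”. Return only the score."""

SCORE_MIN, SCORE_MAX = 0, 10


class ScoreParseError(ValueError):
    """Completion is not a bare base-10 integer."""

    def __init__(self, raw: str):
        self.raw = raw
        super().__init__(f"completion is not a bare integer: {raw!r}")


class ScoreRangeError(ValueError):
    """Completion parsed to an integer outside [0, 10]."""

    def __init__(self, value: int, raw: str):
        self.value = value
        self.raw = raw
        super().__init__(f"score {value} outside [{SCORE_MIN}, {SCORE_MAX}]")


@dataclass(frozen=True)
class DecodingConfig:
    top_p: float
    temperature: float
    max_new_tokens: int = 4
    preset: str = "custom"

    def __post_init__(self) -> None:
        if not 0.0 <= self.top_p <= 1.0:
            raise ValueError("top_p must be in [0, 1]")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.max_new_tokens < 1:
            raise ValueError("max_new_tokens must be >= 1")

    @classmethod
    def deterministic(cls) -> "DecodingConfig":
        """Greedy decoding: a single, reproducible completion per prompt."""
        return cls(top_p=0.0, temperature=0.0001, max_new_tokens=4, preset="deterministic")

    @classmethod
    def stochastic(cls) -> "DecodingConfig":
        """Sampling configuration for response-variability experiments."""
        return cls(top_p=0.8, temperature=0.7, max_new_tokens=4, preset="stochastic")

    def key(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


@runtime_checkable
class ScoringBackend(Protocol):
    backend_id: str
    deterministic: bool

    def complete(self, prompt: str, config: DecodingConfig, seed: int) -> str: ...


def assemble_prompt(interview_text: str, question_text: str) -> str:
    """Insert the interview body and question into the fixed prompt template."""
    if not interview_text or not question_text:
        raise ValueError("interview_text and question_text must be non-empty")
    out = PROMPT_TEMPLATE.replace("[INSERT_INTERVIEW]", interview_text, 1)
    return out.replace("[INSERT_QUESTION]", question_text, 1)


_INT = re.compile(r"[+-]?\d+")


def parse_score(raw: str) -> int:
    """Strict parse of a completion: a bare base-10 integer in [0, 10].

    Anything else — prose, prefixes like ``"Score: 7"``, multiple numbers —
    raises :class:`ScoreParseError`; an integer outside the scale raises
    :class:`ScoreRangeError`.
    """
    stripped = raw.strip()
    if not _INT.fullmatch(stripped):
        raise ScoreParseError(raw)
    value = int(stripped)
    if not SCORE_MIN <= value <= SCORE_MAX:
        raise ScoreRangeError(value, raw)
    return value


@dataclass(frozen=True)
class FeatureScore:
    participant_id: str
    qid: str
    value: int
    raw_response: str
    attempt_count: int = 1

    def __post_init__(self) -> None:
        if not SCORE_MIN <= self.value <= SCORE_MAX:
            raise ValueError(f"score {self.value} outside [{SCORE_MIN}, {SCORE_MAX}]")
        if self.attempt_count < 1:
            raise ValueError("attempt_count must be >= 1")


@dataclass
class FeatureMatrix:
    """Participants x questions table of integer scores in [0, 10].

    ``data`` uses pandas nullable Int64 so that failed cells can be missing;
    every missing cell must appear in ``failures``.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    failures: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype="float64", na_value=np.nan)
        finite = vals[~np.isnan(vals)]
        if finite.size and (finite.min() < SCORE_MIN or finite.max() > SCORE_MAX):
            raise ValueError("feature values must lie in [0, 10]")
        n_missing = int(np.isnan(vals).sum())
        if n_missing != len(self.failures):
            raise ValueError(
                f"{n_missing} missing cells but {len(self.failures)} failure records"
            )

    @property
    def participant_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def qids(self) -> list[str]:
        return list(self.data.columns)

    def is_complete(self) -> bool:
        return not self.failures

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index_label="participant_id")
        meta_path = Path(path).with_suffix(".meta.json")
        meta_path.write_text(json.dumps(self.metadata, indent=2, default=str))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="participant_id").astype("Int64")
        df.index = df.index.astype(str)
        meta_path = Path(path).with_suffix(".meta.json")
        metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(data=df, metadata=metadata)


# --- mock backend -----------------------------------------------------------

#: cue words planted by the synthetic transcript generator, one per built-in
#: question.  Q9-Q12 cues are deliberately drawn from the shipped lexicon
#: (tone/pronoun/tense classes) so lexicon reference metrics track the
#: planted linguistic features.
MOCK_CUE_WORDS: dict[str, str] = {
    "Q1": "uninterested",
    "Q2": "hopeless",
    "Q3": "sleepless",
    "Q4": "exhausted",
    "Q5": "appetite",
    "Q6": "worthless",
    "Q7": "unfocused",
    "Q8": "restless",
    "Q9": "grateful",
    "Q10": "miserable",
    "Q11": "i",
    "Q12": "now",
    "Q13": "bittersweet",
    "Q14": "judged",
    "Q15": "doomed",
    "Q16": "ruined",
    "Q17": "rejected",
    "Q18": "loser",
    "Q19": "fixating",
    "Q20": "failing",
    "Q21": "blame",
    "Q22": "should",
    "Q23": "undeserved",
    "NQ1": "politics",
    "NQ2": "debate",
    "NQ3": "music",
    "NQ4": "guitar",
    "NQ5": "cooking",
    "NQ6": "spicy",
    "NQ7": "hiking",
    "NQ8": "movies",
    "NQ9": "traveling",
    "NQ10": "basketball",
    "DQ1": "struggling",
}


def _builtin_text_to_cue() -> dict[str, str]:
    mapping = {}
    for name in ("depression23", "control_nq", "direct_dq"):
        for q in builtin_set(name).questions:
            mapping[q.text] = MOCK_CUE_WORDS[q.qid]
    return mapping


_PROMPT_INTERVIEW = re.compile(r"\[Interview\]\n\n(.*)\n\n\[End of interview\]", re.S)
_PROMPT_QUESTION = re.compile(r"Question: (.*?)\n\nAnswer should be", re.S)


class MockBackend:
    """Deterministic offline test double.

    Scores each question by counting that question's cue word among the
    participant-turn tokens of the interview body, mapped monotonically to
    0-10 (count capped at 10).  Under a stochastic decoding configuration a
    seeded integer jitter in {-1, 0, +1} is added, emulating sampling
    variability.  Questions outside the built-in banks score 0.
    """

    backend_id = "mock-cue-v1"
    deterministic = True

    def __init__(self, extra_cues: dict[str, str] | None = None):
        # question text -> cue word
        self.cues = _builtin_text_to_cue()
        if extra_cues:
            self.cues.update(extra_cues)

    def complete(self, prompt: str, config: DecodingConfig, seed: int) -> str:
        m_body = _PROMPT_INTERVIEW.search(prompt)
        m_q = _PROMPT_QUESTION.search(prompt)
        if not m_body or not m_q:
            raise ValueError("prompt does not match the expected template")
        body, question = m_body.group(1), m_q.group(1)
        cue = self.cues.get(question)
        participant_lines = [
            line[len("Participant: "):]
            for line in body.splitlines()
            if line.startswith("Participant: ")
        ]
        tokens = tokenize(" ".join(participant_lines))
        score = min(SCORE_MAX, sum(tok == cue for tok in tokens)) if cue else 0
        if config.preset == "stochastic":
            digest = hashlib.sha256(f"{seed}:{prompt}".encode()).digest()
            jitter = int.from_bytes(digest[:4], "big") % 3 - 1
            score = int(np.clip(score + jitter, SCORE_MIN, SCORE_MAX))
        return str(score)


# --- extraction -------------------------------------------------------------


def _cache_key(
    interview_text: str, question_text: str, backend_id: str, cfg: DecodingConfig,
    seed: int, qs_hash: str,
) -> str:
    payload = "\x1f".join(
        [interview_text, question_text, backend_id, cfg.key(), qs_hash,
         str(seed) if cfg.preset == "stochastic" else "-"]
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def _question_set_hash(qs: QuestionSet) -> str:
    payload = json.dumps([(q.qid, q.text) for q in qs.questions])
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def extract_features(
    transcripts: Sequence[Transcript],
    qs: QuestionSet,
    backend: ScoringBackend,
    cfg: DecodingConfig | None = None,
    seed: int = 0,
    retries: int = 3,
    cache_dir: str | Path | None = None,
) -> FeatureMatrix:
    """Score every (participant, question) pair and assemble a FeatureMatrix.

    Parse or range failures are retried with fresh draws under the stochastic
    preset (up to ``retries`` attempts); under greedy decoding the completion
    cannot change, so a single attempt is made.  Exhausted cells are recorded
    in the failure report, never imputed.  With ``cache_dir`` set, completions
    are cached content-addressed on (interview text, question text, backend,
    config, question-set hash), making reruns resumable.
    """
    cfg = cfg if cfg is not None else DecodingConfig.deterministic()
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)
    qs_hash = _question_set_hash(qs)
    max_attempts = 1 if cfg.preset != "stochastic" else max(1, retries)

    for t in transcripts:
        flag = qc_missing_party(t)
        if flag is not QCFlag.OK:
            raise ValueError(f"participant {t.participant_id}: QC flag {flag.value}")

    values: dict[str, dict[str, int]] = {}
    failures: list[dict] = []
    ss_root = np.random.SeedSequence(seed)
    for ti, t in enumerate(transcripts):
        interview = render_interview_text(t)
        row: dict[str, int] = {}
        for qi, q in enumerate(qs.questions):
            prompt = assemble_prompt(interview, q.text)
            cell_seed = int(
                np.random.SeedSequence([seed, ti, qi]).generate_state(1)[0] % (2**31)
            )
            key = _cache_key(interview, q.text, backend.backend_id, cfg, cell_seed, qs_hash)
            cached = None
            if cache is not None:
                f = cache / f"{key}.json"
                if f.exists():
                    cached = json.loads(f.read_text())
            if cached is not None:
                row[q.qid] = int(cached["value"])
                continue
            last_error: Exception | None = None
            for attempt in range(1, max_attempts + 1):
                attempt_seed = int(
                    np.random.SeedSequence([seed, ti, qi, attempt]).generate_state(1)[0]
                    % (2**31)
                ) if cfg.preset == "stochastic" else cell_seed
                raw = backend.complete(prompt, cfg, attempt_seed)
                try:
                    value = parse_score(raw)
                except (ScoreParseError, ScoreRangeError) as exc:
                    last_error = exc
                    continue
                row[q.qid] = value
                if cache is not None:
                    (cache / f"{key}.json").write_text(
                        json.dumps({"value": value, "raw": raw, "attempts": attempt})
                    )
                break
            else:
                failures.append(
                    {
                        "participant_id": t.participant_id,
                        "qid": q.qid,
                        "error": str(last_error),
                        "attempts": max_attempts,
                    }
                )
        values[t.participant_id] = row

    data = pd.DataFrame.from_dict(values, orient="index").reindex(
        index=[t.participant_id for t in transcripts], columns=qs.qids
    ).astype("Int64")
    metadata = {
        "question_set": qs.name,
        "question_set_hash": qs_hash,
        "backend_id": backend.backend_id,
        "decoding": asdict(cfg),
        "seed": seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    return FeatureMatrix(data=data, metadata=metadata, failures=failures)


def run_repeated_extraction(
    transcripts: Sequence[Transcript],
    qs: QuestionSet,
    backend: ScoringBackend,
    cfg: DecodingConfig,
    n_iter: int,
    base_seed: int = 0,
    retries: int = 3,
) -> list[FeatureMatrix]:
    """Repeat extraction ``n_iter`` times with distinct seeds (stochastic
    preset), for response-variability analyses.  With ``n_iter=1`` this is a
    single extraction with seed ``base_seed``."""
    if cfg.preset != "stochastic" and n_iter > 1:
        raise ValueError("repeated extraction requires the stochastic preset")
    out = []
    for i in range(n_iter):
        fm = extract_features(
            transcripts, qs, backend, cfg, seed=base_seed + i, retries=retries
        )
        fm.metadata["iteration"] = i
        out.append(fm)
    return out
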