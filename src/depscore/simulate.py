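"""Synthetic cohorts for exercising the full pipeline offline.

The generator draws a latent depression severity per participant on the
PHQ-8 total scale (0-24, right-skewed as in screening cohorts), allocates
item scores (eight items, 0-3, summing to the total), and produces a 0-10
feature matrix in which each question loads linearly on normalized severity
with category-correlated Gaussian noise:

    feature_iq = round(clip(b_q + lambda_q * 10 * s_i / 24 + eps_iq, 0, 10))

where ``eps`` shares a within-category component (correlation ``rho_cat``)
so the feature correlation matrix has the block structure real instruments
show.  Ground truth (severity, loadings, noise parameters) is returned for
recovery tests.

A paired transcript generator emits interviewer/participant dialogues in
which each question's cue word appears exactly ``feature`` times in the
participant's turns, so the deterministic mock scoring backend approximately
recovers the planted feature matrix end to end.  The texts are cue-carrier
dialogues, not linguistically realistic interviews.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus import (
    INTERVIEWER,
    PARTICIPANT,
    LabelRecord,
    SplitAssignment,
    Transcript,
    Utterance,
)
from .prompting import MOCK_CUE_WORDS, FeatureMatrix
from .questions import QuestionSet, builtin_set

#: per-question loading of normalized severity on the 0-10 score under the
#: strong-signal preset.  Signs and relative magnitudes mirror the pattern a
#: depression instrument shows: core mood/sleep/negative-sentiment items load
#: strongly positive, positive sentiment negatively, and appetite,
#: self-focus and emotion differentiation only weakly.
STRONG_SIGNAL_LOADINGS: dict[str, float] = {
    "Q1": 0.85, "Q2": 1.0, "Q3": 0.9, "Q4": 0.8, "Q5": 0.2, "Q6": 0.8,
    "Q7": 0.7, "Q8": 0.3,
    "Q9": -0.9, "Q10": 0.95, "Q11": 0.15, "Q12": -0.4, "Q13": -0.2,
    "Q14": 0.7, "Q15": 0.7, "Q16": 0.6, "Q17": 0.6, "Q18": 0.65, "Q19": 0.9,
    "Q20": 0.7, "Q21": 0.5, "Q22": 0.5, "Q23": 0.6,
}


@dataclass
class CohortSpec:
    """Study-condition parameters for one synthetic cohort.

    Defaults give the strong-signal preset: loadings above, noise SD 1.5,
    within-category residual correlation 0.3, and a right-skewed severity
    mixture (65% mass from a low Poisson component, 35% from a moderate-to-
    severe tail) resembling screening-cohort PHQ-8 distributions.
    """

    n_participants: int
    seed: int = 0
    loadings: dict[str, float] = field(
        default_factory=lambda: dict(STRONG_SIGNAL_LOADINGS)
    )
    noise_sd: float = 1.5
    rho_cat: float = 0.3
    categories: dict[str, list[str]] | None = None  # defaults to depression23
    low_rate: float = 4.0
    tail_shift: int = 8
    tail_rate: float = 6.0
    tail_weight: float = 0.35

    def resolved_categories(self) -> dict[str, list[str]]:
        if self.categories is not None:
            return self.categories
        qs = builtin_set("depression23")
        return {c: [q.qid for q in qs.by_category(c)] for c in qs.categories()}


def _draw_severity(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_participants
    tail = rng.random(n) < spec.tail_weight
    low = rng.poisson(spec.low_rate, size=n)
    high = spec.tail_shift + rng.poisson(spec.tail_rate, size=n)
    return np.clip(np.where(tail, high, low), 0, 24).astype(int)


def _allocate_items(total: int, rng: np.random.Generator) -> tuple[int, ...]:
    """Distribute a PHQ-8 total across 8 items capped at 3: each point goes
    to a uniformly chosen item with remaining capacity (always feasible for
    totals in [0, 24])."""
    if not 0 <= total <= 24:
        raise ValueError(f"PHQ-8 total {total} outside [0, 24]")
    items = np.zeros(8, dtype=int)
    for _ in range(total):
        open_items = np.flatnonzero(items < 3)
        items[open_items[rng.integers(len(open_items))]] += 1
    return tuple(int(v) for v in items)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[FeatureMatrix, list[LabelRecord], dict]:
    """Generate (FeatureMatrix, labels, ground truth) for one cohort.

    Deterministic per ``spec.seed``.  Ground truth carries the severity
    vector and the generating parameters for parameter-recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    ids = [f"P{i + 1:04d}" for i in range(n)]
    severity = _draw_severity(spec, rng)
    categories = spec.resolved_categories()
    qids = [q for qs_ in categories.values() for q in qs_]
    missing = [q for q in qids if q not in spec.loadings]
    if missing:
        raise ValueError(f"no loading specified for {missing}")

    rho = spec.rho_cat
    if not 0 <= rho < 1:
        raise ValueError("rho_cat must be in [0, 1)")
    values = np.empty((n, len(qids)))
    col = 0
    for cat, cat_qids in categories.items():
        shared = rng.standard_normal(n)
        for qid in cat_qids:
            lam = spec.loadings[qid]
            baseline = 0.5 - 10.0 * min(lam, 0.0)
            eps = spec.noise_sd * (
                np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal(n)
            )
            raw = baseline + lam * 10.0 * severity / 24.0 + eps
            values[:, col] = np.clip(np.round(raw), 0, 10)
            col += 1

    data = pd.DataFrame(values.astype(int), index=ids, columns=qids).astype("Int64")
    fm = FeatureMatrix(
        data=data,
        metadata={"backend_id": "synthetic", "seed": spec.seed,
                  "question_set": "depression23"},
    )
    labels = [
        LabelRecord(
            participant_id=pid,
            phq8_total=int(s),
            phq8_items=_allocate_items(int(s), rng),
        )
        for pid, s in zip(ids, severity)
    ]
    truth = {
        "severity": severity,
        "loadings": dict(spec.loadings),
        "noise_sd": spec.noise_sd,
        "rho_cat": rho,
        "categories": categories,
    }
    return fm, labels, truth


_ELLIE_TURNS = [
    "how are you doing today",
    "tell me about your week",
    "what has been on your mind lately",
    "how have things been at home",
    "anything else you want to share",
    "thank you for talking with me",
]

#: filler tokens: deliberately outside every cue word and lexicon class
_FILLER = ["um", "okay", "well", "yeah", "so", "like", "right", "hmm", "sure", "uh"]


def _planted_tokens(
    feature_row: pd.Series, rng: np.random.Generator, severity: int | None
) -> list[str]:
    tokens: list[str] = []
    for qid, value in feature_row.items():
        v = int(value)
        cue = MOCK_CUE_WORDS.get(str(qid))
        if cue is None:
            continue
        if qid == "Q11":
            # self- vs other-focus: v first-person against 10-v third-person
            tokens += ["i"] * v + ["they"] * (10 - v)
        elif qid == "Q12":
            # present- vs past-focus: v present markers against 10-v past
            tokens += ["now"] * v + ["ago"] * (10 - v)
        else:
            tokens += [cue] * v
    # control-topic cue words: counts independent of severity
    for nq in (f"NQ{i}" for i in range(1, 11)):
        tokens += [MOCK_CUE_WORDS[nq]] * int(rng.integers(0, 11))
    if severity is not None:
        direct = int(np.clip(round(10 * severity / 24 + rng.normal(0, 1)), 0, 10))
        tokens += [MOCK_CUE_WORDS["DQ1"]] * direct
    return tokens


def generate_transcripts(
    fm: FeatureMatrix,
    labels: list[LabelRecord] | None = None,
    seed: int = 0,
    n_participant_turns: int = 5,
) -> list[Transcript]:
    """Build one dialogue per cohort row whose participant turns carry each
    question's cue word exactly ``feature`` times (plus severity-independent
    control-topic cues and a severity-tracking direct-assessment cue), so the
    mock backend recovers the planted features.  Deterministic per seed."""
    rng = np.random.default_rng(seed)
    totals = {r.participant_id: r.phq8_total for r in labels} if labels else {}
    transcripts = []
    for pid in fm.participant_ids:
        planted = _planted_tokens(fm.data.loc[pid], rng, totals.get(pid))
        rng.shuffle(planted)
        chunks = np.array_split(np.array(planted, dtype=object), n_participant_turns)
        utterances = []
        for k in range(n_participant_turns):
            utterances.append(
                Utterance(speaker=INTERVIEWER, text=_ELLIE_TURNS[k % len(_ELLIE_TURNS)])
            )
            words = [str(w) for w in chunks[k]]
            filler = [
                _FILLER[int(rng.integers(len(_FILLER)))]
                for _ in range(int(rng.integers(2, 6)))
            ]
            # filler interleaved around the planted cue words
            body = filler[:2] + words + filler[2:]
            utterances.append(Utterance(speaker=PARTICIPANT, text=" ".join(body)))
        transcripts.append(Transcript(participant_id=pid, utterances=utterances))
    return transcripts


def make_split(
    ids: list[str], n_train: int, n_test1: int, n_test2: int, seed: int = 0
) -> SplitAssignment:
    """Random disjoint train/test1/test2 assignment of the given ids."""
    if n_train + n_test1 + n_test2 > len(ids):
        raise ValueError("split sizes exceed the cohort size")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    return SplitAssignment(
        train_ids=tuple(perm[:n_train]),
        test1_ids=tuple(perm[n_train : n_train + n_test1]),
        test2_ids=tuple(perm[n_train + n_test1 : n_train + n_test1 + n_test2]),
    )


def generate_study(
    seed: int = 0,
    n_train: int = 140,
    n_test1: int = 46,
    n_test2: int = 86,
    **spec_overrides,
) -> dict:
    """One full study: cohort at the benchmark scale (140 train / 46 + 86
    test), transcripts, and a split.  Returns a dict with keys
    features, labels, truth, transcripts, split."""
    n = n_train + n_test1 + n_test2
    spec = CohortSpec(n_participants=n, seed=seed, **spec_overrides)
    fm, labels, truth = generate_cohort(spec)
    transcripts = generate_transcripts(fm, labels, seed=seed + 1)
    split = make_split(fm.participant_ids, n_train, n_test1, n_test2, seed=seed + 2)
    return {
        "features": fm,
        "labels": labels,
        "truth": truth,
        "transcripts": transcripts,
        "split": split,
    }
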