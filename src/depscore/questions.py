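"""Built-in question banks for prompt-based feature scoring.

The primary bank ("depression23") covers three domains of depression-relevant
constructs: the eight PHQ-8 clinical symptoms (Q1-Q8), five linguistic
patterns (Q9-Q13: sentiment, social/temporal focus, emotion differentiation)
and the ten Cognitive Distortion Scale distortion types (Q14-Q23).  Two
control banks support comparison experiments: "control_nq" (ten
non-depression-related questions) and "direct_dq" (a single direct severity
question).

Q1-Q8 carry links to PHQ-8 items 1-8 and Q9-Q12 to lexicon-based linguistic
metrics; these links drive the construct-validity checks in
:mod:`depscore.validity`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

CATEGORIES = (
    "clinical_symptoms",
    "linguistic_patterns",
    "cognitive_distortions",
    "control",
    "direct_severity",
)

#: lexicon metric ids that reference_metric may point to (besides phq8_item_N)
LEXICON_METRICS = ("tone_pos_rate", "tone_neg_rate", "self_focus_ratio", "present_focus_ratio")


class QuestionSetError(ValueError):
    """Raised for malformed or unknown question sets."""


@dataclass(frozen=True)
class Question:
    qid: str
    category: str
    text: str
    reference_metric: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise QuestionSetError(f"{self.qid}: unknown category {self.category!r}")
        if not self.text:
            raise QuestionSetError(f"{self.qid}: empty question text")


@dataclass(frozen=True)
class QuestionSet:
    name: str
    questions: tuple[Question, ...]

    def __post_init__(self) -> None:
        report = validate_set(self)
        if report:
            raise QuestionSetError("; ".join(report))

    @property
    def qids(self) -> list[str]:
        return [q.qid for q in self.questions]

    def __len__(self) -> int:
        return len(self.questions)

    def by_category(self, category: str) -> list[Question]:
        return [q for q in self.questions if q.category == category]

    def categories(self) -> list[str]:
        seen: list[str] = []
        for q in self.questions:
            if q.category not in seen:
                seen.append(q.category)
        return seen


_CLINICAL = [
    "How much does Participant express having little interest or pleasure in doing things?",
    "How much does Participant express feeling down, depressed, irritable or hopeless?",
    "How much does Participant express trouble falling or staying asleep, or sleeping too much?",
    "How much does Participant express feeling tired or having little energy?",
    "How much does Participant express poor appetite or overeating?",
    "How much does Participant express feeling bad about themselves – or that they are a failure or have let themselves or their family down?",
    "How much does Participant express trouble concentrating on things, such as school work, reading or watching television?",
    "How much does Participant express moving or speaking so slowly that other people could have noticed? Or the opposite – being so fidgety or restless that they have been moving around a lot more than usual?",
]

_LINGUISTIC = [
    "How positive is Participant’s sentiment?",
    "How negative is Participant’s sentiment?",
    "To what extent is Participant’s language self-focused compared to other-focused (e.g., “I” vs. “They”)?",
    "To what extent is Participant’s language present-focused compared to past- or future-focused (e.g., “I’m” vs. “I used to”)?",
    "How effectively does Participant differentiate between similar emotions with distinct nuances (e.g., “sad” vs. “disappointed”)?",
]

_DISTORTIONS = [
    "(Mindreading) To what extent does Participant assume others are thinking negatively about them without sufficient evidence? (e.g., “My boss hasn’t replied to the email I sent about the project days ago. He must think I’m incompetent.”)",
    "(Catastrophizing) To what extent does Participant make negative predictions about the future without sufficient evidence? (e.g., “My boyfriend wants to spend more time with his friends. We’ll be distant and eventually break up.”)",
    "(All-or-Nothing Thinking) To what extent does Participant view situations in extremes, without considering middle ground? (e.g., “I got a B+ on the exam, not an A. I’m a failure.”)",
    "(Emotional Reasoning) To what extent does Participant believe something is true because it feels that way, even when the evidence suggests otherwise? (e.g., “My friends couldn’t get enough tickets for the concert. I know they didn’t mean to exclude me, but I feel rejected and believe they did.”)",
    "(Labeling) To what extent does Participant assign negative labels to themselves based on specific incidents? (e.g., “I asked a woman to dance and she turned me down. I am a loser.”)",
    "(Mental Filter) To what extent does Participant focus only on negative details, ignoring positive aspects? (e.g., “My boyfriend said I’m smart and fun, but also mentioned I’m demanding. I’m fixating on that comment and feeling bad.”)",
    "(Overgeneralization) To what extent does Participant assume that one negative event will lead to a pattern of failures? (e.g., “I failed my math exam. I’ll probably fail the exams in my other courses as well.”)",
    "(Personalization) To what extent does Participant assume personal responsibility for negative events that aren’t their fault? (e.g., “My company didn’t get the important contract. It must be my fault.”)",
    "(Should Statements) To what extent does Participant think that things should or must be a certain way? (e.g., “I should always get at least a 90 on my exams. I’m upset because I got an 85.”)",
    "(Minimizing or Disqualifying the Positive) To what extent does Participant ignore the positive things that happen to them? (e.g., “My boss said I did a great job on the sale, but I just got lucky with that. It wasn’t really because of my skill.”)",
]

_LINGUISTIC_LINKS = [
    "tone_pos_rate",       # Q9  positive sentiment
    "tone_neg_rate",       # Q10 negative sentiment
    "self_focus_ratio",    # Q11 self- vs other-focused language
    "present_focus_ratio", # Q12 present- vs past/future-focused language
    None,                  # Q13 emotion differentiation: no reference metric
]

# The original ten control questions are distributed separately; these
# placeholders cover the same non-clinical themes (political opinions, musical
# interests, food preferences).  Substitute the originals via load_custom_set
# if you have them.
_CONTROL_NQ = [
    "How much does Participant express interest in political topics?",
    "How much does Participant express strong opinions about current events?",
    "How much does Participant express enjoyment of listening to music?",
    "How much does Participant express having a favorite musical genre or artist?",
    "How much does Participant express enjoyment of cooking or preparing food?",
    "How much does Participant express preferences for particular foods or cuisines?",
    "How much does Participant express enjoyment of outdoor activities?",
    "How much does Participant express interest in watching movies or television shows?",
    "How much does Participant express enjoyment of travel or visiting new places?",
    "How much does Participant express interest in sports, either playing or watching?",
]

_DQ1 = "How severe are Participant’s depressive symptoms?"


def _depression23() -> QuestionSet:
    questions = []
    for i, text in enumerate(_CLINICAL, start=1):
        questions.append(
            Question(f"Q{i}", "clinical_symptoms", text, reference_metric=f"phq8_item_{i}")
        )
    for j, (text, link) in enumerate(zip(_LINGUISTIC, _LINGUISTIC_LINKS), start=9):
        questions.append(Question(f"Q{j}", "linguistic_patterns", text, reference_metric=link))
    for k, text in enumerate(_DISTORTIONS, start=14):
        questions.append(Question(f"Q{k}", "cognitive_distortions", text))
    return QuestionSet("depression23", tuple(questions))


def _control_nq() -> QuestionSet:
    return QuestionSet(
        "control_nq",
        tuple(Question(f"NQ{i}", "control", t) for i, t in enumerate(_CONTROL_NQ, start=1)),
    )


def _direct_dq() -> QuestionSet:
    return QuestionSet("direct_dq", (Question("DQ1", "direct_severity", _DQ1),))


_BUILTINS = {
    "depression23": _depression23,
    "control_nq": _control_nq,
    "direct_dq": _direct_dq,
}


def builtin_set(name: str) -> QuestionSet:
    """Return a built-in question set by name
    (depression23 | control_nq | direct_dq)."""
    try:
        factory = _BUILTINS[name]
    except KeyError:
        raise QuestionSetError(
            f"unknown built-in question set {name!r}; choose from {sorted(_BUILTINS)}"
        ) from None
    return factory()


def validate_set(qs: QuestionSet) -> list[str]:
    """Return a list of violation messages (empty when valid)."""
    violations: list[str] = []
    seen: set[str] = set()
    for q in qs.questions:
        if q.qid in seen:
            violations.append(f"duplicate qid {q.qid}")
        seen.add(q.qid)
        if q.reference_metric is not None:
            ref = q.reference_metric
            if ref.startswith("phq8_item_"):
                try:
                    idx = int(ref.removeprefix("phq8_item_"))
                except ValueError:
                    idx = -1
                if not 1 <= idx <= 8:
                    violations.append(f"{q.qid}: bad PHQ-8 item link {ref!r}")
            elif ref not in LEXICON_METRICS:
                violations.append(f"{q.qid}: dangling reference link {ref!r}")
    return violations


def load_custom_set(path: str | Path) -> QuestionSet:
    """Load a question set from YAML/JSON: {name, questions: [{qid, category,
    text, reference_metric?}]}.  Violations raise with the offending qid."""
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict) or "questions" not in data:
        raise QuestionSetError(f"{path}: expected a mapping with a 'questions' list")
    questions = []
    for entry in data["questions"]:
        try:
            questions.append(
                Question(
                    qid=str(entry["qid"]),
                    category=str(entry.get("category", "control")),
                    text=str(entry.get("text", "")),
                    reference_metric=entry.get("reference_metric"),
                )
            )
        except KeyError as exc:
            raise QuestionSetError(f"{path}: question entry missing {exc}") from None
    return QuestionSet(str(data.get("name", path.stem)), tuple(questions))


def save_set(qs: QuestionSet, path: str | Path) -> None:
    data = {
        "name": qs.name,
        "questions": [
            {
                "qid": q.qid,
                "category": q.category,
                "text": q.text,
                **({"reference_metric": q.reference_metric} if q.reference_metric else {}),
            }
            for q in qs.questions
        ],
    }
    Path(path).write_text(yaml.safe_dump(data, allow_unicode=True, sort_keys=False))
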