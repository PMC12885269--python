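"""Lexicon-based linguistic reference metrics.

Computes, from participant speech only, the reference quantities used to
check construct validity of the prompt-scored linguistic features: positive
and negative tone rates (matched tokens per 100 tokens), the self-focus ratio
(first-person pronouns among all personal pronouns) and the present-focus
ratio (present-tense markers among all tense markers).

The pronoun and tense word lists are small closed-class lists; the tone lists
are a compact open lexicon and are approximate by nature.  Proprietary
dictionary-based tools cover far larger vocabularies; user-supplied lexicon
files (YAML) are accepted wherever a :class:`LexiconSet` is.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .corpus import Transcript

_TOKEN = re.compile(r"[a-z0-9]+(?:'[a-z]+)*")


def tokenize(text: str) -> list[str]:
    """Lowercased word tokens; apostrophe-bearing contractions kept whole."""
    return _TOKEN.findall(text.lower().replace("’", "'"))


def tokenize_participant_text(t: Transcript) -> list[str]:
    """Tokens from participant utterances only, in order."""
    return tokenize(t.participant_text())


class LexiconError(ValueError):
    pass


@dataclass(frozen=True)
class LexiconSet:
    """Word lists by category.  Lists must be lowercase and duplicate-free;
    the four pronoun categories must be pairwise disjoint."""

    first_person: frozenset[str]
    second_person: frozenset[str]
    third_person: frozenset[str]
    third_plural: frozenset[str]
    tense_present: frozenset[str]
    tense_past: frozenset[str]
    tense_future: frozenset[str]
    tone_positive: frozenset[str]
    tone_negative: frozenset[str]

    def __post_init__(self) -> None:
        for f in fields(self):
            words = getattr(self, f.name)
            bad = [w for w in words if w != w.lower()]
            if bad:
                raise LexiconError(f"{f.name}: non-lowercase entries {bad}")
        pronoun_cats = ["first_person", "second_person", "third_person", "third_plural"]
        for i, a in enumerate(pronoun_cats):
            for b in pronoun_cats[i + 1 :]:
                overlap = getattr(self, a) & getattr(self, b)
                if overlap:
                    raise LexiconError(f"{a} and {b} overlap: {sorted(overlap)}")

    @property
    def all_pronouns(self) -> frozenset[str]:
        return self.first_person | self.second_person | self.third_person | self.third_plural

    @property
    def all_tense(self) -> frozenset[str]:
        return self.tense_present | self.tense_past | self.tense_future


def default_lexicon() -> LexiconSet:
    """The lexicon shipped with the package."""
    return LexiconSet(
        first_person=frozenset(
            "i i'm i've i'll i'd me my mine myself "
            "we we're we've we'll we'd us our ours ourselves".split()
        ),
        second_person=frozenset(
            "you you're you've you'll you'd your yours yourself yourselves".split()
        ),
        third_person=frozenset(
            "she she's she'd she'll he he's he'd he'll "
            "her hers herself him his himself".split()
        ),
        third_plural=frozenset(
            "they they're they've they'll they'd them their theirs themselves".split()
        ),
        tense_present=frozenset(
            "am is are be being do does can now today nowadays currently".split()
        ),
        tense_past=frozenset(
            "was were been did had ago yesterday used previously back then".split()
        ),
        tense_future=frozenset(
            "will won't gonna tomorrow soon shall someday eventually".split()
        ),
        tone_positive=frozenset(
            "good great happy glad love loved enjoy enjoyed fun wonderful "
            "grateful hopeful proud excited nice better amazing pleasant "
            "calm relaxed".split()
        ),
        tone_negative=frozenset(
            "bad sad miserable terrible awful hate hated depressed hopeless "
            "worthless exhausted lonely anxious worried angry upset guilty "
            "stressed worse".split()
        ),
    )


@dataclass(frozen=True)
class LinguisticMetrics:
    """Reference metrics for one participant.  Ratio fields are ``None`` when
    the denominator category has zero matches (flagged absent, never 0)."""

    participant_id: str
    token_count: int
    tone_pos_rate: float  # matched tokens per 100 tokens
    tone_neg_rate: float
    self_focus_ratio: float | None  # first-person / all-pronoun proportion
    present_focus_ratio: float | None  # present / all-tense-marker proportion

    def as_dict(self) -> dict[str, float | int | str | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def compute_linguistic_metrics(
    t: Transcript, lex: LexiconSet | None = None
) -> LinguisticMetrics:
    """Tone rates per 100 tokens and pronoun/tense focus ratios for the
    participant's speech."""
    lex = lex if lex is not None else default_lexicon()
    tokens = tokenize_participant_text(t)
    n = len(tokens)
    if n == 0:
        raise ValueError(
            f"participant {t.participant_id}: no participant tokens (run QC first)"
        )
    pos = sum(tok in lex.tone_positive for tok in tokens)
    neg = sum(tok in lex.tone_negative for tok in tokens)
    first = sum(tok in lex.first_person for tok in tokens)
    pronouns = sum(tok in lex.all_pronouns for tok in tokens)
    present = sum(tok in lex.tense_present for tok in tokens)
    tense = sum(tok in lex.all_tense for tok in tokens)
    return LinguisticMetrics(
        participant_id=t.participant_id,
        token_count=n,
        tone_pos_rate=100.0 * pos / n,
        tone_neg_rate=100.0 * neg / n,
        self_focus_ratio=(first / pronouns) if pronouns else None,
        present_focus_ratio=(present / tense) if tense else None,
    )


def load_lexicon(path: str | Path) -> LexiconSet:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise LexiconError(f"{path}: expected a mapping of category -> word list")
    kwargs = {}
    for f in fields(LexiconSet):
        if f.name not in data:
            raise LexiconError(f"{path}: missing category {f.name!r}")
        words = data[f.name]
        if len(set(words)) != len(words):
            raise LexiconError(f"{path}: {f.name} contains duplicates")
        kwargs[f.name] = frozenset(str(w) for w in words)
    return LexiconSet(**kwargs)


def save_lexicon(lex: LexiconSet, path: str | Path) -> None:
    data = {f.name: sorted(getattr(lex, f.name)) for f in fields(LexiconSet)}
    Path(path).write_text(yaml.safe_dump(data, allow_unicode=True))
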