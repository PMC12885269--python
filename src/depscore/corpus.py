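"""Transcript and label I/O for semi-structured clinical interviews.

Transcripts follow the DAIC-WOZ family convention: a tab-separated table with
``start_time``, ``stop_time``, ``speaker`` and ``value`` columns, one utterance
per row, where the virtual interviewer is labelled "Ellie" and the interviewee
"Participant".  A plain-text ``Speaker: text`` fallback dialect is also
supported.  Labels are PHQ-8 totals (0-24) with optional per-item scores
(eight items, 0-3 each).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

INTERVIEWER = "interviewer"
PARTICIPANT = "participant"

#: case-insensitive speaker label normalization; unknown labels are rejected
SPEAKER_ALIASES = {
    "ellie": INTERVIEWER,
    "interviewer": INTERVIEWER,
    "participant": PARTICIPANT,
    "subject": PARTICIPANT,
}

#: display names used when rendering an interview body for prompting
DISPLAY_NAMES = {INTERVIEWER: "Ellie", PARTICIPANT: "Participant"}


class TranscriptFormatError(ValueError):
    """Raised when a transcript file cannot be parsed."""


class SpeakerLabelError(ValueError):
    """Raised when a speaker label does not normalize to a known party."""


class LabelDataError(ValueError):
    """Raised when a label table is internally inconsistent."""


class QCFlag(str, Enum):
    OK = "ok"
    NO_INTERVIEWER_TEXT = "no_interviewer_text"
    NO_PARTICIPANT_TEXT = "no_participant_text"


@dataclass(frozen=True)
class Utterance:
    """One speaker turn.  ``speaker`` is normalized to interviewer/participant."""

    speaker: str
    text: str
    start_time: float | None = None
    stop_time: float | None = None

    def __post_init__(self) -> None:
        if self.speaker not in (INTERVIEWER, PARTICIPANT):
            raise SpeakerLabelError(f"unnormalized speaker label: {self.speaker!r}")
        if not self.text:
            raise ValueError("utterance text must be non-empty")
        if "\t" in self.text or "\n" in self.text:
            raise ValueError("utterance text must not contain tabs or newlines")
        if self.start_time is not None and self.start_time < 0:
            raise ValueError("start_time must be >= 0")
        if (
            self.start_time is not None
            and self.stop_time is not None
            and self.stop_time < self.start_time
        ):
            raise ValueError("stop_time must be >= start_time")


@dataclass
class Transcript:
    participant_id: str
    utterances: list[Utterance] = field(default_factory=list)

    def by_speaker(self, speaker: str) -> list[Utterance]:
        return [u for u in self.utterances if u.speaker == speaker]

    def participant_text(self) -> str:
        """All participant turns joined by single spaces."""
        return " ".join(u.text for u in self.utterances if u.speaker == PARTICIPANT)


@dataclass
class ParseReport:
    """Accounting of rows dropped during parsing (empty text)."""

    n_rows: int = 0
    n_dropped_empty: int = 0

    @property
    def n_retained(self) -> int:
        return self.n_rows - self.n_dropped_empty


@dataclass(frozen=True)
class LabelRecord:
    participant_id: str
    phq8_total: int
    phq8_items: tuple[int, ...] | None = None
    age: float | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.phq8_total <= 24:
            raise LabelDataError(
                f"participant {self.participant_id}: PHQ-8 total "
                f"{self.phq8_total} outside [0, 24]"
            )
        if self.phq8_items is not None:
            if len(self.phq8_items) != 8:
                raise LabelDataError(
                    f"participant {self.participant_id}: expected 8 item scores"
                )
            if any(not 0 <= v <= 3 for v in self.phq8_items):
                raise LabelDataError(
                    f"participant {self.participant_id}: item scores must be in [0, 3]"
                )
            if sum(self.phq8_items) != self.phq8_total:
                raise LabelDataError(
                    f"participant {self.participant_id}: item scores sum to "
                    f"{sum(self.phq8_items)} but total is {self.phq8_total}"
                )


@dataclass(frozen=True)
class SplitAssignment:
    train_ids: tuple[str, ...]
    test1_ids: tuple[str, ...]
    test2_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for part in (self.train_ids, self.test1_ids, self.test2_ids):
            for pid in part:
                if pid in seen:
                    raise LabelDataError(
                        f"participant {pid} assigned to more than one partition"
                    )
                seen.add(pid)


def normalize_speaker(label: str, *, line: int | None = None) -> str:
    key = label.strip().lower()
    if key not in SPEAKER_ALIASES:
        where = f" at line {line}" if line is not None else ""
        raise SpeakerLabelError(f"unknown speaker label {label!r}{where}")
    return SPEAKER_ALIASES[key]


def _clean_text(raw: object) -> str:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return ""
    return re.sub(r"[\t\n\r]+", " ", str(raw)).strip()


def read_transcript_table(
    path: str | Path,
    dialect: str = "daicwoz_tsv",
    participant_id: str | None = None,
) -> tuple[Transcript, ParseReport]:
    """Read a transcript file in the given dialect.

    Parameters
    ----------
    path
        Transcript file.  ``daicwoz_tsv`` expects a tab-separated header table
        with (case-insensitive) columns start_time, stop_time, speaker, value;
        ``plain_text`` expects ``Speaker: text`` lines, where a line without a
        speaker prefix continues the previous utterance.
    participant_id
        Defaults to the file stem.

    Returns
    -------
    (Transcript, ParseReport)
        Rows with empty text are dropped and counted in the report.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pid = participant_id if participant_id is not None else path.stem
    if dialect == "daicwoz_tsv":
        return _read_daicwoz_tsv(path, pid)
    if dialect == "plain_text":
        return _read_plain_text(path, pid)
    raise ValueError(f"unknown transcript dialect: {dialect!r}")


def _read_daicwoz_tsv(path: Path, pid: str) -> tuple[Transcript, ParseReport]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise TranscriptFormatError(f"{path}: cannot parse as TSV: {exc}") from exc
    cols = {c.strip().lower(): c for c in df.columns}
    required = {"speaker", "value"}
    if not required <= set(cols):
        raise TranscriptFormatError(
            f"{path}: missing or ambiguous header; need columns "
            f"speaker and value (case-insensitive), got {list(df.columns)}"
        )
    report = ParseReport(n_rows=len(df))
    utterances: list[Utterance] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        record = dict(zip(df.columns, row))
        text = _clean_text(record[cols["value"]])
        if not text:
            report.n_dropped_empty += 1
            continue
        speaker = normalize_speaker(str(record[cols["speaker"]]), line=i)
        times = {}
        for key in ("start_time", "stop_time"):
            if key in cols:
                raw = record[cols[key]]
                try:
                    times[key] = float(raw)
                except (TypeError, ValueError):
                    times[key] = None
        utterances.append(Utterance(speaker=speaker, text=text, **times))
    return Transcript(participant_id=pid, utterances=utterances), report


_PLAIN_LINE = re.compile(r"^\s*([A-Za-z][\w ]*?)\s*:\s*(.*)$")


def _read_plain_text(path: Path, pid: str) -> tuple[Transcript, ParseReport]:
    report = ParseReport()
    parts: list[tuple[str, list[str], int]] = []  # (speaker, text pieces, line)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        report.n_rows += 1
        m = _PLAIN_LINE.match(line)
        if m and m.group(1).strip().lower() in SPEAKER_ALIASES:
            speaker = normalize_speaker(m.group(1), line=lineno)
            text = _clean_text(m.group(2))
            parts.append((speaker, [text] if text else [], lineno))
        elif parts:
            # continuation of a wrapped utterance
            parts[-1][1].append(_clean_text(line))
        else:
            raise TranscriptFormatError(
                f"{path}: line {lineno} has no 'Speaker:' prefix and no "
                "preceding utterance to continue"
            )
    utterances = []
    for speaker, pieces, _ in parts:
        text = " ".join(p for p in pieces if p)
        if not text:
            report.n_dropped_empty += 1
            continue
        utterances.append(Utterance(speaker=speaker, text=text))
    return Transcript(participant_id=pid, utterances=utterances), report


def qc_missing_party(t: Transcript) -> QCFlag:
    """Flag transcripts missing either party's text (exclusion is the caller's
    decision, never applied silently)."""
    has_interviewer = any(u.speaker == INTERVIEWER for u in t.utterances)
    has_participant = any(u.speaker == PARTICIPANT for u in t.utterances)
    if not has_interviewer:
        return QCFlag.NO_INTERVIEWER_TEXT
    if not has_participant:
        return QCFlag.NO_PARTICIPANT_TEXT
    return QCFlag.OK


def render_interview_text(t: Transcript) -> str:
    """Render the interview body inserted into the scoring prompt.

    One line per utterance, ``"<Speaker>: <text>"`` with speakers printed as
    "Ellie" and "Participant", in original order.  Deterministic for a fixed
    transcript.
    """
    return "\n".join(f"{DISPLAY_NAMES[u.speaker]}: {u.text}" for u in t.utterances)


def load_labels(path: str | Path) -> list[LabelRecord]:
    """Load a label CSV with headers participant_id, phq8_total and optionally
    phq8_item1..phq8_item8, age, sex.  Item/total consistency is enforced."""
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "participant_id" not in cols or "phq8_total" not in cols:
        raise LabelDataError(
            f"{path}: need columns participant_id and phq8_total, got {list(df.columns)}"
        )
    item_cols = [f"phq8_item{i}" for i in range(1, 9)]
    have_items = all(c in cols for c in item_cols)
    records = []
    for _, row in df.iterrows():
        items = (
            tuple(int(row[cols[c]]) for c in item_cols) if have_items else None
        )
        records.append(
            LabelRecord(
                participant_id=str(row[cols["participant_id"]]),
                phq8_total=int(row[cols["phq8_total"]]),
                phq8_items=items,
                age=float(row[cols["age"]]) if "age" in cols and pd.notna(row[cols["age"]]) else None,
                sex=str(row[cols["sex"]]) if "sex" in cols and pd.notna(row[cols["sex"]]) else None,
            )
        )
    return records


def save_labels(records: Iterable[LabelRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row: dict[str, object] = {
            "participant_id": r.participant_id,
            "phq8_total": r.phq8_total,
        }
        if r.phq8_items is not None:
            for i, v in enumerate(r.phq8_items, start=1):
                row[f"phq8_item{i}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_split(path: str | Path) -> SplitAssignment:
    """Load a split CSV with headers participant_id, partition
    (train/test1/test2)."""
    df = pd.read_csv(path, dtype=str)
    cols = {c.strip().lower(): c for c in df.columns}
    if "participant_id" not in cols or "partition" not in cols:
        raise LabelDataError(
            f"{path}: need columns participant_id and partition, got {list(df.columns)}"
        )
    buckets: dict[str, list[str]] = {"train": [], "test1": [], "test2": []}
    for _, row in df.iterrows():
        part = str(row[cols["partition"]]).strip().lower()
        if part not in buckets:
            raise LabelDataError(f"{path}: unknown partition {part!r}")
        buckets[part].append(str(row[cols["participant_id"]]))
    return SplitAssignment(
        train_ids=tuple(buckets["train"]),
        test1_ids=tuple(buckets["test1"]),
        test2_ids=tuple(buckets["test2"]),
    )


def save_split(split: SplitAssignment, path: str | Path) -> None:
    rows = [
        {"participant_id": pid, "partition": part}
        for part, ids in (
            ("train", split.train_ids),
            ("test1", split.test1_ids),
            ("test2", split.test2_ids),
        )
        for pid in ids
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def save_transcript(t: Transcript, path: str | Path, dialect: str = "daicwoz_tsv") -> None:
    path = Path(path)
    if dialect == "daicwoz_tsv":
        df = pd.DataFrame(
            {
                "start_time": [u.start_time for u in t.utterances],
                "stop_time": [u.stop_time for u in t.utterances],
                "speaker": [DISPLAY_NAMES[u.speaker] for u in t.utterances],
                "value": [u.text for u in t.utterances],
            }
        )
        df.to_csv(path, sep="\t", index=False)
    elif dialect == "plain_text":
        path.write_text(render_interview_text(t) + "\n")
    else:
        raise ValueError(f"unknown transcript dialect: {dialect!r}")


def parse_plain_text(text: str, participant_id: str = "anon") -> Transcript:
    """Parse in-memory ``Speaker: text`` lines (round-trip helper)."""
    utterances = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        m = _PLAIN_LINE.match(line)
        if m and m.group(1).strip().lower() in SPEAKER_ALIASES:
            utterances.append(
                Utterance(
                    speaker=normalize_speaker(m.group(1), line=lineno),
                    text=_clean_text(m.group(2)),
                )
            )
        elif utterances:
            prev = utterances[-1]
            utterances[-1] = Utterance(
                speaker=prev.speaker, text=f"{prev.text} {_clean_text(line)}"
            )
        else:
            raise TranscriptFormatError(f"line {lineno}: no speaker prefix")
    return Transcript(participant_id=participant_id, utterances=utterances)
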