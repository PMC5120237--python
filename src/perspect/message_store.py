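"""Motivational message library with behaviour-change metadata.

A message library is the pool a tailored-messaging system draws from: each
message carries its author type (expert- or peer-written), the set of
readiness-to-quit stages it is coded for, and an open vocabulary of content
tags (e.g. ``MOTIVATIONAL_CONTENT``, ``BEHAVIORAL_TREATMENT``, or
theory-construct labels).  The readiness stages form the five-level
"readiness ladder" used both for stage-matched message filtering and for the
trial's moved-up-the-ladder outcome.
"""

from __future__ import annotations

import enum
import json
from collections.abc import Iterable, Iterator, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "ReadinessStage",
    "MessageSource",
    "Message",
    "MessageLibrary",
    "LibraryParseError",
    "LibraryValidationError",
    "load_library",
    "filter_by_stage",
    "tag_proportions",
]

#: inner separator for the list-valued ``stages`` and ``tags`` columns
LIST_SEP = ";"


class LibraryParseError(ValueError):
    """A library file record could not be parsed (names the offending line)."""


class LibraryValidationError(ValueError):
    """A structurally valid record violates a library invariant."""


class ReadinessStage(enum.IntEnum):
    """Five ordered rungs of the readiness-to-quit ladder.

    The integer values encode the total order used for stage comparisons;
    "moving up the ladder" means a strictly greater value at follow-up.
    """

    NOT_THINKING = 1
    THINKING = 2
    SET_QUIT_DATE = 3
    QUIT_TODAY = 4
    ALREADY_QUIT = 5

    @classmethod
    def parse(cls, token: str | int | ReadinessStage) -> "ReadinessStage":
        if isinstance(token, ReadinessStage):
            return token
        if isinstance(token, int):
            return cls(token)
        name = str(token).strip().upper()
        try:
            return cls[name]
        except KeyError:
            raise LibraryValidationError(f"unknown readiness stage {token!r}") from None


class MessageSource(enum.Enum):
    EXPERT = "EXPERT"
    PEER = "PEER"

    @classmethod
    def parse(cls, token: str | MessageSource) -> "MessageSource":
        if isinstance(token, MessageSource):
            return token
        try:
            return cls[str(token).strip().upper()]
        except KeyError:
            raise LibraryValidationError(f"unknown message source {token!r}") from None


@dataclass(frozen=True)
class Message:
    """One motivational message: the unit being recommended."""

    id: str
    text: str
    source: MessageSource
    stages: frozenset[ReadinessStage]
    tags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not str(self.id):
            raise LibraryValidationError("message id must be nonempty")
        if not self.text:
            raise LibraryValidationError(f"message {self.id!r}: text must be nonempty")
        if not self.stages:
            raise LibraryValidationError(f"message {self.id!r}: stage set must be nonempty")
        object.__setattr__(self, "stages", frozenset(ReadinessStage.parse(s) for s in self.stages))
        object.__setattr__(self, "tags", frozenset(str(t) for t in self.tags))
        object.__setattr__(self, "source", MessageSource.parse(self.source))

    def matches_stage(self, stage: ReadinessStage) -> bool:
        return ReadinessStage.parse(stage) in self.stages


class MessageLibrary(Sequence[Message]):
    """Ordered, id-unique collection of messages."""

    def __init__(self, messages: Iterable[Message]):
        self._messages: list[Message] = list(messages)
        self._by_id: dict[str, Message] = {}
        for m in self._messages:
            if m.id in self._by_id:
                raise LibraryValidationError(f"duplicate message id {m.id!r}")
            self._by_id[m.id] = m

    def __len__(self) -> int:
        return len(self._messages)

    def __getitem__(self, i):  # type: ignore[override]
        return self._messages[i]

    def __iter__(self) -> Iterator[Message]:
        return iter(self._messages)

    def __contains__(self, item: object) -> bool:
        if isinstance(item, Message):
            return item.id in self._by_id
        return item in self._by_id

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MessageLibrary):
            return NotImplemented
        return self._messages == other._messages

    def get(self, message_id: str) -> Message:
        try:
            return self._by_id[message_id]
        except KeyError:
            raise KeyError(f"unknown message id {message_id!r}") from None

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self._messages]

    def filter_by_stage(self, stage: ReadinessStage) -> "MessageLibrary":
        return filter_by_stage(self, stage)

    def tag_proportions(self) -> dict[str, float]:
        return tag_proportions(self)

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": m.id,
                "text": m.text,
                "source": m.source.value,
                "stages": LIST_SEP.join(s.name for s in sorted(m.stages)),
                "tags": LIST_SEP.join(sorted(m.tags)),
            }
            for m in self._messages
        ]
        return pd.DataFrame(rows, columns=["id", "text", "source", "stages", "tags"])

    def save(self, path: str | Path) -> None:
        """Write as delimited text (CSV; list columns use ';' internally)."""
        path = Path(path)
        if path.suffix.lower() in {".yaml", ".yml", ".json"}:
            records = [
                {
                    "id": m.id,
                    "text": m.text,
                    "source": m.source.value,
                    "stages": [s.name for s in sorted(m.stages)],
                    "tags": sorted(m.tags),
                }
                for m in self._messages
            ]
            with open(path, "w") as fh:
                if path.suffix.lower() == ".json":
                    json.dump({"messages": records}, fh, indent=1)
                else:
                    yaml.safe_dump({"messages": records}, fh, sort_keys=False)
        else:
            self.to_frame().to_csv(path, index=False)


def _record_to_message(rec: Mapping, where: str) -> Message:
    missing = {"id", "text", "source", "stages"} - set(rec)
    if missing:
        raise LibraryParseError(f"{where}: missing column(s) {sorted(missing)}")
    stages_raw = rec["stages"]
    tags_raw = rec.get("tags", "") or ""
    if isinstance(stages_raw, str):
        stages = [t for t in stages_raw.split(LIST_SEP) if t.strip()]
    else:
        stages = list(stages_raw)
    if isinstance(tags_raw, str):
        tags = [t.strip() for t in tags_raw.split(LIST_SEP) if t.strip()]
    else:
        tags = list(tags_raw)
    try:
        parsed_stages = frozenset(ReadinessStage.parse(s) for s in stages)
        source = MessageSource.parse(rec["source"])
    except LibraryValidationError as exc:
        raise LibraryParseError(f"{where}: {exc}") from exc
    return Message(
        id=str(rec["id"]),
        text=str(rec["text"]),
        source=source,
        stages=parsed_stages,
        tags=frozenset(tags),
    )


def load_library(path: str | Path) -> MessageLibrary:
    """Load and validate a message library.

    Accepts delimited text (header ``id,text,source,stages,tags``; ``stages``
    and ``tags`` are ';'-separated lists) or a structured YAML/JSON document
    with a top-level ``messages`` list carrying the same fields.

    Raises
    ------
    LibraryParseError
        for malformed records (the message names the offending line/record).
    LibraryValidationError
        for duplicate ids or empty stage sets.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".yaml", ".yml", ".json"}:
        with open(path) as fh:
            doc = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
        records = doc["messages"] if isinstance(doc, Mapping) else doc
        messages = [
            _record_to_message(rec, f"{path.name}: record {i}") for i, rec in enumerate(records)
        ]
    else:
        try:
            frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        except pd.errors.ParserError as exc:
            raise LibraryParseError(f"{path.name}: {exc}") from exc
        required = {"id", "text", "source", "stages"}
        if not required.issubset(frame.columns):
            raise LibraryParseError(
                f"{path.name}: header must contain {sorted(required)}, got {list(frame.columns)}"
            )
        messages = []
        for i, rec in enumerate(frame.to_dict("records")):
            # +2: one for the header line, one for 1-based numbering
            messages.append(_record_to_message(rec, f"{path.name}: line {i + 2}"))
    return MessageLibrary(messages)


def filter_by_stage(lib: MessageLibrary, stage: ReadinessStage) -> MessageLibrary:
    """Messages coded for *stage*, original order preserved."""
    stage = ReadinessStage.parse(stage)
    return MessageLibrary(m for m in lib if stage in m.stages)


def tag_proportions(lib: MessageLibrary) -> dict[str, float]:
    """Fraction of the library carrying each tag (over all tags present)."""
    if len(lib) == 0:
        raise LibraryValidationError("tag_proportions of an empty library is undefined")
    counts: dict[str, int] = {}
    for m in lib:
        for t in m.tags:
            counts[t] = counts.get(t, 0) + 1
    n = len(lib)
    return {t: c / n for t, c in sorted(counts.items())}
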