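"""Data model for annotated utterance corpora.

An :class:`AnnotatedUtterance` is one clause with a verb span, up to two
labeled argument spans (roles ``A`` and ``P``), a verb-class label and a
language tag.  The module provides JSONL/TSV readers and writers with strict
validation, plus descriptive statistics: surface word-order patterns, their
Shannon entropy, role proportions and 1st/2nd-person pronoun rates by role.

JSONL schema (one utterance per line, after a header line)::

    {"id": ..., "language": ..., "tokens": [...], "verb": [s, e],
     "verb_class": ..., "arguments": [{"span": [s, e], "role": "A"|"P",
     "nominality": ...}], "conditions": {...}?}

Spans are 0-based half-open token index pairs.  Token surfaces are
NFC-normalized on construction; case is preserved.
"""

from __future__ import annotations

import json
import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy.stats import entropy as _shannon_entropy

__all__ = [
    "Role",
    "Nominality",
    "Token",
    "ArgumentSpan",
    "AnnotatedUtterance",
    "Corpus",
    "CorpusStats",
    "CorpusFormatError",
    "CorpusValidationError",
    "load_verb_classes",
    "read_corpus",
    "write_corpus",
    "word_order_pattern",
    "word_order_entropy",
    "corpus_statistics",
]

JSONL_HEADER_SCHEMA = "rolepred-corpus-v1"


class Role(str, Enum):
    A = "A"
    P = "P"


class Nominality(str, Enum):
    PRON_1SG = "PRON_1SG"
    PRON_2SG = "PRON_2SG"
    PRON_OTHER = "PRON_OTHER"
    OTHER = "OTHER"


class CorpusValidationError(ValueError):
    """An utterance violates a structural invariant."""

    def __init__(self, message: str, utterance_id: str | None = None, field: str | None = None):
        self.utterance_id = utterance_id
        self.field = field
        prefix = f"[utterance {utterance_id!r}" + (f", field {field!r}" if field else "") + "] " if utterance_id else ""
        super().__init__(prefix + message)


class CorpusFormatError(CorpusValidationError):
    """A serialized record does not conform to the documented schema."""


def load_verb_classes(path: str | Path | None = None) -> tuple[str, ...]:
    """Load the verb-class inventory (one label per line).

    Defaults to the 48-label list shipped with the package.
    """
    if path is None:
        text = resources.files("rolepred.data").joinpath("verb_classes.txt").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    labels = tuple(line.strip() for line in text.splitlines() if line.strip())
    if len(labels) != len(set(labels)):
        raise ValueError("verb-class inventory contains duplicate labels")
    return labels


DEFAULT_VERB_CLASSES = load_verb_classes()


@dataclass(frozen=True)
class Token:
    surface: str
    index: int

    def __post_init__(self):
        if not self.surface:
            raise CorpusValidationError("token surface must be non-empty")
        if self.index < 0:
            raise CorpusValidationError("token index must be non-negative")


@dataclass(frozen=True)
class ArgumentSpan:
    start: int
    end: int
    role: Role
    nominality: Nominality

    def __post_init__(self):
        object.__setattr__(self, "role", Role(self.role))
        object.__setattr__(self, "nominality", Nominality(self.nominality))
        if not (0 <= self.start < self.end):
            raise CorpusValidationError(f"invalid span [{self.start}, {self.end})")


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


@dataclass
class AnnotatedUtterance:
    id: str
    language: str
    tokens: list[str]
    verb_span: tuple[int, int]
    verb_class: str
    arguments: list[ArgumentSpan] = field(default_factory=list)
    conditions: dict[str, str] | None = None

    def __post_init__(self):
        self.tokens = [unicodedata.normalize("NFC", t) for t in self.tokens]
        self.verb_span = (int(self.verb_span[0]), int(self.verb_span[1]))
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self, verb_classes: Sequence[str] | None = None) -> None:
        n = len(self.tokens)
        if n == 0:
            raise CorpusValidationError("utterance has no tokens", self.id, "tokens")
        if any(not t for t in self.tokens):
            raise CorpusValidationError("empty token surface", self.id, "tokens")
        vs, ve = self.verb_span
        if not (0 <= vs < ve <= n):
            raise CorpusValidationError(
                f"verb span [{vs}, {ve}) out of range for {n} tokens", self.id, "verb"
            )
        if len(self.arguments) > 2:
            raise CorpusValidationError("more than two argument spans", self.id, "arguments")
        roles = [a.role for a in self.arguments]
        if len(set(roles)) != len(roles):
            raise CorpusValidationError("duplicate argument roles", self.id, "arguments")
        spans = [(a.start, a.end) for a in self.arguments]
        for a in self.arguments:
            if a.end > n:
                raise CorpusValidationError(
                    f"argument span [{a.start}, {a.end}) out of range", self.id, "arguments"
                )
            if _overlaps((a.start, a.end), self.verb_span):
                raise CorpusValidationError(
                    f"argument span [{a.start}, {a.end}) overlaps verb span", self.id, "arguments"
                )
        if len(spans) == 2 and _overlaps(spans[0], spans[1]):
            raise CorpusValidationError("argument spans overlap each other", self.id, "arguments")
        if verb_classes is not None and self.verb_class not in verb_classes:
            raise CorpusValidationError(
                f"unknown verb class {self.verb_class!r}", self.id, "verb_class"
            )

    # -- convenience --------------------------------------------------------
    def token_objects(self) -> list[Token]:
        return [Token(s, i) for i, s in enumerate(self.tokens)]

    def argument(self, role: Role | str) -> ArgumentSpan | None:
        role = Role(role)
        for a in self.arguments:
            if a.role == role:
                return a
        return None

    def to_record(self) -> dict:
        rec = {
            "id": self.id,
            "language": self.language,
            "tokens": list(self.tokens),
            "verb": [self.verb_span[0], self.verb_span[1]],
            "verb_class": self.verb_class,
            "arguments": [
                {
                    "span": [a.start, a.end],
                    "role": a.role.value,
                    "nominality": a.nominality.value,
                }
                for a in self.arguments
            ],
        }
        if self.conditions is not None:
            rec["conditions"] = {k: self.conditions[k] for k in sorted(self.conditions)}
        return rec

    @classmethod
    def from_record(cls, rec: Mapping, verb_classes: Sequence[str] | None = None) -> "AnnotatedUtterance":
        uid = rec.get("id", "<missing id>")
        for key in ("id", "language", "tokens", "verb", "verb_class", "arguments"):
            if key not in rec:
                raise CorpusFormatError(f"missing key {key!r}", str(uid), key)
        try:
            args = [
                ArgumentSpan(
                    start=int(a["span"][0]),
                    end=int(a["span"][1]),
                    role=Role(a["role"]),
                    nominality=Nominality(a["nominality"]),
                )
                for a in rec["arguments"]
            ]
        except (KeyError, ValueError, TypeError, IndexError) as exc:
            raise CorpusFormatError(f"malformed arguments: {exc}", str(uid), "arguments") from exc
        try:
            utt = cls(
                id=str(rec["id"]),
                language=str(rec["language"]),
                tokens=list(rec["tokens"]),
                verb_span=(int(rec["verb"][0]), int(rec["verb"][1])),
                verb_class=str(rec["verb_class"]),
                arguments=args,
                conditions=dict(rec["conditions"]) if rec.get("conditions") is not None else None,
            )
        except CorpusValidationError:
            raise
        except (ValueError, TypeError, IndexError) as exc:
            raise CorpusFormatError(f"malformed record: {exc}", str(uid)) from exc
        utt.validate(verb_classes)
        return utt


@dataclass
class Corpus:
    utterances: list[AnnotatedUtterance] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [u.id for u in self.utterances]
        if len(ids) != len(set(ids)):
            dup = next(i for i, c in Counter(ids).items() if c > 1)
            raise CorpusValidationError(f"duplicate utterance id {dup!r}")

    def __len__(self) -> int:
        return len(self.utterances)

    def __iter__(self) -> Iterator[AnnotatedUtterance]:
        return iter(self.utterances)

    def __getitem__(self, i):
        return self.utterances[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return (
            [u.to_record() for u in self.utterances] == [u.to_record() for u in other.utterances]
            and self.metadata == other.metadata
        )


@dataclass
class CorpusStats:
    pattern_counts: dict[str, int]
    entropy_bits: float
    role_proportions: dict[Role, float]
    pronoun12_rate_by_role: dict[Role, float]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _dumps(obj: dict) -> str:
    return json.dumps(obj, ensure_ascii=False, separators=(",", ":"))


def write_corpus(corpus: Corpus, path: str | Path, format: str = "jsonl") -> None:
    """Serialize ``corpus`` deterministically (stable key order and bytes)."""
    path = Path(path)
    if format == "jsonl":
        lines = [_dumps({"schema": JSONL_HEADER_SCHEMA, "metadata": _stable(corpus.metadata)})]
        lines += [_dumps(u.to_record()) for u in corpus.utterances]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "tsv":
        out = [f"# corpus_meta = {_dumps(_stable(corpus.metadata))}"]
        for u in corpus.utterances:
            out.append(f"# id = {u.id}")
            out.append(f"# language = {u.language}")
            out.append(f"# verb = {u.verb_span[0]} {u.verb_span[1]}")
            out.append(f"# verb_class = {u.verb_class}")
            for a in u.arguments:
                out.append(f"# arg = {a.start} {a.end} {a.role.value} {a.nominality.value}")
            if u.conditions is not None:
                out.append(f"# conditions = {_dumps({k: u.conditions[k] for k in sorted(u.conditions)})}")
            for i, t in enumerate(u.tokens):
                out.append(f"{i}\t{t}")
            out.append("")
        path.write_text("\n".join(out) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown format {format!r}")


def _stable(obj):
    """Recursively sort mapping keys so serialization is deterministic."""
    if isinstance(obj, Mapping):
        return {k: _stable(obj[k]) for k in sorted(obj)}
    if isinstance(obj, (list, tuple)):
        return [_stable(v) for v in obj]
    return obj


def read_corpus(
    path: str | Path,
    format: str = "jsonl",
    verb_classes: Sequence[str] | None = DEFAULT_VERB_CLASSES,
) -> Corpus:
    """Read a corpus file, rejecting (never dropping) malformed records."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "jsonl":
        return _read_jsonl(path, verb_classes)
    if format == "tsv":
        return _read_tsv(path, verb_classes)
    raise ValueError(f"unknown format {format!r}")


def _read_jsonl(path: Path, verb_classes) -> Corpus:
    lines = path.read_text("utf-8").splitlines()
    if not lines:
        raise CorpusFormatError("empty file: missing header line")
    try:
        header = json.loads(lines[0])
    except json.JSONDecodeError as exc:
        raise CorpusFormatError(f"unparseable header line: {exc}") from exc
    if not isinstance(header, dict) or header.get("schema") != JSONL_HEADER_SCHEMA:
        raise CorpusFormatError(f"bad or missing schema header (expected {JSONL_HEADER_SCHEMA!r})")
    utts = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
        except json.JSONDecodeError as exc:
            raise CorpusFormatError(f"line {ln}: invalid JSON: {exc}") from exc
        utts.append(AnnotatedUtterance.from_record(rec, verb_classes))
    return Corpus(utterances=utts, metadata=header.get("metadata", {}))


def _read_tsv(path: Path, verb_classes) -> Corpus:
    meta: dict = {}
    utts: list[AnnotatedUtterance] = []
    block: dict = {}
    tokens: list[str] = []

    def flush():
        nonlocal block, tokens
        if not block and not tokens:
            return
        rec = {
            "id": block.get("id"),
            "language": block.get("language"),
            "tokens": tokens,
            "verb": block.get("verb"),
            "verb_class": block.get("verb_class"),
            "arguments": block.get("arguments", []),
        }
        if "conditions" in block:
            rec["conditions"] = block["conditions"]
        if rec["id"] is None or rec["verb"] is None:
            raise CorpusFormatError("TSV block missing '# id' or '# verb' line", str(rec["id"]))
        utts.append(AnnotatedUtterance.from_record(rec, verb_classes))
        block, tokens = {}, []

    for raw in path.read_text("utf-8").splitlines():
        line = raw.rstrip("\n")
        if not line.strip():
            flush()
            continue
        if line.startswith("# corpus_meta = "):
            meta = json.loads(line[len("# corpus_meta = "):])
        elif line.startswith("# arg = "):
            parts = line[len("# arg = "):].split()
            block.setdefault("arguments", []).append(
                {"span": [int(parts[0]), int(parts[1])], "role": parts[2], "nominality": parts[3]}
            )
        elif line.startswith("# verb = "):
            s, e = line[len("# verb = "):].split()
            block["verb"] = [int(s), int(e)]
        elif line.startswith("# conditions = "):
            block["conditions"] = json.loads(line[len("# conditions = "):])
        elif line.startswith("# "):
            key, _, val = line[2:].partition(" = ")
            block[key] = val
        else:
            _, _, surface = line.partition("\t")
            tokens.append(surface)
    flush()
    return Corpus(utterances=utts, metadata=meta)


# ---------------------------------------------------------------------------
# descriptive statistics
# ---------------------------------------------------------------------------

def word_order_pattern(utt: AnnotatedUtterance) -> str:
    """Surface order of overt elements as a string over {A, P, V}.

    One letter per overtly realized element, ordered by span start; omitted
    arguments contribute nothing.  The verb's letter sits at its span start.
    """
    elements = [(a.start, a.role.value) for a in utt.arguments]
    elements.append((utt.verb_span[0], "V"))
    return "".join(letter for _, letter in sorted(elements))


def word_order_entropy(corpus: Corpus) -> float:
    """Shannon entropy (bits) of the empirical word-order pattern distribution."""
    if len(corpus) == 0:
        raise ValueError("entropy undefined for an empty corpus")
    counts = Counter(word_order_pattern(u) for u in corpus)
    return float(_shannon_entropy(np.array(list(counts.values()), dtype=float), base=2))


def corpus_statistics(corpus: Corpus) -> CorpusStats:
    """Pattern counts, order entropy, role proportions and pronoun rates.

    Proportions are computed over argument spans of utterances with at least
    one argument; ``pronoun12_rate_by_role`` is the fraction of arguments of
    each role realized as a 1st or 2nd person singular pronoun.
    """
    if len(corpus) == 0:
        raise ValueError("statistics undefined for an empty corpus")
    pattern_counts = Counter(word_order_pattern(u) for u in corpus)
    role_counts: Counter = Counter()
    pron12: Counter = Counter()
    for u in corpus:
        for a in u.arguments:
            role_counts[a.role] += 1
            if a.nominality in (Nominality.PRON_1SG, Nominality.PRON_2SG):
                pron12[a.role] += 1
    total = sum(role_counts.values())
    role_proportions = {r: role_counts[r] / total for r in role_counts} if total else {}
    pronoun12 = {r: pron12[r] / role_counts[r] for r in role_counts} if total else {}
    return CorpusStats(
        pattern_counts=dict(sorted(pattern_counts.items())),
        entropy_bits=word_order_entropy(corpus),
        role_proportions=role_proportions,
        pronoun12_rate_by_role=pronoun12,
    )
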