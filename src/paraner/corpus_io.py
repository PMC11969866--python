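"""Reading, writing and validating BIO-tagged corpora.

The unit of every corpus is the :class:`TaggedSentence` — a token list with
aligned BIO labels (``B-T`` begins an entity of type ``T``, ``I-T``
continues it, ``O`` is outside any entity).  :class:`EntityMention` is the
span view of the same information: a 0-based half-open token span
``[start, end)`` with its type and space-joined surface string.

``labels_to_entities`` / ``entities_to_labels`` convert between the two
views and are mutual inverses on valid input.  ``repair_bio`` fixes the one
defect public BIO corpora commonly contain — an ``I-`` tag with no
compatible predecessor ("orphan I") — by promoting it to ``B-`` (default)
or raising (``strict``).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

logger = logging.getLogger(__name__)

_TAG_RE = re.compile(r"^(O|[BI]-\S+)$")


class ParseError(ValueError):
    """A line of a CoNLL-style file could not be parsed."""


class ValidationError(ValueError):
    """A label sequence violates BIO constraints."""


@dataclass
class TaggedSentence:
    """Tokens with aligned BIO labels; the unit of all corpora."""

    sent_id: str
    tokens: list[str]
    labels: list[str]

    def __post_init__(self):
        if len(self.tokens) == 0:
            raise ValidationError(f"{self.sent_id}: empty sentence")
        if len(self.tokens) != len(self.labels):
            raise ValidationError(
                f"{self.sent_id}: {len(self.tokens)} tokens vs "
                f"{len(self.labels)} labels"
            )
        for lab in self.labels:
            if not _TAG_RE.match(lab):
                raise ValidationError(f"{self.sent_id}: bad tag syntax {lab!r}")

    @property
    def text(self) -> str:
        return " ".join(self.tokens)

    def is_bio_valid(self) -> bool:
        """True iff no I- tag follows O or a tag of a different type."""
        prev = "O"
        for lab in self.labels:
            if lab.startswith("I-"):
                if prev == "O" or prev[2:] != lab[2:]:
                    return False
            prev = lab
        return True


@dataclass(frozen=True)
class EntityMention:
    """Typed half-open token span with its surface string."""

    sent_id: str
    start: int
    end: int
    etype: str
    surface: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"{self.sent_id}: bad span [{self.start},{self.end})"
            )


def _open_maybe(source) -> Iterable[str]:
    if isinstance(source, (str, Path)):
        return Path(source).open(encoding="utf-8")
    return source


def read_conll(source: IO[str] | str | Path, token_col: int = 0,
               label_col: int = -1) -> list[TaggedSentence]:
    """Parse a CoNLL-style token-per-line stream into sentences.

    Columns are whitespace/tab separated; a blank line separates sentences;
    ``-DOCSTART-`` lines are skipped.  Invalid BIO transitions (orphan
    ``I-``) are flagged with a warning but not altered — call
    :func:`repair_bio` to fix them.
    """
    sentences: list[TaggedSentence] = []
    tokens: list[str] = []
    labels: list[str] = []
    stream = _open_maybe(source)

    def flush():
        if tokens:
            sid = f"s{len(sentences)}"
            sent = TaggedSentence(sid, list(tokens), list(labels))
            if not sent.is_bio_valid():
                logger.warning("sentence %s has invalid BIO transitions "
                               "(orphan I-); consider repair_bio", sid)
            sentences.append(sent)
            tokens.clear()
            labels.clear()

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            flush()
            continue
        if line.startswith("-DOCSTART-"):
            continue
        cols = line.split()
        if label_col < 0:  # counted from the end: need token + label distinct
            ncols_needed = max(token_col + 1, -label_col, 2)
        else:
            ncols_needed = max(token_col, label_col) + 1
        if len(cols) < ncols_needed:
            raise ParseError(
                f"line {lineno}: expected at least {ncols_needed} columns, "
                f"got {len(cols)}: {line!r}"
            )
        tok = cols[token_col]
        lab = cols[label_col]
        if not _TAG_RE.match(lab):
            raise ValidationError(f"line {lineno}: unknown tag syntax {lab!r}")
        tokens.append(tok)
        labels.append(lab)
    flush()
    return sentences


def write_conll(sentences: Iterable[TaggedSentence], sink: IO[str]) -> None:
    """Write sentences token-per-line (token TAB label, blank-line separated)."""
    for sent in sentences:
        for tok, lab in zip(sent.tokens, sent.labels):
            sink.write(f"{tok}\t{lab}\n")
        sink.write("\n")


def labels_to_entities(s: TaggedSentence) -> list[EntityMention]:
    """Extract mentions as maximal ``B-T (I-T)*`` runs, sorted by start.

    Raises :class:`ValidationError` on an unrepaired sequence (orphan I-).
    """
    if not s.is_bio_valid():
        raise ValidationError(
            f"{s.sent_id}: invalid BIO sequence; run repair_bio first"
        )
    mentions: list[EntityMention] = []
    start, etype = None, None
    for i, lab in enumerate(s.labels + ["O"]):
        if start is not None and not (lab.startswith("I-") and lab[2:] == etype):
            mentions.append(EntityMention(
                s.sent_id, start, i, etype, " ".join(s.tokens[start:i])
            ))
            start, etype = None, None
        if lab.startswith("B-"):
            start, etype = i, lab[2:]
    return mentions


def entities_to_labels(tokens: list[str],
                       mentions: list[EntityMention]) -> list[str]:
    """Render non-overlapping mentions as a BIO label list over `tokens`."""
    labels = ["O"] * len(tokens)
    occupied = [False] * len(tokens)
    for m in sorted(mentions, key=lambda m: m.start):
        if m.end > len(tokens):
            raise ValidationError(
                f"{m.sent_id}: mention [{m.start},{m.end}) out of bounds "
                f"for {len(tokens)} tokens"
            )
        if any(occupied[m.start:m.end]):
            raise ValidationError(f"{m.sent_id}: overlapping mentions")
        labels[m.start] = f"B-{m.etype}"
        for i in range(m.start + 1, m.end):
            labels[i] = f"I-{m.etype}"
        for i in range(m.start, m.end):
            occupied[i] = True
    return labels


def repair_bio(labels: list[str], policy: str = "promote") -> list[str]:
    """Make a label sequence BIO-valid.

    policy="promote": an orphan ``I-T`` (preceded by O or by a different
    type) becomes ``B-T``; policy="strict": raise instead.
    """
    if policy not in ("promote", "strict"):
        raise ValueError(f"unknown repair policy {policy!r}")
    out: list[str] = []
    prev = "O"
    n_repaired = 0
    for lab in labels:
        if not _TAG_RE.match(lab):
            raise ValidationError(f"bad tag syntax {lab!r}")
        if lab.startswith("I-") and (prev == "O" or prev[2:] != lab[2:]):
            if policy == "strict":
                raise ValidationError(f"orphan {lab} after {prev}")
            lab = "B-" + lab[2:]
            n_repaired += 1
        out.append(lab)
        prev = lab
    if n_repaired:
        logger.warning("repair_bio promoted %d orphan I- tags", n_repaired)
    return out
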