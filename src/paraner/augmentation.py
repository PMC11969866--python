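"""Paraphrase-based data augmentation with entity localization and filtering.

The pipeline per original sentence:

1. build the rephrase prompt (original text + a fixed instruction),
2. obtain ``multiplier`` paraphrases from a pluggable paraphraser
   (production: a chat LLM; tests: the deterministic mock in
   :mod:`paraner.synthetic_data`),
3. tokenize each paraphrase,
4. localize the original entity surfaces in it (case-insensitive exact
   token-sequence match, longest surfaces claimed first, all occurrences
   labeled),
5. project BIO labels onto the located spans,
6. filter: a paraphrase is kept only if every original surface was found
   and the located spans do not overlap.  Duplicates of the original text
   or of an earlier accepted paraphrase of the same sentence are dropped.

Accepted paraphrases join the training pool only; their ``sent_id`` carries
an ``::aug`` provenance tag so evaluation code can assert they never reach
validation or test sets.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from typing import IO, Callable, Iterable, Optional, Protocol

from .corpus_io import EntityMention, TaggedSentence, entities_to_labels, labels_to_entities

logger = logging.getLogger(__name__)

REPHRASE_INSTRUCTION = (
    "Help me rephrase this sentence while preserving the original meaning."
)

AUG_TAG = "::aug"

_PUNCT = ".,;:!?()[]"
_TOKEN_RE = re.compile(r"[.,;:!?()\[\]]|[^\s.,;:!?()\[\]]+")


class ParaphraserContract(Protocol):
    """Callable returning exactly `n` paraphrase strings for a sentence."""

    def __call__(self, sentence_text: str, n: int, seed: int) -> list[str]:
        ...


@dataclass
class AugmentationRecord:
    """One paraphrase attempt with its localization outcome."""

    original_id: str
    paraphrase_text: str
    paraphrase_tokens: list[str]
    projected_labels: Optional[list[str]]
    status: str  # "accepted" | "rejected"
    reject_reason: Optional[str] = None  # missing_entity|count_mismatch|duplicate|empty

    def to_json(self) -> str:
        return json.dumps({
            "original_id": self.original_id,
            "paraphrase_text": self.paraphrase_text,
            "paraphrase_tokens": self.paraphrase_tokens,
            "projected_labels": self.projected_labels,
            "status": self.status,
            "reject_reason": self.reject_reason,
        })

    @staticmethod
    def from_json(line: str) -> "AugmentationRecord":
        return AugmentationRecord(**json.loads(line))


def build_prompt(sentence_text: str) -> str:
    """Splice the original sentence with the fixed rephrase instruction."""
    if not sentence_text or not sentence_text.strip():
        raise ValueError("cannot build a prompt from an empty sentence")
    return f"{sentence_text} {REPHRASE_INSTRUCTION}"


def tokenize_paraphrase(paraphrase_text: str) -> list[str]:
    """Whitespace split, with punctuation characters as their own tokens."""
    tokens = _TOKEN_RE.findall(paraphrase_text)
    if not tokens:
        raise ValueError("paraphrase is empty after tokenization")
    return tokens


def localize_entities(
    paraphrase_tokens: list[str], gold: list[EntityMention]
) -> tuple[Optional[list[EntityMention]], Optional[str]]:
    """Find every gold entity surface in the paraphrase.

    Matching is case-insensitive exact token-sequence match; all maximal
    occurrences of each surface are located and typed as the gold type.
    Longer surfaces claim positions first so a surface nested inside
    another cannot steal its tokens.

    Returns ``(mentions, None)`` on success, sorted by start, or
    ``(None, reason)`` with reason ``missing_entity`` (some surface absent)
    or ``count_mismatch`` (all occurrences of a surface collide with
    already-claimed spans).
    """
    low = [t.lower() for t in paraphrase_tokens]
    # unique (surface tokens, type), longest first, lexicographic tie-break
    keyed: dict[tuple[tuple[str, ...], str], None] = {}
    for m in gold:
        keyed[(tuple(m.surface.lower().split()), m.etype)] = None
    order = sorted(keyed, key=lambda k: (-len(k[0]), k[0], k[1]))

    claimed = [False] * len(low)
    found: list[EntityMention] = []
    for surf, etype in order:
        k = len(surf)
        occurrences = [
            i for i in range(len(low) - k + 1)
            if tuple(low[i:i + k]) == surf
        ]
        if not occurrences:
            return None, "missing_entity"
        placed = 0
        for i in occurrences:
            if any(claimed[i:i + k]):
                continue
            for j in range(i, i + k):
                claimed[j] = True
            found.append(EntityMention(
                "", i, i + k, etype,
                " ".join(paraphrase_tokens[i:i + k]),
            ))
            placed += 1
        if placed == 0:
            return None, "count_mismatch"
    return sorted(found, key=lambda m: m.start), None


def project_labels(
    paraphrase_tokens: list[str],
    located: list[EntityMention],
    sent_id: str = "aug",
) -> TaggedSentence:
    """Render located spans as BIO labels over the paraphrase tokens."""
    labels = entities_to_labels(paraphrase_tokens, located)
    return TaggedSentence(sent_id, list(paraphrase_tokens), labels)


def is_augmented(sent_id: str) -> bool:
    """True if the sentence id carries the augmentation provenance tag."""
    return AUG_TAG in sent_id


def augment_dataset(
    dataset: list[TaggedSentence],
    paraphraser: ParaphraserContract,
    multiplier: int = 5,
    seed: int = 0,
) -> tuple[list[TaggedSentence], list[AugmentationRecord]]:
    """Expand a dataset with filtered, label-projected paraphrases.

    Each sentence gets exactly `multiplier` paraphrase attempts.  Accepted
    paraphrases become new TaggedSentences appended after all originals,
    tagged ``<orig_id>::augN``.  Rejection reasons: ``missing_entity``,
    ``count_mismatch`` (localization failed), ``duplicate`` (same text as
    the original or an earlier accepted paraphrase of the same sentence),
    ``empty`` (blank output or paraphraser failure).
    """
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    records: list[AugmentationRecord] = []
    new_sentences: list[TaggedSentence] = []
    for idx, sent in enumerate(dataset):
        gold = labels_to_entities(sent)
        sent_seed = (seed * 1000003 + idx * 7919) % (2 ** 31)
        try:
            paraphrases = paraphraser(sent.text, multiplier, sent_seed)
        except Exception:  # noqa: BLE001 - external component may fail
            logger.exception("paraphraser failed on %s; rejecting %d slots",
                             sent.sent_id, multiplier)
            paraphrases = [None] * multiplier
        if len(paraphrases) != multiplier:
            raise ValueError(
                f"paraphraser returned {len(paraphrases)} strings, "
                f"expected {multiplier}"
            )
        accepted_texts: set[str] = set()
        n_acc = 0
        for text in paraphrases:
            if text is None or not text.strip():
                records.append(AugmentationRecord(
                    sent.sent_id, text or "", [], None, "rejected", "empty"))
                continue
            if text == sent.text or text in accepted_texts:
                records.append(AugmentationRecord(
                    sent.sent_id, text, [], None, "rejected", "duplicate"))
                continue
            tokens = tokenize_paraphrase(text)
            located, reason = localize_entities(tokens, gold)
            if located is None:
                records.append(AugmentationRecord(
                    sent.sent_id, text, tokens, None, "rejected", reason))
                continue
            aug_id = f"{sent.sent_id}{AUG_TAG}{n_acc}"
            tagged = project_labels(tokens, located, aug_id)
            records.append(AugmentationRecord(
                sent.sent_id, text, tokens, tagged.labels, "accepted"))
            new_sentences.append(tagged)
            accepted_texts.add(text)
            n_acc += 1
    n_accepted = sum(1 for r in records if r.status == "accepted")
    n_rejected = len(records) - n_accepted
    logger.info("augmentation: %d sentences, %d accepted, %d rejected",
                len(dataset), n_accepted, n_rejected)
    return list(dataset) + new_sentences, records


def write_records(records: Iterable[AugmentationRecord], sink: IO[str]) -> None:
    for r in records:
        sink.write(r.to_json() + "\n")


def read_records(source: IO[str]) -> list[AugmentationRecord]:
    return [AugmentationRecord.from_json(line)
            for line in source if line.strip()]
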