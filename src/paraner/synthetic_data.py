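"""Seeded synthetic BIO corpora and a deterministic mock paraphraser.

The generator emulates short biomedical-style sentences: a carrier
template (``"the patient developed {E} after treatment ."``) is
instantiated with 1–3 multi-token entity mentions drawn from a typed
lexicon, and BIO labels are derived from the filled slots.  Three
vocabulary classes — entity tokens, carrier/synonym tokens, and the
adverbs the mock paraphraser prepends — are pairwise disjoint, so entity
localization in a paraphrase has unambiguous ground truth.

The mock paraphraser stands in for a chat-LLM behind the paraphraser
contract.  Per paraphrase it applies seeded transforms: synonym
substitution on non-entity tokens, optional clause rotation around a
preposition, and a prepended adverb (cycled through a seeded permutation,
which makes the n paraphrases of one sentence pairwise distinct).  With
probability ``entity_corruption_prob`` it deletes one token of one entity
mention; because surfaces are unique within a sentence, a corrupted
paraphrase is guaranteed to fail entity localization.

``standard_benchmark()`` returns the fixed spec used by the package's
end-to-end experiments: a 40-surface lexicon over two types, a
400-sentence training pool and a 500-sentence test set, seed 7.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .corpus_io import EntityMention, TaggedSentence, entities_to_labels

# -- fixed vocabularies (pairwise disjoint token classes) ---------------------

# Head/tail vocabularies are kept small enough that a 50-sentence sample
# almost surely contains every token: with hash-coded embeddings an unseen
# entity token is unclassifiable in principle, so token coverage — not the
# model — would otherwise bound few-shot scores on the benchmark.
DISEASE_HEADS = [
    "fibrosis", "melanoma", "neuropathy", "carcinoma",
    "anemia", "sepsis", "dystrophy", "glaucoma",
]
DISEASE_TAILS = ["syndrome", "deficiency", "disorder", "lesion"]

GENE_HEADS = [
    "braf", "egfr", "kras", "tp53",
    "brca1", "notch1", "sox2", "mycn",
]
GENE_TAILS = ["kinase", "receptor", "ligand", "promoter"]

CARRIER_TEMPLATES = [
    "the patient developed {E} after treatment .",
    "clinicians observed {E} and {E} in the cohort .",
    "symptoms of {E} were recorded during the trial .",
    "analysis linked {E} to {E} in several cases .",
    "the study reported {E} among elderly subjects .",
    "doctors diagnosed {E} following surgery .",
    "expression of {E} increased after exposure .",
    "researchers associated {E} with {E} and {E} in mice .",
    "levels of {E} declined during therapy .",
    "screening detected {E} in most participants .",
]

SYNONYM_TABLE = {
    "patient": ["subject", "individual"],
    "developed": ["exhibited", "presented"],
    "observed": ["noted", "documented"],
    "recorded": ["registered", "logged"],
    "reported": ["described", "announced"],
    "diagnosed": ["identified", "confirmed"],
    "increased": ["rose", "climbed"],
    "declined": ["decreased", "dropped"],
    "detected": ["found", "revealed"],
    "linked": ["connected", "related"],
    "associated": ["correlated", "paired"],
    "study": ["investigation", "survey"],
    "trial": ["experiment", "protocol"],
    "cohort": ["group", "population"],
    "cases": ["instances", "records"],
}

ADVERBS = [
    "notably", "importantly", "remarkably", "interestingly", "surprisingly",
    "clinically", "typically", "generally", "frequently", "occasionally",
    "previously", "recently", "historically", "consequently", "accordingly",
    "moreover", "furthermore", "additionally", "meanwhile", "overall",
]

REORDER_PIVOTS = ("after", "during", "following", "among", "in")


def _build_surfaces(heads: list[str], tails: list[str]) -> list[str]:
    """Deterministic 1–3 token surfaces: a head token optionally followed
    by tail tokens ("braf", "braf kinase", "braf kinase domain" style).

    Head tokens only ever open a surface and tail tokens only ever
    continue one, so token identity determines B vs I unambiguously —
    the positional regularity head nouns and qualifiers show in real
    biomedical mentions.
    """
    nh, nt = len(heads), len(tails)
    surfaces = list(heads[:8])
    surfaces += [f"{heads[i % nh]} {tails[i % nt]}" for i in range(8)]
    surfaces += [
        f"{heads[(4 + i) % nh]} {tails[i % nt]} {tails[(i + 1) % nt]}"
        for i in range(4)
    ]
    assert len(set(surfaces)) == 20
    return surfaces


@dataclass
class SynthSpec:
    """Parameters of the synthetic corpus and its mock paraphraser."""

    n_train: int = 400
    n_test: int = 500
    entity_lexicon: dict[str, list[str]] = field(default_factory=lambda: {
        "Disease": _build_surfaces(DISEASE_HEADS, DISEASE_TAILS),
        "Gene": _build_surfaces(GENE_HEADS, GENE_TAILS),
    })
    templates: list[str] = field(
        default_factory=lambda: list(CARRIER_TEMPLATES))
    synonym_table: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in SYNONYM_TABLE.items()})
    entity_corruption_prob: float = 0.0
    seed: int = 7

    def __post_init__(self):
        if not (0.0 <= self.entity_corruption_prob <= 1.0):
            raise ValueError("entity_corruption_prob must be in [0, 1]")
        if not self.entity_lexicon or not any(self.entity_lexicon.values()):
            raise ValueError("entity lexicon must be non-empty")
        if not self.templates:
            raise ValueError("need at least one carrier template")
        ent = self.entity_token_set()
        carrier = self.carrier_token_set()
        clash = ent & (carrier | set(ADVERBS))
        if clash:
            raise ValueError(f"entity tokens overlap other vocab: {clash}")

    def entity_token_set(self) -> set[str]:
        return {tok for surfs in self.entity_lexicon.values()
                for s in surfs for tok in s.split()}

    def carrier_token_set(self) -> set[str]:
        toks = {tok for t in self.templates for tok in t.split()
                if tok != "{E}"}
        for base, alts in self.synonym_table.items():
            toks.add(base)
            toks.update(alts)
        return toks


def make_corpus(spec: SynthSpec) -> tuple[list[TaggedSentence],
                                          list[TaggedSentence]]:
    """Generate (train_pool, test_set); disjoint ids, reproducible per seed."""
    rng = np.random.default_rng(spec.seed)
    flat = [(etype, surf) for etype, surfs in spec.entity_lexicon.items()
            for surf in surfs]
    syn_keys = spec.synonym_table

    def one_sentence(sent_id: str) -> TaggedSentence:
        template = spec.templates[rng.integers(len(spec.templates))]
        slots = template.split().count("{E}")
        # surfaces unique within a sentence (guarantees corruption => reject)
        picks = [flat[i] for i in rng.choice(len(flat), size=slots,
                                             replace=False)]
        tokens: list[str] = []
        mentions: list[EntityMention] = []
        slot_i = 0
        for tok in template.split():
            if tok == "{E}":
                etype, surf = picks[slot_i]
                slot_i += 1
                start = len(tokens)
                tokens.extend(surf.split())
                mentions.append(EntityMention(sent_id, start, len(tokens),
                                              etype, surf))
            else:
                if tok in syn_keys and rng.random() < 0.5:
                    choices = [tok] + syn_keys[tok]
                    tok = choices[rng.integers(1, len(choices))]
                tokens.append(tok)
        return TaggedSentence(sent_id, tokens,
                              entities_to_labels(tokens, mentions))

    train = [one_sentence(f"train{i}") for i in range(spec.n_train)]
    test = [one_sentence(f"test{i}") for i in range(spec.n_test)]
    return train, test


class MockParaphraser:
    """Deterministic paraphraser satisfying the paraphraser contract."""

    def __init__(self, spec: SynthSpec):
        self.spec = spec
        self.entity_tokens = spec.entity_token_set()

    def _rng(self, text: str, seed: int) -> np.random.Generator:
        h = int.from_bytes(
            hashlib.md5(f"{text}|{seed}".encode()).digest()[:4], "little")
        return np.random.default_rng(h % (2 ** 31))

    def __call__(self, sentence_text: str, n: int, seed: int) -> list[str]:
        if n < 1:
            raise ValueError("need at least one paraphrase")
        rng = self._rng(sentence_text, seed)
        adverb_order = rng.permutation(len(ADVERBS))
        out: list[str] = []
        for i in range(n):
            tokens = sentence_text.split()
            # synonym substitution on non-entity tokens
            for j, tok in enumerate(tokens):
                alts = self.spec.synonym_table.get(tok)
                if alts and tok not in self.entity_tokens and rng.random() < 0.6:
                    tokens[j] = alts[rng.integers(len(alts))]
            # optional clause rotation around a preposition
            if rng.random() < 0.3:
                pivots = [j for j, t in enumerate(tokens)
                          if t in REORDER_PIVOTS and 0 < j < len(tokens) - 1]
                if pivots:
                    p = pivots[rng.integers(len(pivots))]
                    body, tail = tokens[:p], tokens[p:]
                    if tail and tail[-1] == ".":
                        tokens = tail[:-1] + body + ["."]
                    else:
                        tokens = tail + body
            # prepended adverb: a seeded permutation keeps the n outputs distinct
            adverb = ADVERBS[adverb_order[i % len(ADVERBS)]]
            tokens = [adverb] + tokens
            # entity corruption: delete one token of one mention
            if rng.random() < self.spec.entity_corruption_prob:
                ent_idx = [j for j, t in enumerate(tokens)
                           if t in self.entity_tokens]
                if ent_idx:
                    del tokens[ent_idx[rng.integers(len(ent_idx))]]
            out.append(" ".join(tokens))
        return out


def standard_benchmark() -> SynthSpec:
    """The fixed spec for the package's end-to-end synthetic experiments."""
    return SynthSpec()
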