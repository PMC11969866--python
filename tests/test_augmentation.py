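import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paraner.augmentation import (
    REPHRASE_INSTRUCTION,
    augment_dataset,
    build_prompt,
    is_augmented,
    localize_entities,
    project_labels,
    read_records,
    tokenize_paraphrase,
    write_records,
)
from paraner.corpus_io import EntityMention, TaggedSentence, labels_to_entities
from paraner.synthetic_data import MockParaphraser, SynthSpec, make_corpus


class TestBuildPrompt:
    def test_template_splice(self):
        assert build_prompt("Aspirin causes Reye syndrome .") == (
            "Aspirin causes Reye syndrome . Help me rephrase this sentence "
            "while preserving the original meaning."
        )

    def test_single_token(self):
        assert build_prompt("fever") == f"fever {REPHRASE_INSTRUCTION}"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_prompt("")


class TestTokenizeParaphrase:
    def test_punctuation_split(self):
        assert tokenize_paraphrase("Reye syndrome, caused by aspirin.") == \
            ["Reye", "syndrome", ",", "caused", "by", "aspirin", "."]

    def test_plain_whitespace(self):
        assert tokenize_paraphrase("a b") == ["a", "b"]

    def test_whitespace_only_rejected(self):
        with pytest.raises(ValueError):
            tokenize_paraphrase("   ")

    @given(st.lists(st.sampled_from(
        ["fever", "severe", "acute", ",", ".", "(", ")", "egfr"]),
        min_size=1, max_size=10))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_join_retokenize_idempotent(self, tokens):
        once = tokenize_paraphrase(" ".join(tokens))
        assert tokenize_paraphrase(" ".join(once)) == once


class TestLocalizeEntities:
    gold = [EntityMention("s", 0, 2, "D", "Reye syndrome")]

    def test_exact_match(self):
        toks = ["Reye", "syndrome", "can", "be", "caused", "by", "aspirin"]
        found, reason = localize_entities(toks, self.gold)
        assert reason is None
        assert [(m.start, m.end, m.etype) for m in found] == [(0, 2, "D")]

    def test_case_insensitive(self):
        found, reason = localize_entities(["reye", "SYNDROME"], self.gold)
        assert reason is None and len(found) == 1

    def test_missing_entity(self):
        found, reason = localize_entities(["aspirin", "only"], self.gold)
        assert found is None and reason == "missing_entity"

    def test_all_occurrences_labeled(self):
        toks = ["Reye", "syndrome", "and", "Reye", "syndrome"]
        found, _ = localize_entities(toks, self.gold)
        assert [(m.start, m.end) for m in found] == [(0, 2), (3, 5)]

    def test_longest_match_claims_first(self):
        gold = [EntityMention("s", 0, 2, "D", "reye syndrome"),
                EntityMention("s", 3, 4, "D", "reye")]
        toks = ["reye", "syndrome", "then", "reye"]
        found, reason = localize_entities(toks, gold)
        assert reason is None
        assert sorted((m.start, m.end) for m in found) == [(0, 2), (3, 4)]

    def test_nested_only_occurrence_is_count_mismatch(self):
        gold = [EntityMention("s", 0, 2, "D", "reye syndrome"),
                EntityMention("s", 3, 4, "D", "syndrome")]
        found, reason = localize_entities(["reye", "syndrome"], gold)
        assert found is None and reason == "count_mismatch"


class TestProjectLabels:
    def test_projection(self):
        located = [EntityMention("", 0, 2, "D", "a b")]
        sent = project_labels(["a", "b", "c", "d", "e", "f", "g"], located)
        assert sent.labels == ["B-D", "I-D", "O", "O", "O", "O", "O"]

    def test_no_mentions_all_outside(self):
        assert project_labels(["a", "b"], []).labels == ["O", "O"]

    @given(st.data())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_projection_roundtrip(self, data):
        n = data.draw(st.integers(1, 10))
        mentions, pos = [], 0
        while pos < n:
            start = data.draw(st.integers(pos, n))
            if start >= n:
                break
            end = data.draw(st.integers(start + 1, n))
            mentions.append(EntityMention("", start, end, "D",
                                          " ".join(f"w{i}" for i in range(start, end))))
            pos = end
        tokens = [f"w{i}" for i in range(n)]
        sent = project_labels(tokens, mentions)
        assert [(m.start, m.end) for m in labels_to_entities(sent)] == \
               [(m.start, m.end) for m in mentions]


class TestAugmentDataset:
    def test_clean_paraphraser_accepts_all(self, corpus, paraphraser):
        train, _ = corpus
        augmented, records = augment_dataset(train[:1], paraphraser,
                                             multiplier=5, seed=1)
        assert sum(r.status == "accepted" for r in records) == 5
        assert len(augmented) == 6  # original + 5

    def test_entity_deleting_paraphraser_rejects_all(self, corpus, spec):
        train, _ = corpus
        corrupting = MockParaphraser(SynthSpec(entity_corruption_prob=1.0))
        _, records = augment_dataset(train[:10], corrupting, multiplier=5,
                                     seed=1)
        assert all(r.status == "rejected" for r in records)
        assert {r.reject_reason for r in records} <= {"missing_entity",
                                                      "count_mismatch"}

    def test_acceptance_rate_tracks_corruption(self):
        spec = SynthSpec(n_train=200, n_test=1, entity_corruption_prob=0.4,
                         seed=5)
        train, _ = make_corpus(spec)
        _, records = augment_dataset(train, MockParaphraser(spec),
                                     multiplier=5, seed=17)
        rate = sum(r.status == "accepted" for r in records) / len(records)
        assert abs(rate - 0.6) < 0.05

    def test_entity_conservation(self, corpus, paraphraser):
        train, _ = corpus
        augmented, _ = augment_dataset(train[:20], paraphraser,
                                       multiplier=5, seed=3)
        originals = {s.sent_id: s for s in train[:20]}
        for s in augmented:
            if not is_augmented(s.sent_id):
                continue
            orig = originals[s.sent_id.split("::")[0]]
            orig_surfs = {(m.surface.lower(), m.etype)
                          for m in labels_to_entities(orig)}
            aug_surfs = {(m.surface.lower(), m.etype)
                         for m in labels_to_entities(s)}
            assert orig_surfs <= aug_surfs

    def test_bounded_expansion(self, corpus, paraphraser):
        train, _ = corpus
        augmented, records = augment_dataset(train[:15], paraphraser,
                                             multiplier=3, seed=9)
        accepted = sum(r.status == "accepted" for r in records)
        assert accepted <= 3 * 15
        assert len(augmented) == 15 + accepted

    def test_deterministic(self, corpus, paraphraser):
        train, _ = corpus
        a1, r1 = augment_dataset(train[:10], paraphraser, multiplier=5, seed=4)
        a2, r2 = augment_dataset(train[:10], paraphraser, multiplier=5, seed=4)
        assert [r.to_json() for r in r1] == [r.to_json() for r in r2]
        assert [(s.tokens, s.labels) for s in a1] == \
               [(s.tokens, s.labels) for s in a2]

    def test_duplicates_rejected(self):
        sent = TaggedSentence("s0", ["egfr", "rose", "."],
                              ["B-Gene", "O", "O"])

        def constant_paraphraser(text, n, seed):
            return ["notably egfr rose ."] * n

        _, records = augment_dataset([sent], constant_paraphraser,
                                     multiplier=3, seed=0)
        statuses = [r.status for r in records]
        assert statuses == ["accepted", "rejected", "rejected"]
        assert all(r.reject_reason == "duplicate"
                   for r in records if r.status == "rejected")

    def test_failing_paraphraser_rejects_empty_and_continues(self):
        sent = TaggedSentence("s0", ["egfr", "rose", "."],
                              ["B-Gene", "O", "O"])

        def broken(text, n, seed):
            raise RuntimeError("api down")

        augmented, records = augment_dataset([sent], broken, multiplier=4,
                                             seed=0)
        assert len(augmented) == 1
        assert [r.reject_reason for r in records] == ["empty"] * 4

    def test_records_jsonl_roundtrip(self, corpus, paraphraser):
        train, _ = corpus
        _, records = augment_dataset(train[:5], paraphraser, multiplier=2,
                                     seed=2)
        buf = io.StringIO()
        write_records(records, buf)
        back = read_records(io.StringIO(buf.getvalue()))
        assert [r.to_json() for r in back] == [r.to_json() for r in records]
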