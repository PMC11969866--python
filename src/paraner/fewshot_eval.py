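"""K-shot sampling, entity-level scoring and the few-shot protocol.

An episode samples K sentences uniformly without replacement from the
training pool and partitions them 8:2 into train/validation (the
validation share is ``max(1, round(0.2 K))``, so K=5 gives 4/1 and K=20
gives 16/4).  Each shot size is run under five seeds; evaluation is always
on the complete test set; per-seed entity F1 is aggregated as mean ±
sample standard deviation (ddof=1).

A predicted mention counts as a true positive only on exact
(sentence, span, type) match — strict CoNLL-style matching, no partial
credit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .augmentation import ParaphraserContract, augment_dataset, is_augmented
from .corpus_io import TaggedSentence, labels_to_entities, repair_bio
from .fusion_decoder import ModelConfig, train_model

logger = logging.getLogger(__name__)

DEFAULT_SHOTS = [5, 20, 50]
DEFAULT_SEEDS = [13, 42, 87, 100, 2023]


@dataclass
class KShotSplit:
    """One seeded few-shot episode."""

    k: int
    seed: int
    train: list[TaggedSentence]
    val: list[TaggedSentence]


@dataclass
class EvalResult:
    """Per-seed entity metrics for one shot size, plus the aggregate."""

    shot: int
    seeds: list[int]
    precision: list[float]
    recall: list[float]
    f1: list[float]
    mean_f1: float = field(init=False)
    std_f1: float = field(init=False)

    def __post_init__(self):
        arr = np.asarray(self.f1, dtype=float)
        self.mean_f1 = float(arr.mean())
        self.std_f1 = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0


def sample_kshot(pool: list[TaggedSentence], k: int, seed: int) -> KShotSplit:
    """Draw k sentences without replacement; last ~20% become validation."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(pool):
        raise ValueError(f"cannot sample {k} sentences from a pool of "
                         f"{len(pool)}")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(pool))[:k]
    drawn = [pool[i] for i in idx]
    n_val = max(1, int(round(0.2 * k)))
    return KShotSplit(k=k, seed=seed, train=drawn[:k - n_val],
                      val=drawn[k - n_val:])


def entity_prf(gold: list[TaggedSentence],
               pred: list[TaggedSentence]) -> tuple[float, float, float]:
    """Entity-level precision/recall/F1 in percent, strict span+type match."""
    if len(gold) != len(pred):
        raise ValueError(f"{len(gold)} gold vs {len(pred)} predicted sentences")
    gold_set: set[tuple] = set()
    pred_set: set[tuple] = set()
    for g, p in zip(gold, pred):
        if g.sent_id != p.sent_id or len(g.tokens) != len(p.tokens):
            raise ValueError(f"misaligned sentences: {g.sent_id} vs {p.sent_id}")
        for m in labels_to_entities(g):
            gold_set.add((g.sent_id, m.start, m.end, m.etype))
        plabels = p.labels if p.is_bio_valid() else repair_bio(p.labels)
        for m in labels_to_entities(TaggedSentence(p.sent_id, p.tokens, plabels)):
            pred_set.add((p.sent_id, m.start, m.end, m.etype))
    tp = len(gold_set & pred_set)
    precision = 100.0 * tp / len(pred_set) if pred_set else 0.0
    recall = 100.0 * tp / len(gold_set) if gold_set else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return precision, recall, f1


def run_experiment(
    train_pool: list[TaggedSentence],
    test_set: list[TaggedSentence],
    cfg: ModelConfig,
    shots: list[int] = None,
    seeds: list[int] = None,
    paraphraser: Optional[ParaphraserContract] = None,
    multiplier: int = 5,
    encoder=None,
) -> dict[int, EvalResult]:
    """The full few-shot protocol: sample → (augment train) → train → score.

    Augmentation, when a paraphraser is given, is applied to the episode's
    training split only — never to validation or test.
    """
    shots = list(shots) if shots is not None else list(DEFAULT_SHOTS)
    seeds = list(seeds) if seeds is not None else list(DEFAULT_SEEDS)
    results: dict[int, EvalResult] = {}
    for shot in shots:
        ps, rs, fs = [], [], []
        for seed in seeds:
            try:
                split = sample_kshot(train_pool, shot, seed)
                train = split.train
                if paraphraser is not None:
                    aug_seed = (seed * 9973 + multiplier) % (2 ** 31)
                    train, _ = augment_dataset(train, paraphraser,
                                               multiplier=multiplier,
                                               seed=aug_seed)
                assert not any(is_augmented(s.sent_id)
                               for s in split.val + list(test_set)), \
                    "augmented sentences leaked into val/test"
                run_cfg = ModelConfig(**{**cfg.__dict__, "seed": seed})
                model = train_model(train, split.val, run_cfg, encoder=encoder)
                preds = model.predict(test_set)
                p, r, f = entity_prf(test_set, preds)
            except Exception as exc:
                raise RuntimeError(
                    f"training failed at shot={shot} seed={seed}: {exc}"
                ) from exc
            logger.info("shot %d seed %d: P %.2f R %.2f F1 %.2f",
                        shot, seed, p, r, f)
            ps.append(p)
            rs.append(r)
            fs.append(f)
        results[shot] = EvalResult(shot, seeds, ps, rs, fs)
        logger.info("shot %d: F1 %.2f ± %.2f", shot,
                    results[shot].mean_f1, results[shot].std_f1)
    return results


def results_to_rows(results: dict[int, EvalResult]) -> list[dict]:
    """Flatten results into CSV-ready rows plus per-shot summary rows."""
    rows = []
    for shot in sorted(results):
        r = results[shot]
        for seed, p, rc, f in zip(r.seeds, r.precision, r.recall, r.f1):
            rows.append({"shot": shot, "seed": seed, "precision": round(p, 4),
                         "recall": round(rc, 4), "f1": round(f, 4)})
        rows.append({"shot": shot, "seed": "mean±std", "precision": "",
                     "recall": "", "f1": f"{r.mean_f1:.2f}±{r.std_f1:.2f}"})
    return rows
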