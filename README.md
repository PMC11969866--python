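# paraner

Few-shot biomedical named-entity recognition (NER) with LLM-paraphrase
data augmentation and multi-scale feature fusion.

Biomedical corpora are expensive to annotate, so NER models must often be
trained from a handful of labelled sentences (5–50). `paraner` implements
a complete few-shot pipeline for BIO-tagged corpora:

1. **Paraphrase data augmentation.** Each training sentence is spliced
   into a fixed rephrase prompt and sent to a pluggable paraphraser (a
   chat LLM in production; a deterministic mock in tests). Generated
   paraphrases are kept only if every original entity surface can be
   located in them by exact case-insensitive token matching; the original
   BIO labels are then projected onto the located spans. Asking for 5
   paraphrases per sentence expands the training pool roughly fivefold
   without label noise.
2. **Multi-scale feature fusion model.** Per-token contextual embeddings
   E come from a pluggable encoder (PubMedBERT-style transformer in
   production, a deterministic hash-embedding mock for tests). Three
   feature streams are combined:
   - per-token windows of widths K = {3, 5, 7} are read by per-scale
     BiLSTMs and concatenated into multi-scale features H;
   - a dynamic 1-D convolution D = Dconv(E), whose kernel is a softmax
     mixture α of M learned templates conditioned on the mean-pooled
     sentence (kernel 5, padding 2);
   - attention fusion O = softmax(o_l [E,H]ᵀ)[E,H] with per-token query
     o_l = Linear([e_t ; H_t]), followed by a gate
     g = σ(W_o O + b_o + W_d D + b_d),  h = g ⊙ O + (1−g) ⊙ D.
3. **Linear + CRF decoding.** Emissions Linear(h) feed a linear-chain CRF
   trained by negative log-likelihood and decoded by Viterbi
   (BIO-constrained at decode time).
4. **Few-shot protocol.** K ∈ {5, 20, 50} sentences are sampled per
   episode, split 8:2 into train/validation, run under 5 seeds, and
   scored on the full test set with strict entity-level F1, reported as
   mean ± sample standard deviation.

Every component is testable offline: a seeded synthetic-corpus generator
produces biomedical-style sentences with dictionary-drawn entity
mentions, and a mock paraphraser with a controllable entity-corruption
rate stands in for the LLM.

## Worked example

```
paraner synth --out data/
paraner sample --input data/train.conll --k 5 --seed 13 \
    --out-train data/k5.conll --out-val data/k5val.conll
paraner augment --input data/k5.conll --out data/k5aug.conll \
    --records data/records.jsonl --multiplier 5 --seed 1
```

The `synth` step writes a 400-sentence training pool and a 500-sentence
test set (two entity types, Disease and Gene). `sample` draws a 5-shot
episode (4 train / 1 validation sentences). `augment` then reports

```
INFO paraner: accepted 20 / 20 paraphrases
```

— every paraphrase of the 4 sentences preserved its entity mentions, so
the training pool grew from 4 to 24 sentences. Training and evaluating a
model on that episode with the desk-scale mock-encoder settings

```
cat > run.yaml <<EOF
encoder:
  width: 64
features:
  lstm_out: 32
train:
  lr_head: 0.003
  epochs: 18
  patience: 18
EOF
paraner train --config run.yaml --train data/k5aug.conll \
    --val data/k5val.conll --out data/model.npz
paraner predict --model data/model.npz --input data/test.conll \
    --out data/pred.conll
paraner evaluate --gold data/test.conll --pred data/pred.conll
```

prints

```
precision=35.64 recall=33.47 f1=34.52
```

(5-shot scores are low by design — four sentences cover only a fraction
of the entity vocabulary; at 50 shots the same pipeline reaches
F1 ≈ 91, see below). `paraner run-protocol --out results.csv` runs the
complete shots × seeds grid and writes per-seed and mean±std rows;
`paraner sweep --multipliers 1 2 5 --out sweep.csv` varies the
augmentation multiplier at a fixed shot size.

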