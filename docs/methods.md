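# Methods

This note documents the model, the synthetic study conditions, and the
numerical and design choices behind `paraner`. It is written for someone
who wants to understand *why* the package behaves as it does, not just
what its API is.

## The model

Input is a BIO-tagged sentence X = (x_1…x_n). A pluggable encoder maps
tokens to contextual embeddings E ∈ ℝ^{n×d} (one row per word; for
subword encoders the word vector is the first-subword vector). Three
stages build the representation the tagger decodes:

**Multi-scale features H.** For each odd scale k ∈ K (default {3, 5, 7})
every token receives a sliding window of k embedding rows centred on it,
zero-padded at sentence boundaries. A per-scale BiLSTM (output 256 by
default, 128 per direction; per-scale parameters are not shared) reads
the window; the token's feature is the concatenation of the final
forward and backward states. Blocks are concatenated ascending-scale
into H ∈ ℝ^{n×(|K|·256)}. Windows rather than disjoint chunks keep H
token-aligned, which the attention fusion requires. A token's H row is
therefore exactly invariant to edits farther than (max K − 1)/2 tokens
away — a property the tests assert bit-exactly.

**Dynamic convolution D.** The effective 1-D kernel (width 5, padding 2,
so sequence length is preserved) is a convex mixture of M = 4 learned
kernel templates. Mixture weights α = softmax(MLP(mean-pooled E)) are
computed once per sentence; the mixture is global, so D's radius-2
locality holds only with α frozen, and the tests assert that conditional
form. With a one-hot α, dynamic convolution equals static convolution
with the selected template exactly — the degeneracy check used in the
tests. M = 4 follows common dynamic-convolution practice; the attention
temperature is 1.

**Fusion and gate.** E-rows and H-rows are linearly projected to a
shared width d_v and stacked into a 2n-row value bank V (keys = values).
Token t's query is a linear map of [e_t ; H_t]; O_t is the
softmax-attention read over V — a convex combination of projected
feature rows. Scores are scaled by 1/√d_v (standard scaled dot-product
attention). The query's E-block is initialised as a copy of the E-side
value projection, so attention is born near-diagonal — each token reads
mostly its own row — and training redistributes it; with a random query
the early attention is diffuse, which on small training sets led to
memorisation through sentence-level attention patterns rather than
per-token features. d_v defaults to |K|·lstm_out (768 at production
widths) so O, D and the gate share one width. The gate
g = σ(O·W_o + b_o + D·W_d + b_d) blends h = g⊙O + (1−g)⊙D; h is
elementwise boxed between O and D by construction.

**Decoder.** A linear layer maps h to per-tag emissions; a linear-chain
CRF scores a path as start[y_1] + Σ_t em[t, y_t] + Σ_t T[y_t, y_{t+1}] +
end[y_n]. Training minimises NLL with the log-space forward algorithm;
the forward pass, Viterbi and the NLL gradient are verified against
exhaustive enumeration and finite differences on hundreds of random
small chains. Decoding adds a −10⁴ mask to transitions that would start
an entity with I- or continue it across a type change, so decoded
sequences are always BIO-valid; without the mask an interior label flip
splits one mention into two (one false negative plus two false
positives), which measurably depressed entity F1. Training is left
unconstrained; `repair_bio` (orphan I- promoted to B-) remains as a
safety net and as the repair tool for external corpora. Viterbi ties
break toward the lowest label index for determinism.

**Ablations.** Config flags reproduce the reduced variants: no
multi-scale stream (value bank is projected E only), no dynamic
convolution (h = O), attention replaced by elementwise addition of the
projected streams, gate replaced by O + D, and augmentation off.

## Data augmentation

The prompt is the original sentence followed by a fixed instruction
("Help me rephrase this sentence while preserving the original
meaning."). For each sentence the paraphraser is asked for `multiplier`
(default 5) rewrites. Each paraphrase is tokenized (whitespace, with
.,;:!?()[] split off), and every gold entity surface is searched as a
case-insensitive exact token sequence; longer surfaces claim positions
first, and all occurrences of a surface are labelled (an unlabelled
extra occurrence would train a false negative). A paraphrase is accepted
only if every original surface is found and the located spans do not
overlap; duplicates of the original or of an earlier accepted paraphrase
are rejected, as are empty outputs and paraphraser failures. Accepted
paraphrases carry an `::aug` provenance tag and join the training pool
only — never validation or test. Rejected slots are not retried. No
fuzzy or stem matching is attempted: the filter's purpose is label
precision, and fuzzy matching would reintroduce exactly the label noise
it exists to remove.

## Training

Adam at head learning rate 1e-3 (production default; 3e-3 in the
desk-scale benchmark config) with a linear warmup over the first tenth
of epochs and cosine decay to zero. Warmup matters beyond optimisation
folklore here: model selection is best-validation-F1 over epochs, the
few-shot validation set is tiny (1–10 sentences), and without warmup a
half-converged early epoch can win the selection on validation luck
while still being poor on test. Validation-F1 ties resolve to the later
(more converged) epoch for the same reason. Gradients are clipped to
global norm 5. Inverted dropout at rate 0.5 is applied to the encoder
output E during training. It is deliberately *not* applied to the fused
representation h: dropping h immediately before the emission layer
corrupts the label scores the CRF fits and cost 6–8 entity F1 at every
width tested. An encoder learning rate (1e-5) is exposed for
fine-tunable transformer encoders; the mock encoder is frozen and has no
trainable parameters. If the validation set is empty the final-epoch
model is used, with a warning.

## Synthetic study conditions

The generator emulates short biomedical-style sentences: a carrier
template ("the patient developed {E} after treatment .") instantiated
with 1–3 typed entity mentions, with synonym substitution on carrier
tokens. Three token classes — entity tokens, carrier/synonym tokens, and
the adverbs the mock paraphraser prepends — are pairwise disjoint, so
entity localization has unambiguous ground truth and tests can assert
exact expectations.

Entity surfaces have head + tail structure ("braf", "braf kinase",
"braf kinase domain" style): heads appear only surface-initial, tails
only surface-internal, so token identity determines B vs I — the
positional regularity head nouns and qualifiers show in real biomedical
mentions. The standard benchmark fixes 2 types × 20 surfaces built from
8 heads + 4 tails per type, a 400-sentence training pool, a 500-sentence
test set, and seed 7. The head/tail vocabularies are sized so that a
50-sentence sample almost surely contains every entity token: the mock
encoder's hash embeddings carry no semantics, so an entity token never
seen in training is unclassifiable in principle, and a larger vocabulary
would turn the benchmark into a test of sampling luck rather than of the
model.

The mock encoder is a frozen hash-seeded embedding table plus one frozen
bidirectional Elman layer; a token's output row is its own embedding
(half the width) next to the forward/backward states (a quarter each).
Embeddings are half-dense ±√2 codes: near-orthogonal like one-hot rows,
linearly separable at moderate width, robust to 0.5 dropout, and
platform-stable via md5. Both properties mirror the transformer the mock
stands in for — token vectors dominated by the token itself, with
context modulation — and both were necessary: purely recurrent outputs
made token identity hard to recover, and dense Gaussian codes were not
linearly separable at desk widths.

The mock paraphraser applies seeded synonym substitution on non-entity
tokens, optional clause rotation around a preposition, and a prepended
adverb drawn from a seeded permutation (making the n paraphrases of a
sentence pairwise distinct for n ≤ 20). With probability
`entity_corruption_prob` it deletes one token of one entity mention;
surfaces are unique within a sentence, so a corrupted paraphrase is
guaranteed to fail localization. Acceptance rate therefore converges to
1 − corruption, which the tests check as a binomial 3σ band at ~1000
attempts.

What the synthetic conditions do **not** emulate: real PubMed token
distributions, subword tokenization, semantically informative
embeddings for unseen mentions, nested or discontinuous entities, and
LLM paraphrase pathologies beyond entity loss (hallucinated entities,
meaning drift). Passing the synthetic suite shows the pipeline's
mechanics are correct under controlled conditions, not that real-corpus
scores transfer.

## Desk-scale configuration

The benchmark config narrows widths so a full five-seed protocol runs in
CPU-minutes while keeping the production structure (scales 3/5/7,
kernel 5, dropout 0.5, 4 templates): mock encoder width 64, per-scale
BiLSTM output 32, d_v = 96, head lr 3e-3, 18 epochs. Width 64 comes from
a linear-probe analysis: hash-coded token identity stops being linearly
separable below roughly the vocabulary size (~116 token types), so
narrower mocks put a representational ceiling well under what the model
can learn. Production defaults (encoder 768/256-width layers, lr 1e-5
encoder fine-tuning) remain in the config for transformer-backed runs.

## Protocol and metrics

`sample_kshot` draws K sentences uniformly without replacement and
assigns the last max(1, round(0.2 K)) of the shuffled draw to
validation: K=5 → 4/1, K=20 → 16/4, K=50 → 40/10. Five seeds
(13, 42, 87, 100, 2023 by default; the protocol treats them as opaque
labels) give per-seed entity F1 on the complete test set, aggregated as
mean ± sample standard deviation (ddof = 1, fixed). Scoring is strict:
a predicted mention counts only on exact (sentence, span, type) match;
empty denominators score 0. Augmentation, when enabled, happens after
the split and touches only the training half.

## Known limitations

- The numpy autodiff engine is single-threaded and sentence-batched;
  it is sized for desk-scale experiments, not GPU-scale training.
- The transformer encoder adapter is untested in this repository (its
  dependencies are optional); the contract it implements is exercised
  through the mock.
- The augmentation filter requires verbatim entity surfaces; a
  paraphraser that legitimately inflects an entity ("tumours" for
  "tumour") is rejected rather than matched.
- 5-shot scores on the synthetic benchmark are bounded by entity-token
  coverage of the 4-sentence training set, not by the model; comparisons
  at 5 shots are meaningful only between configurations sharing the same
  episodes, as in the augmentation on/off experiment.
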