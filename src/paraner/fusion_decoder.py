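"""Feature fusion, CRF decoding and model training.

The fused representation is built in three steps:

1. **Attention fusion** — the encoder features E and the multi-scale
   features H are each linearly projected to a shared width ``d_v`` and
   stacked row-wise into a value bank V (2n rows for an n-token sentence).
   Each token's query is a linear map of its concatenated ``[e_t ; H_t]``;
   its output row O_t is the softmax-attention read over V, i.e. a convex
   combination of projected feature rows.

2. **Gated blending** — a sigmoid gate ``g = σ(O·W_o + b_o + D·W_d + b_d)``
   blends the attention output O with the dynamic-convolution output D
   elementwise: ``h = g ⊙ O + (1 − g) ⊙ D``, so h is boxed between O and D.

3. **Linear + CRF** — a linear layer maps h to per-tag emission scores and
   a linear-chain CRF scores label paths as
   ``start[y_1] + Σ emissions[t, y_t] + Σ transitions[y_t, y_{t+1}] + end[y_n]``.
   Training minimises the negative log-likelihood (log-partition by the
   log-space forward algorithm); decoding is Viterbi with ties broken
   toward the lowest label index.

Ablation flags reproduce the reduced variants: no multi-scale stream, no
dynamic convolution, attention replaced by elementwise addition of the
projected streams, gate replaced by plain addition.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .corpus_io import TaggedSentence, repair_bio
from .encoder import MockEncoder, TokenEmbeddings, encode
from .features import (
    DconvParams,
    LSTMParams,
    ScaleConfig,
    dynamic_conv_t,
    init_dconv,
    init_lstm,
    multiscale_t,
)

logger = logging.getLogger(__name__)


# -- fusion parameter containers ---------------------------------------------

@dataclass
class AttentionParams:
    """Projections to the shared fusion width d_v (E-side, H-side, query)."""

    P_e: Tensor
    b_e: Tensor
    P_q: Tensor
    b_q: Tensor
    P_h: Optional[Tensor] = None
    b_h: Optional[Tensor] = None


@dataclass
class GateParams:
    """Affine maps of O and D into the shared gate pre-activation."""

    W_o: Tensor
    b_o: Tensor
    W_d: Tensor
    b_d: Tensor


@dataclass
class FusionOutput:
    matrix: np.ndarray     # (n, d_v)
    attention: np.ndarray  # (n, n_keys), rows sum to 1


@dataclass
class FusedRepr:
    matrix: np.ndarray  # (n, d_v)


@dataclass
class CRFParams:
    """Transition structure of the linear-chain CRF (L = tagset size)."""

    transitions: Tensor  # (L, L), transitions[a, b] = score of a -> b
    start: Tensor        # (L,)
    end: Tensor          # (L,)

    @property
    def n_labels(self) -> int:
        return self.start.shape[0]


# -- fusion operations --------------------------------------------------------

def attention_fuse_t(E: Tensor, H: Optional[Tensor], p: AttentionParams,
                     temperature: float = 1.0, scaled: bool = True,
                     use_attention: bool = True) -> tuple[Tensor, Optional[Tensor]]:
    """Fuse E and H into O; returns (O, attention rows or None).

    ``scaled`` divides the query-key dot products by sqrt(d_v) (standard
    scaled dot-product attention); ``temperature`` further sharpens
    (→0) or flattens (→∞) the attention distribution.
    """
    if H is not None and E.shape[0] != H.shape[0]:
        raise ValueError(
            f"E has {E.shape[0]} rows but H has {H.shape[0]}; "
            "streams must be token-aligned")
    Ve = E @ p.P_e + p.b_e
    if H is not None:
        if p.P_h is None:
            raise ValueError("H given but no H-side projection parameters")
        Vh = H @ p.P_h + p.b_h
        if not use_attention:
            return Ve + Vh, None
        V = ad.concat([Ve, Vh], axis=0)
        Q = ad.concat([E, H], axis=1) @ p.P_q + p.b_q
    else:
        if not use_attention:
            return Ve, None
        V = Ve
        Q = E @ p.P_q + p.b_q
    denom = temperature * (np.sqrt(V.shape[1]) if scaled else 1.0)
    scores = (Q @ V.T) * (1.0 / denom)
    attn = ad.softmax(scores, axis=-1)
    return attn @ V, attn


def attention_fuse(E: np.ndarray, H: Optional[np.ndarray], p: AttentionParams,
                   temperature: float = 1.0, scaled: bool = True,
                   use_attention: bool = True) -> FusionOutput:
    with ad.no_grad():
        O, attn = attention_fuse_t(Tensor(E), None if H is None else Tensor(H),
                                   p, temperature, scaled, use_attention)
    return FusionOutput(O.data, attn.data if attn is not None else
                        np.zeros((E.shape[0], 0)))


def gate_fuse_t(O: Tensor, D: Tensor, p: GateParams,
                use_gate: bool = True) -> tuple[Tensor, Optional[Tensor]]:
    """Blend O and D; returns (h, gate values or None)."""
    if O.shape != D.shape:
        raise ValueError(f"O shape {O.shape} != D shape {D.shape}")
    if not use_gate:
        return O + D, None
    g = ad.sigmoid(O @ p.W_o + p.b_o + D @ p.W_d + p.b_d)
    return g * O + (1.0 - g) * D, g


def gate_fuse(O: np.ndarray, D: np.ndarray, p: GateParams,
              use_gate: bool = True) -> FusedRepr:
    with ad.no_grad():
        h, _ = gate_fuse_t(Tensor(O), Tensor(D), p, use_gate)
    return FusedRepr(h.data)


# -- CRF ----------------------------------------------------------------------

def crf_score(emissions: np.ndarray, transitions: np.ndarray,
              start: np.ndarray, end: np.ndarray, path: list[int]) -> float:
    """Score one label path under the linear-chain CRF."""
    n, L = emissions.shape
    if len(path) != n:
        raise ValueError(f"path length {len(path)} != sequence length {n}")
    path = list(path)
    if any(y < 0 or y >= L for y in path):
        raise IndexError("label index out of range")
    s = start[path[0]] + end[path[-1]]
    s += sum(emissions[t, y] for t, y in enumerate(path))
    s += sum(transitions[a, b] for a, b in zip(path[:-1], path[1:]))
    return float(s)


def crf_nll_t(emissions: Tensor, crf: CRFParams, path: list[int]) -> Tensor:
    """Negative log-likelihood of `path`: log Z − score(path)."""
    n, L = emissions.shape
    if len(path) != n:
        raise ValueError(f"path length {len(path)} != sequence length {n}")
    if not np.all(np.isfinite(emissions.data)):
        raise ValueError("non-finite emission scores")
    alpha = crf.start + emissions[0]
    for t in range(1, n):
        scores = (alpha.reshape(L, 1) + crf.transitions
                  + emissions[t].reshape(1, L))
        alpha = ad.logsumexp(scores, axis=0)
    log_z = ad.logsumexp(alpha + crf.end, axis=0)
    idx = np.asarray(path)
    gold = (crf.start[idx[0]] + crf.end[idx[-1]]
            + emissions[np.arange(n), idx].sum())
    if n > 1:
        gold = gold + crf.transitions[idx[:-1], idx[1:]].sum()
    return log_z - gold


def crf_nll(emissions: np.ndarray, crf: CRFParams, path: list[int]) -> float:
    with ad.no_grad():
        return float(crf_nll_t(Tensor(emissions), crf, path).data)


def crf_decode(emissions: np.ndarray, transitions: np.ndarray,
               start: np.ndarray, end: np.ndarray) -> list[int]:
    """Viterbi decoding; ties break toward the lowest label index."""
    n, L = emissions.shape
    if n == 0:
        raise ValueError("cannot decode an empty sequence")
    delta = start + emissions[0]
    back = np.zeros((n, L), dtype=int)
    for t in range(1, n):
        scores = delta[:, None] + transitions  # (prev, next)
        best_prev = scores.argmax(axis=0)      # first max = lowest index
        back[t] = best_prev
        delta = scores[best_prev, np.arange(L)] + emissions[t]
    delta = delta + end
    y = int(delta.argmax())
    path = [y]
    for t in range(n - 1, 0, -1):
        y = int(back[t, y])
        path.append(y)
    return path[::-1]


# -- model --------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    ``d_v`` defaults to ``len(scales) * lstm_out`` so the attention output,
    the dynamic-convolution output and the gate all share one width.
    """

    encoder_width: int = 32
    max_len: int = 256
    scales: list[int] = field(default_factory=lambda: [3, 5, 7])
    lstm_out: int = 256
    d_v: Optional[int] = None
    dconv_kernel: int = 5
    dconv_templates: int = 4
    dropout: float = 0.5
    lr_head: float = 1e-3
    lr_encoder: float = 1e-5
    epochs: int = 50
    patience: int = 15
    seed: int = 0
    ablate_multiscale: bool = False
    ablate_dconv: bool = False
    ablate_attention: bool = False
    ablate_gate: bool = False

    @property
    def fused_width(self) -> int:
        return self.d_v if self.d_v is not None else len(self.scales) * self.lstm_out


class NerModel:
    """The full fusion model: encoder -> (H, D) -> attention -> gate -> CRF."""

    def __init__(self, cfg: ModelConfig, tagset: list[str],
                 encoder=None):
        self.cfg = cfg
        self.tagset = list(tagset)
        if "O" not in self.tagset:
            self.tagset.append("O")
            self.tagset.sort()
        self.encoder = encoder if encoder is not None else MockEncoder(
            cfg.encoder_width, cfg.seed)
        self._build_params()

    # -- parameter construction ----------------------------------------------
    def _build_params(self):
        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed + 12582917)
        d = self.encoder.width
        d_v = cfg.fused_width
        L = len(self.tagset)
        self.params: dict[str, Tensor] = {}

        def reg(name, t: Tensor) -> Tensor:
            self.params[name] = t
            return t

        def mk(name, shape):
            return reg(name, Tensor(ad.glorot(rng, shape), requires_grad=True))

        def mkz(name, shape):
            return reg(name, Tensor(np.zeros(shape), requires_grad=True))

        self.scale_cfg = ScaleConfig(list(cfg.scales), cfg.lstm_out)
        self.lstm_params: list[LSTMParams] = []
        d_h = 0
        if not cfg.ablate_multiscale:
            for k in sorted(cfg.scales):
                p = init_lstm(rng, d, cfg.lstm_out)
                for fname in ("W_f", "U_f", "b_f", "W_b", "U_b", "b_b"):
                    reg(f"lstm{k}.{fname}", getattr(p, fname))
                self.lstm_params.append(p)
            d_h = len(cfg.scales) * cfg.lstm_out

        self.dconv_params: Optional[DconvParams] = None
        if not cfg.ablate_dconv:
            p = init_dconv(rng, d, d_v, cfg.dconv_kernel, cfg.dconv_templates)
            for fname in ("templates", "W1", "b1", "W2", "b2"):
                reg(f"dconv.{fname}", getattr(p, fname))
            self.dconv_params = p

        # The query's E-block starts as a copy of the E-side value projection
        # so attention is born near-diagonal (each token reads mostly its own
        # row) and training sharpens or redistributes it from there.
        if cfg.ablate_multiscale:
            P_e = mk("attn.P_e", (d, d_v))
            P_q = reg("attn.P_q", Tensor(P_e.data.copy(), requires_grad=True))
            self.attn_params = AttentionParams(
                P_e=P_e, b_e=mkz("attn.b_e", (d_v,)),
                P_q=P_q, b_q=mkz("attn.b_q", (d_v,)),
            )
        else:
            P_e = mk("attn.P_e", (d, d_v))
            P_q = Tensor(np.concatenate(
                [P_e.data.copy(), ad.glorot(rng, (d_h, d_v)) * 0.1]),
                requires_grad=True)
            self.attn_params = AttentionParams(
                P_e=P_e, b_e=mkz("attn.b_e", (d_v,)),
                P_q=reg("attn.P_q", P_q), b_q=mkz("attn.b_q", (d_v,)),
                P_h=mk("attn.P_h", (d_h, d_v)), b_h=mkz("attn.b_h", (d_v,)),
            )

        self.gate_params: Optional[GateParams] = None
        if not cfg.ablate_dconv and not cfg.ablate_gate:
            self.gate_params = GateParams(
                W_o=mk("gate.W_o", (d_v, d_v)), b_o=mkz("gate.b_o", (d_v,)),
                W_d=mk("gate.W_d", (d_v, d_v)), b_d=mkz("gate.b_d", (d_v,)),
            )

        self.W_out = mk("out.W", (d_v, L))
        self.b_out = mkz("out.b", (L,))
        self.crf = CRFParams(
            transitions=mkz("crf.transitions", (L, L)),
            start=mkz("crf.start", (L,)),
            end=mkz("crf.end", (L,)),
        )

    # -- forward --------------------------------------------------------------
    def forward_emissions(self, tokens: list[str], train: bool = False,
                          drop_rng: Optional[np.random.Generator] = None) -> Tensor:
        """Per-token emission scores.  During training, inverted dropout is
        applied to the encoder output E (the model's single dropout site;
        dropping the fused representation right before the emission layer
        corrupts label scores directly and destabilises the CRF fit)."""
        cfg = self.cfg
        emb = encode(tokens, self.encoder, cfg.max_len)
        E = Tensor(emb.matrix)

        def dropout(x: Tensor) -> Tensor:
            if not train or cfg.dropout <= 0:
                return x
            keep = 1.0 - cfg.dropout
            mask = (drop_rng.random(x.shape) < keep) / keep
            return x * Tensor(mask)

        E = dropout(E)
        H = None
        if not cfg.ablate_multiscale:
            H = multiscale_t(E, self.scale_cfg, self.lstm_params)
        O, _ = attention_fuse_t(E, H, self.attn_params,
                                use_attention=not cfg.ablate_attention)
        if not cfg.ablate_dconv:
            D, _ = dynamic_conv_t(E, self.dconv_params)
            h, _ = gate_fuse_t(O, D, self.gate_params,
                               use_gate=not cfg.ablate_gate)
        else:
            h = O
        return h @ self.W_out + self.b_out

    def sentence_loss(self, sent: TaggedSentence,
                      drop_rng: Optional[np.random.Generator] = None,
                      train: bool = True) -> Tensor:
        tokens = sent.tokens[:self.cfg.max_len]
        labels = sent.labels[:self.cfg.max_len]
        emissions = self.forward_emissions(tokens, train=train,
                                           drop_rng=drop_rng)
        path = [self.tagset.index(lab) for lab in labels]
        return crf_nll_t(emissions, self.crf, path)

    # -- training -------------------------------------------------------------
    def fit(self, train: list[TaggedSentence],
            val: list[TaggedSentence]) -> "NerModel":
        from .fewshot_eval import entity_prf  # local import avoids a cycle

        cfg = self.cfg
        if not train:
            raise ValueError("training set is empty")
        rng = np.random.default_rng(cfg.seed)
        opt = Adam(self.params, lr=cfg.lr_head)
        best_f1 = -1.0
        best_state: Optional[dict[str, np.ndarray]] = None
        epochs_since_best = 0
        if not val:
            logger.warning("validation set empty; "
                           "falling back to the final-epoch model")
        for epoch in range(cfg.epochs):
            # warmup + cosine decay: early epochs ramp up (a half-converged
            # model cannot win the val-F1 selection by luck), late epochs
            # take small steps so the model settles instead of bouncing
            # between sharp minima
            warmup = max(1, cfg.epochs // 10)
            ramp = min(1.0, (epoch + 1) / warmup)
            opt.lr = cfg.lr_head * ramp * 0.5 * (
                1.0 + np.cos(np.pi * epoch / max(1, cfg.epochs)))
            order = rng.permutation(len(train))
            total = 0.0
            for i in order:
                loss = self.sentence_loss(train[i], drop_rng=rng)
                loss.backward()
                self._clip_grads(5.0)
                opt.step()
                opt.zero_grad()
                total += float(loss.data)
            if val:
                preds = self.predict(val)
                _, _, f1 = entity_prf(val, preds)
                logger.debug("epoch %d: loss %.4f val F1 %.2f",
                             epoch, total / len(train), f1)
                # ties go to the later epoch: with a small validation set
                # the F1 takes few distinct values, and the later of two
                # equal-val epochs is the more converged model
                if f1 >= best_f1:
                    best_f1 = f1
                    best_state = {k: p.data.copy()
                                  for k, p in self.params.items()}
                    epochs_since_best = 0
                else:
                    epochs_since_best += 1
                    if epochs_since_best >= cfg.patience:
                        logger.info("early stop at epoch %d (best val F1 %.2f)",
                                    epoch, best_f1)
                        break
        if best_state is not None:
            for k, p in self.params.items():
                p.data = best_state[k]
        return self

    def _clip_grads(self, max_norm: float):
        total = 0.0
        for p in self.params.values():
            if p.grad is not None:
                total += float((p.grad ** 2).sum())
        norm = np.sqrt(total)
        if norm > max_norm:
            scale = max_norm / norm
            for p in self.params.values():
                if p.grad is not None:
                    p.grad *= scale

    # -- inference ------------------------------------------------------------
    def _bio_decode_mask(self) -> tuple[np.ndarray, np.ndarray]:
        """Additive Viterbi masks forbidding invalid BIO transitions.

        Training leaves transitions unconstrained (the CRF learns them);
        decoding masks paths that start with I- or continue an entity of a
        different type, so every decoded sequence is BIO-valid and interior
        label flips cannot split a mention in two.
        """
        tags = self.tagset
        L = len(tags)
        trans = np.zeros((L, L))
        for a in range(L):
            for b in range(L):
                if tags[b].startswith("I-"):
                    if tags[a] == "O" or tags[a][2:] != tags[b][2:]:
                        trans[a, b] = -1e4
        start = np.array([-1e4 if t.startswith("I-") else 0.0 for t in tags])
        return trans, start

    def predict(self, sentences: list[TaggedSentence]) -> list[TaggedSentence]:
        out = []
        n_repaired = 0
        mask_t, mask_s = self._bio_decode_mask()
        with ad.no_grad():
            for sent in sentences:
                tokens = sent.tokens[:self.cfg.max_len]
                emissions = self.forward_emissions(tokens, train=False).data
                path = crf_decode(emissions,
                                  self.crf.transitions.data + mask_t,
                                  self.crf.start.data + mask_s,
                                  self.crf.end.data)
                labels = [self.tagset[y] for y in path]
                repaired = repair_bio(labels, policy="promote")
                if repaired != labels:
                    n_repaired += 1
                if len(sent.tokens) > len(repaired):
                    repaired += ["O"] * (len(sent.tokens) - len(repaired))
                out.append(TaggedSentence(sent.sent_id, list(sent.tokens),
                                          repaired))
        if n_repaired:
            logger.info("repaired BIO transitions in %d predictions",
                        n_repaired)
        return out

    # -- checkpointing --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: all parameters + config + tagset."""
        meta = json.dumps({"config": asdict(self.cfg), "tagset": self.tagset})
        arrays = {k.replace(".", "__"): p.data for k, p in self.params.items()}
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str | Path, encoder=None) -> "NerModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            cfg = ModelConfig(**meta["config"])
            model = cls(cfg, meta["tagset"], encoder=encoder)
            for k, p in model.params.items():
                p.data = data[k.replace(".", "__")].astype(np.float64)
        return model


def train_model(train: list[TaggedSentence], val: list[TaggedSentence],
                cfg: ModelConfig, encoder=None) -> NerModel:
    """Build the tagset from train ∪ val and fit the full model."""
    tags = sorted({lab for s in list(train) + list(val) for lab in s.labels}
                  | {"O"})
    model = NerModel(cfg, tags, encoder=encoder)
    return model.fit(train, val)


def predict(model: NerModel,
            sentences: list[TaggedSentence]) -> list[TaggedSentence]:
    """Viterbi-decode labels for `sentences` (gold labels ignored)."""
    return model.predict(sentences)
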