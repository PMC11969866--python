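"""Pluggable per-token contextual embeddings.

Any callable that maps a token list to an ``n_tokens x d`` matrix satisfies
the encoder contract.  The production choice for biomedical text is a
domain-pretrained transformer (PubMedBERT) behind :class:`HFEncoder`,
which is imported lazily so the package has no hard dependency on it.
The default for tests and desk-scale experiments is :class:`MockEncoder`:
a frozen, seeded random embedding table followed by one frozen
bidirectional recurrent layer — deterministic, CPU-instant, and
contextual (a token's vector depends on its neighbours).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Protocol

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_MAX_LEN = 256


@dataclass
class TokenEmbeddings:
    """Per-token embedding matrix E, one row per word of the sentence."""

    sent_id: str
    matrix: np.ndarray  # (n_tokens, d)

    @property
    def d(self) -> int:
        return self.matrix.shape[1]

    def __post_init__(self):
        if self.matrix.ndim != 2:
            raise ValueError("embedding matrix must be 2-D")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("embedding matrix contains non-finite values")


class EncoderContract(Protocol):
    """Deterministic token-list -> embedding-matrix callable of width `width`."""

    width: int

    def __call__(self, tokens: list[str]) -> np.ndarray:
        ...


def _token_vector(token: str, width: int, seed: int) -> np.ndarray:
    """Stable sparse random vector per (token, seed).

    Feature-hashing style: md5 of the token seeds a generator that places
    ``width/2`` entries of value ±sqrt(2) (unit variance overall).
    Half-dense ± codes keep distinct tokens near-orthogonal and linearly
    separable at moderate width — as one-hot rows would be — while staying
    vocabulary-free and robust to the 0.5 dropout applied during training.
    md5 makes the table platform- and run-stable.
    """
    h = int.from_bytes(hashlib.md5(token.encode("utf-8")).digest()[:4], "little")
    rng = np.random.default_rng(((seed + 1) * 2654435761 + h) % (2 ** 31))
    k = max(1, width // 2)
    vec = np.zeros(width)
    idx = rng.choice(width, size=k, replace=False)
    vec[idx] = rng.choice([-1.0, 1.0], size=k) * np.sqrt(width / k)
    return vec


class MockEncoder:
    """Frozen random embedding table + one frozen bidirectional Elman layer.

    Embeddings are hash-seeded so any token — seen or unseen — gets a
    stable vector.  The output row for a token is its own embedding
    (width/2 dims) concatenated with the forward and backward recurrent
    states (width/4 each): contextual, like the transformer it stands in
    for, but with token identity still carried explicitly — mirroring how
    a pretrained encoder's token vectors remain dominated by the token
    itself.
    """

    def __init__(self, width: int = 32, seed: int = 0):
        if width % 4 != 0:
            raise ValueError("mock encoder width must be a multiple of 4")
        self.width = width
        self.seed = seed
        e, h = width // 2, width // 4
        rng = np.random.default_rng(seed + 104729)
        self._W = rng.standard_normal((e, h)) / np.sqrt(e)
        self._U = rng.standard_normal((h, h)) * (0.5 / np.sqrt(h))
        self._b = np.zeros(h)

    def __call__(self, tokens: list[str]) -> np.ndarray:
        e, h = self.width // 2, self.width // 4
        emb = np.stack([_token_vector(t, e, self.seed) for t in tokens])
        n = len(tokens)
        fwd = np.zeros((n, h))
        bwd = np.zeros((n, h))
        state = np.zeros(h)
        for t in range(n):
            state = np.tanh(emb[t] @ self._W + state @ self._U + self._b)
            fwd[t] = state
        state = np.zeros(h)
        for t in range(n - 1, -1, -1):
            state = np.tanh(emb[t] @ self._W + state @ self._U + self._b)
            bwd[t] = state
        return np.concatenate([emb, fwd, bwd], axis=1)


class HFEncoder:
    """Transformer encoder adapter (production default: PubMedBERT).

    Word vectors are the first-subword hidden states; special tokens are
    excluded.  Requires the optional ``transformers`` + ``torch`` stack.
    """

    def __init__(self, model_name: str =
                 "microsoft/BiomedNLP-PubMedBERT-base-uncased-abstract"):
        try:
            import torch  # noqa: F401
            from transformers import AutoModel, AutoTokenizer
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "HFEncoder needs the 'transformers' and 'torch' packages; "
                "install them or use the mock encoder"
            ) from exc
        self._tokenizer = AutoTokenizer.from_pretrained(model_name)
        self._model = AutoModel.from_pretrained(model_name)
        self._model.eval()
        self.width = self._model.config.hidden_size

    def __call__(self, tokens: list[str]) -> np.ndarray:  # pragma: no cover
        import torch

        enc = self._tokenizer(tokens, is_split_into_words=True,
                              return_tensors="pt", truncation=True)
        with torch.no_grad():
            hidden = self._model(**enc).last_hidden_state[0]
        word_ids = enc.word_ids(0)
        rows = []
        seen = set()
        for pos, wid in enumerate(word_ids):
            if wid is not None and wid not in seen:
                seen.add(wid)
                rows.append(hidden[pos].numpy())
        return np.stack(rows)


def encode(tokens: list[str], encoder: EncoderContract,
           max_len: int = DEFAULT_MAX_LEN, sent_id: str = "") -> TokenEmbeddings:
    """Run the encoder; over-length sentences are truncated with a warning.

    Callers holding labels must truncate them in lockstep (see
    :func:`truncate_sentence`).
    """
    if not tokens:
        raise ValueError("cannot encode an empty token list")
    if len(tokens) > max_len:
        logger.warning("sentence %s truncated from %d to %d tokens",
                       sent_id, len(tokens), max_len)
        tokens = tokens[:max_len]
    matrix = encoder(tokens)
    if matrix.shape[0] != len(tokens):
        raise ValueError(
            f"encoder returned {matrix.shape[0]} rows for {len(tokens)} tokens"
        )
    return TokenEmbeddings(sent_id, matrix)


def truncate_sentence(tokens: list[str], labels: list[str],
                      max_len: int) -> tuple[list[str], list[str]]:
    """Truncate tokens and labels in lockstep."""
    return tokens[:max_len], labels[:max_len]
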