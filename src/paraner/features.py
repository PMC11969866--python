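"""Multi-scale feature extraction and dynamic 1-D convolution.

Two feature streams are computed from the encoder output E:

* **Multi-scale BiLSTM features H** — for each odd scale k (defaults
  3/5/7), every token gets a sliding window of k embedding rows centred on
  it (zero-padded at sentence boundaries).  A per-scale BiLSTM reads the
  window; the token's scale feature is the concatenation of the final
  forward and backward states.  Scale blocks are concatenated column-wise,
  ascending scale, giving H of width ``n_scales * lstm_out``.  Windows keep
  H token-aligned, which the downstream attention fusion requires.

* **Dynamic convolution D** — the effective 1-D kernel is a convex mixture
  of M learned kernel templates; the mixture weights come from a softmax
  over a small feedforward applied to the mean-pooled sentence vector, so
  the kernel adapts per sentence.  Zero padding preserves sequence length
  (default kernel 5, padding 2).

Functions suffixed ``_t`` operate on autodiff :class:`~paraner.autodiff.Tensor`
objects and are what the trainable model uses; the unsuffixed wrappers take
and return numpy and exist as the module's plain functional surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .encoder import TokenEmbeddings


@dataclass
class ScaleConfig:
    """Window lengths and per-scale BiLSTM output width."""

    scales: list[int] = field(default_factory=lambda: [3, 5, 7])
    lstm_out: int = 256  # split half per direction

    def __post_init__(self):
        if not self.scales:
            raise ValueError("need at least one scale")
        for k in self.scales:
            if k < 1 or k % 2 == 0:
                raise ValueError(f"scales must be odd and >= 1, got {k}")
        if self.lstm_out % 2 != 0:
            raise ValueError("lstm_out must be even (half per direction)")


@dataclass
class ScaleWindows:
    """One k x d window per token, centred on that token."""

    scale: int
    windows: np.ndarray  # (n_tokens, k, d)


@dataclass
class MultiScaleFeatures:
    """Column-wise concatenation H of per-scale blocks, ascending scale."""

    matrix: np.ndarray  # (n_tokens, n_scales * lstm_out)


@dataclass
class DconvOutput:
    """Dynamic-convolution features D plus the kernel mixture weights."""

    matrix: np.ndarray          # (n_tokens, d_out)
    kernel_weights: np.ndarray  # (M,), nonnegative, sums to 1


# -- parameters ---------------------------------------------------------------

@dataclass
class LSTMParams:
    """One BiLSTM: gate order [input, forget, cell, output] per direction."""

    W_f: Tensor  # (d_in, 4h) forward input weights
    U_f: Tensor  # (h, 4h)
    b_f: Tensor  # (4h,)
    W_b: Tensor
    U_b: Tensor
    b_b: Tensor
    hidden: int


def init_lstm(rng: np.random.Generator, d_in: int, lstm_out: int) -> LSTMParams:
    h = lstm_out // 2

    def mk(shape):
        return Tensor(ad.glorot(rng, shape), requires_grad=True)

    return LSTMParams(
        W_f=mk((d_in, 4 * h)), U_f=mk((h, 4 * h)),
        b_f=Tensor(np.zeros(4 * h), requires_grad=True),
        W_b=mk((d_in, 4 * h)), U_b=mk((h, 4 * h)),
        b_b=Tensor(np.zeros(4 * h), requires_grad=True),
        hidden=h,
    )


@dataclass
class DconvParams:
    """M kernel templates plus the mixture-attention feedforward."""

    templates: Tensor  # (M, k_c * d_in * d_out)
    W1: Tensor         # (d_in, a)
    b1: Tensor         # (a,)
    W2: Tensor         # (a, M)
    b2: Tensor         # (M,)
    kernel_size: int
    d_in: int
    d_out: int

    @property
    def n_templates(self) -> int:
        return self.templates.shape[0]

    @property
    def padding(self) -> int:
        return (self.kernel_size - 1) // 2


def init_dconv(rng: np.random.Generator, d_in: int, d_out: int,
               kernel_size: int = 5, n_templates: int = 4,
               attn_hidden: int = 16) -> DconvParams:
    if kernel_size % 2 == 0:
        raise ValueError("dynamic-convolution kernel size must be odd")
    if n_templates < 1:
        raise ValueError("need at least one kernel template")
    scale = np.sqrt(2.0 / (kernel_size * d_in + d_out))
    templates = rng.standard_normal(
        (n_templates, kernel_size * d_in * d_out)) * scale
    return DconvParams(
        templates=Tensor(templates, requires_grad=True),
        W1=Tensor(ad.glorot(rng, (d_in, attn_hidden)), requires_grad=True),
        b1=Tensor(np.zeros(attn_hidden), requires_grad=True),
        W2=Tensor(ad.glorot(rng, (attn_hidden, n_templates)), requires_grad=True),
        b2=Tensor(np.zeros(n_templates), requires_grad=True),
        kernel_size=kernel_size,
        d_in=d_in,
        d_out=d_out,
    )


# -- tensor-level operations --------------------------------------------------

def extract_windows_t(E: Tensor, k: int) -> Tensor:
    """Sliding windows (n, k, d), zero-padded beyond sentence boundaries."""
    if k % 2 == 0:
        raise ValueError(f"window length must be odd, got {k}")
    n, d = E.shape
    r = (k - 1) // 2
    if r == 0:
        return E.reshape(n, 1, d)
    pad = Tensor(np.zeros((r, d)))
    padded = ad.concat([pad, E, pad], axis=0)
    idx = np.arange(n)[:, None] + np.arange(k)[None, :]  # (n, k) into padded
    return padded[idx]


def _lstm_direction(xs: Tensor, W: Tensor, U: Tensor, b: Tensor,
                    h: int, reverse: bool) -> Tensor:
    """Run one direction over the window axis; return final state (n, h)."""
    n, k, _ = xs.shape
    state = Tensor(np.zeros((n, h)))
    cell = Tensor(np.zeros((n, h)))
    steps = range(k - 1, -1, -1) if reverse else range(k)
    for t in steps:
        x = xs[:, t, :]
        z = x @ W + state @ U + b
        i = ad.sigmoid(z[:, 0 * h:1 * h])
        f = ad.sigmoid(z[:, 1 * h:2 * h])
        g = ad.tanh(z[:, 2 * h:3 * h])
        o = ad.sigmoid(z[:, 3 * h:4 * h])
        cell = f * cell + i * g
        state = o * ad.tanh(cell)
    return state


def scale_features_t(windows: Tensor, params: LSTMParams) -> Tensor:
    """BiLSTM over each token's window; final fwd ⊕ bwd states, (n, lstm_out)."""
    h = params.hidden
    fwd = _lstm_direction(windows, params.W_f, params.U_f, params.b_f, h, False)
    bwd = _lstm_direction(windows, params.W_b, params.U_b, params.b_b, h, True)
    return ad.concat([fwd, bwd], axis=1)


def multiscale_t(E: Tensor, cfg: ScaleConfig,
                 params: list[LSTMParams]) -> Tensor:
    """Concatenate per-scale BiLSTM blocks column-wise, ascending scale."""
    if len(params) != len(cfg.scales):
        raise ValueError("need one BiLSTM parameter set per scale")
    widths = {2 * p.hidden for p in params}
    if widths != {cfg.lstm_out}:
        raise ValueError(f"all scales must share lstm_out={cfg.lstm_out}, "
                         f"got {sorted(widths)}")
    blocks = []
    for k, p in sorted(zip(cfg.scales, params), key=lambda kp: kp[0]):
        blocks.append(scale_features_t(extract_windows_t(E, k), p))
    return ad.concat(blocks, axis=1)


def kernel_attention_t(E: Tensor, p: DconvParams,
                       temperature: float = 1.0) -> Tensor:
    """Mixture weights α over kernel templates from the mean-pooled sentence."""
    s = E.mean(axis=0).reshape(1, p.W1.shape[0])
    a1 = ad.tanh(s @ p.W1 + p.b1)
    logits = (a1 @ p.W2 + p.b2) * (1.0 / temperature)
    return ad.softmax(logits, axis=-1)  # (1, M)


def dynamic_conv_t(E: Tensor, p: DconvParams,
                   alpha_override: np.ndarray | None = None,
                   temperature: float = 1.0) -> tuple[Tensor, Tensor]:
    """1-D convolution of E with the α-mixed kernel; returns (D, α)."""
    n, d_in = E.shape
    if d_in != p.d_in:
        raise ValueError(f"E width {d_in} != dconv d_in {p.d_in}")
    if alpha_override is not None:
        alpha = Tensor(np.asarray(alpha_override, dtype=float).reshape(1, -1))
        if alpha.shape[1] != p.n_templates:
            raise ValueError("alpha_override length != number of templates")
    else:
        alpha = kernel_attention_t(E, p, temperature)
    kernel = (alpha @ p.templates).reshape(p.kernel_size, p.d_in, p.d_out)
    pad = Tensor(np.zeros((p.padding, d_in)))
    padded = ad.concat([pad, E, pad], axis=0)
    out = None
    for tap in range(p.kernel_size):
        term = padded[tap:tap + n] @ kernel[tap]
        out = term if out is None else out + term
    return out, alpha


# -- numpy functional surface -------------------------------------------------

def extract_windows(E: TokenEmbeddings, k: int) -> ScaleWindows:
    with ad.no_grad():
        w = extract_windows_t(Tensor(E.matrix), k)
    return ScaleWindows(scale=k, windows=w.data)


def scale_features(windows: ScaleWindows, params: LSTMParams) -> np.ndarray:
    with ad.no_grad():
        return scale_features_t(Tensor(windows.windows), params).data


def multiscale(E: TokenEmbeddings, cfg: ScaleConfig,
               params: list[LSTMParams]) -> MultiScaleFeatures:
    with ad.no_grad():
        return MultiScaleFeatures(multiscale_t(Tensor(E.matrix), cfg, params).data)


def dynamic_conv(E: TokenEmbeddings, params: DconvParams,
                 alpha_override: np.ndarray | None = None,
                 temperature: float = 1.0) -> DconvOutput:
    with ad.no_grad():
        D, alpha = dynamic_conv_t(Tensor(E.matrix), params,
                                  alpha_override, temperature)
    return DconvOutput(matrix=D.data, kernel_weights=alpha.data.ravel())
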