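"""Dual-branch Transformer fusion classifier and sequence baselines.

Each modality branch is a single-block Transformer encoder in pre-LN
residual form:

    Y = Dropout( LN2( X + MHA( LN1(X) ) ) )

with fixed sinusoidal positional encoding added to the normalized
modality input, two attention heads of key dimension 32, and the
post-softmax per-head attention maps exposed for rollout attribution.
Branch outputs are concatenated along the feature axis (50x37),
flattened, and classified by a dense-64 / dropout / dense-64 / softmax-2
head. Single-modality ablations keep one branch and the same head;
RNN / CNN / LSTM baselines replace the branch encoders with
capacity-comparable per-modality encoders feeding the identical head.

All networks run on the package's NumPy autodiff engine
(:mod:`frostgrip.nn`); no external deep-learning framework is used.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor, concat, constant, glorot_uniform, parameter, softmax

__all__ = [
    "NetworkConfig",
    "AttentionMaps",
    "sinusoidal_positional_encoding",
    "build_model",
    "extract_attention_maps",
    "MODEL_KINDS",
]

MODEL_KINDS = ("fusion", "pressure_only", "vibration_only", "rnn", "cnn", "lstm")


@dataclass
class NetworkConfig:
    T: int = 50
    d_p: int = 36
    d_v: int = 1
    H: int = 2
    d_k: int = 32
    L: int = 1
    dropout_rate: float = 0.3
    head_units: tuple[int, int] = (64, 64)
    n_classes: int = 2
    pe_base: float = 10000.0
    baseline_units: int = 32   # RNN/LSTM hidden width and CNN filter count
    cnn_kernel: int = 5

    def __post_init__(self):
        if self.H < 1 or self.d_k < 1:
            raise ValueError("H and d_k must be >= 1")
        if self.L != 1:
            raise ValueError("each branch uses a single self-attention block")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass
class AttentionMaps:
    """Post-softmax per-head maps, per branch; each entry is (T, T)."""

    pressure: list[np.ndarray] | None
    vibration: list[np.ndarray] | None


def sinusoidal_positional_encoding(T: int, d: int,
                                   pe_base: float = 10000.0) -> np.ndarray:
    """Fixed encoding PE[t, 2i] = sin(t / base^(2i/d)),
    PE[t, 2i+1] = cos(t / base^(2i/d)); an odd trailing column uses the
    sine term."""
    if T < 1 or d < 1:
        raise ValueError("T and d must be >= 1")
    t = np.arange(T)[:, None].astype(float)
    pe = np.zeros((T, d))
    i = np.arange(0, d, 2)
    angle = t / pe_base ** (i / d)
    pe[:, 0::2] = np.sin(angle)
    if d > 1:
        pe[:, 1::2] = np.cos(angle[:, : (d // 2)])
    return pe


# ---------------------------------------------------------------------------
# layers


def _layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5,
                axis: int = -1):
    """Normalization over `axis` with learned per-feature scale/offset.

    Branches with a single feature channel normalize over the time axis
    instead: normalizing one channel per step would map every step to a
    constant and annihilate the modality signal.
    """
    mu = x.mean(axis=axis, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=axis, keepdims=True)
    return gain * (xc * (var + eps).power(-0.5)) + bias


def _dropout(x: Tensor, rate: float, train: bool, rng: np.random.Generator):
    if not train or rate <= 0.0:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * constant(mask)


def _dense_init(rng, fan_in, fan_out):
    return (parameter(glorot_uniform(rng, fan_in, fan_out)),
            parameter(np.zeros(fan_out)))


class _Branch:
    """Single-block Transformer encoder for one modality."""

    def __init__(self, d: int, cfg: NetworkConfig, rng: np.random.Generator):
        self.d, self.cfg = d, cfg
        self.ln_axis = -1 if d > 1 else -2
        hk = cfg.H * cfg.d_k
        self.ln1_g = parameter(np.ones(d))
        self.ln1_b = parameter(np.zeros(d))
        self.Wq, self.bq = _dense_init(rng, d, hk)
        self.Wk, self.bk = _dense_init(rng, d, hk)
        self.Wv, self.bv = _dense_init(rng, d, hk)
        self.Wo, self.bo = _dense_init(rng, hk, d)
        self.ln2_g = parameter(np.ones(d))
        self.ln2_b = parameter(np.zeros(d))

    def params(self):
        return [self.ln1_g, self.ln1_b, self.Wq, self.bq, self.Wk, self.bk,
                self.Wv, self.bv, self.Wo, self.bo, self.ln2_g, self.ln2_b]

    def forward(self, x: Tensor, train: bool, rng: np.random.Generator):
        """Returns (Y, per-head attention maps as (B, H, T, T) ndarray)."""
        cfg = self.cfg
        B, T, d = x.shape
        xn = _layer_norm(x, self.ln1_g, self.ln1_b, axis=self.ln_axis)

        def heads(w, b):
            proj = xn @ w + b                       # (B, T, H*dk)
            return proj.reshape(B, T, cfg.H, cfg.d_k).transpose(0, 2, 1, 3)

        q, k, v = heads(self.Wq, self.bq), heads(self.Wk, self.bk), \
            heads(self.Wv, self.bv)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(cfg.d_k))
        attn = softmax(scores, axis=-1)             # (B, H, T, T)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, cfg.H * cfg.d_k)
        mha = ctx @ self.Wo + self.bo
        y = _layer_norm(x + mha, self.ln2_g, self.ln2_b, axis=self.ln_axis)
        y = _dropout(y, cfg.dropout_rate, train, rng)
        return y, attn.data.copy()


class _Head:
    """Dense-64 / dropout / dense-64 / softmax-2 classification head.

    Hidden activations are ReLU."""

    def __init__(self, n_in: int, cfg: NetworkConfig, rng: np.random.Generator):
        self.cfg = cfg
        u1, u2 = cfg.head_units
        self.W1, self.b1 = _dense_init(rng, n_in, u1)
        self.W2, self.b2 = _dense_init(rng, u1, u2)
        self.W3, self.b3 = _dense_init(rng, u2, cfg.n_classes)

    def params(self):
        return [self.W1, self.b1, self.W2, self.b2, self.W3, self.b3]

    def forward(self, x: Tensor, train: bool, rng: np.random.Generator):
        h = (x @ self.W1 + self.b1).relu()
        h = _dropout(h, self.cfg.dropout_rate, train, rng)
        h = (h @ self.W2 + self.b2).relu()
        return h @ self.W3 + self.b3   # logits


class _RecurrentEncoder:
    """Simple tanh recurrent encoder; final hidden state is the feature."""

    def __init__(self, d: int, units: int, rng: np.random.Generator):
        self.units = units
        self.Wx, self.b = _dense_init(rng, d, units)
        self.Wh = parameter(glorot_uniform(rng, units, units))

    def params(self):
        return [self.Wx, self.b, self.Wh]

    def forward(self, x: Tensor, train, rng):
        B, T, _ = x.shape
        h = constant(np.zeros((B, self.units)))
        for t in range(T):
            h = (x.step_axis1(t) @ self.Wx + h @ self.Wh + self.b).tanh()
        return h


class _LSTMEncoder:
    """Standard LSTM; final hidden state is the feature."""

    def __init__(self, d: int, units: int, rng: np.random.Generator):
        self.units = units
        self.gates = [( *_dense_init(rng, d, units),
                        parameter(glorot_uniform(rng, units, units)))
                      for _ in range(4)]  # i, f, g, o

    def params(self):
        return [p for w, b, u in self.gates for p in (w, b, u)]

    def forward(self, x: Tensor, train, rng):
        B, T, _ = x.shape
        h = constant(np.zeros((B, self.units)))
        c = constant(np.zeros((B, self.units)))
        (Wi, bi, Ui), (Wf, bf, Uf), (Wg, bg, Ug), (Wo, bo, Uo) = self.gates
        for t in range(T):
            xt = x.step_axis1(t)
            i = (xt @ Wi + h @ Ui + bi).sigmoid()
            f = (xt @ Wf + h @ Uf + bf + 1.0).sigmoid()  # forget bias 1
            g = (xt @ Wg + h @ Ug + bg).tanh()
            o = (xt @ Wo + h @ Uo + bo).sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
        return h


class _ConvEncoder:
    """1-D convolution (valid padding) + ReLU + global average pooling."""

    def __init__(self, d: int, filters: int, kernel: int,
                 rng: np.random.Generator):
        self.kernel = kernel
        self.W = [parameter(glorot_uniform(rng, d * kernel, filters,
                                           shape=(d, filters)))
                  for _ in range(kernel)]
        self.b = parameter(np.zeros(filters))

    def params(self):
        return self.W + [self.b]

    def forward(self, x: Tensor, train, rng):
        B, T, _ = x.shape
        span = T - self.kernel + 1
        acc = self.b
        for off in range(self.kernel):
            acc = acc + x.slice_axis1(off, off + span) @ self.W[off]
        return acc.relu().mean(axis=1)   # global average pooling


# ---------------------------------------------------------------------------
# models


class GraspClassifier:
    """Common wrapper: encoders + head + loss, with seeded init.

    ``required`` names the modalities the model consumes ('P', 'V').
    """

    def __init__(self, kind: str, cfg: NetworkConfig, seed: int = 0):
        if kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {kind!r}")
        self.kind, self.cfg, self.seed = kind, cfg, seed
        rng = np.random.default_rng(seed)
        self.pe_p = sinusoidal_positional_encoding(cfg.T, cfg.d_p, cfg.pe_base)
        self.pe_v = sinusoidal_positional_encoding(cfg.T, cfg.d_v, cfg.pe_base)
        self.branch_p = self.branch_v = None
        self.enc_p = self.enc_v = None
        u = cfg.baseline_units

        if kind == "fusion":
            self.required = ("P", "V")
            self.branch_p = _Branch(cfg.d_p, cfg, rng)
            self.branch_v = _Branch(cfg.d_v, cfg, rng)
            head_in = cfg.T * (cfg.d_p + cfg.d_v)
        elif kind == "pressure_only":
            self.required = ("P",)
            self.branch_p = _Branch(cfg.d_p, cfg, rng)
            head_in = cfg.T * cfg.d_p
        elif kind == "vibration_only":
            self.required = ("V",)
            self.branch_v = _Branch(cfg.d_v, cfg, rng)
            head_in = cfg.T * cfg.d_v
        else:
            self.required = ("P", "V")
            enc_cls = {"rnn": _RecurrentEncoder, "lstm": _LSTMEncoder}.get(kind)
            if enc_cls is not None:
                self.enc_p = enc_cls(cfg.d_p, u, rng)
                self.enc_v = enc_cls(cfg.d_v, u, rng)
            else:  # cnn
                self.enc_p = _ConvEncoder(cfg.d_p, u, cfg.cnn_kernel, rng)
                self.enc_v = _ConvEncoder(cfg.d_v, u, cfg.cnn_kernel, rng)
            head_in = 2 * u
        self.head = _Head(head_in, cfg, rng)

    # -- parameters -------------------------------------------------------

    def params(self) -> list[Tensor]:
        out = []
        for part in (self.branch_p, self.branch_v, self.enc_p, self.enc_v,
                     self.head):
            if part is not None:
                out.extend(part.params())
        return out

    @property
    def n_params(self) -> int:
        return int(sum(p.data.size for p in self.params()))

    def get_state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params(), state, strict=True):
            p.data = s.copy()

    # -- forward ----------------------------------------------------------

    def _check(self, P, V):
        cfg = self.cfg
        if "P" in self.required:
            if P is None:
                raise ValueError(f"{self.kind} model requires pressure input")
            if P.shape[-2:] != (cfg.T, cfg.d_p):
                raise ValueError(
                    f"pressure input must be (..., {cfg.T}, {cfg.d_p})")
        elif P is not None:
            raise ValueError(
                f"{self.kind} model accepts only {cfg.T}x{cfg.d_v} "
                "vibration input")
        if "V" in self.required:
            if V is None:
                raise ValueError(f"{self.kind} model requires vibration input")
            if V.shape[-2:] != (cfg.T, cfg.d_v):
                raise ValueError(
                    f"vibration input must be (..., {cfg.T}, {cfg.d_v})")
        elif V is not None:
            raise ValueError(
                f"{self.kind} model accepts only {cfg.T}x{cfg.d_p} "
                "pressure input")

    def forward(self, P: np.ndarray | None = None,
                V: np.ndarray | None = None, train: bool = False,
                rng: np.random.Generator | None = None):
        """Returns (logits Tensor of shape (B, 2), AttentionMaps-per-batch).

        For Transformer kinds the maps entry holds the post-softmax
        per-head weights as (B, H, T, T) arrays; baselines return None.
        """
        self._check(P, V)
        if rng is None:
            rng = np.random.default_rng(0)
        B = (P if P is not None else V).shape[0]
        feats, maps = [], {"pressure": None, "vibration": None}

        # Content is scaled by sqrt(d) before the positional encoding is
        # added (the standard Transformer recipe) so the unit-amplitude
        # PE does not swamp the modality signal.
        if P is not None:
            P = constant(np.asarray(P, float) * np.sqrt(self.cfg.d_p)
                         + self.pe_p)
        if V is not None:
            V = constant(np.asarray(V, float) * np.sqrt(self.cfg.d_v)
                         + self.pe_v)
        if self.branch_p is not None:
            yp, maps["pressure"] = self.branch_p.forward(P, train, rng)
            feats.append(yp)
        if self.branch_v is not None:
            yv, maps["vibration"] = self.branch_v.forward(V, train, rng)
            feats.append(yv)
        if self.enc_p is not None:
            feats.append(self.enc_p.forward(P, train, rng))
            feats.append(self.enc_v.forward(V, train, rng))

        if self.branch_p is not None or self.branch_v is not None:
            fused = feats[0] if len(feats) == 1 else concat(feats, axis=-1)
            fused = fused.reshape(B, -1)   # flatten (B, T*(d_p+d_v))
        else:
            fused = concat(feats, axis=-1)
        logits = self.head.forward(fused, train, rng)
        return logits, maps

    def predict_proba(self, P=None, V=None) -> np.ndarray:
        logits, _ = self.forward(P, V, train=False)
        return softmax(logits, axis=-1).data

    def loss(self, onehot: np.ndarray, P=None, V=None, train: bool = True,
             rng: np.random.Generator | None = None) -> Tensor:
        logits, _ = self.forward(P, V, train=train, rng=rng)
        return nn.softmax_cross_entropy(logits, onehot)

    def clone_state(self):
        return copy.deepcopy(self.get_state())


def build_model(kind: str, cfg: NetworkConfig | None = None,
                seed: int = 0) -> GraspClassifier:
    """Instantiate a seeded model of the requested kind."""
    return GraspClassifier(kind, cfg or NetworkConfig(), seed=seed)


def extract_attention_maps(model: GraspClassifier, pressure_seq=None,
                           vibration_seq=None) -> AttentionMaps:
    """Inference-mode per-head attention maps for one sample.

    Accepts the (T, d) sequences of a single sample; returns per-branch
    lists of H maps of shape (T, T), rows summing to 1.
    """
    P = None if pressure_seq is None else np.asarray(pressure_seq)[None]
    V = None if vibration_seq is None else np.asarray(vibration_seq)[None]
    _, maps = model.forward(P, V, train=False)
    out = {}
    for name in ("pressure", "vibration"):
        m = maps[name]
        out[name] = None if m is None else [m[0, h] for h in range(m.shape[1])]
    return AttentionMaps(**out)
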