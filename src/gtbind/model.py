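"""The edge-aware graph transformer and its gradients.

The network scores every residue of a protein graph with a binding
probability.  Architecture (pre-layer-norm transformer):

  input projection (d_in -> d)
  L x [ multi-head attention over each node's in-neighbours, with the edge
        feature vector e_ij concatenated onto both the key and the value;
        residual ] [ position-wise feed-forward; residual ]
  final layer norm, then a single linear unit + sigmoid per residue.

Attention per head: score(i, j) = (W_Q h_i)^T (W_K [h_j || e_ij]) / sqrt(d_h),
softmax over j in N_i u {i}, message_i = sum_j alpha_ij [W_V h_j || e_ij];
the concatenated head messages are projected back to d before the residual.

Everything is NumPy float64.  Gradients are written analytically (verified
against central finite differences in the test suite); no autodiff
framework is involved, which keeps the dependency surface small and the
arithmetic bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

_LN_EPS = 1e-5
_CKPT_VERSION = 1


@dataclass
class ModelConfig:
    """Architecture hyperparameters (defaults follow the published protocol)."""

    input_dim: int
    edge_dim: int
    num_layers: int = 4
    num_heads: int = 4
    hidden_dim: int = 64
    dropout: float = 0.2
    ffn_multiplier: int = 4
    use_ffn: bool = True
    scale_by_sqrt_dh: bool = True   # False reproduces the printed 1/d scaling
    head_hidden: int = 0            # optional hidden layer in the output head
    seed: int = 0

    def __post_init__(self):
        if self.hidden_dim % self.num_heads != 0:
            raise ValueError("hidden_dim must be divisible by num_heads")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.input_dim < 1 or self.edge_dim < 1:
            raise ValueError("input_dim and edge_dim must be positive")

    @property
    def head_dim(self) -> int:
        return self.hidden_dim // self.num_heads


def _glorot(rng, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_model(config: ModelConfig) -> dict:
    """Initialize all learnable parameters from ``config.seed``.

    Linear weights use Glorot-uniform fan scaling; norms start at identity.
    Returns a flat ``{name: array}`` dict (the ModelParams container).
    """
    rng = np.random.default_rng(config.seed)
    d, de = config.hidden_dim, config.edge_dim
    dh, h = config.head_dim, config.num_heads
    p = {
        "w_in": _glorot(rng, config.input_dim, d),
        "b_in": np.zeros(d),
    }
    for l in range(config.num_layers):
        p[f"l{l}.ln1.g"] = np.ones(d)
        p[f"l{l}.ln1.b"] = np.zeros(d)
        p[f"l{l}.wq"] = _glorot(rng, d, d)
        p[f"l{l}.wk"] = _glorot(rng, d + de, d)
        p[f"l{l}.wv"] = _glorot(rng, d, d)
        p[f"l{l}.wo"] = _glorot(rng, (dh + de) * h, d)
        p[f"l{l}.bo"] = np.zeros(d)
        if config.use_ffn:
            dff = config.ffn_multiplier * d
            p[f"l{l}.ln2.g"] = np.ones(d)
            p[f"l{l}.ln2.b"] = np.zeros(d)
            p[f"l{l}.w1"] = _glorot(rng, d, dff)
            p[f"l{l}.b1"] = np.zeros(dff)
            p[f"l{l}.w2"] = _glorot(rng, dff, d)
            p[f"l{l}.b2"] = np.zeros(d)
    p["lnf.g"] = np.ones(d)
    p["lnf.b"] = np.zeros(d)
    if config.head_hidden > 0:
        p["head.w1"] = _glorot(rng, d, config.head_hidden)
        p["head.b1"] = np.zeros(config.head_hidden)
        p["head.w"] = _glorot(rng, config.head_hidden, 1)
    else:
        p["head.w"] = _glorot(rng, d, 1)
    p["head.b"] = np.zeros(1)
    return p


# ---------------------------------------------------------------------------
# primitive forward/backward pairs

def _layernorm_fwd(x, g, b):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = xc * inv
    return xhat * g + b, (xhat, inv, g)


def _layernorm_bwd(dy, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=0)
    db = dy.sum(axis=0)
    dxhat = dy * g
    dx = inv * (
        dxhat
        - dxhat.mean(axis=-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
    )
    return dx, dg, db


class _SegIndex:
    """Fast segment reductions over a dst-sorted edge list with self-loops.

    Self-loops guarantee every node owns at least one edge as source and as
    destination, so ``reduceat`` blocks are never empty.
    """

    def __init__(self, src, dst, n):
        self.dst = dst
        self.bounds_dst = np.searchsorted(dst, np.arange(n))
        if not np.array_equal(dst[self.bounds_dst], np.arange(n)):
            raise ValueError("every node needs an incoming edge (self-loop)")
        self.src_order = np.argsort(src, kind="stable")
        src_sorted = src[self.src_order]
        self.bounds_src = np.searchsorted(src_sorted, np.arange(n))
        if not np.array_equal(src_sorted[self.bounds_src], np.arange(n)):
            raise ValueError("every node needs an outgoing edge (self-loop)")

    def sum_dst(self, x):
        return np.add.reduceat(x, self.bounds_dst, axis=0)

    def max_dst(self, x):
        return np.maximum.reduceat(x, self.bounds_dst, axis=0)

    def sum_src(self, x):
        return np.add.reduceat(x[self.src_order], self.bounds_src, axis=0)


def _segment_softmax_fwd(scores, seg):
    """Softmax over edges sharing a destination node; scores is (E, h)."""
    m = seg.max_dst(scores)
    ex = np.exp(scores - m[seg.dst])
    s = seg.sum_dst(ex)
    return ex / s[seg.dst]


def _segment_softmax_bwd(dalpha, alpha, seg):
    t = seg.sum_dst(alpha * dalpha)
    return alpha * (dalpha - t[seg.dst])


def _dropout_mask(rng, shape, rate):
    if rate <= 0.0 or rng is None:
        return None
    return (rng.random(shape) >= rate) / (1.0 - rate)


# ---------------------------------------------------------------------------
# forward (with optional cache for the backward pass)

def _forward(H_in, edges, Ef, params, config: ModelConfig, train_mode=False,
             rng=None, want_cache=False):
    src, dst = edges
    n = H_in.shape[0]
    seg = _SegIndex(src, dst, n)
    d, de, h, dh = (config.hidden_dim, config.edge_dim,
                    config.num_heads, config.head_dim)
    scale = np.sqrt(dh) if config.scale_by_sqrt_dh else float(d)
    drop = config.dropout if train_mode else 0.0
    caches = []

    H = H_in @ params["w_in"] + params["b_in"]
    for l in range(config.num_layers):
        # --- attention sublayer (pre-LN) ---
        Z, ln1c = _layernorm_fwd(H, params[f"l{l}.ln1.g"], params[f"l{l}.ln1.b"])
        Q = Z @ params[f"l{l}.wq"]
        Kin = np.hstack([Z[src], Ef])
        K = Kin @ params[f"l{l}.wk"]
        V = Z @ params[f"l{l}.wv"]
        q = Q[dst].reshape(-1, h, dh)
        k = K.reshape(-1, h, dh)
        scores = (q * k).sum(axis=2) / scale
        alpha = _segment_softmax_fwd(scores, seg)
        mask_a = _dropout_mask(rng, alpha.shape, drop)
        alpha_d = alpha if mask_a is None else alpha * mask_a
        vs = V[src].reshape(-1, h, dh)
        mv = alpha_d[:, :, None] * vs                       # (E, h, dh)
        me = alpha_d[:, :, None] * Ef[:, None, :]           # (E, h, de)
        msg = np.concatenate([mv, me], axis=2)              # (E, h, dh+de)
        Mflat = seg.sum_dst(msg.reshape(-1, h * (dh + de)))
        attn_out = Mflat @ params[f"l{l}.wo"] + params[f"l{l}.bo"]
        H1 = H + attn_out

        layer_cache = {
            "Z": Z, "ln1c": ln1c, "Q": Q, "Kin": Kin, "K": K, "V": V,
            "alpha": alpha, "alpha_d": alpha_d, "mask_a": mask_a,
            "vs": vs, "Mflat": Mflat, "scale": scale,
        }
        # --- feed-forward sublayer (pre-LN) ---
        if config.use_ffn:
            Z2, ln2c = _layernorm_fwd(H1, params[f"l{l}.ln2.g"],
                                      params[f"l{l}.ln2.b"])
            A = Z2 @ params[f"l{l}.w1"] + params[f"l{l}.b1"]
            Ar = np.maximum(A, 0.0)
            Fo = Ar @ params[f"l{l}.w2"] + params[f"l{l}.b2"]
            mask_f = _dropout_mask(rng, Fo.shape, drop)
            Fo_d = Fo if mask_f is None else Fo * mask_f
            H2 = H1 + Fo_d
            layer_cache.update({"Z2": Z2, "ln2c": ln2c, "A": A, "Ar": Ar,
                                "mask_f": mask_f, "H1": H1})
        else:
            H2 = H1
        caches.append(layer_cache)
        H = H2

    Hf, lnfc = _layernorm_fwd(H, params["lnf.g"], params["lnf.b"])
    if config.head_hidden > 0:
        Ph = np.maximum(Hf @ params["head.w1"] + params["head.b1"], 0.0)
        logits = (Ph @ params["head.w"] + params["head.b"])[:, 0]
    else:
        Ph = None
        logits = (Hf @ params["head.w"] + params["head.b"])[:, 0]
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("non-finite activations in forward pass")
    probs = 1.0 / (1.0 + np.exp(-logits))

    if not want_cache:
        return probs
    cache = {"H_in": H_in, "caches": caches, "Hf": Hf, "lnfc": lnfc,
             "Ph": Ph, "logits": logits, "probs": probs, "seg": seg}
    return probs, cache


def model_forward(graph, params, config: ModelConfig, train_mode=False, rng=None):
    """Residue-level binding probabilities for one (batched) graph.

    ``graph`` may be a ProteinGraph or a ``(H, (src, dst), edge_features)``
    triple.  Eval mode (the default) is deterministic.
    """
    H, edges, Ef = _unpack(graph)
    if H.shape[1] != config.input_dim:
        raise ValueError(
            f"node feature dim {H.shape[1]} != config input_dim "
            f"{config.input_dim}"
        )
    if Ef.shape[1] != config.edge_dim:
        raise ValueError(
            f"edge feature dim {Ef.shape[1]} != config edge_dim "
            f"{config.edge_dim}"
        )
    return _forward(H, edges, Ef, params, config, train_mode=train_mode, rng=rng)


def _unpack(graph):
    if isinstance(graph, tuple):
        H, edges, Ef = graph
    else:
        H, edges = graph.H, graph.edges
        Ef = graph.edge_features
    H = np.asarray(H, dtype=float)
    Ef = np.asarray(Ef, dtype=float)
    src = np.asarray(edges[0])
    dst = np.asarray(edges[1])
    # segment reductions need a dst-sorted edge list; canonicalize here so
    # any edge ordering (e.g. after node relabeling) evaluates identically
    if np.any(np.diff(dst) < 0):
        order = np.argsort(dst, kind="stable")
        src, dst, Ef = src[order], dst[order], Ef[order]
    return H, (src, dst), Ef


# ---------------------------------------------------------------------------
# loss and gradients

def bce_loss(probs, labels):
    """Mean binary cross-entropy (computed from probabilities; clipped)."""
    p = np.clip(probs, 1e-12, 1.0 - 1e-12)
    y = np.asarray(labels, dtype=float)
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean())


def loss_and_grads(graph, labels, params, config: ModelConfig,
                   train_mode=False, rng=None):
    """Mean BCE loss and its gradient w.r.t. every parameter.

    Returns ``(loss, probs, grads)`` with ``grads`` keyed like ``params``.
    """
    H_in, edges, Ef = _unpack(graph)
    src, dst = edges
    n = H_in.shape[0]
    y = np.asarray(labels, dtype=float)
    probs, cache = _forward(H_in, edges, Ef, params, config,
                            train_mode=train_mode, rng=rng, want_cache=True)
    loss = bce_loss(probs, y)
    d, de, h, dh = (config.hidden_dim, config.edge_dim,
                    config.num_heads, config.head_dim)
    g = {k: np.zeros_like(v) for k, v in params.items()}

    dlogits = (probs - y) / n
    Hf = cache["Hf"]
    if config.head_hidden > 0:
        Ph = cache["Ph"]
        g["head.w"] = Ph.T @ dlogits[:, None]
        g["head.b"] = np.array([dlogits.sum()])
        dPh = dlogits[:, None] @ params["head.w"].T
        dPh *= (Ph > 0)
        g["head.w1"] = Hf.T @ dPh
        g["head.b1"] = dPh.sum(axis=0)
        dHf = dPh @ params["head.w1"].T
    else:
        g["head.w"] = Hf.T @ dlogits[:, None]
        g["head.b"] = np.array([dlogits.sum()])
        dHf = dlogits[:, None] @ params["head.w"].T
    dH, g["lnf.g"], g["lnf.b"] = _layernorm_bwd(dHf, cache["lnfc"])

    for l in reversed(range(config.num_layers)):
        c = cache["caches"][l]
        # --- FFN sublayer backward ---
        if config.use_ffn:
            dFo = dH if c["mask_f"] is None else dH * c["mask_f"]
            g[f"l{l}.w2"] = c["Ar"].T @ dFo
            g[f"l{l}.b2"] = dFo.sum(axis=0)
            dAr = dFo @ params[f"l{l}.w2"].T
            dA = dAr * (c["A"] > 0)
            g[f"l{l}.w1"] = c["Z2"].T @ dA
            g[f"l{l}.b1"] = dA.sum(axis=0)
            dZ2 = dA @ params[f"l{l}.w1"].T
            dx, g[f"l{l}.ln2.g"], g[f"l{l}.ln2.b"] = _layernorm_bwd(dZ2, c["ln2c"])
            dH = dH + dx  # residual
        # --- attention sublayer backward ---
        dout = dH
        g[f"l{l}.wo"] = c["Mflat"].T @ dout
        g[f"l{l}.bo"] = dout.sum(axis=0)
        dMflat = dout @ params[f"l{l}.wo"].T
        dM = dMflat.reshape(n, h, dh + de)
        dmsg = dM[dst]                                  # (E, h, dh+de)
        dmv, dme = dmsg[:, :, :dh], dmsg[:, :, dh:]
        dalpha_d = (dmv * c["vs"]).sum(axis=2) + (dme * Ef[:, None, :]).sum(axis=2)
        dvs = c["alpha_d"][:, :, None] * dmv
        dalpha = dalpha_d if c["mask_a"] is None else dalpha_d * c["mask_a"]
        seg = cache["seg"]
        dscores = _segment_softmax_bwd(dalpha, c["alpha"], seg)
        q = c["Q"][dst].reshape(-1, h, dh)
        k = c["K"].reshape(-1, h, dh)
        dq = dscores[:, :, None] * k / c["scale"]
        dk = dscores[:, :, None] * q / c["scale"]
        dQ = seg.sum_dst(dq.reshape(-1, d))
        dK = dk.reshape(-1, d)
        dV = seg.sum_src(dvs.reshape(-1, d))
        Z = c["Z"]
        g[f"l{l}.wq"] = Z.T @ dQ
        g[f"l{l}.wv"] = Z.T @ dV
        g[f"l{l}.wk"] = c["Kin"].T @ dK
        dZ = dQ @ params[f"l{l}.wq"].T + dV @ params[f"l{l}.wv"].T
        dKin = dK @ params[f"l{l}.wk"].T
        dZ += seg.sum_src(dKin[:, :d])
        dx, g[f"l{l}.ln1.g"], g[f"l{l}.ln1.b"] = _layernorm_bwd(dZ, c["ln1c"])
        dH = dH + dx  # residual

    g["w_in"] = cache["H_in"].T @ dH
    g["b_in"] = dH.sum(axis=0)
    return loss, probs, g


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(path, params: dict, config: ModelConfig, extra: dict | None = None):
    """Serialize parameters + config (+ e.g. normalization stats) to one file."""
    meta = {"version": _CKPT_VERSION, "config": asdict(config),
            "extra_keys": sorted((extra or {}).keys())}
    arrays = {f"param::{k}": v for k, v in params.items()}
    for k, v in (extra or {}).items():
        arrays[f"extra::{k}"] = np.asarray(v)
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path, expect_config: ModelConfig | None = None):
    """Load a checkpoint; fails loudly on version or config mismatch."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        if meta["version"] != _CKPT_VERSION:
            raise ValueError(f"checkpoint version {meta['version']} unsupported")
        config = ModelConfig(**meta["config"])
        if expect_config is not None and asdict(expect_config) != asdict(config):
            raise ValueError("checkpoint config does not match expected config")
        params = {k[len("param::"):]: z[k] for k in z.files
                  if k.startswith("param::")}
        extra = {k[len("extra::"):]: z[k] for k in z.files
                 if k.startswith("extra::")}
    return params, config, extra
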