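"""Bidirectional transformer encoder over codon tokens, in pure numpy.

Architecture, in brief: codon-token embeddings are summed with a per-sequence
species token-type embedding (no absolute-position embedding); each layer
applies disentangled self-attention — content-to-content, content-to-position
and position-to-content score terms over clipped relative distances, with a
relative-position embedding table shared across layers — followed by a GELU
feed-forward block, both with post-layer-norm residuals. The language head is
weight-tied: output scores are inner products of final hidden states with the
input embedding rows plus a per-token bias.

The forward pass caches every intermediate needed by :func:`backward`, whose
gradients are hand-derived and validated against finite differences in the
test suite (no autodiff framework is available at run time).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field
from typing import Dict, Optional, Tuple

import numpy as np

__all__ = [
    "EncoderConfig",
    "ModelState",
    "PRESETS",
    "init_model",
    "embed_inputs",
    "forward_hidden",
    "lm_logits",
    "mean_pool",
    "forward_with_cache",
    "backward",
    "n_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

_LN_EPS = 1e-5
_PAD_BIAS = -1e9  # guarantees exp underflow to exactly 0 after max-shift


@dataclass(frozen=True)
class EncoderConfig:
    hidden_size: int = 64
    intermediate_size: int = 256
    num_layers: int = 2
    num_heads: int = 4
    max_positions: int = 1024
    vocab_size: int = 69
    num_token_types: int = 501
    dropout: float = 0.1
    relative_position_buckets: int = 32  # distances clipped to [-K, K-1]
    dtype: str = "float64"  # "float32" halves training cost (the full-scale
    # run used 16-bit mixed precision; float64 is kept default so gradient
    # checks and small-scale analyses are exact)

    def __post_init__(self):
        if self.hidden_size % self.num_heads != 0:
            raise ValueError(
                f"hidden_size {self.hidden_size} not divisible by "
                f"num_heads {self.num_heads}"
            )
        if min(self.hidden_size, self.intermediate_size, self.num_layers,
               self.num_heads, self.max_positions, self.vocab_size,
               self.num_token_types, self.relative_position_buckets) < 1:
            raise ValueError("all size fields must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be 'float32' or 'float64'")

    @property
    def np_dtype(self):
        return np.float32 if self.dtype == "float32" else np.float64

    @property
    def head_dim(self) -> int:
        return self.hidden_size // self.num_heads


PRESETS: Dict[str, EncoderConfig] = {
    # published full-scale configuration (not exercised by tests)
    "full": EncoderConfig(768, 3072, 12, 12, max_positions=1024,
                          relative_position_buckets=256),
    # ablation-scale configuration (~1/10 the parameter budget)
    "small-ablation": EncoderConfig(320, 1280, 6, 5, max_positions=1024,
                                    relative_position_buckets=128),
    # desk-scale default used throughout the tests and demos
    "desk": EncoderConfig(64, 256, 2, 4, max_positions=256,
                          relative_position_buckets=32),
}


@dataclass
class ModelState:
    """Named parameter arrays. ``params['E']`` is the tied embedding table:
    it is both the input embedding and the LM-head projection (one array,
    one storage)."""

    config: EncoderConfig
    params: Dict[str, np.ndarray] = field(default_factory=dict)

    def zeros_like_params(self) -> Dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.params.items()}


def init_model(config: EncoderConfig, seed: int = 0) -> ModelState:
    """Deterministic initialization: N(0, 0.02) weights, zero biases, unit LN."""
    rng = np.random.default_rng(seed)
    H, I, V = config.hidden_size, config.intermediate_size, config.vocab_size
    K2 = 2 * config.relative_position_buckets
    std = 0.02

    dt = config.np_dtype

    def w(*shape):
        return rng.normal(0.0, std, size=shape).astype(dt)

    p: Dict[str, np.ndarray] = {
        "E": w(V, H),
        "type_E": w(config.num_token_types, H),
        "head_b": np.zeros(V, dtype=dt),
        "rel_E": w(K2, H),
        "emb_ln_g": np.ones(H, dtype=dt),
        "emb_ln_b": np.zeros(H, dtype=dt),
    }
    for l in range(config.num_layers):
        p[f"l{l}.Wq"] = w(H, H)
        p[f"l{l}.bq"] = np.zeros(H, dtype=dt)
        p[f"l{l}.Wk"] = w(H, H)
        p[f"l{l}.bk"] = np.zeros(H, dtype=dt)
        p[f"l{l}.Wv"] = w(H, H)
        p[f"l{l}.bv"] = np.zeros(H, dtype=dt)
        p[f"l{l}.Wo"] = w(H, H)
        p[f"l{l}.bo"] = np.zeros(H, dtype=dt)
        p[f"l{l}.ln1_g"] = np.ones(H, dtype=dt)
        p[f"l{l}.ln1_b"] = np.zeros(H, dtype=dt)
        p[f"l{l}.W1"] = w(H, I)
        p[f"l{l}.b1"] = np.zeros(I, dtype=dt)
        p[f"l{l}.W2"] = w(I, H)
        p[f"l{l}.b2"] = np.zeros(H, dtype=dt)
        p[f"l{l}.ln2_g"] = np.ones(H, dtype=dt)
        p[f"l{l}.ln2_b"] = np.zeros(H, dtype=dt)
    return ModelState(config=config, params=p)


def n_parameters(state: ModelState) -> int:
    return int(sum(v.size for v in state.params.values()))


# ---------------------------------------------------------------- primitives


def _gelu_fwd(x):
    from scipy.special import erf

    e = erf(x / math.sqrt(2.0))
    y = 0.5 * x * (1.0 + e)
    return y, e


def _gelu_bwd(x, e, dy):
    pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
    return dy * (0.5 * (1.0 + e) + x * pdf)


def _ln_fwd(x, g, b):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv)


def _ln_bwd(cache, g, dy):
    xhat, inv = cache
    dxhat = dy * g
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = (dxhat - m1 - xhat * m2) * inv
    dg = (dy * xhat).reshape(-1, xhat.shape[-1]).sum(axis=0)
    db = dy.reshape(-1, dy.shape[-1]).sum(axis=0)
    return dx, dg, db


def _rel_onehot(L: int, K: int) -> Tuple[np.ndarray, np.ndarray]:
    """Relative-distance index matrix R[i,j]=clip(i-j)+K and its one-hot form."""
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    R = np.clip(i - j, -K, K - 1) + K  # (L, L) in [0, 2K)
    M = np.zeros((L, L, 2 * K))
    M[i, j, R] = 1.0
    return R, M


_REL_CACHE: Dict[Tuple[int, int], Tuple[np.ndarray, np.ndarray]] = {}


def _rel(L, K):
    key = (L, K)
    if key not in _REL_CACHE:
        _REL_CACHE[key] = _rel_onehot(L, K)
    return _REL_CACHE[key]


def _split_heads(x, nh):
    B, L, H = x.shape
    return np.moveaxis(x.reshape(B, L, nh, H // nh), 2, 1)  # (B, nh, L, dh)


def _merge_heads(x):
    B, nh, L, dh = x.shape
    return np.moveaxis(x, 1, 2).reshape(B, L, nh * dh)


def _dropout(x, rate, rng):
    if rate <= 0.0 or rng is None:
        return x, None
    keep = rng.random(x.shape, dtype=np.float32) >= rate
    mask = keep.astype(x.dtype) * np.asarray(1.0 / (1.0 - rate), dtype=x.dtype)
    return x * mask, mask


# ------------------------------------------------------------------- forward


def embed_inputs(state: ModelState, token_ids, token_type_ids) -> np.ndarray:
    """Input vectors: token embedding + token-type embedding, per position."""
    ids = np.asarray(token_ids)
    tids = np.asarray(token_type_ids)
    if ids.shape != tids.shape:
        raise ValueError("token_ids and token_type_ids must have equal shape")
    V, T = state.config.vocab_size, state.config.num_token_types
    if ids.min() < 0 or ids.max() >= V:
        raise ValueError("token id out of range")
    if tids.min() < 0 or tids.max() >= T:
        raise ValueError("token type id out of range")
    return state.params["E"][ids] + state.params["type_E"][tids]


def forward_with_cache(
    state: ModelState,
    token_ids: np.ndarray,
    token_type_ids: np.ndarray,
    valid: Optional[np.ndarray] = None,
    train: bool = False,
    rng: Optional[np.random.Generator] = None,
):
    """Full encoder pass; returns (final hidden (B,L,H), cache for backward)."""
    cfg = state.config
    p = state.params
    ids = np.atleast_2d(np.asarray(token_ids))
    tids = np.atleast_2d(np.asarray(token_type_ids))
    B, L = ids.shape
    if L > cfg.max_positions:
        raise ValueError(f"sequence length {L} exceeds max_positions")
    if valid is None:
        valid = np.ones((B, L), dtype=bool)
    valid = np.atleast_2d(np.asarray(valid, dtype=bool))
    rate = cfg.dropout if train else 0.0
    nh, dh, K = cfg.num_heads, cfg.head_dim, cfg.relative_position_buckets
    scale = 1.0 / math.sqrt(3 * dh)
    R, _M = _rel(L, K)
    Rb = np.broadcast_to(R, (1, 1, L, L))

    x0 = p["E"][ids] + p["type_E"][tids]
    h, emb_ln_cache = _ln_fwd(x0, p["emb_ln_g"], p["emb_ln_b"])
    h, emb_drop = _dropout(h, rate, rng if train else None)

    pad_bias = np.where(valid[:, None, None, :], 0.0, _PAD_BIAS).astype(h.dtype)  # (B,1,1,L)
    layers = []
    for l in range(cfg.num_layers):
        h_in = h
        Qc = _split_heads(h @ p[f"l{l}.Wq"] + p[f"l{l}.bq"], nh)
        Kc = _split_heads(h @ p[f"l{l}.Wk"] + p[f"l{l}.bk"], nh)
        Vc = _split_heads(h @ p[f"l{l}.Wv"] + p[f"l{l}.bv"], nh)
        # shared relative-position table projected by this layer's Wq/Wk
        Kr = _split_heads((p["rel_E"] @ p[f"l{l}.Wk"])[None], nh)[0]  # (nh,2K,dh)
        Qr = _split_heads((p["rel_E"] @ p[f"l{l}.Wq"])[None], nh)[0]
        # content->position and position->content scores for ALL 2K offsets
        # (batched BLAS), then gathered at the actual relative offsets
        c2p_all = Qc @ Kr.swapaxes(-1, -2)          # (B, nh, L, 2K), index i
        p2c_all = Kc @ Qr.swapaxes(-1, -2)          # (B, nh, L, 2K), index j
        c2p = np.take_along_axis(c2p_all, np.broadcast_to(Rb, c2p_all.shape[:2] + (L, L)), axis=-1)
        p2c = np.take_along_axis(p2c_all, np.broadcast_to(Rb, p2c_all.shape[:2] + (L, L)), axis=-1).swapaxes(-1, -2)
        S = Qc @ Kc.swapaxes(-1, -2) + c2p + p2c
        S *= scale
        S = S + pad_bias
        S -= S.max(axis=-1, keepdims=True)
        expS = np.exp(S)
        A = expS / expS.sum(axis=-1, keepdims=True)
        A_d, attn_drop = _dropout(A, rate, rng if train else None)
        ctx = A_d @ Vc
        o = _merge_heads(ctx) @ p[f"l{l}.Wo"] + p[f"l{l}.bo"]
        o, o_drop = _dropout(o, rate, rng if train else None)
        h1, ln1_cache = _ln_fwd(h_in + o, p[f"l{l}.ln1_g"], p[f"l{l}.ln1_b"])
        u = h1 @ p[f"l{l}.W1"] + p[f"l{l}.b1"]
        g_act, erf_c = _gelu_fwd(u)
        f = g_act @ p[f"l{l}.W2"] + p[f"l{l}.b2"]
        f, f_drop = _dropout(f, rate, rng if train else None)
        h, ln2_cache = _ln_fwd(h1 + f, p[f"l{l}.ln2_g"], p[f"l{l}.ln2_b"])
        layers.append(dict(h_in=h_in, Qc=Qc, Kc=Kc, Vc=Vc, Kr=Kr, Qr=Qr,
                           A=A, A_d=A_d, ctx=ctx,
                           attn_drop=attn_drop, o_drop=o_drop, f_drop=f_drop,
                           ln1=ln1_cache, ln2=ln2_cache, h1=h1, u=u,
                           g_act=g_act, erf_c=erf_c))
    cache = dict(ids=ids, tids=tids, valid=valid, x0=x0,
                 emb_ln=emb_ln_cache, emb_drop=emb_drop, layers=layers,
                 R=R, scale=scale)
    return h, cache


def forward_hidden(
    state: ModelState,
    token_ids,
    token_type_ids,
    valid=None,
) -> np.ndarray:
    """Evaluation-mode encoder pass (dropout disabled, deterministic)."""
    h, _ = forward_with_cache(state, token_ids, token_type_ids, valid, train=False)
    return h


def lm_logits(state: ModelState, hidden: np.ndarray) -> np.ndarray:
    """Weight-tied language head: logits[..., v] = <h, E[v]> + b[v]."""
    return hidden @ state.params["E"].T + state.params["head_b"]


def mean_pool(hidden: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Arithmetic mean of hidden states over valid (non-pad) positions."""
    hidden = np.asarray(hidden)
    valid = np.asarray(valid, dtype=bool)
    squeeze = hidden.ndim == 2
    if squeeze:
        hidden, valid = hidden[None], valid[None]
    counts = valid.sum(axis=1)
    if (counts == 0).any():
        raise ValueError("mean_pool needs at least one valid position")
    pooled = (hidden * valid[..., None]).sum(axis=1) / counts[:, None]
    return pooled[0] if squeeze else pooled


def backward(state: ModelState, cache, d_hidden: np.ndarray) -> Dict[str, np.ndarray]:
    """Backpropagate d(loss)/d(final hidden) to all parameters.

    The returned dict covers every parameter; gradients flowing through the
    LM head itself (tied ``E`` rows used as output projection, ``head_b``)
    are the caller's responsibility and should be added on top.
    """
    cfg = state.config
    p = state.params
    grads = state.zeros_like_params()
    scale = cache["scale"]
    L = cache["ids"].shape[1]
    dh = np.asarray(d_hidden)

    for l in reversed(range(cfg.num_layers)):
        c = cache["layers"][l]
        dh1pf, dg2, db2 = _ln_bwd(c["ln2"], p[f"l{l}.ln2_g"], dh)
        grads[f"l{l}.ln2_g"] += dg2
        grads[f"l{l}.ln2_b"] += db2
        df = dh1pf if c["f_drop"] is None else dh1pf * c["f_drop"]
        grads[f"l{l}.b2"] += df.reshape(-1, df.shape[-1]).sum(axis=0)
        grads[f"l{l}.W2"] += c["g_act"].reshape(-1, c["g_act"].shape[-1]).T @ df.reshape(-1, df.shape[-1])
        dgact = df @ p[f"l{l}.W2"].T
        du = _gelu_bwd(c["u"], c["erf_c"], dgact)
        grads[f"l{l}.b1"] += du.reshape(-1, du.shape[-1]).sum(axis=0)
        grads[f"l{l}.W1"] += c["h1"].reshape(-1, c["h1"].shape[-1]).T @ du.reshape(-1, du.shape[-1])
        dh1 = dh1pf + du @ p[f"l{l}.W1"].T

        dhino, dg1, db1 = _ln_bwd(c["ln1"], p[f"l{l}.ln1_g"], dh1)
        grads[f"l{l}.ln1_g"] += dg1
        grads[f"l{l}.ln1_b"] += db1
        do = dhino if c["o_drop"] is None else dhino * c["o_drop"]
        grads[f"l{l}.bo"] += do.reshape(-1, do.shape[-1]).sum(axis=0)
        merged_ctx = _merge_heads(c["ctx"])
        grads[f"l{l}.Wo"] += merged_ctx.reshape(-1, merged_ctx.shape[-1]).T @ do.reshape(-1, do.shape[-1])
        dctx = _split_heads(do @ p[f"l{l}.Wo"].T, cfg.num_heads)

        dA_d = dctx @ c["Vc"].swapaxes(-1, -2)
        dVc = c["A_d"].swapaxes(-1, -2) @ dctx
        dA = dA_d if c["attn_drop"] is None else dA_d * c["attn_drop"]
        A = c["A"]
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dS *= scale
        B, nh = dS.shape[:2]
        K = cfg.relative_position_buckets
        K2 = 2 * K
        # scatter dS into relative-offset bins: walk the 2L-1 diagonals once;
        # diagonal o holds entries (i, j=i+o), so it lands in bin clip(-o)
        # for the content->position term (indexed by i) and bin clip(o) for
        # the position->content term (indexed by j)
        dc2p_all = np.zeros((B, nh, L, K2), dtype=dS.dtype)
        dp2c_all = np.zeros((B, nh, L, K2), dtype=dS.dtype)
        for o in range(-(L - 1), L):
            vals = dS.diagonal(o, axis1=2, axis2=3)  # (B, nh, L-|o|)
            i0 = 0 if o >= 0 else -o
            j0 = o if o >= 0 else 0
            n_diag = L - abs(o)
            r_c2p = int(np.clip(-o, -K, K - 1)) + K
            r_p2c = int(np.clip(o, -K, K - 1)) + K
            dc2p_all[:, :, i0 : i0 + n_diag, r_c2p] += vals
            dp2c_all[:, :, j0 : j0 + n_diag, r_p2c] += vals
        dQc = dS @ c["Kc"] + dc2p_all @ c["Kr"]
        dKc = dS.swapaxes(-1, -2) @ c["Qc"] + dp2c_all @ c["Qr"]
        dKr = (
            dc2p_all.transpose(1, 3, 0, 2).reshape(nh, K2, B * L)
            @ c["Qc"].transpose(1, 0, 2, 3).reshape(nh, B * L, cfg.head_dim)
        )
        dQr = (
            dp2c_all.transpose(1, 3, 0, 2).reshape(nh, K2, B * L)
            @ c["Kc"].transpose(1, 0, 2, 3).reshape(nh, B * L, cfg.head_dim)
        )

        h_in = c["h_in"]
        dh_in = dhino.copy()
        for name, dX in (("Wq", dQc), ("Wk", dKc), ("Wv", dVc)):
            dflat = _merge_heads(dX)
            grads[f"l{l}.b{name[1]}"] += dflat.reshape(-1, dflat.shape[-1]).sum(axis=0)
            grads[f"l{l}.{name}"] += h_in.reshape(-1, h_in.shape[-1]).T @ dflat.reshape(-1, dflat.shape[-1])
            dh_in += dflat @ p[f"l{l}.{name}"].T
        # relative-position projections share rel_E across layers
        K2, H = p["rel_E"].shape
        dKr_flat = np.moveaxis(dKr, 0, 1).reshape(K2, H)
        dQr_flat = np.moveaxis(dQr, 0, 1).reshape(K2, H)
        grads[f"l{l}.Wk"] += p["rel_E"].T @ dKr_flat
        grads[f"l{l}.Wq"] += p["rel_E"].T @ dQr_flat
        grads["rel_E"] += dKr_flat @ p[f"l{l}.Wk"].T + dQr_flat @ p[f"l{l}.Wq"].T
        dh = dh_in

    if cache["emb_drop"] is not None:
        dh = dh * cache["emb_drop"]
    dx0, dge, dbe = _ln_bwd(cache["emb_ln"], p["emb_ln_g"], dh)
    grads["emb_ln_g"] += dge
    grads["emb_ln_b"] += dbe
    np.add.at(grads["E"], cache["ids"], dx0)
    np.add.at(grads["type_E"], cache["tids"], dx0)
    return grads


# --------------------------------------------------------------- checkpoints


def save_checkpoint(state: ModelState, path) -> None:
    """Single-archive checkpoint: config JSON + named parameter arrays."""
    arrays = {f"param::{k}": v for k, v in state.params.items()}
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(state.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> ModelState:
    with np.load(path) as z:
        cfg = EncoderConfig(**json.loads(bytes(z["config_json"]).decode()))
        params = {
            k[len("param::"):]: z[k] for k in z.files if k.startswith("param::")
        }
    expected = init_model(cfg, seed=0).params
    if set(params) != set(expected):
        raise ValueError("checkpoint parameter names do not match config")
    for k, v in params.items():
        if v.shape != expected[k].shape:
            raise ValueError(f"checkpoint shape mismatch for {k}")
    return ModelState(config=cfg, params=params)
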