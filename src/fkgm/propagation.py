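"""Knowledge-aware attention message passing over the CRKG.

Each propagation sweep lets every entity receive an attention-weighted sum
of its neighbors' current representations and fold it in through a
bi-interaction aggregator:

* edge logit:      ``pi_hat_r(e, t) = t_perp . tanh(e_perp + v_r)`` with the
  TransD projection of the edge's relation applied to both endpoints;
* normalisation:   softmax of the logits over each entity's neighborhood;
* message:         ``v_Ne = sum pi_r(e, t) * v_t``;
* aggregation:     ``LeakyReLU(W1 (v_e + v_Ne)) + LeakyReLU(W2 (v_e ⊙ v_Ne))``.

Layer outputs for l = 0..L are concatenated into the final representation,
and user-recipe affinity is the inner product of final representations.

Attention coefficients are computed from the current embeddings, then held
fixed while gradients flow through the aggregation (the standard recipe for
attentive collaborative-KG propagation); :func:`propagate_backward` is the
matching hand-derived reverse pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .embedding import ModelParams, project
from .graph import CRKG

__all__ = [
    "LEAKY_SLOPE",
    "attention_logit",
    "attention_logits",
    "normalize_attention",
    "attention_matrix",
    "aggregate_neighborhood",
    "bi_interaction",
    "propagate",
    "propagate_backward",
    "final_representation",
    "predict_score",
    "PropagationCache",
]

#: Negative slope of the LeakyReLU used by the bi-interaction aggregator.
LEAKY_SLOPE = 0.2


def _leaky(x: np.ndarray, slope: float = LEAKY_SLOPE) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def _leaky_grad(x: np.ndarray, slope: float = LEAKY_SLOPE) -> np.ndarray:
    return np.where(x > 0, 1.0, slope)


def attention_logit(params: ModelParams, e: int, t: int, r: int) -> float:
    """Unnormalised attention of edge ``(e, r, t)``: ``t_perp . tanh(e_perp + v_r)``."""
    v_rp = params.rel_proj[r]
    e_perp = project(params.ent_emb[e], params.ent_proj[e], v_rp)
    t_perp = project(params.ent_emb[t], params.ent_proj[t], v_rp)
    return float(t_perp @ np.tanh(e_perp + params.rel_emb[r]))


def attention_logits(params: ModelParams, crkg: CRKG) -> np.ndarray:
    """Vectorised :func:`attention_logit` over every directed edge of the graph."""
    e, r, t = crkg.edges.T
    v_rp = params.rel_proj[r]
    e_perp = project(params.ent_emb[e], params.ent_proj[e], v_rp)
    t_perp = project(params.ent_emb[t], params.ent_proj[t], v_rp)
    return np.sum(t_perp * np.tanh(e_perp + params.rel_emb[r]), axis=-1)


def normalize_attention(logits: np.ndarray, receivers: np.ndarray | None = None,
                        n_entities: int | None = None) -> np.ndarray:
    """Softmax of attention logits, per receiving entity.

    With ``receivers`` omitted, ``logits`` is one entity's neighborhood and a
    plain (max-subtracted) softmax is returned; otherwise a segment softmax
    grouped by the receiver ids (which must be sorted, as CRKG edges are).
    """
    logits = np.asarray(logits, dtype=float)
    if receivers is None:
        if logits.size == 0:
            return logits.copy()
        shifted = np.exp(logits - logits.max())
        return shifted / shifted.sum()
    receivers = np.asarray(receivers)
    if np.any(np.diff(receivers) < 0):
        raise ValueError("receiver ids must be sorted")
    n = int(n_entities if n_entities is not None else receivers.max() + 1)
    # segment max-subtracted softmax
    seg_max = np.full(n, -np.inf)
    np.maximum.at(seg_max, receivers, logits)
    shifted = np.exp(logits - seg_max[receivers])
    seg_sum = np.zeros(n)
    np.add.at(seg_sum, receivers, shifted)
    return shifted / seg_sum[receivers]


def attention_matrix(crkg: CRKG, params: ModelParams) -> sp.csr_matrix:
    """Row-stochastic sparse attention operator A with ``A[e, t] = pi_r(e, t)``.

    Rows of isolated entities are all-zero (they receive no message).
    Parallel edges between the same pair under different relations keep
    separate coefficients and sum in the matrix entry.
    """
    logits = attention_logits(params, crkg)
    coeffs = normalize_attention(logits, crkg.edges[:, 0], crkg.n_entities)
    mat = sp.coo_matrix(
        (coeffs, (crkg.edges[:, 0], crkg.edges[:, 2])),
        shape=(crkg.n_entities, crkg.n_entities),
    )
    return mat.tocsr()


def aggregate_neighborhood(coefficients: np.ndarray, neighbor_vectors: np.ndarray) -> np.ndarray:
    """Convex combination ``sum_i pi_i v_i`` of one entity's neighbor vectors."""
    coefficients = np.asarray(coefficients, dtype=float)
    neighbor_vectors = np.asarray(neighbor_vectors, dtype=float)
    if coefficients.size == 0:
        return np.zeros(neighbor_vectors.shape[-1] if neighbor_vectors.ndim else 0)
    return coefficients @ neighbor_vectors


def bi_interaction(
    v_e: np.ndarray, v_ne: np.ndarray, W1: np.ndarray, W2: np.ndarray,
    slope: float = LEAKY_SLOPE,
) -> np.ndarray:
    """``LeakyReLU(W1 (v_e + v_Ne)) + LeakyReLU(W2 (v_e ⊙ v_Ne))``."""
    v_e, v_ne = np.asarray(v_e, dtype=float), np.asarray(v_ne, dtype=float)
    if v_e.shape != v_ne.shape:
        raise ValueError(f"shape mismatch: {v_e.shape} vs {v_ne.shape}")
    return _leaky((v_e + v_ne) @ W1.T, slope) + _leaky((v_e * v_ne) @ W2.T, slope)


@dataclass
class PropagationCache:
    """Intermediates of a forward sweep needed by :func:`propagate_backward`."""

    A: sp.csr_matrix
    states: list[np.ndarray]  # V^0..V^L after dropout
    messages: list[np.ndarray]  # M^l = A V^{l-1}
    pre_acts1: list[np.ndarray]
    pre_acts2: list[np.ndarray]
    dropout_masks: list[np.ndarray | None]
    dropout: float
    slope: float


def propagate(
    params: ModelParams,
    A: sp.csr_matrix,
    n_layers: int | None = None,
    message_dropout: float = 0.0,
    training: bool = False,
    rng: np.random.Generator | None = None,
    slope: float = LEAKY_SLOPE,
) -> PropagationCache:
    """Run L sweeps of attention aggregation over all entities at once.

    ``A`` is the (frozen) attention operator from :func:`attention_matrix`.
    Message dropout (inverted scaling) is applied to each layer's output
    only when ``training`` is true.  Returns the cache whose ``states``
    field holds V^0..V^L.
    """
    L = len(params.W1) if n_layers is None else n_layers
    if L < 0 or L > len(params.W1):
        raise ValueError(f"n_layers={L} but {len(params.W1)} weight pairs available")
    v = params.ent_emb
    states = [v]
    messages, pre1, pre2, masks = [], [], [], []
    keep = 1.0 - message_dropout
    for layer in range(L):
        m = A @ v
        s = v + m
        p = v * m
        h1 = s @ params.W1[layer].T
        h2 = p @ params.W2[layer].T
        out = _leaky(h1, slope) + _leaky(h2, slope)
        mask = None
        if training and message_dropout > 0.0:
            if rng is None:
                raise ValueError("training with dropout requires an rng")
            mask = (rng.random(out.shape) < keep).astype(float)
            out = out * mask / keep
        messages.append(m)
        pre1.append(h1)
        pre2.append(h2)
        masks.append(mask)
        states.append(out)
        v = out
    return PropagationCache(
        A=A, states=states, messages=messages, pre_acts1=pre1, pre_acts2=pre2,
        dropout_masks=masks, dropout=message_dropout, slope=slope,
    )


def propagate_backward(
    params: ModelParams, cache: PropagationCache, grads_per_layer: Sequence[np.ndarray]
) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
    """Reverse sweep: gradients w.r.t. the layer-0 table and aggregator weights.

    ``grads_per_layer`` holds dL/dV^l for l = 0..L (zeros where a layer does
    not enter the loss).  The attention operator is treated as a constant.
    Returns ``(d ent_emb, [dW1_l], [dW2_l])``.
    """
    L = len(cache.messages)
    if len(grads_per_layer) != L + 1:
        raise ValueError(f"expected {L + 1} per-layer gradients, got {len(grads_per_layer)}")
    keep = 1.0 - cache.dropout
    dW1 = [np.zeros_like(params.W1[l]) for l in range(L)]
    dW2 = [np.zeros_like(params.W2[l]) for l in range(L)]
    g = np.asarray(grads_per_layer[L], dtype=float)
    AT = cache.A.T.tocsr()
    for layer in range(L - 1, -1, -1):
        mask = cache.dropout_masks[layer]
        if mask is not None:
            g = g * mask / keep
        h1, h2 = cache.pre_acts1[layer], cache.pre_acts2[layer]
        v_prev = cache.states[layer]
        m = cache.messages[layer]
        dh1 = g * _leaky_grad(h1, cache.slope)
        dh2 = g * _leaky_grad(h2, cache.slope)
        dW1[layer] = dh1.T @ (v_prev + m)
        dW2[layer] = dh2.T @ (v_prev * m)
        ds = dh1 @ params.W1[layer]
        dp = dh2 @ params.W2[layer]
        dv_prev = ds + dp * m
        dm = ds + dp * v_prev
        g = dv_prev + AT @ dm + np.asarray(grads_per_layer[layer], dtype=float)
    return g, dW1, dW2


def final_representation(states: Sequence[np.ndarray]) -> np.ndarray:
    """Concatenate layer representations 0..L along the feature axis."""
    if not len(states):
        raise ValueError("no layer states to concatenate")
    return np.concatenate([np.asarray(s) for s in states], axis=-1)


def predict_score(u_repr: np.ndarray, rp_repr: np.ndarray) -> float:
    """Matching score: inner product of final representations."""
    u_repr, rp_repr = np.asarray(u_repr), np.asarray(rp_repr)
    if u_repr.shape[-1] != rp_repr.shape[-1]:
        raise ValueError(f"length mismatch: {u_repr.shape} vs {rp_repr.shape}")
    return float(np.dot(u_repr, rp_repr)) if u_repr.ndim == 1 and rp_repr.ndim == 1 else u_repr @ rp_repr.T
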