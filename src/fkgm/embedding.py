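"""TransD knowledge-graph embedding of the CRKG.

Every entity carries an embedding ``v_e`` and a projection vector ``v_ep``
(length ``d``); every relation carries ``v_r`` and ``v_rp`` (length ``z``).
Head and tail entities are mapped into the relation space by the dynamic
matrix ``M_rx = v_rp v_xp^T + I`` (``I`` the z-by-d rectangular identity),
which is never materialised:

    project(v_x) = v_rp * (v_xp . v_x) + pad_or_truncate(v_x, z)

The plausibility of a triple is the negated squared translation residual
``g(h, r, t) = -|| h_perp + v_r - t_perp ||^2`` (0 for an exact translation,
negative otherwise).  Training uses a pairwise ranking loss over
tail-corrupted triples that pushes valid triples to higher plausibility
than corrupted ones:

    L_kg = sum softplus(-(g(h,r,t) - g(h,r,t')))

Gradients are computed analytically (see :func:`kg_loss_and_grad`) and are
validated against central finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .graph import CRKG

__all__ = [
    "ModelParams",
    "glorot_uniform",
    "init_params",
    "project",
    "triple_score",
    "sample_corrupted",
    "kg_loss",
    "kg_loss_and_grad",
]


@dataclass
class ModelParams:
    """All trainable tensors of the recommender.

    ``ent_emb``/``ent_proj`` are (n_entities, d); ``rel_emb``/``rel_proj``
    are (n_relations, z); ``W1``/``W2`` are the per-layer bi-interaction
    aggregator weights (d_out x d_in each).
    """

    ent_emb: np.ndarray
    ent_proj: np.ndarray
    rel_emb: np.ndarray
    rel_proj: np.ndarray
    W1: list[np.ndarray] = field(default_factory=list)
    W2: list[np.ndarray] = field(default_factory=list)
    seed: int | None = None

    @property
    def d(self) -> int:
        return self.ent_emb.shape[1]

    @property
    def z(self) -> int:
        return self.rel_emb.shape[1]

    @property
    def n_entities(self) -> int:
        return self.ent_emb.shape[0]

    @property
    def n_relations(self) -> int:
        return self.rel_emb.shape[0]

    def copy(self) -> "ModelParams":
        return ModelParams(
            ent_emb=self.ent_emb.copy(),
            ent_proj=self.ent_proj.copy(),
            rel_emb=self.rel_emb.copy(),
            rel_proj=self.rel_proj.copy(),
            W1=[w.copy() for w in self.W1],
            W2=[w.copy() for w in self.W2],
            seed=self.seed,
        )

    def save(self, path) -> None:
        np.savez(
            path,
            ent_emb=self.ent_emb,
            ent_proj=self.ent_proj,
            rel_emb=self.rel_emb,
            rel_proj=self.rel_proj,
            n_layers=np.array([len(self.W1)]),
            **{f"W1_{i}": w for i, w in enumerate(self.W1)},
            **{f"W2_{i}": w for i, w in enumerate(self.W2)},
        )

    @classmethod
    def load(cls, path) -> "ModelParams":
        data = np.load(path)
        n_layers = int(data["n_layers"][0])
        return cls(
            ent_emb=data["ent_emb"],
            ent_proj=data["ent_proj"],
            rel_emb=data["rel_emb"],
            rel_proj=data["rel_proj"],
            W1=[data[f"W1_{i}"] for i in range(n_layers)],
            W2=[data[f"W2_{i}"] for i in range(n_layers)],
        )


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Glorot/Xavier-uniform draw: bound ``sqrt(6 / (fan_in + fan_out))``.

    For a 2-D tensor the fans are its two dimensions (the convention of the
    usual ``xavier_uniform`` initialisers).
    """
    fan_out, fan_in = shape
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_params(crkg: CRKG, d: int = 64, z: int | None = None, seed: int | None = None,
                n_layers: int = 3) -> ModelParams:
    """Glorot-uniform initialisation of all tensors, reproducible by seed."""
    if d < 1 or (z is not None and z < 1):
        raise ValueError(f"embedding dimensions must be >= 1, got d={d}, z={z}")
    z = d if z is None else z
    rng = np.random.default_rng(seed)
    return ModelParams(
        ent_emb=glorot_uniform(rng, (crkg.n_entities, d)),
        ent_proj=glorot_uniform(rng, (crkg.n_entities, d)),
        rel_emb=glorot_uniform(rng, (crkg.n_relations, z)),
        rel_proj=glorot_uniform(rng, (crkg.n_relations, z)),
        W1=[glorot_uniform(rng, (d, d)) for _ in range(n_layers)],
        W2=[glorot_uniform(rng, (d, d)) for _ in range(n_layers)],
        seed=seed,
    )


def _pad_or_truncate(v: np.ndarray, z: int) -> np.ndarray:
    """Apply the rectangular identity: truncate or zero-pad the last axis to z."""
    d = v.shape[-1]
    if d == z:
        return v
    if d > z:
        return v[..., :z]
    pad = [(0, 0)] * (v.ndim - 1) + [(0, z - d)]
    return np.pad(v, pad)


def project(v_x: np.ndarray, v_xp: np.ndarray, v_rp: np.ndarray) -> np.ndarray:
    """Matrix-free TransD projection ``M_rx v_x`` with ``M_rx = v_rp v_xp^T + I``.

    Accepts single vectors or batches (leading axes broadcast); the last axis
    of ``v_x``/``v_xp`` is ``d`` and of ``v_rp`` is ``z``.
    """
    v_x, v_xp, v_rp = np.asarray(v_x), np.asarray(v_xp), np.asarray(v_rp)
    if v_x.shape != v_xp.shape:
        raise ValueError(f"entity vector/projection shape mismatch: {v_x.shape} vs {v_xp.shape}")
    inner = np.sum(v_x * v_xp, axis=-1, keepdims=True)
    return v_rp * inner + _pad_or_truncate(v_x, v_rp.shape[-1])


def triple_score(params: ModelParams, h, r, t) -> np.ndarray | float:
    """Plausibility ``g = -||h_perp + v_r - t_perp||^2`` (<= 0, 0 iff exact)."""
    h = np.asarray(h)
    scalar = h.ndim == 0
    h, r, t = np.atleast_1d(h), np.atleast_1d(r), np.atleast_1d(t)
    if (h >= params.n_entities).any() or (t >= params.n_entities).any() or (
        r >= params.n_relations
    ).any() or min(h.min(), r.min(), t.min()) < 0:
        raise KeyError("triple ids out of range for the parameter tables")
    h_perp = project(params.ent_emb[h], params.ent_proj[h], params.rel_proj[r])
    t_perp = project(params.ent_emb[t], params.ent_proj[t], params.rel_proj[r])
    resid = h_perp + params.rel_emb[r] - t_perp
    g = -np.sum(resid * resid, axis=-1)
    return float(g[0]) if scalar else g


def sample_corrupted(
    crkg: CRKG,
    triples: np.ndarray,
    rng: np.random.Generator,
    filtered: bool = False,
    max_retries: int = 100,
) -> np.ndarray:
    """Tail-corrupt each triple: (h, r, t, t') with t' uniform over entities, t' != t.

    In ``filtered`` mode a corrupted tail that forms an existing edge is
    resampled; exhausting ``max_retries`` raises (e.g. a relation that is
    fully connected leaves no valid corruption).
    """
    triples = np.asarray(triples, dtype=np.int64).reshape(-1, 3)
    if crkg.n_entities < 2:
        raise ValueError("need at least two entities to corrupt tails")
    existing = None
    if filtered:
        existing = {(int(h), int(r), int(t)) for h, r, t in crkg.edges}
    t_neg = np.empty(len(triples), dtype=np.int64)
    for i, (h, r, t) in enumerate(triples):
        for attempt in range(max_retries):
            cand = int(rng.integers(0, crkg.n_entities))
            if cand == t:
                continue
            if existing is not None and (int(h), int(r), cand) in existing:
                continue
            t_neg[i] = cand
            break
        else:
            raise RuntimeError(
                f"could not corrupt tail of ({h},{r},{t}) within {max_retries} tries"
            )
    return np.column_stack([triples, t_neg])


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def kg_loss(params: ModelParams, batch: np.ndarray) -> float:
    """Pairwise ranking loss over a corrupted batch of (h, r, t, t') rows.

    Per record ``softplus(-(g_pos - g_neg))`` (== ``-ln sigma(g_pos - g_neg)``),
    summed over the batch; the margin orientation rewards valid triples being
    more plausible than their corruptions.
    """
    batch = np.asarray(batch, dtype=np.int64).reshape(-1, 4)
    if batch.size == 0:
        raise ValueError("empty corrupted-triple batch")
    g_pos = triple_score(params, batch[:, 0], batch[:, 1], batch[:, 2])
    g_neg = triple_score(params, batch[:, 0], batch[:, 1], batch[:, 3])
    return float(np.sum(_softplus(-(g_pos - g_neg))))


def kg_loss_and_grad(
    params: ModelParams, batch: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """Loss plus analytic gradients w.r.t. the four embedding tables.

    Returns dense gradient arrays shaped like ``ent_emb``, ``ent_proj``,
    ``rel_emb``, ``rel_proj`` (scatter-added over the batch).
    """
    batch = np.asarray(batch, dtype=np.int64).reshape(-1, 4)
    if batch.size == 0:
        raise ValueError("empty corrupted-triple batch")
    h, r, t_pos, t_neg = batch.T
    d, z = params.d, params.z

    g_ent = np.zeros_like(params.ent_emb)
    g_entp = np.zeros_like(params.ent_proj)
    g_rel = np.zeros_like(params.rel_emb)
    g_relp = np.zeros_like(params.rel_proj)

    v_rp = params.rel_proj[r]

    def proj_cache(ids):
        v = params.ent_emb[ids]
        vp = params.ent_proj[ids]
        inner = np.sum(v * vp, axis=-1, keepdims=True)
        return v, vp, inner, v_rp * inner + _pad_or_truncate(v, z)

    vh, vhp, inner_h, h_perp = proj_cache(h)
    vtp_, vtpp, inner_tp, tpos_perp = proj_cache(t_pos)
    vtn, vtnp, inner_tn, tneg_perp = proj_cache(t_neg)
    vr = params.rel_emb[r]

    res_pos = h_perp + vr - tpos_perp
    res_neg = h_perp + vr - tneg_perp
    g_pos = -np.sum(res_pos**2, axis=-1)
    g_neg = -np.sum(res_neg**2, axis=-1)
    margin = g_pos - g_neg
    loss = float(np.sum(_softplus(-margin)))

    # dL/dmargin = -sigma(-margin) (overflow-safe); dg_pos/dres_pos = -2 res_pos
    coef = -np.exp(-np.logaddexp(0.0, margin))  # (B,)
    dg_pos = coef[:, None]  # multiplies dres via -2 res
    dg_neg = -coef[:, None]
    dres_pos = dg_pos * (-2.0 * res_pos)  # dL/dres_pos, (B, z)
    dres_neg = dg_neg * (-2.0 * res_neg)

    # residual = h_perp + v_r - t_perp
    dh_perp = dres_pos + dres_neg
    dt_pos_perp = -dres_pos
    dt_neg_perp = -dres_neg
    np.add.at(g_rel, r, dres_pos + dres_neg)

    def backprop_projection(ids, v, vp, inner, dperp):
        # perp = v_rp * inner + I~ v with inner = v . vp; the adjoint of the
        # rectangular identity I~ is pad_or_truncate back to length d
        dinner = np.sum(dperp * v_rp, axis=-1, keepdims=True)
        dv = dinner * vp + _pad_or_truncate(dperp, d)
        dvp = dinner * v
        dv_rp = dperp * inner
        np.add.at(g_ent, ids, dv)
        np.add.at(g_entp, ids, dvp)
        np.add.at(g_relp, r, dv_rp)

    backprop_projection(h, vh, vhp, inner_h, dh_perp)
    backprop_projection(t_pos, vtp_, vtpp, inner_tp, dt_pos_perp)
    backprop_projection(t_neg, vtn, vtnp, inner_tn, dt_neg_perp)

    return loss, {
        "ent_emb": g_ent,
        "ent_proj": g_entp,
        "rel_emb": g_rel,
        "rel_proj": g_relp,
    }
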