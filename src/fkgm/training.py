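"""Multi-task training: preference BPR + NDS-weighted health BPR.

Each epoch alternates two phases:

* **Phase A (knowledge-graph embedding)** — minibatch ranking loss over
  tail-corrupted triples updates the entity/relation embedding and
  projection tables (TransD translation consistency on the CRKG).
* **Phase B (recommendation)** — attention coefficients are recomputed from
  the current embeddings and frozen; user minibatches then minimise

      Loss = lambda_h * L_health + L_preference + lambda * ||Theta||^2

  where ``L_preference = -ln sigma(y+ - y-)`` over one interacted/
  non-interacted recipe pair per user, and ``L_health`` is the same ranking
  loss with the score margin scaled by the NDS gap
  ``NDS(u, rp_h-) - NDS(u, rp_h+)`` between a health-negative and a
  health-positive recipe (strictly positive by pool construction).

Gradients flow through the full L-layer propagation back to the layer-0
entity table and the aggregator weights; everything is optimised with a
hand-written mini-batch Adam.  All randomness fans out from one seed into
independent per-purpose streams so that ablations (e.g. disabling the
health task) leave the remaining streams untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import evaluation, nutrition, propagation
from .embedding import ModelParams, init_params, kg_loss_and_grad, sample_corrupted
from .graph import CRKG
from .nutrition import HealthPools

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "PreferencePools",
    "Adam",
    "sample_preference_pair",
    "preference_loss",
    "health_loss",
    "total_loss",
    "train",
]


@dataclass
class TrainingConfig:
    """Hyper-parameters of the optimisation (defaults follow the published run)."""

    embedding_dim: int = 64
    n_layers: int = 3
    batch_size: int = 2048
    epochs: int = 300
    learning_rate: float = 1e-4
    message_dropout: float = 0.1
    health_weight: float = 0.1  # lambda_h
    l2_weight: float = 1e-5  # lambda
    nds_cutoff: float = nutrition.NDS_CUTOFF
    leaky_slope: float = propagation.LEAKY_SLOPE
    kg_phase: bool = True
    rec_phase: bool = True  # False = KG pretraining only
    kg_batch_size: int = 2048
    health_task: bool = True
    eval_k: int = 20
    patience: int = 10  # early stopping on validation recall; 0 disables
    seed: int | None = None

    def __post_init__(self):
        if self.health_weight < 0 or self.l2_weight < 0:
            raise ValueError("loss weights must be nonnegative")
        for name in ("embedding_dim", "n_layers", "batch_size", "epochs", "kg_batch_size", "eval_k"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not 0.0 <= self.message_dropout < 1.0:
            raise ValueError("message_dropout must be in [0, 1)")


@dataclass
class PreferencePools:
    """Interacted (P+) recipes per user; P- is the complement of P+ in the universe."""

    positive: dict[int, np.ndarray]
    universe: np.ndarray  # all candidate recipe ids

    def __post_init__(self):
        self.universe = np.asarray(self.universe, dtype=np.int64)
        self._pos_sets = {u: set(map(int, v)) for u, v in self.positive.items()}

    def negatives_of(self, user: int) -> np.ndarray:
        pos = self._pos_sets.get(user, set())
        return np.array([r for r in self.universe if int(r) not in pos], dtype=np.int64)


def sample_preference_pair(
    user: int, pools: PreferencePools, rng: np.random.Generator, max_retries: int = 1000
) -> tuple[int, int]:
    """One (interacted, non-interacted) recipe pair, each uniform over its pool."""
    pos = pools.positive.get(user)
    if pos is None or len(pos) == 0:
        raise ValueError(f"user {user} has an empty positive pool")
    rp_pos = int(pos[rng.integers(len(pos))])
    pos_set = pools._pos_sets[user]
    for _ in range(max_retries):
        rp_neg = int(pools.universe[rng.integers(len(pools.universe))])
        if rp_neg not in pos_set:
            return rp_pos, rp_neg
    raise RuntimeError(f"could not sample a non-interacted recipe for user {user}")


def _softplus(x):
    return np.logaddexp(0.0, x)


def preference_loss(y_pos, y_neg) -> float:
    """BPR ranking loss ``-ln sigma(y+ - y-)``, overflow-safe; sums over batches."""
    return float(np.sum(_softplus(-(np.asarray(y_pos, dtype=float) - y_neg))))


def health_loss(y_pos, y_neg, nds_pos, nds_neg) -> float:
    """NDS-weighted ranking loss ``-ln sigma((NDS- - NDS+) (y+ - y-))``.

    The NDS gap must be strictly positive (guaranteed when the pools were
    split by the cutoff); a nonpositive gap signals corrupted pools.
    """
    w = np.asarray(nds_neg, dtype=float) - np.asarray(nds_pos, dtype=float)
    if np.any(w <= 0):
        raise ValueError("health pair with nonpositive NDS gap: pools are inconsistent")
    return float(np.sum(_softplus(-w * (np.asarray(y_pos, dtype=float) - y_neg))))


def total_loss(l_health: float, l_preference: float, health_weight: float,
               l2_weight: float, params_sq_norm: float = 0.0) -> float:
    """Weighted multi-task objective ``lambda_h L_h + L_p + lambda ||Theta||^2``."""
    return health_weight * l_health + l_preference + l2_weight * params_sq_norm


class Adam(object):
    """Mini-batch Adam with per-tensor first/second moment state."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._state: dict[str, tuple[np.ndarray, np.ndarray, int]] = {}

    def step(self, name: str, param: np.ndarray, grad: np.ndarray) -> None:
        m, v, t = self._state.get(name, (np.zeros_like(param), np.zeros_like(param), 0))
        t += 1
        m = self.beta1 * m + (1 - self.beta1) * grad
        v = self.beta2 * v + (1 - self.beta2) * grad * grad
        m_hat = m / (1 - self.beta1**t)
        v_hat = v / (1 - self.beta2**t)
        param -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
        self._state[name] = (m, v, t)


# ---------------------------------------------------------------------------
# Recommendation-phase loss with analytic gradients (attention frozen)
# ---------------------------------------------------------------------------

def recommendation_loss_and_grad(
    params: ModelParams,
    cache: propagation.PropagationCache,
    pref_pairs: np.ndarray,  # (B, 3): user, rp+, rp-  (CRKG entity ids)
    health_pairs: np.ndarray,  # (Bh, 3): user, rp_h+, rp_h-
    health_weights: np.ndarray,  # (Bh,): NDS gaps, strictly positive
    config: TrainingConfig,
) -> tuple[dict[str, float], np.ndarray, list[np.ndarray], list[np.ndarray]]:
    """Mean multi-task loss over a user minibatch and its gradients.

    Both BPR terms are averaged over their own pair counts (batch-size
    independent); the L2 term covers the tensors this phase trains (entity
    table + aggregator weights).  Returns the loss components and gradients
    ``(d ent_emb, [dW1], [dW2])`` obtained by backpropagating through the
    cached forward sweep.
    """
    F = propagation.final_representation(cache.states)
    L = len(cache.messages)
    d = params.d
    n_pref = len(pref_pairs)
    dF = np.zeros_like(F)

    def pair_scores(pairs):
        u, p, n = pairs.T
        return np.sum(F[u] * F[p], axis=1), np.sum(F[u] * F[n], axis=1)

    y_pos, y_neg = pair_scores(pref_pairs)
    l_pref = preference_loss(y_pos, y_neg) / n_pref
    # dL/d(y+ - y-) = -sigma(-(y+ - y-)), overflow-safe via logaddexp
    ds = -np.exp(-np.logaddexp(0.0, y_pos - y_neg)) / n_pref
    u, p, n = pref_pairs.T
    np.add.at(dF, u, ds[:, None] * (F[p] - F[n]))
    np.add.at(dF, p, ds[:, None] * F[u])
    np.add.at(dF, n, -ds[:, None] * F[u])

    l_health = 0.0
    if len(health_pairs) and config.health_task:
        yh_pos, yh_neg = pair_scores(health_pairs)
        w = np.asarray(health_weights, dtype=float)
        l_health = health_loss(yh_pos, yh_neg, 0.0, w) / len(health_pairs)
        margin = w * (yh_pos - yh_neg)
        dsh = -w * np.exp(-np.logaddexp(0.0, margin)) / len(health_pairs) * config.health_weight
        uh, ph, nh = health_pairs.T
        np.add.at(dF, uh, dsh[:, None] * (F[ph] - F[nh]))
        np.add.at(dF, ph, dsh[:, None] * F[uh])
        np.add.at(dF, nh, -dsh[:, None] * F[uh])

    grads_per_layer = [dF[:, l * d : (l + 1) * d] for l in range(L + 1)]
    d_ent, dW1, dW2 = propagation.propagate_backward(params, cache, grads_per_layer)

    sq_norm = float(np.sum(params.ent_emb**2)) + float(
        sum(np.sum(w**2) for w in params.W1) + sum(np.sum(w**2) for w in params.W2)
    )
    lam = config.l2_weight
    if lam:
        d_ent += 2.0 * lam * params.ent_emb
        for l in range(L):
            dW1[l] += 2.0 * lam * params.W1[l]
            dW2[l] += 2.0 * lam * params.W2[l]

    loss = total_loss(l_health, l_pref, config.health_weight, lam, sq_norm)
    components = {
        "loss": loss,
        "loss_pref": l_pref,
        "loss_health": l_health,
        "l2": lam * sq_norm,
    }
    return components, d_ent, dW1, dW2


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def _spawn_rngs(seed: int | None, names: Sequence[str]) -> dict[str, np.random.Generator]:
    """Derive one independent Generator per named purpose from the master seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def train(
    crkg: CRKG,
    nutrients: pd.DataFrame,
    train_interactions: Mapping[int, Sequence[int]],
    config: TrainingConfig,
    val_interactions: Mapping[int, Sequence[int]] | None = None,
) -> tuple[ModelParams, list[dict]]:
    """Fit the recommender on a fused graph plus nutrient table.

    ``train_interactions``/``val_interactions`` map original user ids to
    original recipe ids (the same id space as ``nutrients.index`` and the
    graph input files).  Returns the best parameters (by validation recall
    when a validation split is given, else the final epoch) and the
    per-epoch history log.
    """
    rngs = _spawn_rngs(config.seed, ["init", "kg", "pref", "health", "dropout", "shuffle"])

    # --- nutrition artifacts (original id space) ----------------------
    ncs_t = nutrition.ncs_table(nutrients)
    nis_t = nutrition.nis_table(dict(train_interactions), ncs_t, fill_empty="population_mean")
    health_pools = nutrition.build_health_pools(nis_t, ncs_t, cutoff=config.nds_cutoff)
    nds_mat = nutrition.nds_matrix(nis_t, ncs_t)

    universe = nutrients.index.to_numpy(dtype=np.int64)
    pref_pools = PreferencePools(
        positive={int(u): np.asarray(sorted(v), dtype=np.int64) for u, v in train_interactions.items()},
        universe=universe,
    )

    params = init_params(
        crkg, d=config.embedding_dim, seed=int(rngs["init"].integers(2**31)),
        n_layers=config.n_layers,
    )
    opt_kg = Adam(config.learning_rate)
    opt_rec = Adam(config.learning_rate)

    kg_triples = crkg.forward_edges
    users = np.array(sorted(u for u in pref_pools.positive if len(pref_pools.positive[u])))
    skipped = sorted(set(train_interactions) - set(users.tolist()))
    if skipped:
        logger.info("skipping %d users with empty positive pools", len(skipped))

    history: list[dict] = []
    best = (None, -np.inf)
    stale = 0

    for epoch in range(config.epochs):
        # ---- phase A: knowledge-graph embedding ----------------------
        loss_kg = float("nan")
        if config.kg_phase and len(kg_triples):
            order = rngs["shuffle"].permutation(len(kg_triples))
            losses = []
            for start in range(0, len(order), config.kg_batch_size):
                idx = order[start : start + config.kg_batch_size]
                batch = sample_corrupted(crkg, kg_triples[idx], rngs["kg"])
                l, grads = kg_loss_and_grad(params, batch)
                scale = 1.0 / len(idx)
                losses.append(l * scale)
                opt_kg.step("ent_emb", params.ent_emb, grads["ent_emb"] * scale)
                opt_kg.step("ent_proj", params.ent_proj, grads["ent_proj"] * scale)
                opt_kg.step("rel_emb", params.rel_emb, grads["rel_emb"] * scale)
                opt_kg.step("rel_proj", params.rel_proj, grads["rel_proj"] * scale)
            loss_kg = float(np.mean(losses))

        # ---- phase B: recommendation ---------------------------------
        if not config.rec_phase:
            history.append({"epoch": epoch, "loss_kg": loss_kg})
            continue
        A = propagation.attention_matrix(crkg, params)
        order = rngs["shuffle"].permutation(len(users))
        comp_sums: dict[str, float] = {}
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            batch_users = users[order[start : start + config.batch_size]]
            pref_pairs, health_pairs, health_w = _sample_batch(
                batch_users, crkg, pref_pools, health_pools, nds_mat, config, rngs
            )
            cache = propagation.propagate(
                params, A, config.n_layers, config.message_dropout,
                training=True, rng=rngs["dropout"], slope=config.leaky_slope,
            )
            comps, d_ent, dW1, dW2 = recommendation_loss_and_grad(
                params, cache, pref_pairs, health_pairs, health_w, config
            )
            if not np.isfinite(comps["loss"]):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {comps} "
                    f"(|ent_emb| max {np.abs(params.ent_emb).max():.3g})"
                )
            opt_rec.step("ent_emb", params.ent_emb, d_ent)
            for l in range(config.n_layers):
                opt_rec.step(f"W1_{l}", params.W1[l], dW1[l])
                opt_rec.step(f"W2_{l}", params.W2[l], dW2[l])
            for key, val in comps.items():
                comp_sums[key] = comp_sums.get(key, 0.0) + val
            n_batches += 1

        record = {"epoch": epoch, "loss_kg": loss_kg}
        record.update({k: v / max(n_batches, 1) for k, v in comp_sums.items()})

        if val_interactions:
            recall = _validation_recall(params, crkg, pref_pools, val_interactions, config)
            record["recall"] = recall
            if recall > best[1]:
                best = (params.copy(), recall)
                stale = 0
            else:
                stale += 1
            if config.patience and stale >= config.patience:
                history.append(record)
                logger.info("early stop at epoch %d (best recall %.4f)", epoch, best[1])
                break
        history.append(record)
        logger.info("epoch %d: %s", epoch, {k: round(v, 4) for k, v in record.items() if k != "epoch"})

    final = best[0] if best[0] is not None else params
    return final, history


def _sample_batch(batch_users, crkg, pref_pools, health_pools, nds_mat, config, rngs):
    """Draw one preference pair and (when possible) one health pair per user.

    Returned triples are in CRKG entity-id space; health weights are the NDS
    gaps of the sampled pairs.
    """
    pref_rows, health_rows, weights = [], [], []
    emap, umap = crkg.entity_map, crkg.user_map
    for user in batch_users:
        user = int(user)
        rp_pos, rp_neg = sample_preference_pair(user, pref_pools, rngs["pref"])
        pref_rows.append((umap[user], emap[rp_pos], emap[rp_neg]))
        if config.health_task:
            h_pos = health_pools.positive.get(user, ())
            h_neg = health_pools.negative.get(user, ())
            if len(h_pos) and len(h_neg):
                hp = int(h_pos[rngs["health"].integers(len(h_pos))])
                hn = int(h_neg[rngs["health"].integers(len(h_neg))])
                health_rows.append((umap[user], emap[hp], emap[hn]))
                weights.append(nds_mat.at[user, hn] - nds_mat.at[user, hp])
    pref_pairs = np.asarray(pref_rows, dtype=np.int64).reshape(-1, 3)
    health_pairs = np.asarray(health_rows, dtype=np.int64).reshape(-1, 3)
    return pref_pairs, health_pairs, np.asarray(weights, dtype=float)


def _validation_recall(params, crkg, pref_pools, val_interactions, config):
    """Recall@K on the held-out split using an inference (dropout-free) sweep."""
    A = propagation.attention_matrix(crkg, params)
    cache = propagation.propagate(params, A, config.n_layers, slope=config.leaky_slope)
    F = propagation.final_representation(cache.states)
    emap, umap = crkg.entity_map, crkg.user_map
    recipe_ids = pref_pools.universe
    recipe_rows = np.array([emap[int(r)] for r in recipe_ids])
    val_users = [u for u, items in val_interactions.items() if len(items) and u in umap]
    if not val_users:
        return float("nan")
    user_rows = np.array([umap[int(u)] for u in val_users])
    recs = evaluation.recommend_users(
        F[user_rows], F[recipe_rows], val_users, recipe_ids, config.eval_k,
        exclude={u: pref_pools.positive.get(u, ()) for u in val_users},
    )
    return evaluation.recall_at_k(recs, {u: val_interactions[u] for u in val_users}, config.eval_k)["micro"]
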