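"""Scikit-learn-style estimator facade over the full recommender.

:class:`FKGMRecommender` bundles graph fusion, nutrient scoring, TransD
embedding, attentive propagation and the multi-task ranking objective into
one ``fit``/``predict`` object with sklearn conventions (constructor-only
hyper-parameters, ``get_params``/``set_params``, fitted attributes with a
trailing underscore).  The lower-level modules remain usable on their own.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import evaluation, graph, nutrition, propagation, training
from .synthetic import SyntheticBundle

__all__ = ["FKGMRecommender"]


class FKGMRecommender(BaseEstimator):
    """Health-aware food recommender on a collaborative recipe knowledge graph.

    Parameters mirror :class:`~fkgm.training.TrainingConfig`; the published
    defaults (embedding 64, 3 layers, batch 2048, 300 epochs, lr 1e-4,
    dropout 0.1, health weight 0.1) are kept.  ``random_state`` seeds every
    stochastic component.

    Attributes (after ``fit``)
    --------------------------
    crkg_ : the fused graph
    params_ : trained :class:`~fkgm.embedding.ModelParams`
    history_ : per-epoch loss/metric log (list of dicts)
    user_repr_, recipe_repr_ : final (concatenated-layer) representations
    user_ids_, recipe_ids_ : original ids aligned with the representation rows
    nis_ : per-user nutrient intake scores (DataFrame)
    ncs_ : per-recipe nutrient content scores (DataFrame)
    """

    def __init__(
        self,
        embedding_dim: int = 64,
        n_layers: int = 3,
        batch_size: int = 2048,
        epochs: int = 300,
        learning_rate: float = 1e-4,
        message_dropout: float = 0.1,
        health_weight: float = 0.1,
        l2_weight: float = 1e-5,
        nds_cutoff: float = nutrition.NDS_CUTOFF,
        kg_phase: bool = True,
        health_task: bool = True,
        eval_k: int = 20,
        patience: int = 10,
        random_state: int | None = None,
    ):
        self.embedding_dim = embedding_dim
        self.n_layers = n_layers
        self.batch_size = batch_size
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.message_dropout = message_dropout
        self.health_weight = health_weight
        self.l2_weight = l2_weight
        self.nds_cutoff = nds_cutoff
        self.kg_phase = kg_phase
        self.health_task = health_task
        self.eval_k = eval_k
        self.patience = patience
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _config(self) -> training.TrainingConfig:
        return training.TrainingConfig(
            embedding_dim=self.embedding_dim,
            n_layers=self.n_layers,
            batch_size=self.batch_size,
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            message_dropout=self.message_dropout,
            health_weight=self.health_weight,
            l2_weight=self.l2_weight,
            nds_cutoff=self.nds_cutoff,
            kg_phase=self.kg_phase,
            health_task=self.health_task,
            eval_k=self.eval_k,
            patience=self.patience,
            seed=self.random_state,
        )

    def fit(self, X, y=None, validation: Mapping[int, Sequence[int]] | None = None):
        """Fit on a data bundle.

        ``X`` is either a :class:`~fkgm.synthetic.SyntheticBundle` or a
        mapping with keys ``triples`` (list of :class:`~fkgm.graph.Triple`),
        ``train`` (user id -> recipe ids), ``nutrients`` (DataFrame indexed
        by recipe id) and optional ``roles``.  ``validation`` enables
        per-epoch Recall@K tracking and early stopping.
        """
        if isinstance(X, SyntheticBundle):
            triples, train_map, nutrients, roles = X.triples, X.train, X.nutrients, X.roles
        else:
            triples = X["triples"]
            train_map = X["train"]
            nutrients = X["nutrients"]
            roles = X.get("roles")
        interactions = graph.InteractionSet(
            pairs=[(int(u), int(r)) for u, items in train_map.items() for r in items]
        )
        self.crkg_ = graph.build_crkg(triples, interactions, roles=roles)
        self.nutrients_ = nutrients
        self.train_interactions_ = {int(u): sorted(map(int, v)) for u, v in train_map.items()}
        self.params_, self.history_ = training.train(
            self.crkg_, nutrients, self.train_interactions_, self._config(),
            val_interactions=validation,
        )
        self.ncs_ = nutrition.ncs_table(nutrients)
        self.nis_ = nutrition.nis_table(
            self.train_interactions_, self.ncs_, fill_empty="population_mean"
        )
        self._refresh_representations()
        return self

    def _refresh_representations(self) -> None:
        A = propagation.attention_matrix(self.crkg_, self.params_)
        cache = propagation.propagate(self.params_, A, self.n_layers)
        F = propagation.final_representation(cache.states)
        self.user_ids_ = np.array(sorted(self.crkg_.user_map), dtype=np.int64)
        self.recipe_ids_ = self.nutrients_.index.to_numpy(dtype=np.int64)
        user_rows = np.array([self.crkg_.user_map[int(u)] for u in self.user_ids_])
        recipe_rows = np.array([self.crkg_.entity_map[int(r)] for r in self.recipe_ids_])
        self.user_repr_ = F[user_rows]
        self.recipe_repr_ = F[recipe_rows]

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("this FKGMRecommender instance is not fitted yet")

    # ------------------------------------------------------------------
    def predict(self, X) -> np.ndarray:
        """Matching scores for an (n, 2) array of (user id, recipe id) pairs."""
        self._check_fitted()
        pairs = np.asarray(X, dtype=np.int64).reshape(-1, 2)
        urow = {int(u): i for i, u in enumerate(self.user_ids_)}
        rrow = {int(r): i for i, r in enumerate(self.recipe_ids_)}
        try:
            ui = np.array([urow[int(u)] for u in pairs[:, 0]])
            ri = np.array([rrow[int(r)] for r in pairs[:, 1]])
        except KeyError as exc:
            raise KeyError(f"unknown user or recipe id {exc}") from None
        return np.sum(self.user_repr_[ui] * self.recipe_repr_[ri], axis=1)

    def recommend(
        self, users: Sequence[int] | None = None, k: int = 20, exclude_train: bool = True
    ) -> dict[int, tuple[np.ndarray, np.ndarray]]:
        """Top-K recipe ids (and scores) per user, training items excluded."""
        self._check_fitted()
        users = self.user_ids_ if users is None else np.asarray(users, dtype=np.int64)
        urow = {int(u): i for i, u in enumerate(self.user_ids_)}
        rows = np.array([urow[int(u)] for u in users])
        exclude = (
            {int(u): self.train_interactions_.get(int(u), []) for u in users}
            if exclude_train
            else None
        )
        return evaluation.recommend_users(
            self.user_repr_[rows], self.recipe_repr_, users, self.recipe_ids_, k, exclude
        )

    def score(self, X, y=None, k: int | None = None) -> float:
        """Micro Recall@K against held-out interactions (mapping user -> recipes)."""
        self._check_fitted()
        k = self.eval_k if k is None else k
        test_sets = X.test if isinstance(X, SyntheticBundle) else dict(X)
        recs = self.recommend([u for u in test_sets if int(u) in set(map(int, self.user_ids_))], k=k)
        return evaluation.recall_at_k(recs, test_sets, k)["micro"]
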