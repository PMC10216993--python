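"""Top-K recommendation generation and evaluation.

Two metric families mirror the two training tasks:

* **Recall@K** — micro-averaged over users exactly as the headline metric
  (``sum_u |R_u ∩ T_u| / sum_u |T_u|``), with the per-user macro mean
  reported alongside;
* **Nutrient@K** — for a high-intake user group on nutrient k, the mean
  grams of k among each member's top-K recommended recipes, averaged over
  the group (lower is a healthier recommendation list).

Rankings are deterministic: strictly descending scores with ascending
recipe-id tie-breaks, and training-set items are excluded from the
candidate pool.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .nutrition import NUTRIENTS

logger = logging.getLogger(__name__)

__all__ = [
    "top_k",
    "recommend_users",
    "recall_at_k",
    "select_intake_groups",
    "nutrient_at_k",
]


def top_k(
    scores: np.ndarray,
    candidate_ids: np.ndarray | Sequence[int],
    k: int,
    exclude: set[int] | Sequence[int] = (),
) -> tuple[np.ndarray, np.ndarray]:
    """Rank candidates by score (ties broken by ascending id), drop excluded.

    Returns ``(ids, scores)`` of the top ``k`` remaining candidates; if fewer
    than ``k`` remain, returns all with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    candidate_ids = np.asarray(candidate_ids)
    exclude = set(map(int, exclude))
    if exclude:
        mask = np.array([int(c) not in exclude for c in candidate_ids])
        scores, candidate_ids = scores[mask], candidate_ids[mask]
    if k > len(candidate_ids):
        warnings.warn(
            f"requested top-{k} but only {len(candidate_ids)} candidates remain",
            stacklevel=2,
        )
        k = len(candidate_ids)
    order = np.lexsort((candidate_ids, -scores))[:k]
    return candidate_ids[order], scores[order]


def recommend_users(
    user_reprs: np.ndarray,
    recipe_reprs: np.ndarray,
    user_ids: Sequence[int],
    recipe_ids: Sequence[int],
    k: int,
    exclude: Mapping[int, Sequence[int]] | None = None,
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Top-K lists for many users from final-representation matrices.

    Rows of ``user_reprs``/``recipe_reprs`` align with ``user_ids`` /
    ``recipe_ids``; affinity is the inner product.  ``exclude`` maps a user
    to recipe ids removed from their candidates (typically training items).
    """
    recipe_ids = np.asarray(recipe_ids)
    all_scores = user_reprs @ recipe_reprs.T
    out: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for i, user in enumerate(user_ids):
        banned = exclude.get(user, ()) if exclude else ()
        out[int(user)] = top_k(all_scores[i], recipe_ids, k, banned)
    return out


def recall_at_k(
    recommendations: Mapping[int, Sequence[int]],
    test_sets: Mapping[int, Sequence[int]],
    k: int,
) -> dict[str, float]:
    """Recall of held-out items within the top-K lists.

    ``micro`` is the pooled ratio ``sum_u hits_u / sum_u |T_u|``; ``macro``
    is the unweighted mean of per-user recalls.  Users with empty test sets
    are skipped; if every test set is empty the metric is undefined.
    """
    hits_total = 0
    test_total = 0
    per_user = []
    for user, tset in test_sets.items():
        tset = set(map(int, tset))
        if not tset:
            continue
        recs = recommendations.get(user, ())
        if isinstance(recs, tuple):  # (ids, scores) pairs from recommend_users
            recs = recs[0]
        top = [int(r) for r in list(recs)[:k]]
        hits = len(tset.intersection(top))
        hits_total += hits
        test_total += len(tset)
        per_user.append(hits / len(tset))
    if test_total == 0:
        raise ValueError("recall undefined: every test set is empty")
    return {"micro": hits_total / test_total, "macro": float(np.mean(per_user))}


def select_intake_groups(nis: pd.DataFrame, group_size: int) -> dict[str, list[int]]:
    """Per nutrient, the ``group_size`` users with the highest intake score.

    Ties are broken by ascending user id; groups may overlap across
    nutrients.  Asking for more users than exist returns everyone (with a
    warning).
    """
    g = group_size
    if g > len(nis):
        warnings.warn(f"group size {g} exceeds user count {len(nis)}", stacklevel=2)
        g = len(nis)
    groups: dict[str, list[int]] = {}
    for nutrient in NUTRIENTS:
        scores = nis[nutrient].to_numpy(dtype=float)
        ids = nis.index.to_numpy()
        order = np.lexsort((ids, -scores))[:g]
        groups[nutrient] = [int(u) for u in ids[order]]
    return groups


def nutrient_at_k(
    recommendations: Mapping[int, Sequence[int]],
    nutrients: pd.DataFrame,
    group: Sequence[int],
    nutrient: str,
    k: int,
) -> float:
    """Mean grams of ``nutrient`` in group members' top-K recommendations.

    For each group user, the mean content among their top-K recipes; the
    metric is the unweighted mean of those per-user means.  Members without
    recommendations are excluded (warned).
    """
    if nutrient not in NUTRIENTS:
        raise KeyError(f"unknown nutrient {nutrient!r}")
    per_user = []
    missing = []
    for user in group:
        recs = recommendations.get(int(user))
        if recs is None or not len(recs):
            missing.append(user)
            continue
        if isinstance(recs, tuple):
            recs = recs[0]
        top = [int(r) for r in list(recs)[:k]]
        per_user.append(float(nutrients.loc[top, nutrient].mean()))
    if missing:
        warnings.warn(f"{len(missing)} group members have no recommendations", stacklevel=2)
    if not per_user:
        raise ValueError("no group member has recommendations")
    return float(np.mean(per_user))
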