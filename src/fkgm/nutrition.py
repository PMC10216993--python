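"""FSA-anchored nutrient scoring for recipes and users.

Three scores drive the health side of the recommender:

* **NCS** (Nutrient Content Score) — per-nutrient recipe score,
  ``content * 10 / threshold`` with the UK Food Standards Agency per-portion
  thresholds (sodium 0.7 g, fat 21 g, sugar 27 g, saturated fat 6 g).
  Scores fall into three bands: healthy ``[0, 4)``, moderate ``[4, 10)``,
  unhealthy ``[10, inf)``.
* **NIS** (Nutrient Intake Score) — per-nutrient user score summarising the
  NCS of the recipes a user interacted with: scores are grouped into the
  three bands and NIS is the count-weighted average of the within-band
  medians (robust to extreme portions).
* **NDS** (Nutrient Discrepancy Score) — health mismatch between a user and
  a recipe: ``sum_k softplus_mod(NIS_k) * softplus_mod(NCS_k)`` where
  ``softplus_mod(x) = ln(1 + exp(x - 4))`` suppresses scores in the healthy
  band.  A pair with NIS = NCS = 10 on a single nutrient lands at ~36, the
  cutoff used to call a recipe unhealthy *for that user*.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NUTRIENTS",
    "DEFAULT_THRESHOLDS",
    "SALT_TO_SODIUM",
    "NDS_CUTOFF",
    "HealthPools",
    "ncs",
    "ncs_vector",
    "ncs_table",
    "band",
    "nis",
    "nis_table",
    "softplus_mod",
    "nds",
    "nds_matrix",
    "build_health_pools",
    "read_nutrients",
    "write_nutrients",
]

#: Canonical nutrient order used by every array-valued function.
NUTRIENTS: tuple[str, ...] = ("sodium", "fat", "sugar", "saturated_fat")

#: FSA per-portion limits in grams; content above the limit marks a recipe
#: unhealthy on that nutrient (NCS >= 10).
DEFAULT_THRESHOLDS: dict[str, float] = {
    "sodium": 0.7,
    "fat": 21.0,
    "sugar": 27.0,
    "saturated_fat": 6.0,
}

#: Grams of sodium per gram of salt, applied at table ingest when a ``salt``
#: column is present.
SALT_TO_SODIUM: float = 0.388

#: Default user-recipe discrepancy cutoff separating the health-positive and
#: health-negative sample pools (>= cutoff is unhealthy for the user).
NDS_CUTOFF: float = 36.0

_BAND_EDGES = (4.0, 10.0)


def _threshold(nutrient: str, thresholds: Mapping[str, float] | None) -> float:
    table = DEFAULT_THRESHOLDS if thresholds is None else thresholds
    if nutrient not in table:
        raise KeyError(f"unknown nutrient {nutrient!r}; expected one of {NUTRIENTS}")
    return float(table[nutrient])


def ncs(content: float, nutrient: str, thresholds: Mapping[str, float] | None = None) -> float:
    """Nutrient Content Score: ``content * 10 / threshold``.

    Parameters
    ----------
    content : grams of the nutrient per portion (must be >= 0).
    nutrient : one of :data:`NUTRIENTS`.
    thresholds : optional override of :data:`DEFAULT_THRESHOLDS`.
    """
    if content < 0 or not np.isfinite(content):
        raise ValueError(f"nutrient content must be finite and >= 0, got {content}")
    return float(content) * 10.0 / _threshold(nutrient, thresholds)


def ncs_vector(
    contents: Mapping[str, float] | Sequence[float],
    thresholds: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Apply :func:`ncs` to all four nutrients; returns scores in
    :data:`NUTRIENTS` order.

    ``contents`` is either a mapping keyed by nutrient name or a length-4
    sequence in canonical order.
    """
    if isinstance(contents, Mapping):
        values = [contents[k] for k in NUTRIENTS]
    else:
        values = list(contents)
        if len(values) != len(NUTRIENTS):
            raise ValueError(f"expected {len(NUTRIENTS)} values, got {len(values)}")
    return np.array([ncs(v, k, thresholds) for v, k in zip(values, NUTRIENTS)])


def ncs_table(
    nutrients: pd.DataFrame, thresholds: Mapping[str, float] | None = None
) -> pd.DataFrame:
    """Score a nutrient table (recipes x :data:`NUTRIENTS`, grams/portion)."""
    limits = np.array([_threshold(k, thresholds) for k in NUTRIENTS])
    contents = nutrients[list(NUTRIENTS)].to_numpy(dtype=float)
    if (contents < 0).any() or not np.isfinite(contents).all():
        raise ValueError("nutrient table contains negative or non-finite values")
    return pd.DataFrame(
        contents * 10.0 / limits, index=nutrients.index, columns=list(NUTRIENTS)
    )


def band(score: float) -> str:
    """Classify a score: healthy ``[0,4)``, moderate ``[4,10)``, unhealthy ``[10,inf)``."""
    if score < 0:
        raise ValueError(f"scores are nonnegative by construction, got {score}")
    if score < _BAND_EDGES[0]:
        return "healthy"
    if score < _BAND_EDGES[1]:
        return "moderate"
    return "unhealthy"


def nis(history_ncs: Sequence[float] | np.ndarray) -> float:
    """Nutrient Intake Score for one nutrient from a user's interaction history.

    The NCS of each interacted recipe is assigned to its band; NIS is
    ``sum_i c_i * median_i / Count`` over the three bands, where ``c_i`` is the
    band count and ``median_i`` the within-band median (mean of the two central
    values for even-sized groups).  Empty bands contribute nothing.
    """
    scores = np.asarray(history_ncs, dtype=float)
    if scores.size == 0:
        raise ValueError("cannot compute an intake score from an empty history")
    if (scores < 0).any():
        raise ValueError("NCS history contains negative values")
    total = 0.0
    lo = np.concatenate(([0.0], _BAND_EDGES))
    hi = np.concatenate((_BAND_EDGES, [np.inf]))
    for a, b in zip(lo, hi):
        group = scores[(scores >= a) & (scores < b)]
        if group.size:
            total += group.size * float(np.median(group))
    return total / scores.size


def nis_table(
    histories: Mapping[int, Sequence[int]],
    recipe_ncs: pd.DataFrame,
    fill_empty: str | None = None,
) -> pd.DataFrame:
    """Per-user NIS for all four nutrients.

    Parameters
    ----------
    histories : mapping of user id -> interacted recipe ids.
    recipe_ncs : NCS table indexed by recipe id (from :func:`ncs_table`).
    fill_empty : how to handle users with no history.  ``None`` (default)
        raises; ``"population_mean"`` assigns the mean NIS of users that do
        have history — used when pools are built for training so that
        cold users do not abort a run.
    """
    rows: dict[int, np.ndarray] = {}
    empty_users = []
    for user, recipes in histories.items():
        recipes = list(recipes)
        if not recipes:
            empty_users.append(user)
            continue
        scores = recipe_ncs.loc[recipes]
        rows[user] = np.array([nis(scores[k].to_numpy()) for k in NUTRIENTS])
    if empty_users:
        if fill_empty != "population_mean":
            raise ValueError(
                f"users {empty_users[:5]} have no interaction history; "
                "pass fill_empty='population_mean' to impute"
            )
        if not rows:
            raise ValueError("no user has any interaction history")
        mean = np.mean(np.stack(list(rows.values())), axis=0)
        for user in empty_users:
            rows[user] = mean
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(NUTRIENTS))
    return out.sort_index()


def softplus_mod(x):
    """Shifted soft-plus ``ln(1 + exp(x - 4))``.

    Maps scores in the healthy band to near zero while preserving large
    (unhealthy) scores; strictly positive and increasing.  Overflow-safe for
    arbitrarily large ``x``.
    """
    return np.logaddexp(0.0, np.asarray(x, dtype=float) - 4.0)


def nds(
    user_nis: Mapping[str, float] | Sequence[float],
    recipe_ncs: Mapping[str, float] | Sequence[float],
) -> float:
    """Nutrient Discrepancy Score between one user and one recipe.

    ``sum_k softplus_mod(NIS_k) * softplus_mod(NCS_k)`` over the four
    nutrients; strictly positive and monotone nondecreasing in every
    component.
    """
    u = _as_score_array(user_nis)
    r = _as_score_array(recipe_ncs)
    return float(np.sum(softplus_mod(u) * softplus_mod(r)))


def _as_score_array(vec) -> np.ndarray:
    if isinstance(vec, Mapping):
        try:
            return np.array([float(vec[k]) for k in NUTRIENTS])
        except KeyError as exc:
            raise KeyError(f"score vector missing nutrient {exc}") from None
    arr = np.asarray(vec, dtype=float)
    if arr.shape != (len(NUTRIENTS),):
        raise ValueError(f"expected a length-{len(NUTRIENTS)} score vector, got shape {arr.shape}")
    return arr


def nds_matrix(user_nis: pd.DataFrame, recipe_ncs: pd.DataFrame) -> pd.DataFrame:
    """All-pairs NDS: users (rows) x recipes (columns)."""
    u = softplus_mod(user_nis[list(NUTRIENTS)].to_numpy(dtype=float))
    r = softplus_mod(recipe_ncs[list(NUTRIENTS)].to_numpy(dtype=float))
    return pd.DataFrame(u @ r.T, index=user_nis.index, columns=recipe_ncs.index)


@dataclass
class HealthPools:
    """Per-user health-positive (H+) and health-negative (H-) recipe pools.

    H- holds recipes whose discrepancy with the user meets the cutoff
    (``NDS >= cutoff``); H+ is the complement within the recipe universe.
    The pools are disjoint by construction, which guarantees a strictly
    positive ``NDS(neg) - NDS(pos)`` weight in the health ranking loss.
    """

    positive: dict[int, np.ndarray]
    negative: dict[int, np.ndarray]
    cutoff: float = NDS_CUTOFF

    def to_json(self, path) -> None:
        payload = {
            "cutoff": self.cutoff,
            "positive": {str(u): v.tolist() for u, v in self.positive.items()},
            "negative": {str(u): v.tolist() for u, v in self.negative.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "HealthPools":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            positive={int(u): np.asarray(v, dtype=np.int64) for u, v in payload["positive"].items()},
            negative={int(u): np.asarray(v, dtype=np.int64) for u, v in payload["negative"].items()},
            cutoff=float(payload["cutoff"]),
        )


def build_health_pools(
    user_nis: pd.DataFrame,
    recipe_ncs: pd.DataFrame,
    cutoff: float = NDS_CUTOFF,
    max_pool: int | None = None,
    seed: int | None = None,
) -> HealthPools:
    """Split the recipe universe into H+ / H- per user by the NDS cutoff.

    ``max_pool`` optionally caps each pool by uniform seeded subsampling
    (large universes make exhaustive pools wasteful for pair sampling).
    """
    matrix = nds_matrix(user_nis, recipe_ncs).to_numpy()
    recipe_ids = recipe_ncs.index.to_numpy()
    rng = np.random.default_rng(seed)
    positive: dict[int, np.ndarray] = {}
    negative: dict[int, np.ndarray] = {}
    for i, user in enumerate(user_nis.index):
        mask = matrix[i] >= cutoff
        neg = recipe_ids[mask]
        pos = recipe_ids[~mask]
        if max_pool is not None:
            if pos.size > max_pool:
                pos = np.sort(rng.choice(pos, size=max_pool, replace=False))
            if neg.size > max_pool:
                neg = np.sort(rng.choice(neg, size=max_pool, replace=False))
        positive[int(user)] = pos.astype(np.int64)
        negative[int(user)] = neg.astype(np.int64)
    return HealthPools(positive=positive, negative=negative, cutoff=cutoff)


def read_nutrients(path) -> pd.DataFrame:
    """Read a per-recipe nutrient table (grams/portion).

    Expected header ``recipe_id,sodium,fat,sugar,saturated_fat[,salt]``.
    When a ``salt`` column is present its sodium equivalent
    (:data:`SALT_TO_SODIUM` g per g of salt) is added to the sodium column
    and the salt column dropped.
    """
    df = pd.read_csv(path)
    required = {"recipe_id", *NUTRIENTS} - set(df.columns)
    # salt may substitute for sodium entirely
    if "sodium" in required and "salt" in df.columns:
        required.discard("sodium")
        df["sodium"] = 0.0
    if required:
        raise ValueError(f"nutrient table {path} missing columns: {sorted(required)}")
    if "salt" in df.columns:
        df["sodium"] = df["sodium"] + SALT_TO_SODIUM * df["salt"]
        df = df.drop(columns=["salt"])
    df = df.set_index("recipe_id")[list(NUTRIENTS)].astype(float)
    if (df.to_numpy() < 0).any() or not np.isfinite(df.to_numpy()).all():
        raise ValueError(f"nutrient table {path} contains negative or non-finite values")
    return df


def write_nutrients(df: pd.DataFrame, path) -> None:
    df.reset_index(names="recipe_id").to_csv(path, index=False)
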