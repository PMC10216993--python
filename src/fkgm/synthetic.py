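"""Seed-reproducible synthetic study data.

Emulates the structures the recommender consumes, at desk scale:

* a recipe knowledge graph — recipe-ingredient edges with a heavy-tailed
  ingredient popularity, plus recipe-type and recipe-cuisine edges from
  small categorical vocabularies;
* a per-recipe nutrient table drawn from a two-component log-normal
  mixture, scaled so the "healthy" component keeps every score below the
  unhealthy band (NCS < 10) and the "unhealthy" component pushes at least
  one nutrient above it;
* user-recipe interactions from a latent-factor choice model in which a
  planted "unhealthy-leaning" user subgroup upweights unhealthy recipes by
  a controllable bias, then a per-user 9:1 train/test split.

The generator defines the study conditions for every stochastic test; its
defaults are fixed once and documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .graph import InteractionSet, Triple
from .nutrition import DEFAULT_THRESHOLDS, NUTRIENTS

__all__ = [
    "SynthConfig",
    "SyntheticBundle",
    "generate_nutrients",
    "generate_graph",
    "generate_interactions",
    "generate_bundle",
    "make_toy_fixture",
    "REL_INGREDIENT",
    "REL_TYPE",
    "REL_CUISINE",
]

REL_INGREDIENT, REL_TYPE, REL_CUISINE = 0, 1, 2


@dataclass
class SynthConfig:
    """Knobs of the synthetic world (counts, mixture fractions, choice model)."""

    n_users: int = 300
    n_recipes: int = 500
    n_ingredients: int = 80
    n_types: int = 6
    n_cuisines: int = 8
    mean_interactions: float = 20.0
    unhealthy_recipe_fraction: float = 0.3
    unhealthy_user_fraction: float = 0.3
    taste_dim: int = 8
    health_bias: float = 2.0
    seed: int | None = None

    def __post_init__(self):
        for name in ("n_users", "n_recipes", "n_ingredients", "n_types", "n_cuisines", "taste_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("unhealthy_recipe_fraction", "unhealthy_user_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SyntheticBundle:
    """Everything one run needs: graph, nutrients, interactions, plantings."""

    triples: list[Triple]
    roles: dict[int, str]
    nutrients: pd.DataFrame
    train: dict[int, list[int]]
    test: dict[int, list[int]]
    unhealthy_users: np.ndarray  # boolean per user id
    unhealthy_recipes: np.ndarray  # boolean per recipe id
    config: SynthConfig | None = None

    @property
    def interactions(self) -> InteractionSet:
        pairs = [(u, r) for u, items in self.train.items() for r in items]
        return InteractionSet(pairs=pairs)


def generate_nutrients(
    n: int, unhealthy_fraction: float, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray]:
    """Nutrient table (grams/portion) with a planted unhealthy mixture.

    Healthy recipes keep all four scores strictly inside [0, 10) (content
    below threshold); unhealthy recipes exceed the threshold (NCS >= 10) on
    at least one nutrient.  Scores are drawn log-normally (right-skewed,
    positive, like per-portion content) and rescaled by the FSA thresholds.
    Returns the table plus the per-recipe unhealthy flags.
    """
    if n < 1:
        raise ValueError("need at least one recipe")
    flags = rng.random(n) < unhealthy_fraction
    limits = np.array([DEFAULT_THRESHOLDS[k] for k in NUTRIENTS])
    # healthy component: NCS ~ lognormal centred near 3, clipped below 9.5
    scores = np.minimum(rng.lognormal(mean=np.log(3.0), sigma=0.5, size=(n, 4)), 9.5)
    # unhealthy component: pick >= 1 nutrient, push its NCS above 10
    for i in np.flatnonzero(flags):
        k = 1 + rng.binomial(3, 0.25)
        cols = rng.choice(4, size=k, replace=False)
        scores[i, cols] = 10.0 + rng.lognormal(mean=np.log(5.0), sigma=0.6, size=k)
    contents = scores * limits / 10.0
    table = pd.DataFrame(contents, columns=list(NUTRIENTS))
    table.index.name = "recipe_id"
    return table, flags


def generate_graph(config: SynthConfig, rng: np.random.Generator) -> tuple[list[Triple], dict[int, str]]:
    """Recipe KG triples plus entity role labels.

    Entity ids: recipes ``0..n_recipes-1``, ingredients next, then type and
    cuisine vocabulary entities.  Every recipe gets >= 3 ingredient edges
    (ingredient popularity is Zipf-like, giving a heavy-tailed ingredient
    degree), one type edge, and one cuisine edge — so no recipe is an
    orphan.
    """
    n_rp, n_ing = config.n_recipes, config.n_ingredients
    ing0 = n_rp
    type0 = ing0 + n_ing
    cui0 = type0 + config.n_types
    popularity = 1.0 / np.arange(1, n_ing + 1) ** 1.1
    popularity /= popularity.sum()
    triples: list[Triple] = []
    for rp in range(n_rp):
        k = min(n_ing, 3 + rng.poisson(2.0))
        ingredients = rng.choice(n_ing, size=k, replace=False, p=popularity)
        for ing in sorted(ingredients):
            triples.append(Triple(rp, REL_INGREDIENT, ing0 + int(ing)))
        triples.append(Triple(rp, REL_TYPE, type0 + int(rng.integers(config.n_types))))
        triples.append(Triple(rp, REL_CUISINE, cui0 + int(rng.integers(config.n_cuisines))))
    roles = {rp: "recipe" for rp in range(n_rp)}
    roles.update({ing0 + i: "other" for i in range(n_ing + config.n_types + config.n_cuisines)})
    return triples, roles


def generate_interactions(
    config: SynthConfig,
    unhealthy_recipes: np.ndarray,
    rng: np.random.Generator,
) -> tuple[dict[int, list[int]], dict[int, list[int]], np.ndarray]:
    """Latent-factor choice model with a planted unhealthy-leaning subgroup.

    Each user draws a taste vector; recipe choice probabilities are
    ``softmax(taste_affinity + b * unhealthy_indicator)`` where ``b`` is the
    health-bias strength for the planted subgroup and 0 for everyone else.
    Every user gets >= 2 interactions; the per-user 9:1 split puts
    ``ceil(0.1 * history)`` items in the test set (random within user; the
    synthetic world has no timestamps).
    """
    n_u, n_rp = config.n_users, config.n_recipes
    unhealthy_users = rng.random(n_u) < config.unhealthy_user_fraction
    taste_u = rng.normal(size=(n_u, config.taste_dim))
    taste_rp = rng.normal(size=(n_rp, config.taste_dim)) / np.sqrt(config.taste_dim)
    train: dict[int, list[int]] = {}
    test: dict[int, list[int]] = {}
    flags = unhealthy_recipes.astype(float)
    for u in range(n_u):
        utility = taste_u[u] @ taste_rp.T
        if unhealthy_users[u]:
            utility = utility + config.health_bias * flags
        probs = np.exp(utility - utility.max())
        probs /= probs.sum()
        size = min(n_rp, max(2, rng.poisson(config.mean_interactions)))
        chosen = rng.choice(n_rp, size=size, replace=False, p=probs)
        chosen = rng.permutation(chosen)
        n_test = int(np.ceil(0.1 * size))
        test[u] = sorted(int(r) for r in chosen[:n_test])
        train[u] = sorted(int(r) for r in chosen[n_test:])
    return train, test, unhealthy_users


def generate_bundle(config: SynthConfig) -> SyntheticBundle:
    """Generate graph + nutrients + interactions from one master seed."""
    ss = np.random.SeedSequence(config.seed)
    rng_nut, rng_graph, rng_inter = (np.random.default_rng(c) for c in ss.spawn(3))
    nutrients, unhealthy_recipes = generate_nutrients(
        config.n_recipes, config.unhealthy_recipe_fraction, rng_nut
    )
    triples, roles = generate_graph(config, rng_graph)
    train, test, unhealthy_users = generate_interactions(config, unhealthy_recipes, rng_inter)
    return SyntheticBundle(
        triples=triples,
        roles=roles,
        nutrients=nutrients,
        train=train,
        test=test,
        unhealthy_users=unhealthy_users,
        unhealthy_recipes=unhealthy_recipes,
        config=config,
    )


def make_toy_fixture() -> SyntheticBundle:
    """Hand-written tiny bundle: 6 users, 10 recipes, 8 ingredients.

    Recipes 0-3 carry the per-portion nutrient rows of four real Allrecipes
    dishes (Homemade Bacon, Foolproof Rosemary Chicken Wings, Cranberry Pork
    Chops II, Chinese Pot Roast); the rest are hand-written, spanning the
    healthy/moderate/unhealthy bands.  Oracle tests run against this bundle.
    """
    nutrients = pd.DataFrame(
        [
            # sodium, fat, sugar, saturated_fat (g/portion)
            [2.01, 23.58, 0.09, 7.73],  # Homemade Bacon
            [0.76, 23.62, 0.23, 5.68],  # Foolproof Rosemary Chicken Wings
            [0.40, 6.31, 26.46, 2.73],  # Cranberry Pork Chops II
            [2.81, 19.97, 12.16, 7.11],  # Chinese Pot Roast
            [0.10, 4.00, 5.00, 1.00],  # all-healthy
            [0.20, 8.00, 10.00, 2.00],  # all-healthy
            [0.35, 10.00, 15.00, 3.10],  # moderate
            [0.50, 15.00, 20.00, 4.00],  # moderate
            [1.40, 30.00, 40.00, 9.00],  # unhealthy everywhere
            [0.05, 2.00, 2.50, 0.50],  # very healthy
        ],
        columns=list(NUTRIENTS),
    )
    nutrients.index.name = "recipe_id"
    n_rp, n_ing = 10, 8
    ing0 = n_rp
    triples = []
    for rp in range(n_rp):
        for ing in {rp % n_ing, (rp * 3 + 1) % n_ing, (rp * 5 + 2) % n_ing}:
            triples.append(Triple(rp, REL_INGREDIENT, ing0 + ing))
    type0 = ing0 + n_ing
    for rp in range(n_rp):
        triples.append(Triple(rp, REL_TYPE, type0 + rp % 2))
    train = {
        0: [0, 1, 3, 8],  # unhealthy-leaning history
        1: [4, 5, 9],
        2: [2, 6, 7],
        3: [0, 4, 8],
        4: [1, 2, 5, 9],
        5: [3, 6],
    }
    test = {0: [4], 1: [6], 2: [9], 3: [5], 4: [7], 5: [8]}
    roles = {rp: "recipe" for rp in range(n_rp)}
    roles.update({ing0 + i: "other" for i in range(n_ing + 2)})
    unhealthy = (nutrients.to_numpy() > np.array([DEFAULT_THRESHOLDS[k] for k in NUTRIENTS])).any(axis=1)
    return SyntheticBundle(
        triples=sorted(triples, key=lambda t: (t.head, t.relation, t.tail)),
        roles=roles,
        nutrients=nutrients,
        train=train,
        test=test,
        unhealthy_users=np.array([True, False, False, False, False, False]),
        unhealthy_recipes=unhealthy,
        config=None,
    )
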