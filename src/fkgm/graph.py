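"""Collaborative recipe knowledge graph (CRKG) construction and queries.

The CRKG fuses two graphs over one contiguous entity-id space:

* a multi-relation recipe knowledge graph (recipe-ingredient, recipe-type,
  recipe-cuisine, ... triples over KG entities), and
* the user-recipe interaction bipartite graph, folded in as an extra
  ``interact`` relation with users appended after the KG entities.

Every stored edge ``(h, r, t)`` is materialised together with its inverse
``(t, r^-1, h)`` so that messages flow in both directions during
propagation.  Adjacency lists are sorted by ``(relation, neighbor)`` and the
whole structure is deterministic given the input files.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Triple",
    "InteractionSet",
    "CRKG",
    "load_triples",
    "load_interactions",
    "write_triples",
    "write_interactions",
    "build_crkg",
    "ROLE_USER",
    "ROLE_RECIPE",
    "ROLE_OTHER",
]

ROLE_OTHER, ROLE_RECIPE, ROLE_USER = 0, 1, 2
_ROLE_NAMES = {ROLE_OTHER: "other", ROLE_RECIPE: "recipe", ROLE_USER: "user"}


@dataclass(frozen=True)
class Triple:
    """One ``head -[relation]-> tail`` edge with nonnegative integer ids."""

    head: int
    relation: int
    tail: int

    def __post_init__(self):
        if min(self.head, self.relation, self.tail) < 0:
            raise ValueError(f"triple ids must be nonnegative: {self}")


@dataclass
class InteractionSet:
    """Deduplicated (user, recipe) pairs with observed user/recipe counts."""

    pairs: list[tuple[int, int]]

    @property
    def users(self) -> list[int]:
        return sorted({u for u, _ in self.pairs})

    @property
    def recipes(self) -> list[int]:
        return sorted({r for _, r in self.pairs})

    @property
    def m(self) -> int:
        return len({u for u, _ in self.pairs})

    @property
    def n(self) -> int:
        return len({r for _, r in self.pairs})

    def by_user(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for u, r in self.pairs:
            out.setdefault(u, []).append(r)
        return {u: sorted(v) for u, v in sorted(out.items())}


def _parse_int_tokens(line: str, lineno: int, path) -> list[int]:
    try:
        return [int(tok) for tok in line.split()]
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: malformed integer token ({exc})") from None


def load_triples(path) -> list[Triple]:
    """Read whitespace-separated ``head relation tail`` lines.

    Lines starting with ``#`` and blank lines are skipped; duplicate triples
    are dropped (count logged).  Malformed lines raise with the line number.
    """
    seen: set[tuple[int, int, int]] = set()
    triples: list[Triple] = []
    duplicates = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = _parse_int_tokens(line, lineno, path)
            if len(tokens) < 3:
                raise ValueError(f"{path}:{lineno}: expected 'head relation tail', got {line!r}")
            h, r, t = tokens[:3]
            if min(h, r, t) < 0:
                raise ValueError(f"{path}:{lineno}: negative id in {line!r}")
            key = (h, r, t)
            if key in seen:
                duplicates += 1
                continue
            seen.add(key)
            triples.append(Triple(h, r, t))
    if duplicates:
        logger.info("load_triples(%s): dropped %d duplicate triples", path, duplicates)
    return triples


def load_interactions(path) -> InteractionSet:
    """Read user-first adjacency lines: ``user item item ...`` per line."""
    seen: set[tuple[int, int]] = set()
    pairs: list[tuple[int, int]] = []
    duplicates = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = _parse_int_tokens(line, lineno, path)
            user, items = tokens[0], tokens[1:]
            if user < 0 or any(i < 0 for i in items):
                raise ValueError(f"{path}:{lineno}: negative id in {line!r}")
            for item in items:
                key = (user, item)
                if key in seen:
                    duplicates += 1
                    continue
                seen.add(key)
                pairs.append(key)
    if duplicates:
        logger.info("load_interactions(%s): dropped %d duplicate pairs", path, duplicates)
    return InteractionSet(pairs=pairs)


def write_triples(triples: Iterable[Triple], path) -> None:
    with open(path, "w") as fh:
        for t in triples:
            fh.write(f"{t.head}\t{t.relation}\t{t.tail}\n")


def write_interactions(by_user: dict[int, Sequence[int]], path) -> None:
    with open(path, "w") as fh:
        for user in sorted(by_user):
            items = " ".join(str(i) for i in by_user[user])
            fh.write(f"{user} {items}\n".rstrip() + "\n")


@dataclass
class CRKG:
    """Fused collaborative recipe knowledge graph.

    Entity ids: KG entities occupy ``0..n_kg_entities-1`` (original ids
    remapped via ``entity_map``), users occupy the following block
    (``user_map``).  Relation ids: original relations remapped to
    ``0..n_base_relations-2``, ``interact`` is ``n_base_relations-1``, and
    relation ``r`` has inverse ``r + n_base_relations``.

    ``edges`` holds every directed edge including inverses as an (E, 3)
    int array of (head, relation, tail) rows, sorted by (head, relation,
    tail); ``adjacency`` gives per-entity CSR-style views of (relation,
    neighbor) pairs.
    """

    n_entities: int
    n_relations: int
    n_kg_entities: int
    n_users: int
    n_base_relations: int  # original relations + interact (inverses excluded)
    interact_relation: int
    edges: np.ndarray
    indptr: np.ndarray  # CSR pointers into `edges` rows, per head entity
    roles: np.ndarray  # ROLE_* per entity
    entity_map: dict[int, int] = field(repr=False, default_factory=dict)
    user_map: dict[int, int] = field(repr=False, default_factory=dict)
    relation_map: dict[int, int] = field(repr=False, default_factory=dict)

    def inverse_relation(self, r: int) -> int:
        if not 0 <= r < self.n_relations:
            raise KeyError(f"unknown relation id {r}")
        return r + self.n_base_relations if r < self.n_base_relations else r - self.n_base_relations

    def neighborhood(self, entity: int) -> list[tuple[int, int]]:
        """Sorted (relation, neighbor) list of ``entity``; empty if isolated."""
        if not 0 <= entity < self.n_entities:
            raise KeyError(f"unknown entity id {entity}")
        rows = self.edges[self.indptr[entity] : self.indptr[entity + 1]]
        return [(int(r), int(t)) for _, r, t in rows]

    @property
    def forward_edges(self) -> np.ndarray:
        """Edges whose relation is non-inverse (KG triples + interact)."""
        return self.edges[self.edges[:, 1] < self.n_base_relations]

    def role_name(self, entity: int) -> str:
        return _ROLE_NAMES[int(self.roles[entity])]

    # --- serialization -------------------------------------------------
    def save(self, prefix) -> None:
        """Write ``<prefix>.npz`` (arrays) and ``<prefix>.json`` (manifest)."""
        prefix = Path(prefix)
        np.savez(
            prefix.with_suffix(".npz"),
            edges=self.edges,
            indptr=self.indptr,
            roles=self.roles,
            entity_map=np.array(sorted(self.entity_map.items()), dtype=np.int64).reshape(-1, 2),
            user_map=np.array(sorted(self.user_map.items()), dtype=np.int64).reshape(-1, 2),
            relation_map=np.array(sorted(self.relation_map.items()), dtype=np.int64).reshape(-1, 2),
        )
        manifest = {
            "n_entities": self.n_entities,
            "n_relations": self.n_relations,
            "n_kg_entities": self.n_kg_entities,
            "n_users": self.n_users,
            "n_base_relations": self.n_base_relations,
            "interact_relation": self.interact_relation,
            "n_edges": int(self.edges.shape[0]),
        }
        prefix.with_suffix(".json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    @classmethod
    def load(cls, prefix) -> "CRKG":
        prefix = Path(prefix)
        manifest = json.loads(prefix.with_suffix(".json").read_text())
        arrays = np.load(prefix.with_suffix(".npz"))
        return cls(
            n_entities=manifest["n_entities"],
            n_relations=manifest["n_relations"],
            n_kg_entities=manifest["n_kg_entities"],
            n_users=manifest["n_users"],
            n_base_relations=manifest["n_base_relations"],
            interact_relation=manifest["interact_relation"],
            edges=arrays["edges"],
            indptr=arrays["indptr"],
            roles=arrays["roles"],
            entity_map=dict(map(tuple, arrays["entity_map"])),
            user_map=dict(map(tuple, arrays["user_map"])),
            relation_map=dict(map(tuple, arrays["relation_map"])),
        )


def build_crkg(
    triples: Sequence[Triple],
    interactions: InteractionSet,
    min_entity_freq: int = 0,
    min_relation_freq: int = 0,
    roles: dict[int, str] | None = None,
) -> CRKG:
    """Fuse KG triples and user-recipe interactions into one graph.

    Low-frequency KG relations/entities (strictly below the thresholds,
    counted over the raw triples) are dropped before fusion; recipes that
    appear in interactions always survive (added as fresh entities when the
    KG does not mention them).  Each relation gains a materialised inverse
    and interactions become an ``interact`` relation; users are appended
    after the KG-entity id block.
    """
    rel_freq = Counter(t.relation for t in triples)
    ent_freq = Counter()
    for t in triples:
        ent_freq[t.head] += 1
        ent_freq[t.tail] += 1

    keep_rel = {r for r, c in rel_freq.items() if c >= min_relation_freq}
    keep_ent = {e for e, c in ent_freq.items() if c >= min_entity_freq}
    kept = [
        t
        for t in triples
        if t.relation in keep_rel and t.head in keep_ent and t.tail in keep_ent
    ]

    interaction_recipes = set(interactions.recipes)
    kg_entity_ids = sorted({t.head for t in kept} | {t.tail for t in kept} | interaction_recipes)
    entity_map = {orig: i for i, orig in enumerate(kg_entity_ids)}
    n_kg = len(entity_map)

    user_ids = sorted({u for u, _ in interactions.pairs})
    user_map = {orig: n_kg + i for i, orig in enumerate(user_ids)}
    n_users = len(user_map)
    n_entities = n_kg + n_users

    kept_rel_ids = sorted({t.relation for t in kept})
    relation_map = {orig: i for i, orig in enumerate(kept_rel_ids)}
    interact = len(relation_map)
    n_base = interact + 1
    n_relations = 2 * n_base

    rows: list[tuple[int, int, int]] = []
    for t in kept:
        h, r, tl = entity_map[t.head], relation_map[t.relation], entity_map[t.tail]
        rows.append((h, r, tl))
        rows.append((tl, r + n_base, h))
    for u, rp in interactions.pairs:
        uu, rr = user_map[u], entity_map[rp]
        if rr >= n_kg:  # impossible by construction: recipes live in the KG block
            raise RuntimeError("interaction recipe id fell into the user id range")
        rows.append((uu, interact, rr))
        rows.append((rr, interact + n_base, uu))

    edges = np.array(sorted(set(rows)), dtype=np.int64).reshape(-1, 3)
    indptr = np.zeros(n_entities + 1, dtype=np.int64)
    if edges.size:
        counts = np.bincount(edges[:, 0], minlength=n_entities)
        indptr[1:] = np.cumsum(counts)

    role_arr = np.full(n_entities, ROLE_OTHER, dtype=np.int8)
    for rp in interaction_recipes:
        role_arr[entity_map[rp]] = ROLE_RECIPE
    if roles:
        name_to_code = {v: k for k, v in _ROLE_NAMES.items()}
        for orig, name in roles.items():
            if orig in entity_map and name in name_to_code:
                role_arr[entity_map[orig]] = name_to_code[name]
    role_arr[n_kg:] = ROLE_USER

    return CRKG(
        n_entities=n_entities,
        n_relations=n_relations,
        n_kg_entities=n_kg,
        n_users=n_users,
        n_base_relations=n_base,
        interact_relation=interact,
        edges=edges,
        indptr=indptr,
        roles=role_arr,
        entity_map=entity_map,
        user_map=user_map,
        relation_map=relation_map,
    )
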