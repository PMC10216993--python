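import numpy as np
import pytest

from fkgm import embedding, graph, propagation
from fkgm.synthetic import make_toy_fixture


@pytest.fixture(scope="session")
def toy_bundle():
    return make_toy_fixture()


@pytest.fixture(scope="session")
def toy_crkg(toy_bundle):
    return graph.build_crkg(toy_bundle.triples, toy_bundle.interactions, roles=toy_bundle.roles)


@pytest.fixture()
def small_crkg():
    """5 KG entities + 2 items as heads, 3 users; two relations."""
    triples = [
        graph.Triple(0, 0, 6),
        graph.Triple(1, 0, 6),
        graph.Triple(2, 0, 7),
        graph.Triple(3, 1, 7),
        graph.Triple(4, 0, 6),
    ]
    inter = graph.InteractionSet(
        pairs=[(100, 0), (100, 1), (101, 2), (101, 3), (102, 4), (102, 0)]
    )
    return graph.build_crkg(triples, inter)


@pytest.fixture()
def small_params(small_crkg):
    return embedding.init_params(small_crkg, d=3, seed=3, n_layers=2)


def dense_propagation_oracle(params, crkg, n_layers):
    """Naive per-entity reference recomputation of the full sweep."""
    V = params.ent_emb.copy()
    states = [V]
    for layer in range(n_layers):
        new_v = np.zeros_like(V)
        for e in range(crkg.n_entities):
            nbrs = crkg.neighborhood(e)
            if nbrs:
                logits = np.array([propagation.attention_logit(params, e, t, r) for r, t in nbrs])
                coeffs = propagation.normalize_attention(logits)
                v_ne = sum(c * V[t] for c, (_, t) in zip(coeffs, nbrs))
            else:
                v_ne = np.zeros(V.shape[1])
            new_v[e] = propagation.bi_interaction(V[e], v_ne, params.W1[layer], params.W2[layer])
        V = new_v
        states.append(V)
    return states
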