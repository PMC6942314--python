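import numpy as np
import pytest

import evokgsim as ek


@pytest.fixture()
def toy_graph():
    """Single-aspect diamond-free toy DAG: R <- A <- C, R <- B.

    With per-aspect maxnodes = 4: IC(R) = 0 (clamped), IC(A) = 1 - log3/log4,
    IC(B) = IC(C) = 0.5.
    """
    g = ek.build_graph([("A", "R"), ("B", "R"), ("C", "A")])
    return ek.compute_ic(g)


@pytest.fixture()
def toy_store(toy_graph):
    store = ek.AnnotationStore(direct={}, graph_ref=toy_graph)
    for entity, term in [("p1", "C"), ("p2", "B"), ("p3", "A"),
                         ("q1", "C"), ("q1", "B"), ("q2", "A")]:
        store.add(entity, term)
    return store


@pytest.fixture(scope="session")
def small_synth():
    """A small full synthetic world shared across tests (read-only)."""
    spec = ek.SyntheticSpec(
        n_terms_per_aspect=40, n_entities=40, n_pairs=200, seed=7
    )
    graph, store, dataset, table = ek.generate_all(spec)
    return spec, graph, store, dataset, table


@pytest.fixture(scope="session")
def labeled_table(small_synth):
    return small_synth[4]
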