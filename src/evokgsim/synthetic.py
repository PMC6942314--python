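"""Synthetic ontologies, annotations and labeled pair datasets.

Emulates the statistical structure the pipeline assumes — a multi-aspect
rooted is-a DAG, per-entity per-aspect direct annotation sets with
controllable sparsity, and pairs labeled by a known ground-truth
combination rule over the aspect similarity scores — so every stage can be
exercised and validated without external downloads.

Ground-truth rules are written in the same expression language as the
evolved models (e.g. ``"max(BP, CC)"`` with a threshold), so recovery
experiments compare like with like.  Direct terms are drawn with
probability proportional to IC (leaf-biased), which spreads entity
similarities over [0, 1] instead of clustering near zero.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from . import expr
from .evaluation import PairDataset
from .ontology import (
    AnnotationStore,
    OntologyGraph,
    build_graph,
    compute_ic,
    write_gaf,
    write_obo,
)
from .similarity import FeatureTable, compute_features

_NAMESPACE_OF = {
    "BP": "biological_process",
    "CC": "cellular_component",
    "MF": "molecular_function",
}


@dataclass
class SyntheticSpec:
    """Generator configuration; every quantity has an explicit default.

    ``aspect_annotation_prob`` may be a single float or a per-aspect dict;
    lowering one aspect's probability emulates datasets where that aspect
    is sparsely annotated.
    """

    aspects: tuple[str, ...] = ("BP", "CC", "MF")
    n_terms_per_aspect: int | dict = 100
    max_parents: int = 2
    n_entities: int = 120
    direct_terms_per_aspect: tuple[int, int] = (2, 4)
    aspect_annotation_prob: float | dict = 1.0
    truth_expression: str = "max(BP, CC)"
    truth_threshold: float = 0.6
    label_noise: float = 0.05
    sampling: str = "unbalanced"  # or "balanced"
    n_pairs: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        probs = self._probs().values()
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("aspect_annotation_prob values must lie in [0, 1]")
        if not (0.0 <= self.label_noise <= 1.0):
            raise ValueError("label_noise must lie in [0, 1]")
        lo, hi = self.direct_terms_per_aspect
        if lo < 1 or hi < lo:
            raise ValueError("direct_terms_per_aspect range is empty")
        if self.sampling not in ("balanced", "unbalanced"):
            raise ValueError(f"unknown sampling mode {self.sampling!r}")
        for a, n in self._sizes().items():
            if n < 2:
                raise ValueError(f"aspect {a!r} needs at least 2 terms")

    def _sizes(self) -> dict[str, int]:
        if isinstance(self.n_terms_per_aspect, dict):
            return {a: int(self.n_terms_per_aspect[a]) for a in self.aspects}
        return {a: int(self.n_terms_per_aspect) for a in self.aspects}

    def _probs(self) -> dict[str, float]:
        if isinstance(self.aspect_annotation_prob, dict):
            return {a: float(self.aspect_annotation_prob[a]) for a in self.aspects}
        return {a: float(self.aspect_annotation_prob) for a in self.aspects}


def generate_ontology(spec: SyntheticSpec, seed: int | None = None) -> OntologyGraph:
    """Per aspect, a rooted DAG grown by attaching each new term to
    1..max_parents existing terms of the same aspect; acyclic by
    construction.  IC is computed before returning."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    edges: list[tuple[str, str]] = []
    terms: list[str] = []
    namespaces: dict[str, str] = {}
    names: dict[str, str] = {}
    for aspect in spec.aspects:
        n = spec._sizes()[aspect]
        ids = [f"{aspect}:{i:07d}" for i in range(n)]
        terms.extend(ids)
        namespaces[ids[0]] = _NAMESPACE_OF.get(aspect, aspect)
        for t in ids:
            names[t] = f"synthetic term {t}"
        for i in range(1, n):
            k = int(rng.integers(1, min(spec.max_parents, i) + 1))
            parents = rng.choice(i, size=k, replace=False)
            for p in sorted(int(j) for j in parents):
                edges.append((ids[i], ids[p]))
    graph = build_graph(edges, terms=terms, names=names, namespaces=namespaces)
    return compute_ic(graph)


def generate_annotations(
    graph: OntologyGraph, spec: SyntheticSpec, seed: int | None = None
) -> AnnotationStore:
    """Annotate each entity per aspect with the configured probability,
    drawing direct terms with weight proportional to IC (+0.01 so the root
    remains reachable).  Entities that come out empty in every aspect are
    resampled so the downstream annotation filter keeps everything."""
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    probs = spec._probs()
    lo, hi = spec.direct_terms_per_aspect
    by_aspect = {a: sorted(graph.aspect_terms(a)) for a in spec.aspects}
    weights = {
        a: np.array([graph.ic[t] + 0.01 for t in ts]) for a, ts in by_aspect.items()
    }
    for a in weights:
        weights[a] = weights[a] / weights[a].sum()

    store = AnnotationStore(direct={}, graph_ref=graph)
    for i in range(spec.n_entities):
        entity = f"E{i:04d}"
        for attempt in range(100):
            chosen: dict[str, list[str]] = {}
            for aspect in spec.aspects:
                if rng.random() >= probs[aspect]:
                    continue
                count = int(rng.integers(lo, hi + 1))
                count = min(count, len(by_aspect[aspect]))
                picks = rng.choice(
                    len(by_aspect[aspect]), size=count, replace=False,
                    p=weights[aspect],
                )
                chosen[aspect] = [by_aspect[aspect][int(j)] for j in picks]
            if chosen:
                break
        else:
            # all aspects declined 100 times; force the likeliest aspect
            aspect = max(spec.aspects, key=lambda a: probs[a])
            picks = rng.choice(len(by_aspect[aspect]), size=lo, replace=False,
                               p=weights[aspect])
            chosen = {aspect: [by_aspect[aspect][int(j)] for j in picks]}
        for aspect, ts in chosen.items():
            for t in ts:
                store.add(entity, t)
    return store


def _truth_tree(spec: SyntheticSpec):
    try:
        return expr.parse_expression(spec.truth_expression, variables=spec.aspects)
    except ValueError as err:
        raise ValueError(
            f"truth model {spec.truth_expression!r} is not a valid expression "
            f"over aspects {spec.aspects}: {err}"
        ) from None


def _greedy_balanced(rng, pos_pairs, neg_pool):
    """Match per-entity negative occurrence counts to the positive counts.

    Strictly greedy: a negative pair is accepted only while both of its
    entities still have remaining positive-side quota, so no entity ends up
    with more negative than positive occurrences.  The negative set may
    come up short when the pool is exhausted.
    """
    quota: dict[str, int] = {}
    for e1, e2 in pos_pairs:
        quota[e1] = quota.get(e1, 0) + 1
        quota[e2] = quota.get(e2, 0) + 1
    order = rng.permutation(len(neg_pool))
    chosen = []
    for idx in order:
        e1, e2 = neg_pool[int(idx)]
        if quota.get(e1, 0) > 0 and quota.get(e2, 0) > 0:
            chosen.append(int(idx))
            quota[e1] -= 1
            quota[e2] -= 1
        if len(chosen) >= len(pos_pairs):
            break
    return chosen


def generate_labeled_pairs(
    graph: OntologyGraph,
    store: AnnotationStore,
    spec: SyntheticSpec,
    measure: str = "ResnikMax",
    seed: int | None = None,
) -> tuple[PairDataset, FeatureTable]:
    """Sample entity pairs, label them by the ground-truth rule, and
    return both the (noisy) pair dataset and the feature table.

    Candidate unordered pairs are enumerated, shuffled, and scored with the
    chosen measure; the truth rule (expression output strictly above the
    threshold) splits them into positives and negatives.  Unbalanced
    sampling takes negatives uniformly; balanced sampling greedily matches
    per-entity occurrence counts between the classes.  Each final label is
    flipped independently with probability ``label_noise``.
    """
    rng = np.random.default_rng(spec.seed + 2 if seed is None else seed)
    truth = _truth_tree(spec)
    entities = sorted(store.entities)
    all_pairs = [
        (entities[i], entities[j])
        for i in range(len(entities))
        for j in range(i + 1, len(entities))
    ]
    order = rng.permutation(len(all_pairs))
    n_pos_target = spec.n_pairs // 2

    pos: list[tuple[str, str]] = []
    neg: list[tuple[str, str]] = []
    feats: dict[tuple[str, str], np.ndarray] = {}
    for idx in order:
        pair = all_pairs[int(idx)]
        row = compute_features(graph, store, [pair], measure).scores[0]
        feats[pair] = row
        if expr.eval_point(truth, row) > spec.truth_threshold:
            if len(pos) < n_pos_target:
                pos.append(pair)
        else:
            neg.append(pair)
        # stop once both classes can be filled
        if len(pos) >= n_pos_target and len(neg) >= spec.n_pairs - n_pos_target:
            break

    if spec.sampling == "balanced":
        chosen_neg = [neg[i] for i in _greedy_balanced(rng, pos, neg)]
    else:
        chosen_neg = neg[: spec.n_pairs - len(pos)]

    records = [(p, 1) for p in pos] + [(p, 0) for p in chosen_neg]
    flips = rng.random(len(records)) < spec.label_noise
    labeled = [
        (e1, e2, (lab ^ 1) if flip else lab)
        for ((e1, e2), lab), flip in zip(records, flips)
    ]
    dataset = PairDataset(pairs=labeled, name="synthetic")
    table = FeatureTable(
        pairs=[(e1, e2) for e1, e2, _ in dataset.pairs],
        aspects=tuple(spec.aspects),
        scores=np.array([feats[(e1, e2)] for e1, e2, _ in dataset.pairs]),
        measure=measure,
        labels=np.array([lab for _, _, lab in dataset.pairs]),
        graph_checksum=graph.checksum(),
    )
    return dataset, table


def write_fixture(
    graph: OntologyGraph,
    store: AnnotationStore,
    dataset: PairDataset,
    directory,
) -> dict[str, str]:
    """Write OBO + GAF + pair TSV that round-trip through the loaders."""
    os.makedirs(directory, exist_ok=True)
    paths = {
        "obo": os.path.join(directory, "ontology.obo"),
        "gaf": os.path.join(directory, "annotations.gaf"),
        "pairs": os.path.join(directory, "pairs.tsv"),
    }
    write_obo(graph, paths["obo"])
    write_gaf(store, paths["gaf"])
    dataset.save(paths["pairs"])
    return paths


def generate_all(
    spec: SyntheticSpec, measure: str = "ResnikMax"
) -> tuple[OntologyGraph, AnnotationStore, PairDataset, FeatureTable]:
    """Convenience: ontology + annotations + labeled pairs in one call."""
    graph = generate_ontology(spec)
    store = generate_annotations(graph, spec)
    dataset, table = generate_labeled_pairs(graph, store, spec, measure)
    return graph, store, dataset, table
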