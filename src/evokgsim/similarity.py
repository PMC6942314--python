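"""Entity-level semantic similarity per aspect.

Three measures over a shared intrinsic-IC ontology:

* **SimGIC** — IC-weighted Jaccard of the *extended* (direct + inherited)
  annotation sets.
* **Resnik max** — maximum, over all direct-term pairs, of the IC of the
  most informative common ancestor (MICA).
* **Resnik best-match average (BMA)** — each direct term's best MICA match
  against the other set, averaged per side and summed.

All measures are symmetric, bounded in [0, 1], and return 0 when either
entity lacks annotations in the aspect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ontology import AnnotationStore, OntologyGraph, ancestors, annotations

MEASURES = ("SimGIC", "ResnikMax", "ResnikBMA")


def term_similarity(graph: OntologyGraph, t1: str, t2: str) -> float:
    """IC of the most informative common ancestor (reflexive closure)."""
    a1, a2 = graph.aspect_of.get(t1), graph.aspect_of.get(t2)
    if a1 is None or a2 is None:
        raise KeyError(f"unknown term in pair ({t1!r}, {t2!r})")
    if a1 != a2:
        raise ValueError(f"terms {t1!r} and {t2!r} belong to different aspects")
    common = ancestors(graph, t1) & ancestors(graph, t2)
    return max(graph.ic[t] for t in common) if common else 0.0


def sim_gic(
    graph: OntologyGraph,
    store: AnnotationStore,
    p1: str,
    p2: str,
    aspect: str,
    annotation_mode: str = "extended",
) -> float:
    go1 = annotations(store, p1, aspect, annotation_mode)
    go2 = annotations(store, p2, aspect, annotation_mode)
    if not go1 or not go2:
        return 0.0
    union = sum(graph.ic[t] for t in go1 | go2)
    if union == 0.0:
        return 0.0
    inter = sum(graph.ic[t] for t in go1 & go2)
    return inter / union


def resnik_max(
    graph: OntologyGraph,
    store: AnnotationStore,
    p1: str,
    p2: str,
    aspect: str,
    annotation_mode: str = "direct",
) -> float:
    go1 = annotations(store, p1, aspect, annotation_mode)
    go2 = annotations(store, p2, aspect, annotation_mode)
    if not go1 or not go2:
        return 0.0
    return max(term_similarity(graph, t1, t2) for t1 in go1 for t2 in go2)


def resnik_bma(
    graph: OntologyGraph,
    store: AnnotationStore,
    p1: str,
    p2: str,
    aspect: str,
    annotation_mode: str = "direct",
) -> float:
    go1 = annotations(store, p1, aspect, annotation_mode)
    go2 = annotations(store, p2, aspect, annotation_mode)
    if not go1 or not go2:
        return 0.0
    sims = {
        (t1, t2): term_similarity(graph, t1, t2) for t1 in go1 for t2 in go2
    }
    side1 = sum(max(sims[(t1, t2)] for t2 in go2) for t1 in go1)
    side2 = sum(max(sims[(t1, t2)] for t1 in go1) for t2 in go2)
    return side1 / (2 * len(go1)) + side2 / (2 * len(go2))


_MEASURE_FN = {"SimGIC": sim_gic, "ResnikMax": resnik_max, "ResnikBMA": resnik_bma}


def entity_similarity(
    graph: OntologyGraph,
    store: AnnotationStore,
    p1: str,
    p2: str,
    aspect: str,
    measure: str,
) -> float:
    """Dispatch to the named measure (one of ``MEASURES``)."""
    try:
        fn = _MEASURE_FN[measure]
    except KeyError:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    return fn(graph, store, p1, p2, aspect)


@dataclass
class FeatureTable:
    """Per-pair aspect similarity scores, optionally labeled.

    ``scores`` has one row per pair and one column per aspect (the order of
    ``aspects``); all values lie in [0, 1].
    """

    pairs: list[tuple[str, str]]
    aspects: tuple[str, ...]
    scores: np.ndarray
    measure: str
    labels: np.ndarray | None = None
    graph_checksum: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def X(self) -> np.ndarray:
        """The (n_pairs, n_aspects) feature matrix."""
        return self.scores

    @property
    def y(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("feature table has no labels")
        return self.labels

    def subset(self, idx) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(
            pairs=[self.pairs[i] for i in idx],
            aspects=self.aspects,
            scores=self.scores[idx],
            measure=self.measure,
            labels=None if self.labels is None else self.labels[idx],
            graph_checksum=self.graph_checksum,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores, columns=[f"ss_{a}" for a in self.aspects]
        )
        df.insert(0, "entity1", [p[0] for p in self.pairs])
        df.insert(1, "entity2", [p[1] for p in self.pairs])
        df.insert(
            2, "label", self.labels if self.labels is not None else np.nan
        )
        return df

    def save(self, path) -> None:
        """TSV with measure and graph checksum in a header comment."""
        with open(path, "w") as fh:
            fh.write(
                f"# measure={self.measure} graph={self.graph_checksum} "
                f"aspects={','.join(self.aspects)}\n"
            )
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "FeatureTable":
        measure, checksum = "", ""
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                meta = dict(
                    kv.split("=", 1) for kv in first[1:].split() if "=" in kv
                )
                measure = meta.get("measure", "")
                checksum = meta.get("graph", "")
                df = pd.read_csv(fh, sep="\t")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t")
        aspect_cols = [c for c in df.columns if c.startswith("ss_")]
        labels = None
        if "label" in df and not df["label"].isna().any():
            labels = df["label"].astype(int).to_numpy()
        return cls(
            pairs=list(zip(df["entity1"], df["entity2"])),
            aspects=tuple(c[3:] for c in aspect_cols),
            scores=df[aspect_cols].to_numpy(dtype=float),
            measure=measure,
            labels=labels,
            graph_checksum=checksum,
        )


def compute_features(
    graph: OntologyGraph,
    store: AnnotationStore,
    pairs: Iterable[tuple[str, str] | tuple[str, str, int]],
    measure: str = "ResnikMax",
) -> FeatureTable:
    """Score every pair in every aspect with the chosen measure.

    Pairs may carry an optional 0/1 label as a third element.  Pairs whose
    entities are unannotated in *all* aspects must be filtered out first
    (see :func:`evokgsim.evaluation.filter_pairs`); such a pair raises.
    """
    aspects = graph.aspects
    pair_list: list[tuple[str, str]] = []
    labels: list[int] = []
    have_labels = None
    rows = []
    for rec in pairs:
        if len(rec) == 3:
            p1, p2, lab = rec
            if have_labels is False:
                raise ValueError("mixed labeled and unlabeled pairs")
            have_labels = True
            labels.append(int(lab))
        else:
            p1, p2 = rec  # type: ignore[misc]
            if have_labels is True:
                raise ValueError("mixed labeled and unlabeled pairs")
            have_labels = False
        for p in (p1, p2):
            if not any(store.direct.get(p, {}).get(a) for a in aspects):
                raise ValueError(
                    f"entity {p!r} has no annotation in any aspect; "
                    "run the annotation filter before computing features"
                )
        pair_list.append((p1, p2))
        rows.append(
            [entity_similarity(graph, store, p1, p2, a, measure) for a in aspects]
        )
    return FeatureTable(
        pairs=pair_list,
        aspects=aspects,
        scores=np.asarray(rows, dtype=float).reshape(len(pair_list), len(aspects)),
        measure=measure,
        labels=np.asarray(labels, dtype=int) if have_labels else None,
        graph_checksum=graph.checksum(),
    )
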