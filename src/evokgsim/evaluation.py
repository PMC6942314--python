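"""Dataset handling, cross-validation protocols, WAF scoring and method
comparison.

Pairs are unordered throughout: a pair is stored with its two entity ids in
canonical (sorted) order, so (A, B) and (B, A) are the same pair for
deduplication and train/test overlap checks.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from sklearn.base import clone
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold

from .ontology import AnnotationStore
from .similarity import FeatureTable

logger = logging.getLogger("evokgsim")


def _canonical(e1: str, e2: str) -> tuple[str, str]:
    return (e1, e2) if e1 <= e2 else (e2, e1)


@dataclass
class PairDataset:
    """Labeled entity pairs (label 1 = interaction, 0 = no interaction)."""

    pairs: list[tuple[str, str, int]]
    name: str = ""
    species: str | None = None

    def __post_init__(self) -> None:
        deduped: list[tuple[str, str, int]] = []
        seen: set[tuple[str, str, int]] = set()
        for e1, e2, lab in self.pairs:
            key = _canonical(e1, e2) + (int(lab),)
            if key in seen:
                continue
            seen.add(key)
            deduped.append(key)
        removed = len(self.pairs) - len(deduped)
        if removed:
            logger.info("%s: removed %d duplicate pair rows", self.name or "dataset", removed)
        self.pairs = deduped

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def labels(self) -> np.ndarray:
        return np.array([lab for _, _, lab in self.pairs], dtype=int)

    def pair_keys(self) -> set[tuple[str, str]]:
        return {(e1, e2) for e1, e2, _ in self.pairs}

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# dataset={self.name} species={self.species or ''}\n")
            for e1, e2, lab in self.pairs:
                fh.write(f"{e1}\t{e2}\t{lab}\n")

    @classmethod
    def load(cls, path, name: str = "", species: str | None = None) -> "PairDataset":
        pairs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                e1, e2, lab = line.split("\t")
                pairs.append((e1, e2, int(lab)))
        return cls(pairs=pairs, name=name or str(path), species=species)


def filter_pairs(dataset: PairDataset, store: AnnotationStore) -> PairDataset:
    """Keep a pair only when both entities have at least one direct
    annotation in at least one semantic aspect; log the removed count."""

    def annotated(entity: str) -> bool:
        return any(terms for terms in store.direct.get(entity, {}).values())

    kept = [(e1, e2, lab) for e1, e2, lab in dataset.pairs
            if annotated(e1) and annotated(e2)]
    removed = len(dataset.pairs) - len(kept)
    if removed:
        logger.info("%s: annotation filter removed %d pairs", dataset.name, removed)
    return PairDataset(pairs=kept, name=dataset.name, species=dataset.species)


def waf(y_true, y_pred) -> float:
    """Weighted average of per-class F-measures (weights = class support).

    A class with zero true and zero predicted positives contributes F = 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        raise ValueError("empty label sequences")
    return float(f1_score(y_true, y_pred, average="weighted", zero_division=0))


def stratified_kfold(data, k: int = 10, seed: int = 0):
    """Deterministic stratified k-fold index pairs.

    ``data`` may be a :class:`PairDataset`, a labeled
    :class:`~evokgsim.similarity.FeatureTable`, or a label array.  The same
    seed always yields the same folds, so a pinned seed reproduces the same
    folds across every experiment.
    """
    if isinstance(data, PairDataset):
        y = data.labels
    elif isinstance(data, FeatureTable):
        y = data.y
    else:
        y = np.asarray(data, dtype=int)
    if k < 2 or k > y.size:
        raise ValueError(f"k={k} incompatible with {y.size} samples")
    counts = np.bincount(y)
    small = counts[(counts > 0) & (counts < k)]
    if small.size:
        logger.warning(
            "stratified_kfold: smallest class has %d < k=%d members; "
            "some folds will miss it", int(small.min()), k
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return [(train, test) for train, test in skf.split(np.zeros_like(y), y)]


def dedup_across(
    train: PairDataset, test: PairDataset, remove_from: str = "train"
) -> tuple[PairDataset, PairDataset]:
    """Remove unordered-pair overlap between two datasets.

    Pairs occurring (in either orientation) in both sets are removed from
    the chosen side (default: train, preserving the reported test set).
    """
    overlap = train.pair_keys() & test.pair_keys()
    if not overlap:
        return train, test
    logger.info(
        "dedup_across: %d overlapping pairs removed from %s", len(overlap), remove_from
    )
    if remove_from == "train":
        kept = [p for p in train.pairs if _canonical(p[0], p[1]) not in overlap]
        return PairDataset(kept, train.name, train.species), test
    if remove_from == "test":
        kept = [p for p in test.pairs if _canonical(p[0], p[1]) not in overlap]
        return train, PairDataset(kept, test.name, test.species)
    raise ValueError("remove_from must be 'train' or 'test'")


@dataclass
class EvaluationReport:
    """Per-fold (or per-run) test WAF values for one method."""

    method: str
    params: dict
    protocol: str
    fold_scores: list[float]
    seeds: list[int] = field(default_factory=list)
    extras: list[dict] = field(default_factory=list)

    @property
    def median_waf(self) -> float:
        return float(median(self.fold_scores))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "params": self.params,
            "protocol": self.protocol,
            "fold_scores": self.fold_scores,
            "median_waf": self.median_waf,
            "seeds": self.seeds,
            "extras": self.extras,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "EvaluationReport":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            method=d["method"], params=d.get("params", {}),
            protocol=d["protocol"], fold_scores=d["fold_scores"],
            seeds=d.get("seeds", []), extras=d.get("extras", []),
        )


_EXPORT_ATTRS = ("threshold_", "train_waf_", "weights_", "fitness_")


def _fit_extras(est) -> dict:
    out = {}
    for attr in _EXPORT_ATTRS:
        if hasattr(est, attr):
            v = getattr(est, attr)
            out[attr.rstrip("_")] = list(v) if isinstance(v, tuple) else v
    if hasattr(est, "expression_"):
        out["model"] = est.expression_()
    return out


def _is_stochastic(estimator) -> bool:
    return "random_state" in estimator.get_params()


def run_protocol(
    datasets,
    estimator,
    protocol: str = "cv",
    seeds: Sequence[int] = (0,),
    k: int = 10,
    remove_from: str = "train",
    features: dict | None = None,
) -> EvaluationReport:
    """Evaluate one method under one protocol.

    ``cv``: ``datasets`` is a single labeled feature table; stratified
    ``k``-fold with folds pinned by ``seeds[0]``; one model per fold, with
    stochastic methods seeded per fold from ``seeds[0]``.

    ``cross``: ``datasets`` is a (train_table, test_table) pair; the
    unordered-pair overlap is removed from the chosen side first, then the
    model is trained once per seed (deterministic methods run once) and
    scored on the fixed test set.
    """
    seeds = list(seeds)
    scores: list[float] = []
    extras: list[dict] = []
    if protocol == "cv":
        table: FeatureTable = datasets
        folds = stratified_kfold(table, k=k, seed=seeds[0])
        for fold_i, (train_idx, test_idx) in enumerate(folds):
            est = clone(estimator)
            if _is_stochastic(est):
                est.set_params(random_state=int(seeds[0]) * 1000 + fold_i)
            tr, te = table.subset(train_idx), table.subset(test_idx)
            est.fit(tr.X, tr.y)
            scores.append(waf(te.y, est.predict(te.X)))
            extras.append(_fit_extras(est))
    elif protocol == "cross":
        train_table, test_table = datasets
        overlap = {_canonical(*p) for p in train_table.pairs} & {
            _canonical(*p) for p in test_table.pairs
        }
        if overlap:
            if remove_from == "train":
                keep = [i for i, p in enumerate(train_table.pairs)
                        if _canonical(*p) not in overlap]
                train_table = train_table.subset(keep)
            else:
                keep = [i for i, p in enumerate(test_table.pairs)
                        if _canonical(*p) not in overlap]
                test_table = test_table.subset(keep)
            logger.info("cross protocol: removed %d overlapping pairs from %s",
                        len(overlap), remove_from)
        run_seeds = seeds if _is_stochastic(estimator) else seeds[:1]
        for s in run_seeds:
            est = clone(estimator)
            if _is_stochastic(est):
                est.set_params(random_state=int(s))
            est.fit(train_table.X, train_table.y)
            scores.append(waf(test_table.y, est.predict(test_table.X)))
            extras.append(_fit_extras(est))
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    return EvaluationReport(
        method=type(estimator).__name__,
        params={k_: v for k_, v in estimator.get_params().items()
                if isinstance(v, (int, float, str, bool, tuple, type(None)))},
        protocol=protocol,
        fold_scores=scores,
        seeds=seeds,
        extras=extras,
    )


def compare_methods(
    report_a: EvaluationReport | Sequence[float],
    report_b: EvaluationReport | Sequence[float],
    alpha: float = 0.01,
) -> tuple[float, float, bool]:
    """Two-sample Kruskal-Wallis test on fold scores.

    Returns (statistic, p-value, significant at ``alpha``).  Identical
    constant score vectors give statistic 0 and are never significant.
    """
    a = list(report_a.fold_scores) if isinstance(report_a, EvaluationReport) else list(report_a)
    b = list(report_b.fold_scores) if isinstance(report_b, EvaluationReport) else list(report_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 scores")
    if len(set(a) | set(b)) == 1:
        return 0.0, 1.0, False
    stat, p = stats.kruskal(a, b)
    return float(stat), float(p), bool(p < alpha)
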