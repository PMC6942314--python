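"""Independent brute-force reference implementations.

Everything here works directly on raw edge lists and annotation dicts with
naive recursion and no caching, so it shares no code path with the package
it checks.
"""

import math


def naive_ancestors(edges, term):
    """Reflexive closure by repeated parent lookup on the raw edge list."""
    parents = {}
    for child, parent in edges:
        parents.setdefault(child, set()).add(parent)
    out = {term}
    frontier = [term]
    while frontier:
        t = frontier.pop()
        for p in parents.get(t, ()):
            if p not in out:
                out.add(p)
                frontier.append(p)
    return out


def naive_descendant_count(edges, term, universe):
    """hypo(t): terms whose ancestor closure contains t (includes t)."""
    return sum(1 for u in universe if term in naive_ancestors(edges, u))


def naive_ic(edges, universe, term):
    hypo = naive_descendant_count(edges, term, universe)
    raw = 1.0 - math.log(hypo + 1) / math.log(len(universe))
    return max(raw, 0.0)


def naive_ic_table(edges, universe):
    """IC of every term in the aspect, computed naively once."""
    return {t: naive_ic(edges, universe, t) for t in universe}


def naive_term_sim(edges, ic, t1, t2):
    common = naive_ancestors(edges, t1) & naive_ancestors(edges, t2)
    if not common:
        return 0.0
    return max(ic[t] for t in common)


def naive_sim_gic(edges, ic, terms1, terms2):
    ext1 = set().union(*(naive_ancestors(edges, t) for t in terms1)) if terms1 else set()
    ext2 = set().union(*(naive_ancestors(edges, t) for t in terms2)) if terms2 else set()
    if not ext1 or not ext2:
        return 0.0
    union = sum(ic[t] for t in ext1 | ext2)
    if union == 0.0:
        return 0.0
    return sum(ic[t] for t in ext1 & ext2) / union


def naive_resnik_max(edges, ic, terms1, terms2):
    if not terms1 or not terms2:
        return 0.0
    return max(naive_term_sim(edges, ic, a, b) for a in terms1 for b in terms2)


def naive_resnik_bma(edges, ic, terms1, terms2):
    if not terms1 or not terms2:
        return 0.0
    s1 = sum(
        max(naive_term_sim(edges, ic, a, b) for b in terms2) for a in terms1
    )
    s2 = sum(
        max(naive_term_sim(edges, ic, a, b) for a in terms1) for b in terms2
    )
    return s1 / (2 * len(terms1)) + s2 / (2 * len(terms2))


def naive_waf(y_true, y_pred):
    """Per-class precision/recall F-measures weighted by true support."""
    classes = sorted(set(y_true) | set(y_pred))
    total = len(y_true)
    acc = 0.0
    for c in classes:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        support = tp + fn
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        acc += f * support
    return acc / total
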