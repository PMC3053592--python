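"""Semantic similarity over the ontology DAG.

Semantic contributions (S-values) propagate from a focal term through its
ancestor closure with relation-specific edge weights; term similarity is the
normalized overlap of two terms' contribution maps, and gene similarity is
the best-match average over the genes' term sets.
"""

from __future__ import annotations

from collections import deque
from typing import Dict, FrozenSet, Optional, Set

from .core_io import GeneGoAnnotation, GoDAG
from .errors import UsageError

__all__ = ["ancestor_closure", "s_values", "term_similarity", "gene_similarity"]


def _require(dag: GoDAG, term: str) -> None:
    if term not in dag:
        raise UsageError(f"unknown ontology term {term!r}")


def ancestor_closure(dag: GoDAG, a: str) -> FrozenSet[str]:
    """The focal term plus everything reachable via parent edges."""
    _require(dag, a)
    seen: Set[str] = {a}
    queue = deque([a])
    while queue:
        t = queue.popleft()
        for parent, _rel in dag.parents[t]:
            if parent not in seen:
                seen.add(parent)
                queue.append(parent)
    return frozenset(seen)


def s_values(dag: GoDAG, a: str) -> Dict[str, float]:
    """Semantic contribution of every ancestor t to the focal term a.

    S(a) = 1; for any other ancestor t, S(t) is the maximum over in-closure
    children c of t of w(c->t) * S(c) — equivalently the maximum edge-weight
    product over all directed paths from a to t.
    """
    closure = ancestor_closure(dag, a)
    s: Dict[str, float] = {a: 1.0}
    # memoized post-order walk: each closure node depends only on closure
    # children, which lie strictly closer to the focal term (DAG guarantees
    # termination)
    def value(t: str) -> float:
        if t in s:
            return s[t]
        best = 0.0
        for child, rel in dag.children[t]:
            if child in closure:
                cand = dag.edge_weights[rel] * value(child)
                if cand > best:
                    best = cand
        s[t] = best
        return best

    for t in closure:
        value(t)
    return s


def term_similarity(dag: GoDAG, a: str, b: str) -> float:
    """Wang-style similarity of two terms, in (0, 1]; symmetric; 1 for a == b."""
    sa = s_values(dag, a)
    sb = s_values(dag, b)
    common = set(sa) & set(sb)
    overlap = sum(sa[t] + sb[t] for t in common)
    # guard against fp drift pushing identical-closure pairs past 1
    return min(1.0, overlap / (sum(sa.values()) + sum(sb.values())))


def gene_similarity(
    dag: GoDAG,
    ann: GeneGoAnnotation,
    ga: str,
    gb: str,
    combine: str = "BMA",
    _cache: Optional[Dict] = None,
) -> float:
    """Best-match-average similarity between two genes' term sets.

    For the matrix of term similarities between the genes' annotation sets,
    the average of (row maxima ++ column maxima). NaN when either gene has
    no annotation. ``_cache`` may hold term-pair similarities across calls.
    """
    if combine != "BMA":
        raise UsageError(f"unsupported combine mode {combine!r}")
    terms_a = sorted(ann.get(ga, ()))
    terms_b = sorted(ann.get(gb, ()))
    if not terms_a or not terms_b:
        return float("nan")
    cache = _cache if _cache is not None else {}

    def tsim(x: str, y: str) -> float:
        key = (x, y) if x <= y else (y, x)
        if key not in cache:
            cache[key] = term_similarity(dag, x, y)
        return cache[key]

    sims = [[tsim(x, y) for y in terms_b] for x in terms_a]
    row_max = [max(row) for row in sims]
    col_max = [max(sims[i][j] for i in range(len(terms_a))) for j in range(len(terms_b))]
    return (sum(row_max) + sum(col_max)) / (len(row_max) + len(col_max))
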