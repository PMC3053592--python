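"""Independent brute-force oracles used to cross-check the package.

Everything here is written from first principles (loops, enumeration) and
deliberately avoids the vectorized/recursive implementations it checks.
"""

from __future__ import annotations

import math
from typing import Dict, List, Tuple

import numpy as np


def expected_profile_loops(counts: np.ndarray) -> np.ndarray:
    """Per-offset mean contact via explicit loops."""
    n = counts.shape[0]
    out = np.zeros(n)
    for d in range(n):
        vals = [counts[i][i + d] for i in range(n - d)]
        out[d] = sum(vals) / len(vals)
    return out


def pearson_two_rows(oe: np.ndarray, i: int, j: int, min_shared: int = 3) -> float:
    """Direct two-row Pearson over columns defined in both rows."""
    xi, xj = [], []
    for k in range(oe.shape[1]):
        if math.isfinite(oe[i, k]) and math.isfinite(oe[j, k]):
            xi.append(oe[i, k])
            xj.append(oe[j, k])
    if len(xi) < min_shared:
        return float("nan")
    mx = sum(xi) / len(xi)
    my = sum(xj) / len(xj)
    num = sum((a - mx) * (b - my) for a, b in zip(xi, xj))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in xi) * sum((b - my) ** 2 for b in xj)
    )
    if den == 0:
        return float("nan")
    return num / den


def pair_interaction_loops(ga, gb, mat: np.ndarray, resolution: int) -> float:
    """Weighted-average interaction via nested loops over all bins."""
    n_bins = mat.shape[0]

    def weights(g):
        w = {}
        for k in range(n_bins):
            ov = min(g.end, (k + 1) * resolution) - max(g.start, k * resolution)
            if ov > 0:
                w[k] = ov / (g.end - g.start)
        return w

    wa, wb = weights(ga), weights(gb)
    num = den = 0.0
    for k, wk in wa.items():
        for l, wl in wb.items():
            if math.isfinite(mat[k, l]):
                num += wk * wl * mat[k, l]
                den += wk * wl
    return num / den if den > 0 else float("nan")


def tcs_brute(a, b) -> float:
    """TCS by explicit element counting."""
    a, b = set(a), set(b)
    only = 0
    for x in a | b:
        if (x in a) != (x in b):
            only += 1
    return 1.0 - only / (len(a) + len(b))


def svalues_paths(dag, focal: str) -> Dict[str, float]:
    """S-values by enumerating every directed path focal -> ancestor."""
    best: Dict[str, float] = {focal: 1.0}

    def walk(term: str, product: float) -> None:
        for parent, rel in dag.parents[term]:
            p = product * dag.edge_weights[rel]
            # a dominated prefix can never yield a better extension, so it
            # is sound to prune it; equal prefixes add nothing either
            if p > best.get(parent, 0.0):
                best[parent] = p
                walk(parent, p)

    walk(focal, 1.0)
    return best


def term_similarity_paths(dag, a: str, b: str) -> float:
    sa = svalues_paths(dag, a)
    sb = svalues_paths(dag, b)
    common = set(sa) & set(sb)
    return sum(sa[t] + sb[t] for t in common) / (
        sum(sa.values()) + sum(sb.values())
    )


def random_dag(rng: np.random.Generator, n_terms: int):
    """Random small DAG with mixed is_a/part_of edges; term 0 is the root."""
    from chromex.core_io import GoDAG

    terms = [f"T{i:03d}" for i in range(n_terms)]
    edges: List[Tuple[str, str, str]] = []
    for i in range(1, n_terms):
        k = int(rng.integers(1, min(3, i) + 1))
        parents = rng.choice(i, size=k, replace=False)
        for p in parents:
            rel = "is_a" if rng.random() < 0.7 else "part_of"
            edges.append((terms[i], terms[int(p)], rel))
    return GoDAG(terms, edges)


def mutual_ranks_brute(expr: np.ndarray, ids: List[str]) -> Dict[Tuple[str, str], float]:
    """Exhaustive double-ranking mutual ranks (average rank on ties)."""
    n = len(ids)
    corr = np.corrcoef(expr)

    def rank_of(g: int, h: int) -> float:
        greater = equal = 0
        for k in range(n):
            if k == g:
                continue
            if corr[g, k] > corr[g, h]:
                greater += 1
            elif corr[g, k] == corr[g, h]:
                equal += 1
        return greater + (equal + 1) / 2.0

    out = {}
    for i in range(n):
        for j in range(i + 1, n):
            out[(ids[i], ids[j])] = math.sqrt(rank_of(i, j) * rank_of(j, i))
    return out


def binning_sweep(x, n_groups: int) -> np.ndarray:
    """Reference equal-size binning by an explicit sorted sweep."""
    x = list(x)
    n = len(x)
    order = sorted(range(n), key=lambda i: (x[i], i))
    group_of_value: Dict[float, int] = {}
    assign = [0] * n
    for pos, idx in enumerate(order):
        tentative = (pos * n_groups) // n
        if x[idx] not in group_of_value:
            group_of_value[x[idx]] = tentative
        assign[idx] = group_of_value[x[idx]]
    return np.array(assign)
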