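"""Independent brute-force oracles used by the test suite.

Everything here is written as naively as possible (exhaustive
enumeration, fixed-point iteration) and stays independent of the package
code paths it checks.
"""

from __future__ import annotations

import math
from itertools import combinations
from typing import Mapping, Sequence


def transitive_equivalence_closure(
    nodes: list[tuple[str, str]], edges: list[tuple[tuple[str, str], tuple[str, str]]]
) -> list[set[tuple[str, str]]]:
    """Fixed-point closure of an equivalence relation into components."""
    comps = [{n} for n in nodes]
    changed = True
    while changed:
        changed = False
        for a, b in edges:
            ca = next((c for c in comps if a in c), None)
            cb = next((c for c in comps if b in c), None)
            if ca is not None and cb is not None and ca is not cb:
                ca |= cb
                comps.remove(cb)
                changed = True
    return comps


def ancestors(graph_parents: Mapping[str, list[str]], node: str) -> set[str]:
    """Reflexive ancestor set by recursive walk over child → parents maps."""
    seen = {node}
    stack = [node]
    while stack:
        for p in graph_parents.get(stack.pop(), []):
            if p not in seen:
                seen.add(p)
                stack.append(p)
    return seen


def descendants(graph_parents: Mapping[str, list[str]], node: str) -> set[str]:
    all_nodes = set(graph_parents)
    for ps in graph_parents.values():
        all_nodes.update(ps)
    return {n for n in all_nodes if node in ancestors(graph_parents, n)}


def ic_by_descendant_counting(
    entity_sets: Mapping[str, set[str]], graph_parents: Mapping[str, list[str]]
) -> dict[str, float]:
    """IC via explicit descendant counting: count(c) = pairs annotated to
    c or any descendant of c."""
    total = sum(len(s) for s in entity_sets.values())
    all_nodes = set(graph_parents)
    for ps in graph_parents.values():
        all_nodes.update(ps)
    out = {}
    for c in all_nodes:
        reach = descendants(graph_parents, c) | {c}
        count = sum(1 for s in entity_sets.values() for iri in s if iri in reach)
        if count > 0:
            out[c] = -math.log(count / total)
    return out


def naive_resnik(
    c1: str, c2: str, ic: Mapping[str, float], graph_parents: Mapping[str, list[str]]
) -> float:
    common = ancestors(graph_parents, c1) & ancestors(graph_parents, c2)
    vals = [ic[a] for a in common if a in ic]
    return max(vals, default=0.0)


def naive_bma(
    set_a: set[str], set_b: set[str], ic, graph_parents
) -> float:
    if not set_a or not set_b:
        return 0.0
    fwd = sum(max(naive_resnik(a, b, ic, graph_parents) for b in set_b) for a in set_a)
    rev = sum(max(naive_resnik(a, b, ic, graph_parents) for a in set_a) for b in set_b)
    return 0.5 * (fwd / len(set_a) + rev / len(set_b))


def all_matches_then_filter(
    tokens: list[tuple[str, str, int, int]],
    forms: Mapping[tuple[str, ...], set[str]],
) -> list[tuple[int, int, frozenset[str]]]:
    """All token-window matches, filtered longest-then-leftmost.

    ``tokens`` are (surface, lemma, start, end); both surface and lemma
    windows are looked up.  Returns accepted (start, end, iris) spans.
    """
    found: dict[tuple[int, int], set[str]] = {}
    n = len(tokens)
    for i in range(n):
        for j in range(i + 1, n + 1):
            window = tokens[i:j]
            surf = tuple(t[0].lower() for t in window)
            lem = tuple(t[1] for t in window)
            iris = forms.get(surf, set()) | forms.get(lem, set())
            if iris:
                span = (window[0][2], window[-1][3])
                found.setdefault(span, set()).update(iris)
    accepted: list[tuple[int, int, frozenset[str]]] = []
    for (s, e), iris in sorted(found.items(), key=lambda kv: (-(kv[0][1] - kv[0][0]), kv[0][0])):
        if all(e <= a or s >= b for a, b, _ in accepted):
            accepted.append((s, e, frozenset(iris)))
    return sorted(accepted)


def naive_reciprocal_rank(neighbours: Sequence[str], relevant: set[str]) -> float:
    ranks = [i for i, n in enumerate(neighbours, 1) if n in relevant]
    return 1.0 / ranks[0] if ranks else 0.0


def naive_average_precision(
    neighbours: Sequence[str], relevant: set[str], k: int
) -> float | None:
    if not relevant:
        return None
    precisions = []
    for i in range(1, min(k, len(neighbours)) + 1):
        if neighbours[i - 1] in relevant:
            top = neighbours[:i]
            precisions.append(sum(1 for n in top if n in relevant) / i)
    return sum(precisions) / min(k, len(relevant))


def exact_ranksum(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """Exact two-sided rank-sum test by full enumeration (no ties)."""
    pooled = sorted(list(sample_a) + list(sample_b))
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free samples"
    rank_of = {v: i + 1 for i, v in enumerate(pooled)}
    n1 = len(sample_a)
    w_obs = sum(rank_of[v] for v in sample_a)
    all_ranks = list(range(1, len(pooled) + 1))
    w_values = [sum(c) for c in combinations(all_ranks, n1)]
    n = len(w_values)
    p_le = sum(1 for w in w_values if w <= w_obs) / n
    p_ge = sum(1 for w in w_values if w >= w_obs) / n
    return float(w_obs), min(1.0, 2.0 * min(p_le, p_ge))


def random_dag_parents(rng, n_nodes: int, extra_parent_rate: float = 0.3) -> dict[str, list[str]]:
    """Random rooted DAG as a child → parents map over string node names."""
    names = [f"N{i}" for i in range(n_nodes)]
    parents: dict[str, list[str]] = {names[0]: []}
    for i in range(1, n_nodes):
        ps = [names[rng.randrange(i)]]
        if rng.random() < extra_parent_rate and i > 1:
            q = names[rng.randrange(i)]
            if q not in ps:
                ps.append(q)
        parents[names[i]] = ps
    return parents
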