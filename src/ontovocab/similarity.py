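"""Resnik semantic similarity with best-match-average aggregation.

Information content (IC) of a class is the negative natural log of its
annotation probability: with propagation (the default), an annotation to
a class counts toward that class and all of its ancestors, so ancestor
probabilities dominate descendant probabilities and IC is anti-monotone
along subclass edges.  The corpus supplying the probabilities is the
very annotation corpus being compared (self-referential IC, the standard
setup for annotation-based patient similarity).

Pairwise similarity between two classes is the IC of their most
informative common ancestor (MICA, Resnik); groupwise similarity between
two annotation sets is the best-match average (BMA):

    BMA(A, B) = 1/2 [ mean_a max_b sim(a, b) + mean_b max_a sim(a, b) ]
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "subclass_graph",
    "ancestors_of",
    "compute_ic",
    "resnik",
    "bma",
    "similarity_matrix",
]


def subclass_graph(subclass_edges: Iterable[tuple[str, str]]) -> nx.DiGraph:
    """Directed graph with child → parent edges."""
    g = nx.DiGraph()
    g.add_edges_from(subclass_edges)
    return g


def ancestors_of(graph: nx.DiGraph, iri: str) -> set[str]:
    """Reflexive ancestor set (the class itself plus all superclasses)."""
    if iri not in graph:
        return {iri}
    return {iri} | nx.descendants(graph, iri)  # edges point child → parent


def _roots(graph: nx.DiGraph) -> set[str]:
    return {n for n in graph.nodes if graph.out_degree(n) == 0}


def compute_ic(
    entity_sets: Mapping[str, set[str]],
    graph: nx.DiGraph,
    propagate: bool = True,
) -> dict[str, float]:
    """IC table from an annotation corpus.

    With ``propagate`` each (entity, class) annotation pair counts toward
    the class and every ancestor; probabilities are counts over the total
    number of (entity, class) pairs.  Classes never reached have
    undefined IC and are absent from the table.  Annotations to classes
    missing from the subclass graph are kept as root-attached leaves
    (they count toward themselves and the graph roots) with a warning.
    """
    total = sum(len(s) for s in entity_sets.values())
    if total == 0:
        raise ValueError("cannot compute IC from an empty annotation corpus")
    roots = _roots(graph)
    missing: set[str] = set()
    counts: dict[str, int] = {}
    for terms in entity_sets.values():
        for iri in terms:
            if iri in graph:
                reached = ancestors_of(graph, iri)
            else:
                missing.add(iri)
                reached = {iri} | roots
            if not propagate:
                reached = {iri}
            for a in reached:
                counts[a] = counts.get(a, 0) + 1
    if missing:
        warnings.warn(
            f"{len(missing)} annotated classes absent from the ontology graph; "
            "treated as root-attached leaves"
        )
    return {iri: -math.log(c / total) for iri, c in counts.items()}


def resnik(
    c1: str,
    c2: str,
    ic_table: Mapping[str, float],
    graph: nx.DiGraph,
) -> float:
    """IC of the most informative common ancestor of ``c1`` and ``c2``.

    A class is its own ancestor, so ``resnik(c, c) = IC(c)`` and
    subsumption pairs score the IC of the subsumer.  Without any common
    ancestor of defined IC the similarity is 0.
    """
    common = ancestors_of(graph, c1) & ancestors_of(graph, c2)
    best = 0.0
    for a in common:
        ic = ic_table.get(a)
        if ic is not None and ic > best:
            best = ic
    return best


def bma(
    set_a: Iterable[str],
    set_b: Iterable[str],
    ic_table: Mapping[str, float],
    graph: nx.DiGraph,
) -> float:
    """Best-match-average groupwise similarity; 0 when either set is empty."""
    a = sorted(set(set_a))
    b = sorted(set(set_b))
    if not a or not b:
        return 0.0
    sims = np.array([[resnik(x, y, ic_table, graph) for y in b] for x in a])
    return 0.5 * (sims.max(axis=1).mean() + sims.max(axis=0).mean())


def similarity_matrix(
    entity_sets: Mapping[str, set[str]],
    ic_table: Mapping[str, float],
    graph: nx.DiGraph,
) -> pd.DataFrame:
    """All-pairs BMA over entity annotation sets (sorted entity order).

    Entities with empty annotation sets get similarity 0 everywhere,
    including on the diagonal.
    """
    ids = sorted(entity_sets)
    used = sorted({iri for s in entity_sets.values() for iri in s})
    pos = {iri: i for i, iri in enumerate(used)}
    # pairwise Resnik between every used class, computed once
    anc = {iri: ancestors_of(graph, iri) for iri in used}
    r = np.zeros((len(used), len(used)))
    for i, x in enumerate(used):
        for j, y in enumerate(used[i:], start=i):
            common = anc[x] & anc[y]
            best = 0.0
            for c in common:
                ic = ic_table.get(c)
                if ic is not None and ic > best:
                    best = ic
            r[i, j] = r[j, i] = best

    idx = {e: np.array([pos[iri] for iri in sorted(entity_sets[e])], dtype=int) for e in ids}
    n = len(ids)
    m = np.zeros((n, n))
    for i, a in enumerate(ids):
        ia = idx[a]
        if ia.size == 0:
            continue
        for j in range(i, n):
            ib = idx[ids[j]]
            if ib.size == 0:
                continue
            block = r[np.ix_(ia, ib)]
            val = 0.5 * (block.max(axis=1).mean() + block.max(axis=0).mean())
            m[i, j] = m[j, i] = val
    return pd.DataFrame(m, index=ids, columns=ids)
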