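"""End-to-end replication pipeline on synthetic data.

Runs the whole study design once per seed: generate a multi-ontology
repository and a note corpus, build the unexpanded (base-ontology-only)
and expanded vocabularies, annotate the corpus with each, compute
self-referential-IC Resnik/BMA similarity matrices, and score both by
how well similarity rankings predict shared primary diagnosis.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass

import pandas as pd

from .annotate import Document, annotate_corpus, compile_lexicon, entity_annotation_sets
from .evaluation import compare_rankings, evaluate_rankings, relevant_pair_ranks
from .expansion import ExpansionResult, PruneConfig, expand_set
from .ontology import Repository
from .similarity import compute_ic, similarity_matrix, subclass_graph
from .simulate import (
    CorpusBlueprint,
    CorpusTruth,
    RepositoryBlueprint,
    RepositoryTruth,
    generate_corpus,
    generate_repository,
)

__all__ = ["ReplicationRun", "run_replication", "annotate_and_rank"]


@dataclass
class ReplicationRun:
    """Outcome of one seed of the expanded-vs-unexpanded comparison."""

    seed: int
    n_labels_base: int
    n_labels_expanded: int
    n_annotations_base: int
    n_annotations_expanded: int
    map_base: float
    map_expanded: float
    mrr_base: float
    mrr_expanded: float
    ranksum_statistic: float
    ranksum_pvalue: float
    repository_truth: RepositoryTruth | None = None
    corpus_truth: CorpusTruth | None = None


def annotate_and_rank(
    vocabulary: ExpansionResult,
    corpus: CorpusTruth,
    repo_truth: RepositoryTruth,
    k: int = 10,
):
    """Annotate the corpus with one vocabulary and rank entities.

    Returns ``(n_annotations, RankingResult, relevant_pair_ranks,
    similarity matrix)``.
    """
    lexicon = compile_lexicon(vocabulary.to_frame())
    documents = [Document(e, d, t) for e, d, t in corpus.documents]
    annotations = annotate_corpus(documents, lexicon)
    sets = entity_annotation_sets(annotations, drop_negated=True)
    for entity in corpus.diagnoses:
        sets.setdefault(entity, set())
    graph = subclass_graph(repo_truth.subclass_edges)
    ic = compute_ic(sets, graph, propagate=True)
    matrix = similarity_matrix(sets, ic, graph)
    result = evaluate_rankings(matrix, corpus.diagnoses, k=k)
    ranks = relevant_pair_ranks(matrix, corpus.diagnoses)
    return len(annotations), result, ranks, matrix


def run_replication(
    seed: int = 0,
    repository_blueprint: RepositoryBlueprint | None = None,
    corpus_blueprint: CorpusBlueprint | None = None,
    k: int = 10,
    keep_truth: bool = False,
    config: PruneConfig = PruneConfig(),
) -> ReplicationRun:
    """One full expanded-vs-unexpanded comparison at the given seed."""
    repo_bp = repository_blueprint or RepositoryBlueprint(seed=seed)
    corpus_bp = corpus_blueprint or CorpusBlueprint(seed=seed)
    if repository_blueprint is None and repo_bp.seed != seed:
        repo_bp = RepositoryBlueprint(**{**repo_bp.__dict__, "seed": seed})

    with tempfile.TemporaryDirectory() as tmp:
        repo_truth = generate_repository(repo_bp, tmp)
        corpus = generate_corpus(corpus_bp, repo_truth)
        repository = repo_truth.load_repository()
        base_only = Repository(
            [d for d in repository.documents if d.ontology_id == repo_truth.base_ontology_id]
        )

        iris = repo_truth.concept_iris()
        vocab_base = expand_set(iris, base_only, config=config)
        vocab_expanded = expand_set(
            iris, repository, config=config, input_ontology=repo_truth.base_ontology_id
        )

        n_base, res_base, ranks_base, _ = annotate_and_rank(
            vocab_base, corpus, repo_truth, k=k
        )
        n_exp, res_exp, ranks_exp, _ = annotate_and_rank(
            vocab_expanded, corpus, repo_truth, k=k
        )
        stat, pvalue = compare_rankings(ranks_exp, ranks_base)

    return ReplicationRun(
        seed=seed,
        n_labels_base=vocab_base.n_labels_after,
        n_labels_expanded=vocab_expanded.n_labels_after,
        n_annotations_base=n_base,
        n_annotations_expanded=n_exp,
        map_base=res_base.map,
        map_expanded=res_exp.map,
        mrr_base=res_base.mrr,
        mrr_expanded=res_exp.mrr,
        ranksum_statistic=stat,
        ranksum_pvalue=pvalue,
        repository_truth=repo_truth if keep_truth else None,
        corpus_truth=corpus if keep_truth else None,
    )


def replication_table(runs: list[ReplicationRun]) -> pd.DataFrame:
    rows = [
        {
            "seed": r.seed,
            "labels_base": r.n_labels_base,
            "labels_expanded": r.n_labels_expanded,
            "annotations_base": r.n_annotations_base,
            "annotations_expanded": r.n_annotations_expanded,
            "map_base": r.map_base,
            "map_expanded": r.map_expanded,
            "mrr_base": r.mrr_base,
            "mrr_expanded": r.mrr_expanded,
            "ranksum_pvalue": r.ranksum_pvalue,
        }
        for r in runs
    ]
    return pd.DataFrame(rows)
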