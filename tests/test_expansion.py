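import random

import pytest

from ontovocab.expansion import (
    CandidateSynonym,
    PruneConfig,
    equivalency_candidates,
    expand_set,
    expand_term,
    lexical_candidates,
    prune,
    write_vocabulary,
)
from ontovocab.ontology import Repository, TermRecord, curie_to_iri
from ontovocab.simulate import RepositoryBlueprint, generate_repository, hypertension_example

from conftest import write_obo


def _input_record(repo, ont, curie):
    return repo.record(ont, curie_to_iri(curie))


class TestLexicalCandidates:
    def test_matching_class_contributes_all_labels_and_synonyms(self, two_ontology_repo):
        rec = _input_record(two_ontology_repo, "BASE", "BASE:0000001")
        cands = lexical_candidates(rec, two_ontology_repo)
        assert {c.text for c in cands} == {"Hypertension", "HTN", "arterial tension"}
        assert all(c.method == "lexical" for c in cands)

    def test_no_shared_label_gives_empty_list(self, bradycardia_repo):
        rec = _input_record(bradycardia_repo, "HP", "HP:0001662")
        assert lexical_candidates(rec, bradycardia_repo) == []

    def test_homonym_synonyms_are_emitted_without_disambiguation(self, tmp_path):
        base = tmp_path / "a.obo"
        hom = tmp_path / "b.obo"
        write_obo(base, "[Term]\nid: A:0000001\nname: cold\n")
        write_obo(hom, '[Term]\nid: B:0000001\nname: cold\nsynonym: "low temperature" EXACT []\n')
        repo = Repository.load([(base, "obo", "A"), (hom, "obo", "B")])
        cands = lexical_candidates(_input_record(repo, "A", "A:0000001"), repo)
        assert "low temperature" in {c.text for c in cands}


class TestEquivalencyCandidates:
    def test_axiom_linked_synonyms_found_only_by_equivalency(self, bradycardia_repo):
        rec = _input_record(bradycardia_repo, "HP", "HP:0001662")
        eq = {c.text for c in equivalency_candidates(rec, bradycardia_repo)}
        lex = {c.text for c in lexical_candidates(rec, bradycardia_repo)}
        assert {"decreased heart rate", "bradyrhythmia", "reduced heart rate"} <= eq
        assert not lex

    def test_singleton_component_gives_empty_list(self, two_ontology_repo):
        rec = _input_record(two_ontology_repo, "BASE", "BASE:0000002")
        assert equivalency_candidates(rec, two_ontology_repo) == []

    def test_shared_iri_reuse_contributes_extra_synonym(self, tmp_path):
        a = tmp_path / "a.obo"
        b = tmp_path / "b.obo"
        write_obo(a, "[Term]\nid: X:0000001\nname: fever\n")
        write_obo(b, '[Term]\nid: X:0000001\nname: pyrexia\nsynonym: "febrile response" EXACT []\n')
        repo = Repository.load([(a, "obo", "A"), (b, "obo", "B")])
        cands = equivalency_candidates(_input_record(repo, "A", "X:0000001"), repo)
        assert {c.text for c in cands} == {"pyrexia", "febrile response"}


def _cand(text, ont="EXT"):
    return CandidateSynonym(text=text, source_ontology=ont, source_iri="I", method="lexical",
                            scope="exact")


class TestPrune:
    RECORD = TermRecord(iri="X", ontology_id="DO", labels=("hypertension",))

    def test_identifier_form_removed(self):
        accepted, removed = prune([_cand("DOID:10763")], self.RECORD)
        assert accepted == [] and removed[0][1] == "identifier"

    def test_substring_removed_shorter_string_kept(self):
        accepted, removed = prune(
            [_cand("pulmonary hypertension"), _cand("high blood pressure")], self.RECORD
        )
        assert [c.text for c in accepted] == ["high blood pressure"]
        assert removed[0][1] == "substring"

    def test_blocked_ontology_removed_first(self):
        # MONDO candidate also has identifier form; blocklist reason wins
        accepted, removed = prune([_cand("MONDO:0001", ont="MONDO")], self.RECORD)
        assert removed[0][1] == "blocked_ontology"

    def test_pseudo_label_removed(self):
        _, removed = prune([_cand("Europe PMC")], self.RECORD)
        assert removed[0][1] == "pseudo_label"

    def test_empty_config_disables_set_based_pruning(self):
        cfg = PruneConfig(blocked_ontologies=frozenset(), blocked_pseudo_labels=frozenset(),
                          identifier_chars=frozenset())
        accepted, removed = prune(
            [_cand("DOID:1"), _cand("elevated pressure", ont="MONDO")], self.RECORD, cfg
        )
        assert len(accepted) == 2 and not removed


class TestExpandTerm:
    def test_hypertension_worked_example_counts(self):
        repo, rec = hypertension_example()
        vocab = expand_term(rec, repo)
        assert vocab.n_unique_accepted == 28
        assert vocab.n_novel == 25
        assert vocab.n_lexical - sum(
            1 for c, r in vocab.removed if c.method == "lexical"
        ) == 56  # 56 lexical candidates beyond the input label itself
        assert vocab.n_equivalency == 14

    def test_identity_case_keeps_only_originals(self, tmp_path):
        p = tmp_path / "solo.obo"
        write_obo(p, '[Term]\nid: S:0000001\nname: fever\nsynonym: "pyrexia" EXACT []\n')
        repo = Repository.load([(p, "obo", "S")])
        vocab = expand_term(_input_record(repo, "S", "S:0000001"), repo)
        assert sorted(vocab.surface_forms()) == ["fever", "pyrexia"]
        assert vocab.n_novel == 0

    def test_originals_bypass_pruning(self, tmp_path):
        # an original synonym containing the first label as substring stays
        p = tmp_path / "solo.obo"
        write_obo(p, '[Term]\nid: S:0000001\nname: fever\nsynonym: "drug fever" EXACT []\n')
        repo = Repository.load([(p, "obo", "S")])
        vocab = expand_term(_input_record(repo, "S", "S:0000001"), repo)
        assert "drug fever" in vocab.surface_forms()

    def test_determinism_byte_identical_tsv(self, tmp_path):
        repo, rec = hypertension_example()
        result = expand_set([rec.iri], repo, input_ontology="DO")
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_vocabulary(result, a)
        write_vocabulary(expand_set([rec.iri], repo, input_ontology="DO"), b)
        assert a.read_bytes() == b.read_bytes()

    def test_monotonicity_adding_an_ontology_never_removes_synonyms(self, tmp_path):
        bp = RepositoryBlueprint(n_concepts=8, n_ontologies=3, seed=5)
        truth = generate_repository(bp, tmp_path)
        full = truth.load_repository()
        smaller = Repository(full.documents[:-1])
        iris = truth.concept_iris()
        before = expand_set(iris, smaller, input_ontology="BASE")
        after = expand_set(iris, full, input_ontology="BASE")
        for iri in iris:
            small_set = {s.lower() for s in before.vocabularies[iri].surface_forms()}
            big_set = {s.lower() for s in after.vocabularies[iri].surface_forms()}
            assert small_set <= big_set


class TestExpandSet:
    def test_empty_iri_list(self, two_ontology_repo):
        result = expand_set([], two_ontology_repo)
        assert result.vocabularies == {} and result.to_frame().empty

    def test_unresolvable_iri_reported_and_run_continues(self, two_ontology_repo):
        result = expand_set(
            ["http://nope", curie_to_iri("BASE:0000001")], two_ontology_repo,
            input_ontology="BASE",
        )
        assert ("http://nope", "unresolvable") in result.skipped
        assert curie_to_iri("BASE:0000001") in result.vocabularies

    def test_planted_ground_truth_recovered(self, tmp_path):
        bp = RepositoryBlueprint(n_concepts=10, n_ontologies=3, seed=11)
        truth = generate_repository(bp, tmp_path)
        repo = truth.load_repository()
        result = expand_set(truth.concept_iris(), repo, input_ontology="BASE")
        for concept in truth.concepts.values():
            vocab = result.vocabularies[concept.iri]
            assert sorted(vocab.novel_surface_forms()) == concept.expected_novel

    def test_equivalency_only_is_subset_of_both(self, tmp_path):
        bp = RepositoryBlueprint(n_concepts=12, n_ontologies=4, seed=3)
        truth = generate_repository(bp, tmp_path)
        repo = truth.load_repository()
        iris = truth.concept_iris()
        both = expand_set(iris, repo, input_ontology="BASE")
        eq_only = expand_set(iris, repo, mode="equivalency_only", input_ontology="BASE")
        for iri in iris:
            assert set(eq_only.vocabularies[iri].surface_forms()) <= set(
                both.vocabularies[iri].surface_forms()
            )


def test_pruning_soundness_on_random_candidates():
    """No accepted non-original synonym may carry an identifier character,
    contain the input first label, or come from a blocked ontology."""
    rng = random.Random(42)
    record = TermRecord(iri="X", ontology_id="DO", labels=("alpha beta",))
    alphabet = ["alpha", "beta", "gamma", "delta", "alpha beta", "alpha beta gamma",
                "DOID:1", "a_b", "europe pmc", "kegg compound", "zeta eta"]
    onts = ["EXT1", "EXT2", "MONDO", "GO-PLUS", "CCONT", "phenX"]
    for _ in range(200):
        cands = [
            _cand(rng.choice(alphabet), ont=rng.choice(onts))
            for _ in range(rng.randint(1, 10))
        ]
        accepted, removed = prune(cands, record)
        assert len(accepted) + len(removed) == len(cands)
        for c in accepted:
            assert ":" not in c.text and "_" not in c.text
            assert "alpha beta" not in c.text.lower()
            assert c.source_ontology not in PruneConfig().blocked_ontologies
            assert c.text.lower() not in PruneConfig().blocked_pseudo_labels
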