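import random

import pytest
from hypothesis import given, settings, strategies as st

from ontovocab.ontology import (
    OntologyDocument,
    Repository,
    TermRecord,
    UnlabelledClassError,
    build_equivalence_graph,
    build_label_index,
    curie_to_iri,
    extract_first_label,
    load_ontology,
    normalize_label,
    read_term_records,
    subclasses_of,
    write_term_records,
)

from conftest import write_obo
from oracles import transitive_equivalence_closure


class TestLoading:
    def test_minimal_obo_document(self, tmp_path):
        p = tmp_path / "t.obo"
        write_obo(p, """\
            [Term]
            id: TST:0000001
            name: fever
            synonym: "pyrexia" EXACT []
            """)
        doc = load_ontology(p, "obo", "TST")
        rec = doc.record(curie_to_iri("TST:0000001"))
        assert rec.labels == ("fever",)
        assert rec.synonyms == (("pyrexia", "exact"),)

    def test_related_scope_synonyms_are_excluded(self, tmp_path):
        p = tmp_path / "t.obo"
        write_obo(p, """\
            [Term]
            id: TST:0000001
            name: fever
            synonym: "temperature" RELATED []
            synonym: "febrile state" NARROW []
            """)
        rec = next(iter(load_ontology(p, "obo", "TST")))
        assert ("temperature", "related") not in rec.synonyms
        assert all(t != "temperature" for t, _ in rec.synonyms)
        assert ("febrile state", "narrow") in rec.synonyms

    def test_rdfxml_class_with_related_synonym(self, tmp_path):
        p = tmp_path / "t.owl"
        p.write_text("""<?xml version="1.0"?>
<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
         xmlns:rdfs="http://www.w3.org/2000/01/rdf-schema#"
         xmlns:owl="http://www.w3.org/2002/07/owl#"
         xmlns:oboInOwl="http://www.geneontology.org/formats/oboInOwl#">
  <owl:Class rdf:about="http://example.org/A">
    <rdfs:label>fever</rdfs:label>
    <oboInOwl:hasExactSynonym>pyrexia</oboInOwl:hasExactSynonym>
    <oboInOwl:hasRelatedSynonym>temperature</oboInOwl:hasRelatedSynonym>
  </owl:Class>
  <owl:Class rdf:about="http://example.org/B">
    <rdfs:label>chill</rdfs:label>
    <owl:equivalentClass rdf:resource="http://example.org/A"/>
  </owl:Class>
</rdf:RDF>""")
        doc = load_ontology(p, "owl_rdfxml", "EX")
        rec = doc.record("http://example.org/A")
        assert ("pyrexia", "exact") in rec.synonyms
        assert all(t != "temperature" for t, _ in rec.synonyms)
        assert ("http://example.org/B", "http://example.org/A") in doc.equivalence_axioms

    def test_obo_equivalence_axiom_read_through(self, tmp_path):
        p = tmp_path / "t.obo"
        write_obo(p, """\
            [Term]
            id: TST:0000001
            name: a
            equivalent_to: OTH:0000009
            """)
        doc = load_ontology(p, "obo", "TST")
        assert (curie_to_iri("TST:0000001"), curie_to_iri("OTH:0000009")) in doc.equivalence_axioms

    def test_unknown_format_and_missing_file(self, tmp_path):
        with pytest.raises(ValueError):
            load_ontology(tmp_path / "x.obo", "turtle", "X")
        from ontovocab.ontology import OntologyLoadError
        with pytest.raises(OntologyLoadError):
            load_ontology(tmp_path / "nope.obo", "obo", "X")


class TestFirstLabel:
    def test_single_label(self):
        rec = TermRecord(iri="X", ontology_id="T", labels=("hypertension",))
        assert extract_first_label(rec) == "hypertension"

    def test_multiple_labels_tie_break_lexicographic(self):
        rec = TermRecord(iri="X", ontology_id="T", labels=("b-label", "a-label"))
        assert extract_first_label(rec) == "a-label"

    def test_no_labels_raises(self):
        rec = TermRecord(iri="X", ontology_id="T")
        with pytest.raises(UnlabelledClassError):
            extract_first_label(rec)


class TestLabelIndex:
    def test_case_insensitive_merge_across_ontologies(self, two_ontology_repo):
        hits = two_ontology_repo.label_index.lookup("HYPERTENSION")
        assert hits == {
            ("BASE", curie_to_iri("BASE:0000001")),
            ("OTHER", curie_to_iri("OTHER:0000001")),
        }

    def test_synonym_and_label_share_a_key(self, two_ontology_repo):
        hits = two_ontology_repo.label_index.lookup("bradycardia")
        assert hits == {
            ("BASE", curie_to_iri("BASE:0000002")),
            ("OTHER", curie_to_iri("OTHER:0000002")),
        }

    def test_empty_repository_gives_empty_index(self):
        assert len(build_label_index([])) == 0

    def test_completeness_over_all_loaded_strings(self, two_ontology_repo):
        for rec in two_ontology_repo:
            for text in rec.all_label_texts():
                assert (rec.ontology_id, rec.iri) in two_ontology_repo.label_index.lookup(text)

    @given(st.text(min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_normalisation_is_idempotent(self, s):
        assert normalize_label(normalize_label(s)) == normalize_label(s)


def _doc(ont, records, axioms=()):
    return OntologyDocument(
        ontology_id=ont,
        source_path="<test>",
        classes={r.iri: r for r in records},
        equivalence_axioms=list(axioms),
    )


class TestEquivalenceGraph:
    def test_shared_iri_plus_axiom_merge(self):
        a = _doc("A", [TermRecord(iri="X", ontology_id="A", labels=("x",))])
        b = _doc(
            "B",
            [TermRecord(iri="X", ontology_id="B", labels=("x2",)),
             TermRecord(iri="Y", ontology_id="B", labels=("y",))],
            axioms=[("X", "Y")],
        )
        g = build_equivalence_graph([a, b])
        assert g.members("A", "X") == {("A", "X"), ("B", "X"), ("B", "Y")}

    def test_no_links_gives_singletons(self):
        a = _doc("A", [TermRecord(iri="X", ontology_id="A", labels=("x",))])
        b = _doc("B", [TermRecord(iri="Y", ontology_id="B", labels=("y",))])
        g = build_equivalence_graph([a, b])
        assert g.members("A", "X") == {("A", "X")}
        assert g.n_components == 2

    def test_transitive_chain_across_documents(self):
        a = _doc(
            "A",
            [TermRecord(iri="X", ontology_id="A", labels=("x",)),
             TermRecord(iri="Y", ontology_id="A", labels=("y",))],
            axioms=[("X", "Y")],
        )
        b = _doc(
            "B",
            [TermRecord(iri="Y", ontology_id="B", labels=("y2",)),
             TermRecord(iri="Z", ontology_id="B", labels=("z",))],
            axioms=[("Y", "Z")],
        )
        g = build_equivalence_graph([a, b])
        assert g.members("A", "X") == {("A", "X"), ("A", "Y"), ("B", "Y"), ("B", "Z")}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_closure_on_random_fixtures(self, seed):
        rng = random.Random(seed)
        n_onts, n_iris = rng.randint(2, 4), rng.randint(5, 15)
        iris = [f"I{i}" for i in range(n_iris)]
        docs = []
        for k in range(n_onts):
            members = rng.sample(iris, rng.randint(1, n_iris))
            recs = [TermRecord(iri=i, ontology_id=f"O{k}", labels=(i.lower(),)) for i in members]
            axioms = [
                tuple(rng.sample(members, 2))
                for _ in range(rng.randint(0, 3))
                if len(members) >= 2
            ]
            docs.append(_doc(f"O{k}", recs, axioms))
        g = build_equivalence_graph(docs)

        nodes = [(d.ontology_id, r.iri) for d in docs for r in d]
        edges = []
        by_iri = {}
        for ont, iri in nodes:
            by_iri.setdefault(iri, []).append((ont, iri))
        for occ in by_iri.values():
            edges.extend(zip(occ, occ[1:]))
        for d in docs:
            for x, y in d.equivalence_axioms:
                for a in by_iri.get(x, []):
                    for b in by_iri.get(y, []):
                        edges.append((a, b))
        expected = transitive_equivalence_closure(nodes, edges)
        for comp in expected:
            node = next(iter(comp))
            assert g.members(*node) == comp


class TestSubclasses:
    def test_chain_and_obsolete_exclusion(self, tmp_path):
        p = tmp_path / "t.obo"
        write_obo(p, """\
            [Term]
            id: T:0000001
            name: root

            [Term]
            id: T:0000002
            name: mid
            is_a: T:0000001

            [Term]
            id: T:0000003
            name: leaf
            is_a: T:0000002

            [Term]
            id: T:0000004
            name: gone
            is_a: T:0000001
            is_obsolete: true
            """)
        doc = load_ontology(p, "obo", "T")
        subs = subclasses_of(doc, curie_to_iri("T:0000001"))
        assert subs == {curie_to_iri("T:0000002"), curie_to_iri("T:0000003")}
        assert subclasses_of(doc, curie_to_iri("T:0000003")) == set()

    def test_unknown_root_raises(self, tmp_path):
        p = tmp_path / "t.obo"
        write_obo(p, "[Term]\nid: T:0000001\nname: root\n")
        doc = load_ontology(p, "obo", "T")
        with pytest.raises(KeyError):
            subclasses_of(doc, "http://nope")


def test_term_record_tsv_round_trip(two_ontology_repo, tmp_path):
    out = tmp_path / "records.tsv"
    write_term_records(two_ontology_repo.documents, out)
    reread = {(r.ontology_id, r.iri): r for r in read_term_records(out)}
    for rec in two_ontology_repo:
        back = reread[(rec.ontology_id, rec.iri)]
        assert back.labels == rec.labels
        assert back.synonyms == rec.synonyms
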