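import textwrap

import pytest

from ontovocab.ontology import Repository, load_ontology


def write_obo(path, body: str) -> None:
    path.write_text("format-version: 1.2\n\n" + textwrap.dedent(body))


@pytest.fixture
def two_ontology_repo(tmp_path):
    """Two small ontologies sharing a first label and an extra synonym link.

    BASE:0000001 'hypertension' also appears (capitalised) in OTHER, which
    contributes two extra synonyms; OTHER:0000002's synonym equals
    BASE:0000002's label.
    """
    base = tmp_path / "base.obo"
    other = tmp_path / "other.obo"
    write_obo(base, """\
        [Term]
        id: BASE:0000001
        name: hypertension
        synonym: "high blood pressure" EXACT []

        [Term]
        id: BASE:0000002
        name: bradycardia
        is_a: BASE:0000001
        """)
    write_obo(other, """\
        [Term]
        id: OTHER:0000001
        name: Hypertension
        synonym: "HTN" EXACT []
        synonym: "arterial tension" EXACT []

        [Term]
        id: OTHER:0000002
        name: slow pulse
        synonym: "bradycardia" EXACT []
        """)
    return Repository.load([(base, "obo", "BASE"), (other, "obo", "OTHER")])


@pytest.fixture
def bradycardia_repo(tmp_path):
    """Equivalence-axiom fixture: synonyms reachable only by equivalency.

    PHENO asserts 'decreased heart rate' ≡ HP's 'bradycardia'; the two
    classes do not share a first label, so lexical matching cannot link
    them.
    """
    hp = tmp_path / "hp.obo"
    pheno = tmp_path / "pheno.obo"
    write_obo(hp, """\
        [Term]
        id: HP:0001662
        name: bradycardia
        synonym: "slow heart rate" EXACT []
        """)
    write_obo(pheno, """\
        [Term]
        id: MP:0005333
        name: decreased heart rate
        synonym: "bradyrhythmia" EXACT []
        synonym: "reduced heart rate" EXACT []
        equivalent_to: HP:0001662
        """)
    return Repository.load([(hp, "obo", "HP"), (pheno, "obo", "PHENO")])
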