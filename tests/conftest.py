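import datetime

import pytest

from lbdnet.corpus import Document, EntityCluster, Lexicon


def make_doc(doc_id, text, year=2003, month=6, day=15):
    return Document(
        id=doc_id, date=datetime.date(year, month, day), text=text
    )


def cluster(rep, category, *synonyms):
    return EntityCluster(
        representative=rep, category=category, synonyms=frozenset(synonyms)
    )


@pytest.fixture
def drug_disease_lexicon():
    """Two categories x two clusters, with multiword synonyms."""
    return Lexicon(
        [
            cluster("aspirin", "drug", "acetylsalicylic acid"),
            cluster("tamoxifen", "drug"),
            cluster(
                "type 2 diabetes", "disease", "diabetes mellitus type 2"
            ),
            cluster("breast cancer", "disease", "breast adenocarcinoma"),
        ]
    )


@pytest.fixture
def four_doc_corpus():
    """Small corpus with controlled entity occurrences for VSM checks."""
    return [
        make_doc("D1", "aspirin aspirin tamoxifen filler words", 2001),
        make_doc("D2", "aspirin and type 2 diabetes studied here", 2002),
        make_doc("D3", "breast cancer treated with tamoxifen tamoxifen", 2003),
        make_doc("D4", "nothing relevant in this record", 2004),
    ]
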