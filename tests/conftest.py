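import datetime as dt

import pytest

from crisnss.corpus import Document
from crisnss.lexicon import Lexicon, RuleSet


@pytest.fixture(scope="session")
def lexicon() -> Lexicon:
    return Lexicon.default()


@pytest.fixture(scope="session")
def rules() -> RuleSet:
    return RuleSet()


def make_doc(
    text: str,
    doc_id: str = "d1",
    patient_id: str = "p1",
    date: dt.date = dt.date(2010, 6, 1),
) -> Document:
    return Document(doc_id=doc_id, patient_id=patient_id, date=date, text=text)


@pytest.fixture
def doc_factory():
    return make_doc
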