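import numpy as np
import pytest

from pamflow.model import GenomeRecord, SearchParams


@pytest.fixture
def params():
    return SearchParams()


@pytest.fixture
def rng():
    return np.random.default_rng(20230623)


def make_subject(seq, sid="subj", title="", **kw):
    return GenomeRecord(id=sid, title=title, sequence=seq, **kw)


@pytest.fixture
def make_record():
    return make_subject
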