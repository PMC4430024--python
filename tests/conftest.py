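import numpy as np
import pytest

from crossreg import motif, seqio


@pytest.fixture(scope="session")
def bundled():
    """Bundled synthetic matrices, keyed by TF name."""
    return {p.tf_name: p for p in motif.bundled_pfms()}


@pytest.fixture()
def rng():
    return np.random.default_rng(20150417)


def make_record(seq, rec_id="s", **kw):
    return seqio.SequenceRecord(id=rec_id, seq=seq, **kw)


@pytest.fixture()
def record_factory():
    return make_record
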