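import numpy as np
import pytest

from myxocol.seqio import HspRecord


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_hsp(
    query_id="c1",
    subject_id="s1",
    pct_identity=95.0,
    q_start=1,
    q_end=100,
    evalue=1e-30,
    bitscore=180.0,
    **kw,
):
    return HspRecord(
        query_id=query_id,
        subject_id=subject_id,
        pct_identity=pct_identity,
        aln_len=q_end - q_start + 1,
        mismatches=kw.get("mismatches", 0),
        gap_opens=kw.get("gap_opens", 0),
        q_start=q_start,
        q_end=q_end,
        s_start=kw.get("s_start", q_start),
        s_end=kw.get("s_end", q_end),
        evalue=evalue,
        bitscore=bitscore,
    )


@pytest.fixture
def hsp_factory():
    return make_hsp
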