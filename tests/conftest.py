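import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from trbdyn.repertoire import (
    Compartment,
    FrameStatus,
    RearrangementRecord,
    Repertoire,
    Sex,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_record(nt="ACGTACGTACGT", count=1, **kw):
    defaults = dict(
        v_call="TRBV02-01",
        d_call="TRBD01-01",
        j_call="TRBJ01-01",
        frame_status=FrameStatus.IN_FRAME,
        cdr3_start=3,
        n2_start=6,
    )
    defaults.update(kw)
    return RearrangementRecord(nucleotide=nt, copy_count=count, **defaults)


@pytest.fixture
def toy_repertoire():
    """Three records, copy counts (5, 3, 2): the worked micro-example."""
    records = [
        make_record("AAACCCGGGTTT", 5),
        make_record("CCCGGGTTTAAA", 3, frame_status=FrameStatus.OUT_OF_FRAME),
        make_record("GGGTTTAAACCC", 2, frame_status=FrameStatus.STOP_CODON),
    ]
    return Repertoire(
        sample_id="toy",
        records=records,
        donor_id="d1",
        age=30,
        sex=Sex.FEMALE,
        compartment=Compartment.WHOLE_BLOOD,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20230913)
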