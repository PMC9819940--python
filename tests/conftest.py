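import numpy as np
import pytest

from azoband import ExcitationEntry, SnapshotRecord


@pytest.fixture
def two_snapshot_records():
    """Hand-checkable fixture: two snapshots, one S1 state each.

    With bin edges {1.75, 2.25, 2.75} the raw f/ΔE histogram is
    {0.1/2.0, 0.2/2.5} = {0.05, 0.08}; normalized {0.625, 1.0}.
    """
    return [
        SnapshotRecord("snap-1", 10.0,
                       (ExcitationEntry(1, 2.0, 0.1),)),
        SnapshotRecord("snap-2", 20.0,
                       (ExcitationEntry(1, 2.5, 0.2),)),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
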