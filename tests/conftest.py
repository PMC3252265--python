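import numpy as np
import pandas as pd
import pytest

from resic import (
    AlterationEvent,
    EventKind,
    EventMatrix,
    OncogenicDirection,
    SampleGenotype,
    load_gbm_pathways,
)
from resic.simulate import binary_events


@pytest.fixture(scope="session")
def gbm_pathways():
    return {p.name: p for p in load_gbm_pathways()}


@pytest.fixture
def pair_events():
    """Two binary pathway-style events with equal mutation rates."""
    return binary_events(["A", "B"])


@pytest.fixture
def triple_events():
    return binary_events(["A", "B", "C"])


@pytest.fixture
def gene_events_two_level():
    """Two gene-level events with two allelic levels each."""
    return [
        AlterationEvent(
            id="EGFR_amp",
            kind=EventKind.focal_amplification,
            genes=("EGFR",),
            oncogenic_direction=OncogenicDirection.gain_of_signal,
            allelic_levels=2,
        ),
        AlterationEvent(
            id="PTEN_del",
            kind=EventKind.focal_deletion,
            genes=("PTEN",),
            oncogenic_direction=OncogenicDirection.loss_of_signal,
            allelic_levels=2,
        ),
    ]


def make_matrix(levels: dict[str, list[int]], events) -> EventMatrix:
    n = len(next(iter(levels.values())))
    idx = [f"S{i:03d}" for i in range(n)]
    return EventMatrix(pd.DataFrame(levels, index=idx), events)


@pytest.fixture
def make_event_matrix():
    return make_matrix


@pytest.fixture
def genotype():
    def _make(sample_id="S1", **calls):
        return SampleGenotype(sample_id=sample_id, cna_call=dict(calls))

    return _make
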