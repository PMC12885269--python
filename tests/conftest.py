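import numpy as np
import pandas as pd
import pytest

import depscore as d
from depscore import pipeline


@pytest.fixture(scope="session")
def depression23():
    return d.builtin_set("depression23")


@pytest.fixture(scope="session")
def small_study():
    """Small synthetic study (30 train / 10 + 10 test) shared across tests."""
    return d.generate_study(seed=7, n_train=30, n_test1=10, n_test2=10)


@pytest.fixture(scope="session")
def small_partitions(small_study, depression23):
    fm = small_study["features"]
    return pipeline.partition_frames(
        fm, small_study["labels"], small_study["split"], depression23.qids
    )


@pytest.fixture()
def two_turn_transcript():
    return d.Transcript(
        participant_id="t1",
        utterances=[
            d.Utterance(speaker="interviewer", text="hi"),
            d.Utterance(speaker="participant", text="hello"),
        ],
    )
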