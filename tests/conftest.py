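import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

# reproducible property tests regardless of any example database state
settings.register_profile("resogest", derandomize=True)
settings.load_profile("resogest")

from resogest.corpus import (
    EDATrace,
    GestureAnnotation,
    IPU,
    Participant,
    QuoteSpan,
    Recording,
    Story,
)
from resogest.eda import append_eda_outcomes, build_response_table
from resogest.features import build_feature_table
from resogest.simulate import SimConfig, simulate_corpus


def make_tables(cfg: SimConfig):
    """Simulate a corpus and run it through features + EDA outcomes.

    Returns (feature_table, response_table, recordings).
    """
    recs = simulate_corpus(cfg)
    tables, resp = [], []
    for r in recs:
        t = build_feature_table(
            r.recording, r.stories, r.gestures, r.ipus, r.quotes
        )
        t = append_eda_outcomes(t, r.gestures, r.traces)
        resp.append(build_response_table(t, r.gestures, r.traces))
        tables.append(t)
    return (
        pd.concat(tables, ignore_index=True),
        pd.concat(resp, ignore_index=True),
        recs,
    )


def simple_gesture(
    gid="g1", story="s1", onset=10.0, offset=13.0,
    nucleus=(10.4, 12.0), hold=None,
    SZ=False, FO=False, CV=False, SL=False, MA=False,
):
    phases = [("preparation", onset, nucleus[0]),
              ("nucleus", nucleus[0], nucleus[1])]
    cur = nucleus[1]
    if hold is not None:
        phases.append(("hold", cur, cur + hold))
        cur += hold
    phases.append(("retraction", cur, offset))
    return GestureAnnotation(
        id=gid, story_id=story, onset=onset, offset=offset, phases=phases,
        coded_SZ=SZ, coded_FO=FO, coded_CV=CV, coded_SL=SL, coded_MA=MA,
    )


@pytest.fixture(scope="session")
def small_recording():
    """A tiny hand-built recording: 1 dyad, 1 story, 3 gestures."""
    recording = Recording(
        id="rec1",
        participants=[Participant("pA", "female"), Participant("pB", "male")],
        group_compose="mixed",
        duration=60.0,
    )
    story = Story(
        id="s1", recording_id="rec1", narrator_id="pA",
        onset=5.0, offset=40.0, climax_onset=30.0, climax_offset=40.0,
        protagonist="narrator", recency="recent",
    )
    gestures = [
        simple_gesture("g1", onset=8.0, offset=11.0, nucleus=(8.4, 9.4),
                       SZ=True),
        simple_gesture("g2", onset=15.0, offset=18.5, nucleus=(15.4, 17.4),
                       hold=0.5, FO=True),
        simple_gesture("g3", onset=31.0, offset=34.0, nucleus=(31.4, 33.4)),
    ]
    ipus = [
        IPU("u1", "s1", 7.0, 12.0, ["a", "b", "c"], [0.5, -0.1, 0.2]),
        IPU("u2", "s1", 14.0, 19.0, ["d", "e"], [-0.4, -0.6]),
    ]
    quotes = [QuoteSpan("s1", 31.5, 33.0)]
    return recording, [story], gestures, ipus, quotes


@pytest.fixture(scope="session")
def flat_traces():
    """Constant 2 uS traces for both participants of `small_recording`."""
    return {
        pid: EDATrace(pid, [2.0] * 240, sampling_rate=4.0, t0=0.0)
        for pid in ("pA", "pB")
    }
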