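"""Domain-type invariants and round-trip fidelity of the file dialects."""

import numpy as np
import pytest

from resogest.corpus import (
    EDATrace,
    GestureAnnotation,
    Participant,
    Recording,
    Story,
    ValidationError,
    ParseError,
    validate_referential_integrity,
)
from resogest.io import (
    read_annotations,
    read_eda,
    read_recording,
    read_feature_table,
    write_annotations,
    write_eda,
    write_feature_table,
)
from resogest.features import build_feature_table
from resogest.simulate import SimConfig, simulate_recording

from conftest import simple_gesture


# ---------------------------------------------------------------------------
# type invariants


def test_recording_group_size_must_be_2_or_3():
    with pytest.raises(ValidationError):
        Recording("r", [Participant("p1")], "mixed", 10.0)


def test_recording_compose_must_match_sexes():
    with pytest.raises(ValidationError):
        Recording(
            "r",
            [Participant("p1", "female"), Participant("p2", "female")],
            "all-male",
            10.0,
        )


def test_diverse_sex_combination_is_mixed():
    rec = Recording(
        "r",
        [Participant("p1", "diverse/NA"), Participant("p2", "female")],
        "mixed",
        10.0,
    )
    assert rec.group_size == 2


def test_story_climax_ordering_enforced():
    with pytest.raises(ValidationError):
        Story("s", "r", "p", onset=10.0, offset=20.0,
              climax_onset=25.0, climax_offset=20.0)


def test_gesture_phase_outside_span_rejected():
    with pytest.raises(ValidationError, match="gx"):
        GestureAnnotation(
            id="gx", story_id="s", onset=1.0, offset=2.0,
            phases=[("nucleus", 1.0, 2.5)],
            coded_SZ=False, coded_FO=False, coded_CV=False,
            coded_SL=False, coded_MA=False,
        )


def test_gesture_requires_nucleus():
    with pytest.raises(ValidationError, match="nucleus"):
        GestureAnnotation(
            id="gy", story_id="s", onset=1.0, offset=2.0,
            phases=[("preparation", 1.0, 2.0)],
            coded_SZ=False, coded_FO=False, coded_CV=False,
            coded_SL=False, coded_MA=False,
        )


def test_eda_trace_range_enforced():
    with pytest.raises(ValidationError):
        EDATrace("p", [2.0, 150.0, 2.0])


def test_referential_integrity_catches_orphan_gesture(small_recording):
    recording, stories, gestures, ipus, quotes = small_recording
    orphan = simple_gesture("g9", story="nope", onset=50.0, offset=52.0,
                            nucleus=(50.4, 51.4))
    with pytest.raises(ValidationError, match="g9"):
        validate_referential_integrity(
            recording, stories, gestures + [orphan], ipus, quotes
        )


# ---------------------------------------------------------------------------
# tabular dialect round trip


def test_tabular_round_trip_preserves_boundaries(tmp_path, small_recording):
    recording, stories, gestures, ipus, quotes = small_recording
    write_annotations(tmp_path / "rec", recording, stories, gestures,
                      ipus, quotes)
    stories2, gestures2, ipus2, quotes2 = read_annotations(
        tmp_path / "rec", "tabular"
    )
    assert [s.onset for s in stories2] == [s.onset for s in stories]
    for g, g2 in zip(gestures, gestures2):
        assert g2.id == g.id
        assert g2.onset == pytest.approx(g.onset, abs=1e-3)
        assert [p[0] for p in g2.phases] == [p[0] for p in g.phases]
        assert [p[1:] for p in g2.phases] == pytest.approx(
            [p[1:] for p in g.phases], abs=1e-3
        )
        assert (g2.coded_SZ, g2.coded_FO) == (g.coded_SZ, g.coded_FO)
    assert [u.word_sentiments for u in ipus2] == [
        u.word_sentiments for u in ipus
    ]
    assert [q.start for q in quotes2] == pytest.approx(
        [q.start for q in quotes], abs=1e-3
    )
    rec2 = read_recording(tmp_path / "rec")
    assert rec2.id == recording.id
    assert rec2.group_size == recording.group_size


def test_simulated_recording_round_trips(tmp_path):
    rec = simulate_recording(
        SimConfig(stories_per_recording=2, gestures_per_story=(3, 6), seed=7)
    )
    write_annotations(tmp_path / "r", rec.recording, rec.stories,
                      rec.gestures, rec.ipus, rec.quotes)
    stories2, gestures2, _, _ = read_annotations(tmp_path / "r")
    assert len(stories2) == len(rec.stories)
    assert [g.id for g in gestures2] == [g.id for g in rec.gestures]
    for g, g2 in zip(rec.gestures, gestures2):
        assert g2.nucleus_duration == pytest.approx(
            g.nucleus_duration, abs=2e-3
        )


# ---------------------------------------------------------------------------
# EAF dialect

EAF_TEMPLATE = """<?xml version="1.0" encoding="UTF-8"?>
<ANNOTATION_DOCUMENT xmlns:rg="urn:resogest" rg:recording="rec1"
    AUTHOR="" DATE="2024-01-01T00:00:00+00:00" FORMAT="3.0" VERSION="3.0">
  <TIME_ORDER>
    {slots}
  </TIME_ORDER>
  {tiers}
</ANNOTATION_DOCUMENT>
"""


def _eaf(tmp_path, slot_ms, tier_annotations):
    slots = "\n".join(
        f'<TIME_SLOT TIME_SLOT_ID="ts{i}" TIME_VALUE="{ms}"/>'
        for i, ms in enumerate(slot_ms)
    )
    tiers = []
    for tier_id, anns in tier_annotations.items():
        body = "\n".join(
            f'<ANNOTATION><ALIGNABLE_ANNOTATION ANNOTATION_ID="a{tier_id}{k}"'
            f' TIME_SLOT_REF1="ts{i1}" TIME_SLOT_REF2="ts{i2}">'
            f"<ANNOTATION_VALUE>{value}</ANNOTATION_VALUE>"
            "</ALIGNABLE_ANNOTATION></ANNOTATION>"
            for k, (i1, i2, value) in enumerate(anns)
        )
        tiers.append(
            f'<TIER LINGUISTIC_TYPE_REF="t" TIER_ID="{tier_id}">{body}</TIER>'
        )
    path = tmp_path / "rec1.eaf"
    path.write_text(
        EAF_TEMPLATE.format(slots=slots, tiers="\n".join(tiers)),
        encoding="utf-8",
    )
    return path


CODES = "SZ=yes;FO=no;CV=no;SL=no;MA=no"


def test_eaf_fixture_one_story_two_gestures(tmp_path):
    # slots (ms): story 5000-40000, g1 8000-11000, g2 15000-18000
    path = _eaf(
        tmp_path,
        [5000, 40000, 8000, 11000, 15000, 18000, 8000, 10500, 15000, 17500],
        {
            "stories": [(0, 1, "s1|pA|30000|40000|narrator|recent")],
            "gestures": [(2, 3, f"g1|s1|{CODES}|"),
                         (4, 5, f"g2|s1|{CODES}|")],
            "phases": [(6, 7, "g1|nucleus"), (8, 9, "g2|nucleus")],
        },
    )
    stories, gestures, ipus, quotes = read_annotations(path, "eaf")
    assert len(stories) == 1 and stories[0].recording_id == "rec1"
    assert [g.id for g in gestures] == ["g1", "g2"]
    assert [g.onset for g in gestures] == [8.0, 15.0]
    assert gestures[0].coded_SZ and not gestures[0].coded_FO
    assert ipus == [] and quotes == []


def test_eaf_empty_gesture_tier_yields_empty_list(tmp_path):
    path = _eaf(
        tmp_path,
        [5000, 40000],
        {"stories": [(0, 1, "s1|pA|30000|40000")], "gestures": []},
    )
    stories, gestures, _, _ = read_annotations(path, "eaf")
    assert len(stories) == 1
    assert gestures == []


def test_eaf_phase_past_gesture_offset_is_validation_error(tmp_path):
    path = _eaf(
        tmp_path,
        [5000, 40000, 8000, 11000, 8000, 12000],
        {
            "stories": [(0, 1, "s1|pA|30000|40000")],
            "gestures": [(2, 3, f"g1|s1|{CODES}|")],
            "phases": [(4, 5, "g1|nucleus")],
        },
    )
    with pytest.raises(ValidationError, match="g1"):
        read_annotations(path, "eaf")


def test_eaf_malformed_payload_names_tier(tmp_path):
    path = _eaf(
        tmp_path, [0, 1000], {"stories": [(0, 1, "only-one-field")]}
    )
    with pytest.raises(ParseError, match="stories"):
        read_annotations(path, "eaf")


# ---------------------------------------------------------------------------
# EDA CSV


def test_read_eda_duration_arithmetic(tmp_path):
    trace = EDATrace("pA", [2.0, 2.1, 2.2, 2.1, 2.0, 2.0, 2.1, 2.2])
    write_eda(trace, tmp_path / "eda.csv")
    back = read_eda(tmp_path / "eda.csv")
    assert len(back) == 8
    assert back.sampling_rate == 4.0
    assert back.t_end - back.t0 == pytest.approx(2.0)


def test_read_eda_out_of_range_names_sample(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text(
        "participant,t0,rate,value\npA,0,4,2.0\npA,0,4,150\npA,0,4,2.0\n"
    )
    with pytest.raises(ValidationError, match="sample 1"):
        read_eda(p)


def test_read_eda_non_numeric_is_parse_error(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("participant,t0,rate,value\npA,0,4,2.0\npA,0,4,oops\n")
    with pytest.raises(ParseError):
        read_eda(p)


def test_eda_round_trip_exact(tmp_path):
    rng = np.random.default_rng(0)
    values = list(np.round(rng.uniform(0.5, 5.0, 50), 6))
    trace = EDATrace("pX", values, sampling_rate=4.0, t0=2.5)
    write_eda(trace, tmp_path / "t.csv")
    back = read_eda(tmp_path / "t.csv")
    assert back.participant_id == "pX"
    assert back.t0 == 2.5
    assert back.values == values


# ---------------------------------------------------------------------------
# feature table


def _table(small_recording):
    recording, stories, gestures, ipus, quotes = small_recording
    return build_feature_table(recording, stories, gestures, ipus, quotes)


def test_feature_table_rows_and_round_trip(tmp_path, small_recording):
    table = _table(small_recording)
    path = tmp_path / "feat.csv"
    write_feature_table(table, path)
    assert len(path.read_text().strip().splitlines()) == len(table) + 1
    back = read_feature_table(path)
    assert list(back.columns)[: len(table.columns)] == list(table.columns)
    for col in table.columns:
        assert list(back[col]) == list(table[col]), col


def test_feature_table_accepts_dataclass_records(tmp_path):
    from resogest.features import GestureFeatureRecord

    rec = GestureFeatureRecord(
        gesture_id="g1", story_id="s1", recording_id="r1",
        narrator_id="pA", SZ=1, FO=0, CV=0, SL=0, HO=0, MA=0, ND=1,
        G_expressivity=2 / 7, G_position_rel=0.5, G_quote=0,
        Sentiment=0.1, protagonist="narrator", recency="recent",
        group_size=2, group_compose="mixed",
    )
    write_feature_table([rec], tmp_path / "one.csv")
    back = read_feature_table(tmp_path / "one.csv")
    assert back.loc[0, "G_expressivity"] == 2 / 7


def test_feature_table_empty_rejected(tmp_path):
    with pytest.raises(ValueError, match="empty"):
        write_feature_table([], tmp_path / "x.csv")


def test_feature_table_duplicate_ids_rejected(tmp_path, small_recording):
    table = _table(small_recording)
    import pandas as pd

    dup = pd.concat([table, table.iloc[[0]]], ignore_index=True)
    with pytest.raises(ValueError, match="duplicate"):
        write_feature_table(dup, tmp_path / "x.csv")
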