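"""Readers and writers for annotation tiers, EDA traces and feature tables.

Two annotation dialects are supported:

``tabular``
    A directory of UTF-8 CSV files, one per tier, with all times in integer
    or fractional *milliseconds* (the ELAN time base): ``recording.csv``,
    ``participants.csv``, ``stories.csv``, ``gestures.csv``, ``phases.csv``,
    ``ipus.csv``, ``quotes.csv``.  This is the package's canonical on-disk
    format; the synthetic generator writes it and tests round-trip it.

``eaf``
    A thin adapter for ELAN ``.eaf`` XML files carrying the same information
    on five tiers named ``stories``, ``gestures``, ``phases``, ``ipus`` and
    ``quotes``.  Annotation values encode the non-temporal fields as
    ``|``-separated payloads (see the tier notes on each ``_eaf_*`` helper).

Times are converted to seconds on read and back to milliseconds on write, so
parse -> serialize preserves boundaries to the millisecond.
"""

from __future__ import annotations

import csv
import io as _stdlib_io
from pathlib import Path

import pandas as pd
from lxml import etree

from .corpus import (
    EDA_RANGE,
    EDATrace,
    GestureAnnotation,
    IPU,
    ParseError,
    Participant,
    QuoteSpan,
    Recording,
    Story,
    ValidationError,
)

__all__ = [
    "read_annotations",
    "write_annotations",
    "read_recording",
    "read_eda",
    "write_eda",
    "FEATURE_COLUMNS",
    "OUTCOME_COLUMNS",
    "write_feature_table",
    "read_feature_table",
]

_MS = 1000.0

TIER_FILES = {
    "recording": "recording.csv",
    "participants": "participants.csv",
    "stories": "stories.csv",
    "gestures": "gestures.csv",
    "phases": "phases.csv",
    "ipus": "ipus.csv",
    "quotes": "quotes.csv",
}


def _read_tier_csv(path: Path, required: tuple[str, ...]) -> list[dict]:
    if not path.exists():
        return []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        missing = set(required) - set(reader.fieldnames)
        if missing:
            raise ParseError(
                f"{path.name}: missing columns {sorted(missing)}"
            )
        return list(reader)


def _bool(s: str, where: str) -> bool:
    v = s.strip().lower()
    if v in ("yes", "1", "true"):
        return True
    if v in ("no", "0", "false"):
        return False
    raise ParseError(f"{where}: expected yes/no, got {s!r}")


# ---------------------------------------------------------------------------
# tabular dialect


def _read_tabular(
    root: Path,
) -> tuple[list[Story], list[GestureAnnotation], list[IPU], list[QuoteSpan]]:
    stories = [
        Story(
            id=row["story_id"],
            recording_id=row["recording_id"],
            narrator_id=row["narrator_id"],
            onset=float(row["onset_ms"]) / _MS,
            offset=float(row["offset_ms"]) / _MS,
            climax_onset=float(row["climax_onset_ms"]) / _MS,
            climax_offset=float(row["climax_offset_ms"]) / _MS,
            protagonist=row.get("protagonist", "narrator"),
            recency=row.get("recency", "recent"),
        )
        for row in _read_tier_csv(
            root / TIER_FILES["stories"],
            ("story_id", "recording_id", "narrator_id", "onset_ms",
             "offset_ms", "climax_onset_ms", "climax_offset_ms"),
        )
    ]

    phases_by_gesture: dict[str, list[tuple[str, float, float]]] = {}
    for row in _read_tier_csv(
        root / TIER_FILES["phases"],
        ("gesture_id", "phase", "start_ms", "end_ms"),
    ):
        phases_by_gesture.setdefault(row["gesture_id"], []).append(
            (row["phase"], float(row["start_ms"]) / _MS,
             float(row["end_ms"]) / _MS)
        )
    for segs in phases_by_gesture.values():
        segs.sort(key=lambda p: p[1])

    gestures = [
        GestureAnnotation(
            id=row["gesture_id"],
            story_id=row["story_id"],
            onset=float(row["onset_ms"]) / _MS,
            offset=float(row["offset_ms"]) / _MS,
            phases=phases_by_gesture.get(row["gesture_id"], []),
            coded_SZ=_bool(row["SZ"], f"gesture {row['gesture_id']} SZ"),
            coded_FO=_bool(row["FO"], f"gesture {row['gesture_id']} FO"),
            coded_CV=_bool(row["CV"], f"gesture {row['gesture_id']} CV"),
            coded_SL=_bool(row["SL"], f"gesture {row['gesture_id']} SL"),
            coded_MA=_bool(row["MA"], f"gesture {row['gesture_id']} MA"),
            description=row.get("description", ""),
        )
        for row in _read_tier_csv(
            root / TIER_FILES["gestures"],
            ("gesture_id", "story_id", "onset_ms", "offset_ms",
             "SZ", "FO", "CV", "SL", "MA"),
        )
    ]

    ipus = []
    for row in _read_tier_csv(
        root / TIER_FILES["ipus"],
        ("ipu_id", "story_id", "start_ms", "end_ms", "words",
         "word_sentiments"),
    ):
        words = row["words"].split() if row["words"].strip() else []
        sents = (
            [float(x) for x in row["word_sentiments"].split()]
            if row["word_sentiments"].strip()
            else []
        )
        ipus.append(
            IPU(
                id=row["ipu_id"],
                story_id=row["story_id"],
                start=float(row["start_ms"]) / _MS,
                end=float(row["end_ms"]) / _MS,
                words=words,
                word_sentiments=sents,
            )
        )

    quotes = [
        QuoteSpan(
            story_id=row["story_id"],
            start=float(row["start_ms"]) / _MS,
            end=float(row["end_ms"]) / _MS,
        )
        for row in _read_tier_csv(
            root / TIER_FILES["quotes"], ("story_id", "start_ms", "end_ms")
        )
    ]
    return stories, gestures, ipus, quotes


def read_recording(path: str | Path) -> Recording:
    """Read recording + participant metadata from a tabular tier directory."""
    root = Path(path)
    rec_rows = _read_tier_csv(
        root / TIER_FILES["recording"],
        ("recording_id", "duration_ms", "group_compose"),
    )
    if len(rec_rows) != 1:
        raise ParseError(
            f"{TIER_FILES['recording']}: expected exactly one row, "
            f"got {len(rec_rows)}"
        )
    participants = [
        Participant(id=row["participant_id"], sex=row.get("sex", "unknown"))
        for row in _read_tier_csv(
            root / TIER_FILES["participants"], ("participant_id",)
        )
    ]
    row = rec_rows[0]
    return Recording(
        id=row["recording_id"],
        participants=participants,
        group_compose=row["group_compose"],
        duration=float(row["duration_ms"]) / _MS,
    )


def write_annotations(
    path: str | Path,
    recording: Recording,
    stories: list[Story],
    gestures: list[GestureAnnotation],
    ipus: list[IPU] = (),
    quotes: list[QuoteSpan] = (),
) -> None:
    """Write a tabular tier directory (times back in milliseconds)."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)

    def dump(name: str, header: list[str], rows: list[list]) -> None:
        with open(root / TIER_FILES[name], "w", newline="",
                  encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(header)
            w.writerows(rows)

    def ms(t: float) -> float:
        return round(t * _MS, 6)

    dump("recording",
         ["recording_id", "duration_ms", "group_compose"],
         [[recording.id, ms(recording.duration), recording.group_compose]])
    dump("participants", ["participant_id", "sex"],
         [[p.id, p.sex] for p in recording.participants])
    dump("stories",
         ["story_id", "recording_id", "narrator_id", "onset_ms", "offset_ms",
          "climax_onset_ms", "climax_offset_ms", "protagonist", "recency"],
         [[s.id, s.recording_id, s.narrator_id, ms(s.onset), ms(s.offset),
           ms(s.climax_onset), ms(s.climax_offset), s.protagonist, s.recency]
          for s in stories])
    dump("gestures",
         ["gesture_id", "story_id", "onset_ms", "offset_ms",
          "SZ", "FO", "CV", "SL", "MA", "description"],
         [[g.id, g.story_id, ms(g.onset), ms(g.offset)]
          + ["yes" if b else "no"
             for b in (g.coded_SZ, g.coded_FO, g.coded_CV, g.coded_SL,
                       g.coded_MA)]
          + [g.description]
          for g in gestures])
    dump("phases", ["gesture_id", "phase", "start_ms", "end_ms"],
         [[g.id, lab, ms(s), ms(e)]
          for g in gestures for lab, s, e in g.phases])
    dump("ipus",
         ["ipu_id", "story_id", "start_ms", "end_ms", "words",
          "word_sentiments"],
         [[u.id, u.story_id, ms(u.start), ms(u.end), " ".join(u.words),
           " ".join(repr(float(x)) for x in u.word_sentiments)]
          for u in ipus])
    dump("quotes", ["story_id", "start_ms", "end_ms"],
         [[q.story_id, ms(q.start), ms(q.end)] for q in quotes])


# ---------------------------------------------------------------------------
# EAF dialect

def _read_eaf(
    path: Path,
) -> tuple[list[Story], list[GestureAnnotation], list[IPU], list[QuoteSpan]]:
    """Parse an ELAN .eaf file using the package's tier conventions.

    Tier payloads (ANNOTATION_VALUE, fields ``|``-separated):

    - ``stories``:  id|narrator_id|climax_onset_ms|climax_offset_ms|protagonist|recency
      (recording_id lives in the document's MEDIA or is supplied externally;
      here it is read from the header attribute ``resogest:recording`` when
      present, else the file stem is used)
    - ``gestures``: id|story_id|SZ=yes;FO=no;CV=no;SL=no;MA=no|description
    - ``phases``:   gesture_id|label
    - ``ipus``:     id|story_id|word word ...|score score ...
    - ``quotes``:   story_id
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"{path.name}: not well-formed EAF XML: {exc}")
    root = tree.getroot()

    slots: dict[str, float] = {}
    for ts in root.iter("TIME_SLOT"):
        val = ts.get("TIME_VALUE")
        if val is not None:
            slots[ts.get("TIME_SLOT_ID")] = float(val) / _MS

    rec_id = root.get("{urn:resogest}recording") or path.stem

    tiers: dict[str, list[tuple[float, float, str]]] = {}
    for tier in root.iter("TIER"):
        tid = tier.get("TIER_ID")
        anns = []
        for ann in tier.iter("ALIGNABLE_ANNOTATION"):
            r1, r2 = ann.get("TIME_SLOT_REF1"), ann.get("TIME_SLOT_REF2")
            if r1 not in slots or r2 not in slots:
                raise ParseError(
                    f"{path.name}: tier {tid}: dangling time-slot reference"
                )
            value_el = ann.find("ANNOTATION_VALUE")
            value = value_el.text if value_el is not None else ""
            anns.append((slots[r1], slots[r2], value or ""))
        anns.sort(key=lambda a: a[0])
        tiers[tid] = anns

    def fields(value: str, n_min: int, tier: str) -> list[str]:
        parts = value.split("|")
        if len(parts) < n_min:
            raise ParseError(
                f"{path.name}: tier {tier}: malformed payload {value!r}"
            )
        return parts

    stories = []
    for start, end, value in tiers.get("stories", []):
        f = fields(value, 4, "stories")
        stories.append(
            Story(
                id=f[0], recording_id=rec_id, narrator_id=f[1],
                onset=start, offset=end,
                climax_onset=float(f[2]) / _MS,
                climax_offset=float(f[3]) / _MS,
                protagonist=f[4] if len(f) > 4 else "narrator",
                recency=f[5] if len(f) > 5 else "recent",
            )
        )

    phases_by_gesture: dict[str, list[tuple[str, float, float]]] = {}
    for start, end, value in tiers.get("phases", []):
        f = fields(value, 2, "phases")
        phases_by_gesture.setdefault(f[0], []).append((f[1], start, end))

    gestures = []
    for start, end, value in tiers.get("gestures", []):
        f = fields(value, 3, "gestures")
        codes = {}
        for item in f[2].split(";"):
            key, _, val = item.partition("=")
            codes[key.strip()] = _bool(val, f"gesture {f[0]} {key}")
        try:
            gestures.append(
                GestureAnnotation(
                    id=f[0], story_id=f[1], onset=start, offset=end,
                    phases=sorted(phases_by_gesture.get(f[0], []),
                                  key=lambda p: p[1]),
                    coded_SZ=codes["SZ"], coded_FO=codes["FO"],
                    coded_CV=codes["CV"], coded_SL=codes["SL"],
                    coded_MA=codes["MA"],
                    description=f[3] if len(f) > 3 else "",
                )
            )
        except KeyError as exc:
            raise ParseError(
                f"{path.name}: tier gestures: gesture {f[0]} missing "
                f"coding {exc}"
            )

    ipus = []
    for start, end, value in tiers.get("ipus", []):
        f = fields(value, 4, "ipus")
        ipus.append(
            IPU(
                id=f[0], story_id=f[1], start=start, end=end,
                words=f[2].split(),
                word_sentiments=[float(x) for x in f[3].split()],
            )
        )

    quotes = [
        QuoteSpan(story_id=value.split("|")[0], start=start, end=end)
        for start, end, value in tiers.get("quotes", [])
    ]
    return stories, gestures, ipus, quotes


def read_annotations(
    path: str | Path, dialect: str = "tabular"
) -> tuple[list[Story], list[GestureAnnotation], list[IPU], list[QuoteSpan]]:
    """Read one recording's annotation tiers.

    Parameters
    ----------
    path
        Tier directory (``tabular``) or ``.eaf`` file (``eaf``).
    dialect
        ``"tabular"`` or ``"eaf"``.

    Returns ``(stories, gestures, ipus, quotes)`` with all times in seconds.
    Raises :class:`ParseError` for malformed files and
    :class:`~resogest.corpus.ValidationError` when an object violates its
    invariants (e.g. a gesture phase outside the gesture span).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such annotation source: {path}")
    if dialect == "tabular":
        return _read_tabular(path)
    if dialect == "eaf":
        return _read_eaf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# EDA traces

def read_eda(path: str | Path) -> EDATrace:
    """Read one participant's EDA trace from CSV.

    Expected header: ``participant,t0,rate,value``; ``participant``, ``t0``
    (seconds) and ``rate`` (Hz) are constant per file, one sample per row in
    microsiemens.  Values outside the device range raise a
    :class:`~resogest.corpus.ValidationError` naming the sample index.
    """
    path = Path(path)
    rows = _read_tier_csv(path, ("participant", "t0", "rate", "value"))
    if not rows:
        raise ParseError(f"{path.name}: empty EDA file")
    pid, t0, rate = rows[0]["participant"], rows[0]["t0"], rows[0]["rate"]
    values = []
    lo, hi = EDA_RANGE
    for i, row in enumerate(rows):
        try:
            v = float(row["value"])
        except ValueError:
            raise ParseError(
                f"{path.name}: non-numeric EDA value {row['value']!r} "
                f"at sample {i}"
            )
        if not lo <= v <= hi:
            raise ValidationError(
                f"{path.name}: value {v} at sample {i} outside [{lo}, {hi}]"
            )
        values.append(v)
    return EDATrace(
        participant_id=pid, values=values,
        sampling_rate=float(rate), t0=float(t0),
    )


def write_eda(trace: EDATrace, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["participant", "t0", "rate", "value"])
        for v in trace.values:
            w.writerow([trace.participant_id, repr(float(trace.t0)),
                        repr(float(trace.sampling_rate)), repr(float(v))])


# ---------------------------------------------------------------------------
# feature table

#: Stable column order of the per-gesture feature table.
FEATURE_COLUMNS = [
    "gesture_id", "story_id", "recording_id", "narrator_id",
    "SZ", "FO", "CV", "SL", "HO", "MA", "ND",
    "G_expressivity", "G_position_rel", "G_quote", "Sentiment",
    "protagonist", "recency", "group_size", "group_compose",
]

#: EDA outcome columns appended by the response stage.
OUTCOME_COLUMNS = ["EDA_specific_narrator", "n_specific", "EDA_G_resonance"]


def write_feature_table(records, path: str | Path) -> None:
    """Write the per-gesture feature table as CSV in the documented order.

    ``records`` may be a DataFrame or a list of mapping-like records.  Raises
    ``ValueError`` on an empty table or duplicate gesture ids.
    """
    if not isinstance(records, pd.DataFrame):
        import dataclasses

        records = pd.DataFrame(
            [dataclasses.asdict(r) if dataclasses.is_dataclass(r)
             else dict(r) for r in records]
        )
    if records.empty:
        raise ValueError("feature table is empty")
    dupes = records["gesture_id"][records["gesture_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate gesture ids: {sorted(set(dupes))}")
    cols = [c for c in FEATURE_COLUMNS + OUTCOME_COLUMNS
            if c in records.columns]
    extra = [c for c in records.columns if c not in cols]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # full-precision floats so the table round-trips losslessly
    records[cols + extra].to_csv(
        path, index=False, float_format=lambda x: repr(float(x))
    )


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"feature table missing columns {missing}")
    return df
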