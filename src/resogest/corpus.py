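"""Domain types for multiparty storytelling recordings.

A *recording* holds 2-3 participants seated in an F-formation; within each
recording a number of conversational *stories* are told by one narrator each.
Stories carry annotated *gestures* (with gesture-phase segmentation and binary
expressivity codings), *inter-pausal units* (IPUs, stretches of speech bounded
by pauses, with word-level sentiment scores) and *quote spans* (constructed
dialog).  Each participant additionally contributes a skin-conductance (EDA)
trace sampled uniformly, by default at 4 Hz in microsiemens.

All times are stored in seconds on a single shared clock per recording;
readers convert from the millisecond time base used by ELAN-style annotation
files.  Windows throughout the package are half-open intervals ``[start, end)``
so that a 4 Hz sample never contributes twice across a shared boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "CorpusError",
    "ValidationError",
    "ParseError",
    "EDA_RANGE",
    "GESTURE_PHASES",
    "Participant",
    "Recording",
    "Story",
    "GestureAnnotation",
    "IPU",
    "QuoteSpan",
    "EDATrace",
    "validate_referential_integrity",
]


class CorpusError(Exception):
    """Base class for corpus-layer errors."""


class ValidationError(CorpusError):
    """A domain object violates one of its invariants."""


class ParseError(CorpusError):
    """A corpus file does not conform to its declared dialect."""


#: Valid EDA range of the recording device, in microsiemens.
EDA_RANGE = (0.01, 100.0)

#: Recognised gesture-phase labels.  The *nucleus* is the expressive core
#: (stroke plus any embedded strokes); preparation and retraction are
#: transport phases, and a hold is a momentary cessation of movement.
GESTURE_PHASES = ("preparation", "nucleus", "hold", "retraction")

GROUP_COMPOSITIONS = ("all-female", "all-male", "mixed")


@dataclass
class Participant:
    id: str
    sex: str = "unknown"  # "female" | "male" | "diverse/NA" | "unknown"


@dataclass
class Recording:
    id: str
    participants: list[Participant]
    group_compose: str
    duration: float

    def __post_init__(self) -> None:
        if len(self.participants) not in (2, 3):
            raise ValidationError(
                f"recording {self.id}: group size must be 2 or 3, "
                f"got {len(self.participants)}"
            )
        if self.group_compose not in GROUP_COMPOSITIONS:
            raise ValidationError(
                f"recording {self.id}: unknown group_compose {self.group_compose!r}"
            )
        sexes = {p.sex for p in self.participants}
        if sexes <= {"female"} and self.group_compose != "all-female":
            raise ValidationError(
                f"recording {self.id}: all participants female but "
                f"group_compose={self.group_compose!r}"
            )
        if sexes <= {"male"} and self.group_compose != "all-male":
            raise ValidationError(
                f"recording {self.id}: all participants male but "
                f"group_compose={self.group_compose!r}"
            )
        # any other mix (incl. diverse/NA or unknown labels) maps to "mixed";
        # the three-level factor admits no fourth level
        if len(sexes - {"unknown"}) > 1 and self.group_compose != "mixed":
            raise ValidationError(
                f"recording {self.id}: mixed sexes but "
                f"group_compose={self.group_compose!r}"
            )

    @property
    def group_size(self) -> int:
        return len(self.participants)


@dataclass
class Story:
    """One conversational storytelling, from onset to (climax) offset.

    The climax span is part of the manual annotation and is consumed, never
    computed, by this package.
    """

    id: str
    recording_id: str
    narrator_id: str
    onset: float
    offset: float
    climax_onset: float
    climax_offset: float
    protagonist: str = "narrator"  # "narrator" | "third-person"
    recency: str = "recent"  # "recent" | "distant"

    def __post_init__(self) -> None:
        if not (
            self.onset < self.climax_onset <= self.climax_offset <= self.offset
        ):
            raise ValidationError(
                f"story {self.id}: require onset < climax_onset <= "
                f"climax_offset <= offset, got "
                f"({self.onset}, {self.climax_onset}, "
                f"{self.climax_offset}, {self.offset})"
            )


@dataclass
class GestureAnnotation:
    """A coded co-speech gesture by the story narrator.

    ``phases`` is an ordered list of ``(label, start, end)`` segments in
    seconds.  The five stored binary codings are Size (SZ), Force (FO),
    Character viewpoint (CV), Silent gesture (SL) and Multiple articulators
    (MA); Hold phase (HO) and Nucleus duration (ND) are *derived* from the
    phase segmentation, not stored.
    """

    id: str
    story_id: str
    onset: float
    offset: float
    phases: list[tuple[str, float, float]]
    coded_SZ: bool
    coded_FO: bool
    coded_CV: bool
    coded_SL: bool
    coded_MA: bool
    description: str = ""

    def __post_init__(self) -> None:
        if self.onset >= self.offset:
            raise ValidationError(f"gesture {self.id}: onset >= offset")
        eps = 1e-9
        prev_end = None
        n_nucleus = 0
        for label, start, end in self.phases:
            if label not in GESTURE_PHASES:
                raise ValidationError(
                    f"gesture {self.id}: unknown phase label {label!r}"
                )
            if start >= end:
                raise ValidationError(
                    f"gesture {self.id}: empty phase segment {label}"
                )
            if start < self.onset - eps or end > self.offset + eps:
                raise ValidationError(
                    f"gesture {self.id}: phase {label} [{start}, {end}] outside "
                    f"gesture span [{self.onset}, {self.offset}]"
                )
            if prev_end is not None and start < prev_end - eps:
                raise ValidationError(
                    f"gesture {self.id}: overlapping phase segments at {start}"
                )
            prev_end = end
            n_nucleus += label == "nucleus"
        if n_nucleus == 0:
            raise ValidationError(f"gesture {self.id}: no nucleus phase")

    @property
    def nucleus_duration(self) -> float:
        """Total duration of all nucleus segments, in seconds."""
        return sum(e - s for lab, s, e in self.phases if lab == "nucleus")

    @property
    def has_hold(self) -> bool:
        return any(lab == "hold" for lab, _, _ in self.phases)


@dataclass
class IPU:
    """Inter-pausal unit: a pause-bounded stretch of speech with word-level
    composite sentiment scores in [-1, 1]."""

    id: str
    story_id: str
    start: float
    end: float
    words: list[str]
    word_sentiments: list[float]

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"IPU {self.id}: start >= end")
        if len(self.words) != len(self.word_sentiments):
            raise ValidationError(
                f"IPU {self.id}: {len(self.words)} words but "
                f"{len(self.word_sentiments)} sentiment scores"
            )
        for s in self.word_sentiments:
            if not -1.0 <= s <= 1.0:
                raise ValidationError(
                    f"IPU {self.id}: sentiment score {s} outside [-1, 1]"
                )

    @property
    def mean_sentiment(self) -> float:
        if not self.word_sentiments:
            return 0.0
        return float(sum(self.word_sentiments) / len(self.word_sentiments))


@dataclass
class QuoteSpan:
    """A span of constructed dialog (direct speech) within a story."""

    story_id: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"quote in story {self.story_id}: start >= end"
            )


@dataclass
class EDATrace:
    """One participant's uniformly sampled skin-conductance series.

    Samples sit at ``t0 + k / sampling_rate`` for ``k = 0 .. n-1`` and must lie
    within the device range of 0.01-100 microsiemens.
    """

    participant_id: str
    values: list[float] = field(repr=False)
    sampling_rate: float = 4.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if len(self.values) < 2:
            raise ValidationError(
                f"EDA trace {self.participant_id}: need >= 2 samples"
            )
        if self.sampling_rate <= 0:
            raise ValidationError(
                f"EDA trace {self.participant_id}: non-positive sampling rate"
            )
        lo, hi = EDA_RANGE
        for i, v in enumerate(self.values):
            if not lo <= v <= hi:
                raise ValidationError(
                    f"EDA trace {self.participant_id}: value {v} at sample {i} "
                    f"outside [{lo}, {hi}]"
                )

    def __len__(self) -> int:
        return len(self.values)

    @property
    def t_end(self) -> float:
        """Time just past the last sample (half-open trace span)."""
        return self.t0 + len(self.values) / self.sampling_rate

    def times(self):
        import numpy as np

        return self.t0 + np.arange(len(self.values)) / self.sampling_rate


def validate_referential_integrity(
    recording: Recording,
    stories: list[Story],
    gestures: list[GestureAnnotation],
    ipus: list[IPU] = (),
    quotes: list[QuoteSpan] = (),
) -> None:
    """Check that every gesture/IPU/quote maps to a known story, every story to
    the recording, and each story's narrator is a recording participant."""
    pids = {p.id for p in recording.participants}
    sids = set()
    for st in stories:
        if st.recording_id != recording.id:
            raise ValidationError(
                f"story {st.id} references recording {st.recording_id}, "
                f"expected {recording.id}"
            )
        if st.narrator_id not in pids:
            raise ValidationError(
                f"story {st.id}: narrator {st.narrator_id} not a participant"
            )
        if st.id in sids:
            raise ValidationError(f"duplicate story id {st.id}")
        sids.add(st.id)
    for g in gestures:
        if g.story_id not in sids:
            raise ValidationError(
                f"gesture {g.id} references unknown story {g.story_id}"
            )
    for u in ipus:
        if u.story_id not in sids:
            raise ValidationError(
                f"IPU {u.id} references unknown story {u.story_id}"
            )
    for q in quotes:
        if q.story_id not in sids:
            raise ValidationError(
                f"quote references unknown story {q.story_id}"
            )
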