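"""Per-gesture analysis variables.

The Gesture Expressivity Index (GEI) is the mean of seven binary parameters:
Size (SZ), Force (FO), Character viewpoint (CV), Silent gesture (SL),
Hold phase (HO), Multiple articulators (MA) and Nucleus duration (ND).
SZ/FO/CV/SL/MA come coded from the annotation; HO and ND are derived here
from the phase segmentation (HO: any hold segment present; ND: the gesture's
total nucleus duration strictly exceeds the story's mean nucleus duration).

Contextual covariates derived alongside:

- ``G_position_rel``: the gesture's relative position within its story,
  equi-distanced in [0, 1] — gesture ``i`` of ``n`` (sorted by onset) gets
  ``(i - 1) / (n - 1)``; a single-gesture story gets the midpoint 0.5.
- ``G_quote``: whether the gesture is a co-quote gesture, by fuzzy start-time
  matching (|quote.start - gesture.onset| <= 1.5 s by default).
- ``Sentiment``: the mean word-level composite sentiment of the IPU that
  maximally overlaps the gesture span (0 when no IPU overlaps).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import pandas as pd

from .corpus import (
    GestureAnnotation,
    IPU,
    QuoteSpan,
    Recording,
    Story,
)

__all__ = [
    "QUOTE_TOLERANCE",
    "GestureFeatureRecord",
    "derive_ho",
    "derive_nd",
    "compute_gei",
    "relative_positions",
    "assign_quote",
    "assign_sentiment",
    "build_feature_table",
]

#: Fuzzy co-quote matching tolerance on start times, seconds.
QUOTE_TOLERANCE = 1.5

GEI_PARAMS = ("SZ", "FO", "CV", "SL", "HO", "MA", "ND")


@dataclass
class GestureFeatureRecord:
    """One analysis row: a gesture with its GEI components and covariates."""

    gesture_id: str
    story_id: str
    recording_id: str
    narrator_id: str
    SZ: int
    FO: int
    CV: int
    SL: int
    HO: int
    MA: int
    ND: int
    G_expressivity: float
    G_position_rel: float
    G_quote: int
    Sentiment: float
    protagonist: str
    recency: str
    group_size: int
    group_compose: str

    def __post_init__(self) -> None:
        n_yes = sum((self.SZ, self.FO, self.CV, self.SL, self.HO, self.MA,
                     self.ND))
        if abs(self.G_expressivity - n_yes / 7) > 1e-12:
            raise ValueError(
                f"gesture {self.gesture_id}: G_expressivity "
                f"{self.G_expressivity} != {n_yes}/7"
            )
        if not 0.0 <= self.G_position_rel <= 1.0:
            raise ValueError(
                f"gesture {self.gesture_id}: G_position_rel outside [0, 1]"
            )


def derive_ho(g: GestureAnnotation) -> bool:
    """Hold-phase parameter: yes iff any phase segment is labelled hold."""
    return g.has_hold


def derive_nd(
    g: GestureAnnotation, story_gestures: list[GestureAnnotation]
) -> bool:
    """Nucleus-duration parameter: yes iff this gesture's total nucleus
    duration strictly exceeds the story's mean nucleus duration.

    In a single-gesture story the gesture cannot exceed its own mean, so the
    result is always no.
    """
    if not story_gestures:
        raise ValueError("derive_nd: empty story")
    if not any(s.id == g.id for s in story_gestures):
        raise ValueError(
            f"derive_nd: gesture {g.id} not among story gestures"
        )
    mean_nd = sum(s.nucleus_duration for s in story_gestures) / len(
        story_gestures
    )
    return g.nucleus_duration > mean_nd


def compute_gei(SZ, FO, CV, SL, HO, MA, ND) -> float:
    """Gesture Expressivity Index: (#yes)/7 over the seven binary parameters.

    No imputation: a missing (None) coding raises.
    """
    vals = (SZ, FO, CV, SL, HO, MA, ND)
    if any(v is None for v in vals):
        missing = [n for n, v in zip(GEI_PARAMS, vals) if v is None]
        raise ValueError(f"compute_gei: missing codings {missing}")
    return sum(bool(v) for v in vals) / 7


def relative_positions(
    story_gestures: list[GestureAnnotation],
) -> list[float]:
    """Equi-distanced relative positions in [0, 1] for a story's gestures.

    Input must be sorted by onset.  Gesture ``i`` (1-based) of ``n`` gets
    ``(i - 1)/(n - 1)``; a lone gesture gets 0.5.
    """
    n = len(story_gestures)
    if n == 0:
        raise ValueError("relative_positions: empty story")
    onsets = [g.onset for g in story_gestures]
    if any(b < a for a, b in zip(onsets, onsets[1:])):
        raise ValueError("relative_positions: gestures not sorted by onset")
    if n == 1:
        return [0.5]
    return [i / (n - 1) for i in range(n)]


def assign_quote(
    g: GestureAnnotation,
    quotes: list[QuoteSpan],
    tolerance: float = QUOTE_TOLERANCE,
) -> bool:
    """Co-quote flag: yes iff some quote's start lies within ``tolerance``
    seconds (in either direction) of the gesture onset."""
    return any(abs(q.start - g.onset) <= tolerance for q in quotes)


def assign_sentiment(g: GestureAnnotation, ipus: list[IPU]) -> float:
    """Sentiment of the IPU with maximal temporal overlap with the gesture.

    Overlap is measured on the raw spans; ties break to the earlier IPU, and
    a gesture with no overlapping IPU gets the neutral score 0.
    """
    best: IPU | None = None
    best_overlap = 0.0
    for u in sorted(ipus, key=lambda u: u.start):
        overlap = min(g.offset, u.end) - max(g.onset, u.start)
        if overlap > best_overlap + 1e-12:
            best, best_overlap = u, overlap
    return best.mean_sentiment if best is not None else 0.0


def build_feature_table(
    recording: Recording,
    stories: list[Story],
    gestures: list[GestureAnnotation],
    ipus: list[IPU],
    quotes: list[QuoteSpan],
    quote_tolerance: float = QUOTE_TOLERANCE,
) -> pd.DataFrame:
    """Derive one :class:`GestureFeatureRecord` row per gesture.

    Gestures are grouped by story and sorted by onset within each story; the
    story's covariates are copied onto each row.  Every input gesture appears
    exactly once in the output.
    """
    story_by_id = {s.id: s for s in stories}
    by_story: dict[str, list[GestureAnnotation]] = {}
    for g in gestures:
        by_story.setdefault(g.story_id, []).append(g)

    records: list[GestureFeatureRecord] = []
    for story_id in sorted(by_story, key=lambda sid: story_by_id[sid].onset):
        story = story_by_id[story_id]
        sg = sorted(by_story[story_id], key=lambda g: g.onset)
        positions = relative_positions(sg)
        story_quotes = [q for q in quotes if q.story_id == story_id]
        story_ipus = [u for u in ipus if u.story_id == story_id]
        for g, pos in zip(sg, positions):
            comps = dict(
                SZ=int(g.coded_SZ), FO=int(g.coded_FO), CV=int(g.coded_CV),
                SL=int(g.coded_SL), HO=int(derive_ho(g)),
                MA=int(g.coded_MA), ND=int(derive_nd(g, sg)),
            )
            records.append(
                GestureFeatureRecord(
                    gesture_id=g.id,
                    story_id=story_id,
                    recording_id=recording.id,
                    narrator_id=story.narrator_id,
                    **comps,
                    G_expressivity=compute_gei(**comps),
                    G_position_rel=pos,
                    G_quote=int(
                        assign_quote(g, story_quotes, quote_tolerance)
                    ),
                    Sentiment=assign_sentiment(g, story_ipus),
                    protagonist=story.protagonist,
                    recency=story.recency,
                    group_size=recording.group_size,
                    group_compose=recording.group_compose,
                )
            )
    return pd.DataFrame([asdict(r) for r in records])
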