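"""Two-rater agreement statistics for binary coding schemes.

Percent agreement and the Holley-Guilford G index.  G is chance-symmetric,
``(#agreements - #disagreements) / N``, which for binary codes reduces to
``2 * p_agree - 1``; unlike Cohen's kappa it stays informative when the
rating margins are heavily skewed toward one category, the usual situation
for rare gesture-kinematic features.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

__all__ = [
    "RatingPair",
    "percent_agreement",
    "g_index",
    "agreement_report",
    "read_ratings",
    "round_half_up",
]


@dataclass
class RatingPair:
    """Binary codes by two raters over the same items."""

    rater_a: list[int]
    rater_b: list[int]
    items: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.rater_a) != len(self.rater_b):
            raise ValueError(
                f"rater sequences differ in length: "
                f"{len(self.rater_a)} vs {len(self.rater_b)}"
            )
        if not self.rater_a:
            raise ValueError("empty rating pair")
        for seq in (self.rater_a, self.rater_b):
            if any(int(v) not in (0, 1) for v in seq):
                raise ValueError("ratings must be binary (0/1)")

    def __len__(self) -> int:
        return len(self.rater_a)

    @property
    def n_agree(self) -> int:
        return sum(
            int(a) == int(b) for a, b in zip(self.rater_a, self.rater_b)
        )


def percent_agreement(r: RatingPair) -> float:
    """100 * (#items with identical codes) / N."""
    return 100.0 * r.n_agree / len(r)


def g_index(r: RatingPair) -> float:
    """Holley-Guilford G = (#agreements - #disagreements) / N, in [-1, 1]."""
    n = len(r)
    return (r.n_agree - (n - r.n_agree)) / n


def round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero at ``ndigits`` decimals (report rounding)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def agreement_report(pairs: dict[str, RatingPair]) -> pd.DataFrame:
    """Tabulate agreement % and G per coding scheme, rounded half-up to the
    reporting precision (2 d.p.)."""
    rows = [
        {
            "parameter": name,
            "n_items": len(pair),
            "agreement_pct": round_half_up(percent_agreement(pair), 2),
            "g_index": round_half_up(g_index(pair), 2),
        }
        for name, pair in pairs.items()
    ]
    return pd.DataFrame(rows)


def read_ratings(path) -> RatingPair:
    """Read a two-column (rater_a, rater_b) CSV of binary codes."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("rating CSV needs at least two columns")
    return RatingPair(
        rater_a=[int(v) for v in df.iloc[:, 0]],
        rater_b=[int(v) for v in df.iloc[:, 1]],
    )
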