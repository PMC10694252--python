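"""Passage segmentation and the counterbalanced within-subject design.

A discourse passage is presented either continuously or in a self-paced
format where playback halts at annotated clause/sentence boundaries and
the listener triggers each next segment. Segmentation here is
text-level: boundaries are word indices supplied as annotation (the
linguistic judgment of where a "major clause boundary" falls is an
input, not something this module infers).

The design builder assigns each participant all eight passages, one per
cell of the 2 (format: continuous / self-paced) x 2 (clarity: clear /
vocoded) x 2 (predictability: high / low) within-subject design, with
Latin-square rotation so that across every block of eight participants
each passage occurs in each format x clarity cell equally often.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

FORMATS = ("continuous", "selfpaced")
CLARITIES = ("clear", "vocoded")
PREDICTABILITIES = ("high", "low")

#: The four format x clarity cells, in canonical order.
CELLS = tuple((f, c) for f in FORMATS for c in CLARITIES)


@dataclass(frozen=True)
class Passage:
    """A normed prose passage.

    ``mean_cloze`` is the mean inter-word cloze predictability in [0, 1]
    (the fraction of norming respondents supplying each word from its
    context); ``predictability_class`` dichotomizes it.
    """

    id: str
    words: tuple[str, ...]
    predictability_class: str
    mean_cloze: float

    def __post_init__(self) -> None:
        if len(self.words) == 0:
            raise ValueError(f"passage {self.id}: words must be non-empty")
        if self.predictability_class not in PREDICTABILITIES:
            raise ValueError(
                f"passage {self.id}: predictability_class must be one of "
                f"{PREDICTABILITIES}, got {self.predictability_class!r}"
            )
        if not (0.0 <= self.mean_cloze <= 1.0):
            raise ValueError(f"passage {self.id}: mean_cloze must be in [0, 1]")
        object.__setattr__(self, "words", tuple(self.words))


@dataclass(frozen=True)
class SegmentedPassage:
    """A passage partitioned at boundary indices.

    A boundary at index k interrupts before word k (0-based), so
    boundaries lie strictly inside (0, n_words) and the segments
    concatenate back to the original word list.
    """

    passage_id: str
    words: tuple[str, ...]
    boundaries: tuple[int, ...]

    @property
    def segments(self) -> list[tuple[str, ...]]:
        cuts = [0, *self.boundaries, len(self.words)]
        return [tuple(self.words[a:b]) for a, b in zip(cuts[:-1], cuts[1:])]

    @property
    def n_segments(self) -> int:
        return len(self.boundaries) + 1


def segment_passage(passage: Passage, boundaries: list[int]) -> SegmentedPassage:
    """Partition a passage at the given word indices.

    Boundaries must be strictly ascending and lie in (0, len(words));
    a boundary at 0 or len(words) would create an empty segment.
    """
    n = len(passage.words)
    bounds = tuple(int(b) for b in boundaries)
    if any(b2 <= b1 for b1, b2 in zip(bounds[:-1], bounds[1:])):
        raise ValueError(f"boundaries must be strictly ascending: {bounds}")
    if any(not (0 < b < n) for b in bounds):
        raise ValueError(
            f"boundaries must lie strictly inside (0, {n}): {bounds}"
        )
    return SegmentedPassage(passage.id, passage.words, bounds)


def segment_stats(segmented: list[SegmentedPassage]) -> dict[str, float]:
    """Mean segments per passage and mean words per segment."""
    if not segmented:
        raise ValueError("need at least one segmented passage")
    n_segments = [s.n_segments for s in segmented]
    words_per_segment = [len(seg) for s in segmented for seg in s.segments]
    return {
        "mean_segments_per_passage": float(np.mean(n_segments)),
        "mean_words_per_segment": float(np.mean(words_per_segment)),
    }


@dataclass(frozen=True)
class DesignPlan:
    """Counterbalanced participant x passage condition assignment."""

    table: pd.DataFrame  # columns: participant, passage, format, clarity, predictability

    def assignment(self, participant: str, passage: str) -> tuple[str, str]:
        row = self.table[
            (self.table.participant == participant) & (self.table.passage == passage)
        ]
        if row.empty:
            raise KeyError(f"no assignment for ({participant}, {passage})")
        r = row.iloc[0]
        return r["format"], r["clarity"]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DesignPlan":
        return cls(pd.read_csv(path))


def build_design(n_participants: int, passages: list[Passage], seed: int = 0) -> DesignPlan:
    """Build the counterbalanced design.

    Requires exactly eight passages, four high- and four low-
    predictability. Within each block of eight participants a fixed
    Latin-square rotation places each passage in each format x clarity
    cell exactly twice; the seed permutes which participant gets which
    rotation row (balance is a property of the square, so any
    permutation preserves it).
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if len(passages) != 8:
        raise ValueError(f"need exactly 8 passages, got {len(passages)}")
    high = [p for p in passages if p.predictability_class == "high"]
    low = [p for p in passages if p.predictability_class == "low"]
    if len(high) != 4 or len(low) != 4:
        raise ValueError(
            f"need 4 high- and 4 low-predictability passages, got "
            f"{len(high)} high / {len(low)} low"
        )
    if n_participants % 8 != 0:
        warnings.warn(
            f"n_participants = {n_participants} is not a multiple of 8; "
            "passage-level counterbalancing is only exact within complete "
            "blocks of 8",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    rows = []
    n_blocks = -(-n_participants // 8)
    pid = 0
    for block in range(n_blocks):
        # seed permutes participant-to-row assignment only
        row_order = rng.permutation(8)
        for r in row_order:
            if pid >= n_participants:
                break
            # Cyclic rotation: high passage h sits in cell (r + h) mod 4,
            # low passage l in cell (r + l + r//4) mod 4. Each participant
            # covers all 4 cells once per class; over rows 0..7 each
            # (passage, cell) pair occurs exactly twice.
            for h, p in enumerate(high):
                fmt, clar = CELLS[(r + h) % 4]
                rows.append((f"P{pid:03d}", p.id, fmt, clar, "high"))
            for l, p in enumerate(low):
                fmt, clar = CELLS[(r + l + r // 4) % 4]
                rows.append((f"P{pid:03d}", p.id, fmt, clar, "low"))
            pid += 1
    table = pd.DataFrame(
        rows, columns=["participant", "passage", "format", "clarity", "predictability"]
    )
    return DesignPlan(table)


# ---------------------------------------------------------------------------
# Passage file I/O and fixture helpers


def load_passage(path) -> tuple[Passage, list[int]]:
    """Read a passage JSON file: {id, text, predictability_class, mean_cloze, boundaries}."""
    with open(path) as fh:
        obj = json.load(fh)
    passage = Passage(
        id=obj["id"],
        words=tuple(obj["text"].split()),
        predictability_class=obj["predictability_class"],
        mean_cloze=float(obj["mean_cloze"]),
    )
    return passage, [int(b) for b in obj.get("boundaries", [])]


def heuristic_boundaries(words: list[str]) -> list[int]:
    """Crude boundary guesser for fixture generation only.

    Splits after sentence-final punctuation and after commas followed by
    a coordinating conjunction. This is NOT a linguistic segmenter: real
    clause-boundary annotation requires human judgment.
    """
    conj = {"and", "but", "or", "so", "yet", "for", "nor"}
    bounds = []
    for i, w in enumerate(words[:-1]):
        if w.endswith((".", "!", "?")):
            bounds.append(i + 1)
        elif w.endswith(",") and words[i + 1].lower() in conj:
            bounds.append(i + 1)
    return bounds
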