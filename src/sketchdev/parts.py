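"""Multi-rater part annotations: consensus, unique parts, and emphasis.

Annotators tag each stroke of a drawing with one or more object-part
labels (or "unintelligible", or a custom free-text label).  A stroke's
consensus is the label *set* endorsed identically by at least two raters;
the number of distinct consensus labels (excluding unintelligible) is the
drawing's unique-part count, and each part's *emphasis* is the fraction of
the drawing's total stroke arc length attributed to it, with multi-part
strokes splitting their length equally among their labels.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .corpus import Drawing, stroke_length

__all__ = [
    "UNINTELLIGIBLE",
    "NO_CONSENSUS",
    "parse_annotations",
    "consensus_labels",
    "unique_parts",
    "part_emphasis",
    "summarize_drawing",
    "PartSummary",
]

UNINTELLIGIBLE = "unintelligible"
#: Sentinel consensus for strokes on which no label set reached agreement.
NO_CONSENSUS = None


@dataclass(frozen=True)
class PartSummary:
    drawing_id: str
    consensus: tuple  # per-stroke frozenset of labels, or None
    n_unique_parts: int
    emphasis: dict[str, float]
    agreement: float

    def __post_init__(self) -> None:
        total = sum(self.emphasis.values())
        if total > 1.0 + 1e-9:
            raise ValueError("emphasis fractions exceed 1")


def parse_annotations(df: pd.DataFrame) -> pd.DataFrame:
    """Normalize an annotation table: split ``;``-joined labels into frozensets.

    Expects columns ``drawing_id``, ``stroke_index``, ``rater_id``,
    ``labels``; returns a copy with a ``label_set`` column.
    """
    out = df.copy()
    out["label_set"] = [
        frozenset(s.strip() for s in str(lab).split(";") if s.strip())
        for lab in out["labels"]
    ]
    if any(len(s) == 0 for s in out["label_set"]):
        raise ValueError("annotations with empty label sets are invalid")
    return out


def consensus_labels(
    annotations: pd.DataFrame,
    mode: str = "set",
    min_raters: int = 2,
) -> tuple[dict[int, Optional[frozenset]], float]:
    """Per-stroke consensus for one drawing's annotations.

    With the default ``mode="set"``, a stroke's consensus is the exact
    label set reported identically by at least two raters (ties between
    competing majority sets are broken toward the more endorsed, then
    lexicographically smallest set).  ``mode="label"`` instead keeps every
    individual label endorsed by at least two raters.  Strokes with fewer
    than ``min_raters`` raters are excluded from the agreement denominator
    with a warning.

    Returns (stroke_index -> consensus set or None, agreement rate).
    """
    if mode not in ("set", "label"):
        raise ValueError(f"unknown consensus mode {mode!r}")
    if "label_set" not in annotations.columns:
        annotations = parse_annotations(annotations)
    consensus: dict[int, Optional[frozenset]] = {}
    n_eligible = 0
    n_agree = 0
    for stroke, grp in annotations.groupby("stroke_index"):
        sets = list(grp["label_set"])
        if len(sets) < min_raters:
            warnings.warn(
                f"stroke {stroke} has only {len(sets)} rater(s); excluded from "
                "the agreement denominator",
                stacklevel=2,
            )
            consensus[int(stroke)] = NO_CONSENSUS
            continue
        n_eligible += 1
        if mode == "set":
            counts = Counter(sets)
            winners = [
                (n, tuple(sorted(s)), s) for s, n in counts.items() if n >= 2
            ]
            if winners:
                winners.sort(key=lambda t: (-t[0], t[1]))
                consensus[int(stroke)] = winners[0][2]
                n_agree += 1
            else:
                consensus[int(stroke)] = NO_CONSENSUS
        else:
            label_counts = Counter(lab for s in sets for lab in s)
            agreed = frozenset(lab for lab, n in label_counts.items() if n >= 2)
            if agreed:
                consensus[int(stroke)] = agreed
                n_agree += 1
            else:
                consensus[int(stroke)] = NO_CONSENSUS
    rate = n_agree / n_eligible if n_eligible else float("nan")
    return consensus, rate


def unique_parts(
    consensus: dict[int, Optional[frozenset]],
    vocabulary: Optional[Sequence[str]] = None,
) -> int:
    """Count distinct consensus part labels, excluding unintelligible
    strokes and no-consensus strokes.

    When a ``vocabulary`` is given, custom (out-of-vocabulary) labels are
    also excluded from the count.
    """
    labels: set[str] = set()
    for s in consensus.values():
        if s is NO_CONSENSUS:
            continue
        labels |= set(s)
    labels.discard(UNINTELLIGIBLE)
    if vocabulary is not None:
        labels &= set(vocabulary)
    return len(labels)


def part_emphasis(
    drawing: Drawing,
    consensus: dict[int, Optional[frozenset]],
    vocabulary: Optional[Sequence[str]] = None,
) -> dict[str, float]:
    """Fraction of total stroke arc length attributed to each part.

    A stroke's length is divided equally among its consensus labels; the
    denominator is the total length of *all* strokes in the drawing,
    including unintelligible and no-consensus strokes, so emphases plus the
    unattributed fraction sum exactly to 1.  A drawing of zero total length
    has undefined emphasis: an empty mapping is returned.
    """
    lengths = [stroke_length(s) for s in drawing.strokes]
    total = sum(lengths)
    if total == 0:
        return {}
    emphasis: dict[str, float] = {}
    for k, length in enumerate(lengths):
        labs = consensus.get(k, NO_CONSENSUS)
        if labs is NO_CONSENSUS:
            continue
        labs = set(labs)
        share = length / len(labs)
        for lab in labs:
            if lab == UNINTELLIGIBLE:
                continue
            if vocabulary is not None and lab not in vocabulary:
                continue
            emphasis[lab] = emphasis.get(lab, 0.0) + share / total
    return emphasis


def summarize_drawing(
    drawing: Drawing,
    annotations: pd.DataFrame,
    mode: str = "set",
    vocabulary: Optional[Sequence[str]] = None,
) -> PartSummary:
    """Full part summary of one drawing from its long annotation table."""
    cons, rate = consensus_labels(annotations, mode=mode)
    return PartSummary(
        drawing_id=drawing.drawing_id,
        consensus=tuple(cons.get(k) for k in range(drawing.n_strokes)),
        n_unique_parts=unique_parts(cons, vocabulary=vocabulary),
        emphasis=part_emphasis(drawing, cons, vocabulary=vocabulary),
        agreement=rate,
    )
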