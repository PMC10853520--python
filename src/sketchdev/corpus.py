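"""Core data model for stroke-based drawings, tracings, and category metadata.

A drawing is an ordered list of strokes; each stroke is an ordered sequence
of ``(x, y, t)`` touch samples in source canvas units (pixels) with
timestamps in milliseconds.  The coordinate convention throughout the
package is raster-style: origin at the top-left, x rightward, y downward,
0-based pixel indices.  Stroke coordinates are stored in canvas units and
scaled to the requested raster size only at render time.

Rasters are plain ``numpy`` float arrays with grayscale intensity in
``[0, 1]`` where 1 is the white background — black ink is 0.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

__all__ = [
    "Stroke",
    "Drawing",
    "TracingTrial",
    "CategoryMeta",
    "EffortCovariates",
    "Corpus",
    "CorpusValidationError",
    "CorpusParseError",
    "load_corpus",
    "save_corpus",
    "rasterize",
    "stroke_length",
    "drawing_to_svg",
    "effort_covariates",
    "DEFAULT_RASTER_SIZE",
    "DEFAULT_STROKE_WIDTH",
    "DRAW_TIME_CAP_S",
]

#: Default raster resolution; matches the standard input size of common
#: convolutional encoders so rendered drawings can be fed to one directly.
DEFAULT_RASTER_SIZE = 224
DEFAULT_STROKE_WIDTH = 3
#: Kiosk-style per-trial time cap in seconds.
DRAW_TIME_CAP_S = 30.0


class CorpusValidationError(ValueError):
    """A record violates a type invariant (bad timestamps, unknown category...)."""


class CorpusParseError(ValueError):
    """A record could not be parsed at all."""


@dataclass(frozen=True)
class Stroke:
    """One pen stroke: an (n, 3) array of ``(x, y, t)`` samples.

    Timestamps must be non-decreasing; at least one point is required.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 1:
            raise CorpusValidationError(
                f"stroke points must be an (n>=1, 3) array, got shape {pts.shape}"
            )
        if np.any(np.diff(pts[:, 2]) < 0):
            raise CorpusValidationError("stroke timestamps must be non-decreasing")
        object.__setattr__(self, "points", pts)

    @property
    def xy(self) -> np.ndarray:
        return self.points[:, :2]

    def __len__(self) -> int:
        return self.points.shape[0]


def stroke_length(stroke: Stroke) -> float:
    """Euclidean arc length of the stroke polyline, in canvas units."""
    d = np.diff(stroke.xy, axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass(frozen=True)
class Drawing:
    """A child's drawing of one category prompt within one kiosk session."""

    drawing_id: str
    strokes: tuple[Stroke, ...]
    category: str
    age_years: int
    session_id: str
    draw_time_s: float
    canvas_size: tuple[int, int] = (300, 300)

    def __post_init__(self) -> None:
        object.__setattr__(self, "strokes", tuple(self.strokes))
        w, h = self.canvas_size
        if self.draw_time_s < 0:
            raise CorpusValidationError(
                f"{self.drawing_id}: draw_time_s must be >= 0"
            )
        if self.draw_time_s > DRAW_TIME_CAP_S:
            warnings.warn(
                f"{self.drawing_id}: draw_time_s {self.draw_time_s:.1f}s exceeds "
                f"the {DRAW_TIME_CAP_S:.0f}s trial cap; clipping",
                stacklevel=2,
            )
            object.__setattr__(self, "draw_time_s", DRAW_TIME_CAP_S)
        for k, s in enumerate(self.strokes):
            xy = s.xy
            if (
                np.any(xy[:, 0] < 0)
                or np.any(xy[:, 0] > w)
                or np.any(xy[:, 1] < 0)
                or np.any(xy[:, 1] > h)
            ):
                raise CorpusValidationError(
                    f"{self.drawing_id}: stroke {k} has coordinates outside the "
                    f"{w}x{h} canvas"
                )

    @property
    def n_strokes(self) -> int:
        return len(self.strokes)


@dataclass(frozen=True)
class TracingTrial:
    """A shape-tracing trial: the child's strokes plus the target raster."""

    session_id: str
    shape_id: str
    strokes: tuple[Stroke, ...]
    target: np.ndarray
    canvas_size: tuple[int, int] = (300, 300)

    def __post_init__(self) -> None:
        object.__setattr__(self, "strokes", tuple(self.strokes))
        t = np.asarray(self.target, dtype=float)
        if t.ndim != 2 or np.any(t < 0) or np.any(t > 1):
            raise CorpusValidationError(
                f"target raster for {self.session_id}/{self.shape_id} must be a "
                "2-D array with values in [0, 1]"
            )
        object.__setattr__(self, "target", t)


@dataclass(frozen=True)
class CategoryMeta:
    """Semantic metadata for one category prompt.

    ``big`` is the real-world size class of inanimate objects (bigger than
    a chair vs. holdable in one hand) and is undefined — ``None`` — for
    animals.  ``draw_frequency`` is a parent-reported practice score.
    """

    category: str
    animate: bool
    big: Optional[bool] = None
    draw_frequency: float = 0.0

    def __post_init__(self) -> None:
        if self.animate and self.big is not None:
            raise CorpusValidationError(
                f"{self.category}: size class must be undefined for animate categories"
            )
        if not self.animate and self.big is None:
            raise CorpusValidationError(
                f"{self.category}: inanimate categories require a size class"
            )


@dataclass(frozen=True)
class EffortCovariates:
    draw_time_s: float
    n_strokes: int
    ink_proportion: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ink_proportion <= 1.0:
            raise CorpusValidationError("ink_proportion must lie in [0, 1]")


@dataclass
class Corpus:
    """A validated collection of drawings, tracing trials, and metadata."""

    drawings: list[Drawing] = field(default_factory=list)
    tracings: list[TracingTrial] = field(default_factory=list)
    categories: dict[str, CategoryMeta] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.drawings)

    @property
    def sessions(self) -> dict[str, list[Drawing]]:
        out: dict[str, list[Drawing]] = {}
        for d in self.drawings:
            out.setdefault(d.session_id, []).append(d)
        return out


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def rasterize(
    drawing: Drawing | Sequence[Stroke],
    size: int = DEFAULT_RASTER_SIZE,
    stroke_width: int = DEFAULT_STROKE_WIDTH,
    canvas_size: Optional[tuple[int, int]] = None,
) -> np.ndarray:
    """Render strokes as black polylines on a white square raster.

    Strokes are drawn as connected polylines in their recorded order with no
    anti-aliasing, so ink coverage is binary and exactly reproducible.
    Later strokes never lighten already-black pixels.  A drawing with zero
    strokes yields an all-white raster.

    Parameters
    ----------
    drawing
        A :class:`Drawing` or a bare stroke sequence (then ``canvas_size``
        is required).
    size
        Output raster is ``size x size`` pixels; must be >= 16.
    stroke_width
        Pen width in output pixels, >= 1.
    """
    if size < 16:
        raise ValueError("raster size must be >= 16")
    if stroke_width < 1:
        raise ValueError("stroke_width must be >= 1")
    if isinstance(drawing, Drawing):
        strokes: Sequence[Stroke] = drawing.strokes
        cw, ch = drawing.canvas_size
    else:
        strokes = drawing
        if canvas_size is None:
            raise ValueError("canvas_size is required for bare stroke sequences")
        cw, ch = canvas_size

    img = Image.new("L", (size, size), color=255)
    draw = ImageDraw.Draw(img)
    sx, sy = size / cw, size / ch
    for s in strokes:
        pts = [(x * sx, y * sy) for x, y in s.xy]
        if len(pts) == 1:
            x, y = pts[0]
            r = stroke_width / 2.0
            draw.ellipse([x - r, y - r, x + r, y + r], fill=0)
        else:
            draw.line(pts, fill=0, width=stroke_width, joint="curve")
    return np.asarray(img, dtype=float) / 255.0


def effort_covariates(drawing: Drawing, raster: np.ndarray) -> EffortCovariates:
    """Effort measures: draw time, stroke count, and proportion of inked pixels.

    "Ink" is any pixel strictly darker than the white background.
    """
    ink = float(np.mean(np.asarray(raster) < 1.0))
    return EffortCovariates(
        draw_time_s=drawing.draw_time_s,
        n_strokes=drawing.n_strokes,
        ink_proportion=ink,
    )


def drawing_to_svg(drawing: Drawing) -> str:
    """Minimal SVG export (one ``<polyline>`` per stroke) for inspection."""
    w, h = drawing.canvas_size
    lines = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{w}" height="{h}" '
        f'viewBox="0 0 {w} {h}">',
        f'<rect width="{w}" height="{h}" fill="white"/>',
    ]
    for s in drawing.strokes:
        pts = " ".join(f"{x:.2f},{y:.2f}" for x, y in s.xy)
        lines.append(
            f'<polyline points="{pts}" fill="none" stroke="black" stroke-width="2"/>'
        )
    lines.append("</svg>")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# corpus I/O
# ---------------------------------------------------------------------------
#
# On-disk layout under a corpus directory:
#   drawings.jsonl    one drawing per line:
#       {"drawing_id": ..., "session_id": ..., "category": ..., "age": ...,
#        "draw_time_s": ..., "canvas": [w, h], "strokes": [[[x,y,t],...],...]}
#   tracings.jsonl    one tracing trial per line (target raster stored as a
#       nested list of floats — targets are small binary shapes)
#   categories.csv    columns: category, animate, big, draw_frequency


def _drawing_from_record(rec: dict) -> Drawing:
    try:
        strokes = tuple(Stroke(np.asarray(s, dtype=float)) for s in rec["strokes"])
        return Drawing(
            drawing_id=str(rec["drawing_id"]),
            strokes=strokes,
            category=str(rec["category"]),
            age_years=int(rec["age"]),
            session_id=str(rec["session_id"]),
            draw_time_s=float(rec["draw_time_s"]),
            canvas_size=tuple(rec.get("canvas", (300, 300))),
        )
    except CorpusValidationError as exc:
        raise CorpusValidationError(
            f"record {rec.get('drawing_id', '<missing id>')}: {exc}"
        ) from exc
    except (KeyError, TypeError, ValueError) as exc:
        raise CorpusParseError(
            f"record {rec.get('drawing_id', '<missing id>')}: {exc}"
        ) from exc


def _drawing_to_record(d: Drawing) -> dict:
    return {
        "drawing_id": d.drawing_id,
        "session_id": d.session_id,
        "category": d.category,
        "age": d.age_years,
        "draw_time_s": d.draw_time_s,
        "canvas": list(d.canvas_size),
        "strokes": [s.points.tolist() for s in d.strokes],
    }


def load_corpus(path: str | Path) -> Corpus:
    """Load a corpus directory (see module docstring for the layout).

    Missing files are treated as empty; an empty directory yields an empty
    corpus.  Records violating type invariants are rejected with an error
    naming the offending record.  Drawings with a category not present in
    ``categories.csv`` (when that file exists) are a validation error.
    """
    path = Path(path)
    corpus = Corpus()

    cat_file = path / "categories.csv"
    if cat_file.exists():
        df = pd.read_csv(cat_file)
        for _, row in df.iterrows():
            big = row.get("big")
            if pd.isna(big):
                big = None
            else:
                big = bool(big)
            corpus.categories[str(row["category"])] = CategoryMeta(
                category=str(row["category"]),
                animate=bool(row["animate"]),
                big=big,
                draw_frequency=float(row.get("draw_frequency", 0.0)),
            )

    dfile = path / "drawings.jsonl"
    if dfile.exists():
        with open(dfile) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusParseError(
                        f"{dfile.name}:{lineno}: invalid JSON ({exc})"
                    ) from exc
                d = _drawing_from_record(rec)
                if corpus.categories and d.category not in corpus.categories:
                    raise CorpusValidationError(
                        f"record {d.drawing_id}: unknown category {d.category!r}"
                    )
                corpus.drawings.append(d)

    tfile = path / "tracings.jsonl"
    if tfile.exists():
        with open(tfile) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                rec = json.loads(line)
                corpus.tracings.append(
                    TracingTrial(
                        session_id=str(rec["session_id"]),
                        shape_id=str(rec["shape_id"]),
                        strokes=tuple(
                            Stroke(np.asarray(s, dtype=float)) for s in rec["strokes"]
                        ),
                        target=np.asarray(rec["target"], dtype=float),
                        canvas_size=tuple(rec.get("canvas", (300, 300))),
                    )
                )
    return corpus


def save_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus directory in the format :func:`load_corpus` reads."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "drawings.jsonl", "w") as fh:
        for d in corpus.drawings:
            fh.write(json.dumps(_drawing_to_record(d)) + "\n")
    with open(path / "tracings.jsonl", "w") as fh:
        for t in corpus.tracings:
            fh.write(
                json.dumps(
                    {
                        "session_id": t.session_id,
                        "shape_id": t.shape_id,
                        "canvas": list(t.canvas_size),
                        "strokes": [s.points.tolist() for s in t.strokes],
                        "target": np.asarray(t.target).tolist(),
                    }
                )
                + "\n"
            )
    if corpus.categories:
        rows = [
            {
                "category": m.category,
                "animate": m.animate,
                "big": m.big,
                "draw_frequency": m.draw_frequency,
            }
            for m in corpus.categories.values()
        ]
        pd.DataFrame(rows).to_csv(path / "categories.csv", index=False)
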