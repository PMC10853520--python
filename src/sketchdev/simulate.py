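"""Synthetic study generator.

Every input the analysis pipeline consumes — drawings, tracings, ratings,
stroke annotations, recognition-game sessions, and drawing embeddings —
can be generated here with controllable ground truth, so each downstream
stage is testable end-to-end with no external data.

The generative story mirrors the structure of the kiosk study, not its
visual appearance.  Each category is a template of named parts (polylines
in the unit square with salience weights); a child of a given age includes
each part independently with an age-increasing probability and draws it
with age-decreasing motor jitter.  Categories within the same broad class
(animals, big objects, small objects) share part vocabulary and embedding
structure, so classifier confusions concentrate within class.  Recognition
sessions choose among four alternatives with softmax sensitivity to a
drawing's classifier evidence that grows with the recognizer's age.
Tracing ratings come from a known proportional-odds model with rater
intercepts.

All generators are pure functions of their parameters and a seed; a single
seed fans out into independent component streams via ``sketchdev._rng``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._rng import child_rng
from .corpus import (
    CategoryMeta,
    Drawing,
    Stroke,
    TracingTrial,
    rasterize,
)
from .tracing import AffineParams

__all__ = [
    "Part",
    "CategoryTemplate",
    "AgeModel",
    "GeneratedDrawing",
    "ToyEncoder",
    "generate_category_library",
    "library_metadata",
    "generate_drawing",
    "generate_drawing_set",
    "make_target_shape",
    "generate_tracing_trial",
    "generate_annotations",
    "generate_ratings",
    "generate_recognition_sessions",
    "RecognitionSimConfig",
    "ANIMATE_PART_VOCAB",
    "INANIMATE_PART_VOCAB",
]

# Shared part vocabularies: animals share body-plan parts, objects share
# structural parts, which is what concentrates annotation confusions and
# embedding similarity within a broad class.
ANIMATE_PART_VOCAB = (
    "head", "body", "leg", "tail", "ear", "eye", "arm",
    "wing", "nose", "mouth", "foot", "neck", "whisker",
)
INANIMATE_PART_VOCAB = (
    "top", "base", "side", "handle", "door", "window", "wheel",
    "screen", "button", "leg", "lid", "corner", "edge",
)


@dataclass(frozen=True)
class Part:
    label: str
    polyline: np.ndarray  # (k, 2) vertices in the unit square
    salience: float

    def __post_init__(self) -> None:
        if self.salience <= 0:
            raise ValueError("salience weights must be positive")
        object.__setattr__(self, "polyline", np.asarray(self.polyline, dtype=float))


@dataclass(frozen=True)
class CategoryTemplate:
    category: str
    parts: tuple[Part, ...]
    animate: bool
    big: Optional[bool]

    def __post_init__(self) -> None:
        if len(self.parts) < 1:
            raise ValueError("a template needs at least one part")

    @property
    def part_labels(self) -> tuple[str, ...]:
        return tuple(p.label for p in self.parts)


@dataclass(frozen=True)
class AgeModel:
    """Age-graded drawing behavior.

    Per-part inclusion probability rises linearly with age (clipped to
    [0, 1]); motor jitter (Gaussian contour noise, canvas units) falls
    linearly with age to a floor.  Defaults span ages 2-10 with inclusion
    going 0.35 -> 0.91 and jitter 9 -> 1.5 canvas units, which produces the
    age-monotone recognizability the analyses are designed to detect.
    """

    base_inclusion: float = 0.35
    part_inclusion_slope: float = 0.07
    jitter_at_base: float = 9.0
    jitter_decay_per_year: float = 1.1
    jitter_floor: float = 1.5
    base_age: int = 2
    ms_per_point: float = 25.0

    def inclusion_prob(self, age_years: float) -> float:
        return float(
            np.clip(
                self.base_inclusion
                + self.part_inclusion_slope * (age_years - self.base_age),
                0.0,
                1.0,
            )
        )

    def jitter_scale(self, age_years: float) -> float:
        return float(
            max(
                self.jitter_floor,
                self.jitter_at_base
                - self.jitter_decay_per_year * (age_years - self.base_age),
            )
        )


def _part_polyline(rng: np.random.Generator, n_pts: int = 8) -> np.ndarray:
    """A small random open contour (arc, zigzag, or segment) in [0, 1]^2."""
    kind = rng.integers(3)
    t = np.linspace(0, 1, n_pts)
    if kind == 0:  # arc
        a0 = rng.uniform(0, 2 * math.pi)
        a1 = a0 + rng.uniform(math.pi / 2, 2 * math.pi)
        ang = a0 + (a1 - a0) * t
        xy = 0.5 + 0.4 * np.column_stack([np.cos(ang), np.sin(ang)])
    elif kind == 1:  # zigzag
        x = t
        y = 0.5 + 0.3 * np.where(np.arange(n_pts) % 2 == 0, 1.0, -1.0) * rng.uniform(
            0.3, 1.0
        )
        xy = np.column_stack([x, y])
    else:  # straight-ish segment
        p0 = rng.uniform(0.1, 0.9, size=2)
        p1 = rng.uniform(0.1, 0.9, size=2)
        xy = p0 + (p1 - p0) * t[:, None]
    return np.clip(xy, 0.0, 1.0)


def generate_category_library(
    n_categories: int = 48,
    n_animate: int = 22,
    seed: int = 0,
    big_fraction: float = 0.5,
    parts_per_category: tuple[int, int] = (5, 9),
    shared_parts: int = 3,
) -> list[CategoryTemplate]:
    """Build a deterministic library of category templates.

    Exactly ``n_animate`` categories are animate; a ``big_fraction`` share
    of the inanimate ones are flagged big (larger than a chair), the rest
    small.  Each category has ``shared_parts`` labels drawn from its broad
    class's shared vocabulary plus category-specific detail parts, so that
    categories within a class overlap in parts.
    """
    if n_categories < 2:
        raise ValueError("classification is undefined for fewer than 2 categories")
    if not 0 <= n_animate <= n_categories:
        raise ValueError("n_animate must lie in [0, n_categories]")
    rng = child_rng(seed, "library")
    n_inanimate = n_categories - n_animate
    n_big = int(round(big_fraction * n_inanimate))

    templates: list[CategoryTemplate] = []
    for i in range(n_categories):
        animate = i < n_animate
        if animate:
            name = f"animal{i:02d}"
            big = None
            vocab = ANIMATE_PART_VOCAB
        else:
            j = i - n_animate
            big = j < n_big
            name = f"object{j:02d}"
            vocab = INANIMATE_PART_VOCAB
        n_parts = int(rng.integers(parts_per_category[0], parts_per_category[1] + 1))
        n_shared = min(shared_parts, n_parts, len(vocab))
        labels = [str(v) for v in rng.choice(vocab, size=n_shared, replace=False)]
        labels += [f"{name}_detail{k}" for k in range(n_parts - n_shared)]
        parts = tuple(
            Part(
                label=lab,
                polyline=_part_polyline(rng),
                salience=float(rng.lognormal(0.0, 0.4)),
            )
            for lab in labels
        )
        templates.append(
            CategoryTemplate(category=name, parts=parts, animate=animate, big=big)
        )
    return templates


def library_metadata(
    library: Sequence[CategoryTemplate], seed: int = 0
) -> dict[str, CategoryMeta]:
    """Category metadata table (animacy, size class, parent-reported drawing
    frequency on a 1-5 scale) for a generated library."""
    rng = child_rng(seed, "draw-frequency")
    out = {}
    for t in library:
        out[t.category] = CategoryMeta(
            category=t.category,
            animate=t.animate,
            big=t.big,
            draw_frequency=float(np.clip(rng.normal(3.0, 1.0), 1.0, 5.0)),
        )
    return out


@dataclass(frozen=True)
class GeneratedDrawing:
    """A synthetic drawing plus its ground truth (per-stroke part labels)."""

    drawing: Drawing
    part_labels: tuple[str, ...]  # one label per stroke

    @property
    def drawing_id(self) -> str:
        return self.drawing.drawing_id


def generate_drawing(
    template: CategoryTemplate,
    age_years: int,
    age_model: AgeModel,
    seed: int | np.random.Generator,
    drawing_id: Optional[str] = None,
    session_id: Optional[str] = None,
    canvas_size: tuple[int, int] = (300, 300),
    inclusion_prob: Optional[float] = None,
) -> GeneratedDrawing:
    """Simulate one drawing: each template part is independently included
    with its age-dependent probability and rendered as one jittered stroke.

    ``inclusion_prob`` overrides the age model's probability when given
    (useful for boundary and calibration tests).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else child_rng(int(seed), f"drawing:{template.category}:{age_years}")
    )
    p_inc = (
        age_model.inclusion_prob(age_years) if inclusion_prob is None else inclusion_prob
    )
    jitter = age_model.jitter_scale(age_years)
    w, h = canvas_size
    margin = 0.1 * min(w, h)
    strokes: list[Stroke] = []
    labels: list[str] = []
    t_ms = 0.0
    for part in template.parts:
        if rng.random() >= p_inc:
            continue
        xy = margin + part.polyline * np.array([w - 2 * margin, h - 2 * margin])
        # salience stretches the part's drawn extent about its centroid
        centroid = xy.mean(axis=0)
        xy = centroid + (xy - centroid) * min(part.salience, 1.8)
        if jitter > 0:
            xy = xy + rng.normal(0.0, jitter, size=xy.shape)
        xy = np.clip(xy, [0, 0], [w, h])
        n = xy.shape[0]
        ts = t_ms + age_model.ms_per_point * np.arange(n)
        t_ms = ts[-1] + 200.0  # inter-stroke pause
        strokes.append(Stroke(np.column_stack([xy, ts])))
        labels.append(part.label)
    did = drawing_id or f"{template.category}-a{age_years}-{rng.integers(1 << 30)}"
    drawing = Drawing(
        drawing_id=did,
        strokes=tuple(strokes),
        category=template.category,
        age_years=age_years,
        session_id=session_id or f"sess-{did}",
        draw_time_s=min(t_ms / 1000.0, 30.0),
        canvas_size=canvas_size,
    )
    return GeneratedDrawing(drawing=drawing, part_labels=tuple(labels))


def generate_drawing_set(
    library: Sequence[CategoryTemplate],
    ages: Sequence[int],
    n_per_age_per_category: int,
    age_model: AgeModel,
    seed: int,
) -> list[GeneratedDrawing]:
    """A balanced synthetic drawing set: n drawings per (age, category)."""
    out: list[GeneratedDrawing] = []
    for template in library:
        for age in ages:
            rng = child_rng(seed, f"set:{template.category}:{age}")
            for k in range(n_per_age_per_category):
                out.append(
                    generate_drawing(
                        template,
                        age,
                        age_model,
                        rng,
                        drawing_id=f"{template.category}-a{age}-{k:03d}",
                        session_id=f"sess-{template.category}-a{age}-{k:03d}",
                    )
                )
    return out


# ---------------------------------------------------------------------------
# tracing trials
# ---------------------------------------------------------------------------


def make_target_shape(
    shape_id: str, size: int = 224, stroke_width: int = 3, extent: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Return (contour polyline in pixel units, target raster) for a shape.

    ``square`` is the easy shape; ``star`` is the complex one with both
    sharp and oblique segments.  ``extent`` scales the shape about the
    center (useful when the shape must stay in frame under large
    perturbations).
    """
    c = (size - 1) / 2.0
    if shape_id == "square":
        r = 0.28 * size * extent
        pts = np.array(
            [[-r, -r], [r, -r], [r, r], [-r, r], [-r, -r]], dtype=float
        ) + c
    elif shape_id == "star":
        n_tips = 5
        outer, inner = 0.34 * size * extent, 0.15 * size * extent
        ang = -math.pi / 2 + np.arange(2 * n_tips + 1) * math.pi / n_tips
        rad = np.where(np.arange(2 * n_tips + 1) % 2 == 0, outer, inner)
        pts = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)]) + c
    else:
        raise ValueError(f"unknown shape_id {shape_id!r}")
    # densify so per-point jitter acts like contour noise, not vertex noise
    dense = [pts[0]]
    for a, b in zip(pts[:-1], pts[1:]):
        seg = np.linalg.norm(b - a)
        n = max(2, int(seg / 4))
        for t in np.linspace(0, 1, n + 1)[1:]:
            dense.append(a + t * (b - a))
    contour = np.asarray(dense)
    ts = np.arange(len(contour), dtype=float) * 10.0
    raster = rasterize(
        [Stroke(np.column_stack([contour, ts]))],
        size=size,
        stroke_width=stroke_width,
        canvas_size=(size, size),
    )
    return contour, raster


def generate_tracing_trial(
    shape_id: str,
    true_affine: AffineParams,
    contour_noise: float,
    seed: int,
    size: int = 224,
    stroke_width: int = 3,
    session_id: str = "sim-session",
) -> TracingTrial:
    """Simulate a tracing: the target contour mapped through ``true_affine``
    (about the raster center) plus Gaussian contour noise.

    The caller's ``true_affine`` is the ground truth a registration should
    invert.  Degenerate transforms (non-positive scale) are rejected by
    :class:`AffineParams` itself.
    """
    contour, raster = make_target_shape(shape_id, size=size, stroke_width=stroke_width)
    rng = child_rng(seed, f"tracing:{shape_id}")
    c = (size - 1) / 2.0
    ct, st = math.cos(true_affine.theta), math.sin(true_affine.theta)
    rot = np.array([[ct, -st], [st, ct]])
    scale = np.diag([true_affine.sx, true_affine.sy])
    xy = (contour - c) @ (rot @ scale).T + c + np.array([true_affine.tx, true_affine.ty])
    if contour_noise > 0:
        xy = xy + rng.normal(0.0, contour_noise, size=xy.shape)
    xy = np.clip(xy, [0, 0], [size, size])
    ts = np.arange(len(xy), dtype=float) * 15.0
    return TracingTrial(
        session_id=session_id,
        shape_id=shape_id,
        strokes=(Stroke(np.column_stack([xy, ts])),),
        target=raster,
        canvas_size=(size, size),
    )


# ---------------------------------------------------------------------------
# toy embedding encoder
# ---------------------------------------------------------------------------


class ToyEncoder:
    """A controllable stand-in encoder producing category-informative embeddings.

    ``embedding = signal * (category prototype + part projection)
                 + (1 - signal) * Gaussian noise``

    Category prototypes mix a broad-class center (animals / big objects /
    small objects) with a category-specific direction, so embedding
    similarity — and hence classifier confusion — concentrates within a
    class.  ``within_class`` in [0, 1) sets the share of prototype variance
    from the class center (0 gives unstructured, class-free prototypes).
    Deterministic per (input key, seed).
    """

    def __init__(
        self,
        library: Sequence[CategoryTemplate],
        dim: int = 64,
        signal: float = 0.5,
        seed: int = 0,
        within_class: float = 0.5,
        part_scale: float = 0.4,
    ):
        if dim < len(library):
            raise ValueError("embedding dim must be >= number of categories")
        if not 0.0 <= signal <= 1.0:
            raise ValueError("signal must lie in [0, 1]")
        self.dim = dim
        self.signal = float(signal)
        self.seed = int(seed)
        self.part_scale = part_scale
        rng = child_rng(seed, "encoder")

        def unit(v: np.ndarray) -> np.ndarray:
            return v / np.linalg.norm(v)

        class_centers = {
            key: unit(rng.normal(size=dim))
            for key in ("animate", "big", "small")
        }
        self.prototypes: dict[str, np.ndarray] = {}
        for t in library:
            key = "animate" if t.animate else ("big" if t.big else "small")
            own = unit(rng.normal(size=dim))
            self.prototypes[t.category] = unit(
                math.sqrt(within_class) * class_centers[key]
                + math.sqrt(1.0 - within_class) * own
            )
        all_labels = sorted({p.label for t in library for p in t.parts})
        self.part_vectors = {lab: unit(rng.normal(size=dim)) for lab in all_labels}
        self.categories = [t.category for t in library]

    def encode(
        self, category: str, part_labels: Sequence[str] = (), key: str = ""
    ) -> np.ndarray:
        signal_vec = self.prototypes[category].copy()
        labs = sorted(set(part_labels))
        if labs:
            pv = sum(self.part_vectors[lab] for lab in labs if lab in self.part_vectors)
            if np.ndim(pv):
                signal_vec = signal_vec + self.part_scale * pv / math.sqrt(len(labs))
        rng = child_rng(self.seed, f"noise:{key}")
        noise = rng.normal(size=self.dim)
        return self.signal * signal_vec + (1.0 - self.signal) * noise

    def encode_drawings(
        self, drawings: Sequence[GeneratedDrawing]
    ) -> tuple[pd.DataFrame, pd.Series]:
        """Embed a drawing set; returns (raw embedding matrix, target labels),
        both indexed by drawing id."""
        ids = [g.drawing_id for g in drawings]
        rows = [
            self.encode(g.drawing.category, g.part_labels, key=g.drawing_id)
            for g in drawings
        ]
        x = pd.DataFrame(np.asarray(rows), index=ids)
        y = pd.Series([g.drawing.category for g in drawings], index=ids, name="target")
        return x, y


# ---------------------------------------------------------------------------
# annotations, ratings, recognition sessions
# ---------------------------------------------------------------------------


def generate_annotations(
    generated: GeneratedDrawing,
    agreement_rate: float,
    n_raters: int = 3,
    seed: int = 0,
    vocabulary: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Simulate multi-rater per-stroke part labels.

    Each rater reports the true label with probability ``agreement_rate``;
    otherwise they pick uniformly from the other vocabulary labels plus
    "unintelligible".  Returns the long annotation table
    (drawing_id, stroke_index, rater_id, labels).
    """
    if not 0.0 <= agreement_rate <= 1.0:
        raise ValueError("agreement_rate must lie in [0, 1]")
    if n_raters < 1:
        raise ValueError("need at least one rater")
    rng = child_rng(seed, f"annotations:{generated.drawing_id}")
    vocab = list(vocabulary) if vocabulary is not None else sorted(
        set(generated.part_labels)
    )
    rows = []
    for k, true_label in enumerate(generated.part_labels):
        for r in range(n_raters):
            if rng.random() < agreement_rate:
                lab = true_label
            else:
                alternatives = [v for v in vocab if v != true_label] + ["unintelligible"]
                lab = alternatives[rng.integers(len(alternatives))]
            rows.append(
                {
                    "drawing_id": generated.drawing_id,
                    "stroke_index": k,
                    "rater_id": f"rater{r}",
                    "labels": lab,
                }
            )
    return pd.DataFrame(rows)


def generate_ratings(
    errors: pd.DataFrame,
    coefficients: pd.Series | dict,
    thresholds: Sequence[float],
    rater_sd: float,
    seed: int = 0,
    n_raters: int = 20,
    ratings_per_tracing: int = 3,
) -> pd.DataFrame:
    """Simulate 1-5 tracing quality ratings from a proportional-odds model.

    ``P(rating <= k) = logistic(threshold_k - (X @ coef + u_rater))`` with
    rater intercepts ``u ~ N(0, rater_sd^2)``.  ``errors`` holds one row per
    tracing (indexed by id) with the coefficient columns.
    """
    thr = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thr) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    coef = pd.Series(coefficients)
    rng = child_rng(seed, "ratings")
    u = rng.normal(0.0, rater_sd, size=n_raters)
    eta = errors[coef.index.tolist()].to_numpy(dtype=float) @ coef.to_numpy()
    rows = []
    for i, tid in enumerate(errors.index):
        raters = rng.choice(n_raters, size=ratings_per_tracing, replace=False)
        for r in raters:
            cum = 1.0 / (1.0 + np.exp(-(thr - (eta[i] + u[r]))))
            probs = np.diff(np.concatenate([[0.0], cum, [1.0]]))
            rating = int(rng.choice(len(probs), p=probs)) + 1
            rows.append(
                {"tracing_id": tid, "rater_id": f"rater{r}", "rating": rating}
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RecognitionSimConfig:
    """Guessing-game simulation settings.

    The probability of choosing the target among 4 options is a softmax
    with utility ``beta(age) * evidence`` for the target and 0 for each
    distractor, ``beta(age) = beta0 + beta_age * (age - 3)``.  Reaction
    times are lognormal in ms with a configurable fraction replaced by
    out-of-range outliers; photograph (practice/catch) trials have a flat
    per-trial error rate.
    """

    ages: tuple[int, ...] = (3, 4, 5, 6, 7, 8)
    n_sessions_per_age: int = 25
    n_drawing_trials: int = 40
    catch_every: int = 10
    beta0: float = 0.8
    beta_age: float = 0.25
    catch_error_rate: float = 0.05
    dont_know_rate: float = 0.02
    rt_log_mu: float = 7.2  # ~1.3 s median
    rt_log_sigma: float = 0.5
    rt_outlier_rate: float = 0.01
    interference_sessions: int = 0
    underage_sessions: int = 0
    adult_sessions: int = 0


def _simulate_session(
    rng: np.random.Generator,
    session_id: str,
    age: float,
    is_adult: bool,
    interference: bool,
    game_id: str,
    categories: Sequence[str],
    drawings: pd.DataFrame,
    cfg: RecognitionSimConfig,
) -> list[dict]:
    beta = cfg.beta0 + cfg.beta_age * (age - 3.0) if not is_adult else cfg.beta0 + 2.0
    rows = []

    def rt() -> float:
        if rng.random() < cfg.rt_outlier_rate:
            return float(rng.choice([rng.uniform(10, 90), rng.uniform(10_500, 25_000)]))
        return float(np.exp(rng.normal(cfg.rt_log_mu, cfg.rt_log_sigma)))

    def photo_trial(kind: str) -> dict:
        target = categories[rng.integers(len(categories))]
        if rng.random() < cfg.catch_error_rate:
            others = [c for c in categories if c != target]
            resp = others[rng.integers(len(others))]
        else:
            resp = target
        return {
            "session_id": session_id,
            "recognizer_age_years": age,
            "is_adult": is_adult,
            "interference": interference,
            "game_id": game_id,
            "trial_type": kind,
            "drawing_id": f"photo-{target}",
            "category": target,
            "choices": ";".join(categories),
            "response": resp,
            "rt_ms": rt(),
            "correct": resp == target,
        }

    for _ in range(4):
        rows.append(photo_trial("practice"))
    n_done = 0
    for k in range(cfg.n_drawing_trials):
        if n_done and n_done % cfg.catch_every == 0:
            rows.append(photo_trial("catch"))
        draw = drawings.iloc[int(rng.integers(len(drawings)))]
        target = draw["category"]
        p_correct = math.exp(beta * draw["evidence"]) / (
            math.exp(beta * draw["evidence"]) + (len(categories) - 1)
        )
        if rng.random() < cfg.dont_know_rate:
            resp = "dont-know"
        elif rng.random() < p_correct:
            resp = target
        else:
            others = [c for c in categories if c != target]
            resp = others[rng.integers(len(others))]
        rows.append(
            {
                "session_id": session_id,
                "recognizer_age_years": age,
                "is_adult": is_adult,
                "interference": interference,
                "game_id": game_id,
                "trial_type": "drawing",
                "drawing_id": draw["drawing_id"],
                "category": target,
                "choices": ";".join(categories),
                "response": resp,
                "rt_ms": rt(),
                "correct": resp == target,
            }
        )
        n_done += 1
    return rows


def generate_recognition_sessions(
    games: dict[str, pd.DataFrame],
    cfg: RecognitionSimConfig,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate 4AFC guessing-game sessions.

    ``games`` maps game id to a drawing table with columns
    ``drawing_id``, ``category`` (4 distinct values), ``evidence``.
    Sessions to be excluded downstream (interference, under-3, adult) are
    appended after the clean sessions, each with its flag set.
    """
    rng = child_rng(seed, "recognition")
    game_ids = sorted(games)
    for gid in game_ids:
        cats = sorted(games[gid]["category"].unique())
        if len(cats) != 4:
            raise ValueError(f"game {gid} must have exactly 4 categories")
    rows: list[dict] = []
    i = 0
    for age in cfg.ages:
        for _ in range(cfg.n_sessions_per_age):
            gid = game_ids[i % len(game_ids)]
            cats = sorted(games[gid]["category"].unique())
            rows += _simulate_session(
                rng, f"recog-{i:05d}", float(age), False, False, gid,
                cats, games[gid], cfg,
            )
            i += 1
    specials = (
        [(float(rng.choice(cfg.ages)), False, True)] * cfg.interference_sessions
        + [(2.0, False, False)] * cfg.underage_sessions
        + [(30.0, True, False)] * cfg.adult_sessions
    )
    for age, adult, interf in specials:
        gid = game_ids[i % len(game_ids)]
        cats = sorted(games[gid]["category"].unique())
        rows += _simulate_session(
            rng, f"recog-{i:05d}", age, adult, interf, gid, cats, games[gid], cfg
        )
        i += 1
    return pd.DataFrame(rows)
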