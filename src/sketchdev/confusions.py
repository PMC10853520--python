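"""Semantic structure in classifier confusions.

Even when a drawing is misclassified, the category the classifier confuses
it with may share the target's broad semantic attributes — its animacy, or
(for inanimate objects) its real-world size class.  This module builds the
mean confusion-probability matrix, scores per-(age, category) attribute
match of the top confused category against the target, corrects those
proportions for baseline attribute prevalence, and attaches category-level
bootstrap confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .corpus import CategoryMeta

__all__ = [
    "confusion_matrix",
    "attribute_match",
    "bootstrap_category_ci",
    "AttributeScore",
]


@dataclass(frozen=True)
class AttributeScore:
    age_years: int
    category: str
    attribute: str
    raw_match: float
    baseline: float
    corrected: float
    n_drawings: int

    def __post_init__(self) -> None:
        if self.n_drawings < 1:
            raise ValueError("n_drawings must be >= 1")
        if not -1.0 <= self.corrected <= 1.0:
            raise ValueError("corrected score must lie in [-1, 1]")


def _prob_columns(outputs: pd.DataFrame) -> list[str]:
    cols = [c for c in outputs.columns if c.startswith("p_") and c != "p_target"]
    if not cols:
        raise ValueError("outputs frame carries no per-category probability columns")
    return cols


def confusion_matrix(
    outputs: pd.DataFrame, restrict_misclassified: bool = True
) -> pd.DataFrame:
    """Mean probability matrix: rows are intended categories, columns the
    categories probability was assigned to.

    With ``restrict_misclassified`` only incorrectly classified drawings
    enter the averages.  Rows sum to 1; a target with no (misclassified)
    drawings yields a row of NaNs with a warning.
    """
    cols = _prob_columns(outputs)
    cats = [c[2:] for c in cols]
    df = outputs[~outputs["correct"]] if restrict_misclassified else outputs
    mat = pd.DataFrame(index=cats, columns=cats, dtype=float)
    for cat in cats:
        rows = df[df["target"] == cat]
        if len(rows) == 0:
            warnings.warn(f"no drawings for target {cat!r}; row is NaN", stacklevel=2)
            continue
        mat.loc[cat] = rows[cols].mean(axis=0).to_numpy()
    sums = mat.sum(axis=1, skipna=False)
    ok = ~sums.isna()
    np.testing.assert_allclose(sums[ok].to_numpy(dtype=float), 1.0, atol=1e-8)
    return mat


def _attr_value(meta: CategoryMeta, attribute: str) -> Optional[bool]:
    if attribute == "animacy":
        return meta.animate
    if attribute == "size":
        return meta.big  # None for animals: undefined
    raise ValueError(f"unknown attribute {attribute!r}")


def attribute_match(
    outputs: pd.DataFrame,
    meta: dict[str, CategoryMeta],
    attribute: str,
    ages: Optional[pd.Series] = None,
    baseline_mode: str = "category",
) -> tuple[pd.DataFrame, dict]:
    """Baseline-corrected attribute decoding from misclassified drawings.

    For every misclassified drawing, the top predicted (non-target)
    category either matches the target's attribute class or not; matches
    are averaged per (age, category) and corrected by subtracting the
    baseline prevalence of the target's attribute class.  With the default
    ``baseline_mode="category"`` the baseline is the share of the target's
    class among the other K-1 candidate categories; ``"drawing"`` weights
    categories by their drawing counts in ``outputs`` instead.

    Drawings whose target lacks the attribute (size for animals) are
    skipped and tallied in the returned skip report.

    Parameters
    ----------
    ages
        Drawer age per drawing id; defaults to an ``age_years`` column of
        ``outputs`` if present, else a single pooled pseudo-age of -1.
    """
    if baseline_mode not in ("category", "drawing"):
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}")
    mis = outputs[~outputs["correct"]].copy()
    if ages is not None:
        mis["age_years"] = ages.loc[mis.index].to_numpy()
    elif "age_years" not in mis.columns:
        mis["age_years"] = -1

    cats = sorted({c[2:] for c in _prob_columns(outputs)})
    attr_of = {c: _attr_value(meta[c], attribute) for c in cats}
    drawing_counts = outputs["target"].value_counts()

    skip: dict[str, int] = {"undefined_attribute": 0}
    rows = []
    for (age, cat), grp in mis.groupby(["age_years", "target"]):
        target_attr = attr_of[cat]
        if target_attr is None:
            skip["undefined_attribute"] += len(grp)
            continue
        others = [c for c in cats if c != cat and attr_of[c] is not None]
        matches = [attr_of[p] == target_attr for p in grp["predicted"]]
        raw = float(np.mean(matches))
        if baseline_mode == "category":
            base = float(np.mean([attr_of[c] == target_attr for c in others]))
        else:
            w = np.array([drawing_counts.get(c, 0) for c in others], dtype=float)
            m = np.array([attr_of[c] == target_attr for c in others], dtype=float)
            base = float((w * m).sum() / w.sum())
        rows.append(
            {
                "age_years": age,
                "category": cat,
                "attribute": attribute,
                "raw_match": raw,
                "baseline": base,
                "corrected": raw - base,
                "n_drawings": len(grp),
            }
        )
    return pd.DataFrame(rows), skip


def bootstrap_category_ci(
    values: Sequence[float],
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean, resampling categories.

    Deterministic per seed; requires at least 2 categories and B >= 100.
    """
    vals = np.asarray(values, dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least 2 categories to bootstrap")
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(vals), size=(B, len(vals)))
    means = vals[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
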