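"""4AFC guessing-game analysis.

Raw trial logs pass through a staged, ordered exclusion pipeline
(interference sessions, out-of-range recognizer ages, one-trial
participants, out-of-range reaction times, and participants failing the
photograph-matching accuracy gate), with a reconciling report of counts
removed at every stage.  Each drawing presented in a game gets a
leave-one-out classifier evidence score from a 4-way logistic model
trained on the game's other drawings, and recognition accuracy is
summarized by recognizer age, evidence decile, or unique-part count with
bootstrap confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .recognize import DEFAULT_HYPER, _fit_logistic, classifier_evidence

__all__ = [
    "ExclusionReport",
    "apply_exclusions",
    "loo_game_evidence",
    "accuracy_summary",
    "RT_MIN_MS",
    "RT_MAX_MS",
    "PHOTO_ACCURACY_MIN",
    "MIN_RECOGNIZER_AGE",
]

RT_MIN_MS = 100.0
RT_MAX_MS = 10_000.0
PHOTO_ACCURACY_MIN = 0.75
MIN_RECOGNIZER_AGE = 3.0


@dataclass(frozen=True)
class ExclusionReport:
    """Counts removed at each staged filter, reconciling to the input."""

    input_sessions: int
    input_trials: int
    interference_sessions: int
    age_out_sessions: int
    one_trial_sessions: int
    rt_out_trials: int
    catch_fail_sessions: int
    remaining_sessions: int
    remaining_trials: int
    remaining_drawing_trials: int
    mean_trials_per_session: float

    def reconciles(self) -> bool:
        sessions_ok = (
            self.input_sessions
            - self.interference_sessions
            - self.age_out_sessions
            - self.one_trial_sessions
            - self.catch_fail_sessions
            == self.remaining_sessions
        )
        return sessions_ok

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def apply_exclusions(
    trials: pd.DataFrame,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the staged exclusion rules to a 4AFC trial log.

    Stages, in order: (1) drop sessions with reported interference;
    (2) drop sessions with recognizer age below 3 and adult sessions;
    (3) drop participants who completed at most 1 trial after the practice
    trials; (4) drop individual trials with reaction time below 100 ms or
    above 10 s; (5) drop participants below 75% accuracy on photograph
    (practice + catch) trials — exactly 75% is retained.  "Don't-know"
    responses are kept and score as incorrect.

    Returns the retained trials (all trial types) and the reconciling
    :class:`ExclusionReport`.
    """
    required = {"session_id", "trial_type", "rt_ms", "correct"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial log missing columns: {sorted(missing)}")
    bad_rt = trials["rt_ms"].isna()
    if bad_rt.any():
        ids = trials.index[bad_rt].tolist()[:10]
        raise ValueError(f"trials with missing reaction times: {ids}")

    df = trials.copy()
    input_sessions = df["session_id"].nunique()
    input_trials = len(df)

    # stage 1: reported interference
    if "interference" in df.columns:
        interf = df.groupby("session_id")["interference"].any()
        drop1 = set(interf.index[interf])
    else:
        drop1 = set()
    df = df[~df["session_id"].isin(drop1)]

    # stage 2: recognizer age out of range (under 3, or adult)
    age = df.get("recognizer_age_years", pd.Series(np.nan, index=df.index))
    adult = df.get("is_adult", pd.Series(False, index=df.index)).astype(bool)
    out = (age < MIN_RECOGNIZER_AGE) | adult
    drop2 = set(df.loc[out, "session_id"].unique()) - drop1
    df = df[~df["session_id"].isin(drop2)]

    # stage 3: at most one post-practice trial
    post = df[df["trial_type"] != "practice"]
    n_post = post.groupby("session_id").size()
    all_sessions = df["session_id"].unique()
    drop3 = {
        s for s in all_sessions if n_post.get(s, 0) <= 1
    }
    df = df[~df["session_id"].isin(drop3)]

    # stage 4: out-of-range reaction times (trial-level)
    rt_bad = (df["rt_ms"] < RT_MIN_MS) | (df["rt_ms"] > RT_MAX_MS)
    n_rt_out = int(rt_bad.sum())
    df = df[~rt_bad]

    # stage 5: photograph-trial accuracy below threshold
    photo = df[df["trial_type"].isin(["practice", "catch"])]
    acc = photo.groupby("session_id")["correct"].mean()
    drop5 = set(acc.index[acc < PHOTO_ACCURACY_MIN])
    df = df[~df["session_id"].isin(drop5)]

    n_drawing = int((df["trial_type"] == "drawing").sum())
    remaining_sessions = df["session_id"].nunique()
    report = ExclusionReport(
        input_sessions=input_sessions,
        input_trials=input_trials,
        interference_sessions=len(drop1),
        age_out_sessions=len(drop2),
        one_trial_sessions=len(drop3),
        rt_out_trials=n_rt_out,
        catch_fail_sessions=len(drop5),
        remaining_sessions=remaining_sessions,
        remaining_trials=len(df),
        remaining_drawing_trials=n_drawing,
        mean_trials_per_session=(
            len(df) / remaining_sessions if remaining_sessions else float("nan")
        ),
    )
    assert report.reconciles(), "exclusion stages do not reconcile"
    return df, report


def loo_game_evidence(
    embeddings: pd.DataFrame,
    targets: pd.Series,
    hyper: Optional[dict] = None,
) -> pd.DataFrame:
    """Leave-one-out 4-way classifier evidence for one game's drawings.

    For each drawing, a logistic model trained on every *other* drawing in
    the game yields its probability over the game's 4 categories; evidence
    is the log-odds of the target probability.  A category represented by a
    single drawing cannot be held out against a model that still knows the
    category, so its drawing is skipped with a warning.
    """
    hyper = {**DEFAULT_HYPER, **(hyper or {})}
    targets = targets.loc[embeddings.index]
    cats = sorted(targets.unique())
    if len(cats) != 4:
        raise ValueError(f"a game requires exactly 4 categories, got {len(cats)}")
    counts = targets.value_counts()
    singletons = set(counts.index[counts < 2])
    if singletons:
        warnings.warn(
            f"skipping drawings of single-drawing categories: {sorted(singletons)}",
            stacklevel=2,
        )
    keep = ~targets.isin(singletons)
    x = embeddings.to_numpy(dtype=float)
    y = targets.to_numpy()
    rows = []
    for i, did in enumerate(embeddings.index):
        if not keep.iloc[i]:
            continue
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        clf = _fit_logistic(x[mask], y[mask], hyper)
        prob = clf.predict_proba(x[i : i + 1])[0]
        classes = list(clf.classes_)
        p_t = prob[classes.index(y[i])]
        rows.append(
            {
                "drawing_id": did,
                "target": y[i],
                "predicted": classes[int(np.argmax(prob))],
                "p_target": p_t,
                "evidence": classifier_evidence(p_t),
            }
        )
    out = pd.DataFrame(rows).set_index("drawing_id")
    out["correct"] = out["predicted"] == out["target"]
    return out


def accuracy_summary(
    trials: pd.DataFrame,
    grouping: str = "age",
    B: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Grouped recognition accuracy with percentile bootstrap CIs.

    ``grouping`` is one of ``"age"``, ``"age_x_evidence"`` (deciles of the
    evidence distribution over presented drawings), or ``"age_x_parts"``
    (unique-part counts).  Only drawing trials enter; empty groups simply
    do not appear.  Requires an ``evidence`` / ``n_unique_parts`` column
    joined onto the trials where the grouping needs it.
    """
    df = trials[trials["trial_type"] == "drawing"].copy()
    df["age"] = df["recognizer_age_years"].astype(int)
    if grouping == "age":
        keys = ["age"]
    elif grouping == "age_x_evidence":
        per_drawing = df.drop_duplicates("drawing_id")["evidence"]
        edges = np.unique(np.quantile(per_drawing, np.linspace(0, 1, n_bins + 1)))
        df["evidence_bin"] = pd.cut(
            df["evidence"], bins=edges, labels=False, include_lowest=True
        )
        keys = ["age", "evidence_bin"]
    elif grouping == "age_x_parts":
        keys = ["age", "n_unique_parts"]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    rng = np.random.default_rng(seed)
    alpha = (1.0 - level) / 2.0
    rows = []
    for key_vals, grp in df.groupby(keys):
        vals = grp["correct"].to_numpy(dtype=float)
        idx = rng.integers(0, len(vals), size=(B, len(vals)))
        means = vals[idx].mean(axis=1)
        lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        rows.append(
            dict(zip(keys, key_vals))
            | {
                "accuracy": float(vals.mean()),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "n_trials": len(vals),
            }
        )
    return pd.DataFrame(rows)
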