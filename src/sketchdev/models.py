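"""Mixed-effects models of drawing production and recognition.

Three model families, each a fixed contract (link, fixed-effect set,
random structure, Wald tests) over established fitting backends:

* **production**: logit GLMM of per-drawing binary classification
  (recognizability) on drawer age, parent-reported drawing frequency,
  their interaction, tracing score, and effort covariates (draw time,
  ink, stroke count), with random intercepts for participant and
  category.
* **conditional evidence**: linear mixed model of log-odds classifier
  evidence on the same predictor set, restricted to correctly classified
  drawings.
* **recognition**: logit GLMM of 4AFC recognition success on classifier
  evidence, recognizer age, and their interaction, with random intercepts
  for subject and category and a random evidence slope by category.

Predictors are z-scored before fitting (a 0-1 min-max option is exposed),
so coefficients are standardized and comparable.  No multiple-comparison
adjustment is applied.

Backends
--------
The default backend shells out to R's ``lme4`` (``lmerTest`` for linear
models, giving Satterthwaite degrees of freedom), which provides
well-calibrated standard errors for generalized mixed models.  Pure-Python
fallbacks are available: ``statsmodels`` REML :class:`MixedLM` for linear
models (exact, but normal-approximation p-values) and variational-Bayes
``BinomialBayesMixedGLM`` for logistic models.  The variational posterior
SDs are known to understate uncertainty for logistic mixed models, so the
VB path is a fallback, selected only when no ``Rscript`` is on the PATH
(with a warning) or explicitly.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats

__all__ = [
    "ModelFit",
    "fit_production_model",
    "fit_conditional_evidence_model",
    "fit_recognition_model",
    "production_recognition_correlation",
    "PRODUCTION_PREDICTORS",
]

#: Predictor columns of the production / conditional-evidence models.
PRODUCTION_PREDICTORS = (
    "age",
    "draw_frequency",
    "tracing_score",
    "draw_time_s",
    "ink_proportion",
    "n_strokes",
)


@dataclass
class ModelFit:
    """Fixed-effect table, variance components, and fit diagnostics.

    ``fixed`` has one row per fixed effect with columns estimate, se, z,
    p, ci_low, ci_high (Wald 95% intervals, two-tailed tests).
    """

    fixed: pd.DataFrame
    random: dict[str, float]
    n_obs: int
    converged: bool
    method: str

    def coef(self, name: str) -> float:
        return float(self.fixed.loc[name, "estimate"])

    def se(self, name: str) -> float:
        return float(self.fixed.loc[name, "se"])


def _wald_table(
    names: Sequence[str],
    est: np.ndarray,
    se: np.ndarray,
    p: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    est = np.asarray(est, dtype=float)
    se = np.asarray(se, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = est / se
    if p is None:
        p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "z": z,
            "p": np.asarray(p, dtype=float),
            "ci_low": est - 1.96 * se,
            "ci_high": est + 1.96 * se,
        },
        index=list(names),
    )


def _scale_predictors(
    df: pd.DataFrame, cols: Sequence[str], scaling: str
) -> pd.DataFrame:
    """Scale predictor columns; zero-variance columns are dropped (their
    slope is unidentifiable) with a warning."""
    if scaling not in ("zscore", "minmax"):
        raise ValueError(f"unknown scaling {scaling!r}")
    out = {}
    for c in cols:
        x = df[c].to_numpy(dtype=float)
        if np.std(x) == 0:
            warnings.warn(f"predictor {c!r} is constant; dropped", stacklevel=3)
            continue
        if scaling == "zscore":
            out[c] = (x - x.mean()) / x.std()
        else:
            out[c] = (x - x.min()) / (x.max() - x.min())
    return pd.DataFrame(out, index=df.index)


# ---------------------------------------------------------------------------
# lme4 backend
# ---------------------------------------------------------------------------

_R_TEMPLATE = """
suppressMessages({{library(lme4); library(jsonlite)}})
d <- read.csv("{csv}")
ws <- character(0)
withCallingHandlers({{
  if ("{family}" == "binomial") {{
    m <- glmer({formula}, data = d, family = binomial,
               control = glmerControl(optimizer = "bobyqa"))
  }} else {{
    suppressMessages(library(lmerTest))
    m <- lmerTest::lmer({formula}, data = d, REML = TRUE)
  }}
}}, warning = function(w) {{ ws <<- c(ws, conditionMessage(w)); invokeRestart("muffleWarning") }})
co <- as.data.frame(summary(m)$coefficients)
vc <- as.data.frame(VarCorr(m))
out <- list(names = rownames(co), coef = co[, 1], se = co[, 2],
            p = co[, ncol(co)],
            vc_grp = paste(vc$grp, ifelse(is.na(vc$var1), "(Intercept)", vc$var1),
                           ifelse(is.na(vc$var2), "", vc$var2), sep = ":"),
            vc_var = vc$vcov, warnings = ws, n = nobs(m))
cat(toJSON(out, digits = 12, na = "null"))
"""


def _have_rscript() -> bool:
    return shutil.which("Rscript") is not None


def _fit_lme4(data: pd.DataFrame, formula: str, family: str) -> ModelFit:
    with tempfile.TemporaryDirectory() as tmp:
        csv = Path(tmp) / "data.csv"
        data.to_csv(csv, index=False)
        script = Path(tmp) / "fit.R"
        script.write_text(
            _R_TEMPLATE.format(csv=csv.as_posix(), formula=formula, family=family)
        )
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script)],
            capture_output=True,
            text=True,
            timeout=900,
        )
    if proc.returncode != 0:
        raise RuntimeError(f"lme4 fit failed:\n{proc.stderr[-2000:]}")
    out = json.loads(proc.stdout)
    names = ["Intercept" if n == "(Intercept)" else n for n in out["names"]]
    fixed = _wald_table(
        names,
        np.atleast_1d(out["coef"]),
        np.atleast_1d(out["se"]),
        np.atleast_1d(out["p"]),
    )
    rand = {
        g.rstrip(":"): float(v)
        for g, v in zip(np.atleast_1d(out["vc_grp"]), np.atleast_1d(out["vc_var"]))
    }
    warns = list(np.atleast_1d(out.get("warnings", [])))
    converged = not any("converge" in w.lower() for w in warns)
    label = "lme4 logit GLMM" if family == "binomial" else "lmerTest REML LMM"
    return ModelFit(
        fixed=fixed,
        random=rand,
        n_obs=int(np.atleast_1d(out["n"])[0]),
        converged=converged,
        method=label,
    )


# ---------------------------------------------------------------------------
# pure-Python fallbacks
# ---------------------------------------------------------------------------


def _dummies(codes: np.ndarray, n_levels: int) -> sparse.csr_matrix:
    n = len(codes)
    return sparse.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, n_levels)
    )


def _fit_binomial_vb(
    endog: np.ndarray,
    exog: pd.DataFrame,
    vc_blocks: dict[str, sparse.csr_matrix],
) -> ModelFit:
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    exog_vc = sparse.hstack(list(vc_blocks.values()), format="csr")
    ident = np.concatenate(
        [np.full(b.shape[1], i) for i, b in enumerate(vc_blocks.values())]
    )
    model = BinomialBayesMixedGLM(
        endog.astype(float),
        exog.to_numpy(dtype=float),
        exog_vc,
        ident.astype(int),
        vcp_p=2.0,
        fe_p=2.0,
        fep_names=list(exog.columns),
        vcp_names=list(vc_blocks.keys()),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit_vb()
    fixed = _wald_table(exog.columns, res.fe_mean, res.fe_sd)
    rand = {
        name: float(np.exp(2 * m))
        for name, m in zip(vc_blocks.keys(), res.vcp_mean)
    }
    return ModelFit(
        fixed=fixed,
        random=rand,
        n_obs=len(endog),
        converged=True,
        method="variational Bayes logit GLMM",
    )


def _fit_lmm_statsmodels(
    data: pd.DataFrame, response: str, predictors: Sequence[str]
) -> ModelFit:
    from statsmodels.regression.mixed_linear_model import MixedLM

    data = data.copy()
    data["_const"] = 1
    safe = {c: c.replace(":", "_x_") for c in predictors}
    data = data.rename(columns=safe)
    terms = " + ".join(safe.values()) or "1"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(
            f"{response} ~ {terms}",
            data=data,
            groups="_const",
            re_formula="0",
            vc_formula={
                "participant": "0 + C(participant)",
                "category": "0 + C(category)",
            },
        )
        res = model.fit(reml=True)
    names = ["Intercept"] + [c for c in predictors]
    fixed = _wald_table(names, res.fe_params, res.bse_fe)
    rand = {name: float(v) for name, v in zip(model.exog_vc.names, res.vcomp)}
    rand["residual"] = float(res.scale)
    return ModelFit(
        fixed=fixed,
        random=rand,
        n_obs=int(res.nobs),
        converged=bool(res.converged),
        method="statsmodels REML LMM (normal-approximation p-values)",
    )


def _choose_backend(backend: str) -> str:
    if backend == "auto":
        if _have_rscript():
            return "lme4"
        warnings.warn(
            "Rscript not found; falling back to the pure-Python backend "
            "(variational-Bayes SEs understate uncertainty for logistic "
            "mixed models)",
            stacklevel=3,
        )
        return "python"
    if backend not in ("lme4", "python"):
        raise ValueError(f"unknown backend {backend!r}")
    return backend


# ---------------------------------------------------------------------------
# model contracts
# ---------------------------------------------------------------------------


def _production_design(
    df: pd.DataFrame, response: str, scaling: str
) -> tuple[pd.DataFrame, list[str]]:
    _check_columns(df, list(PRODUCTION_PREDICTORS) + [response, "participant", "category"])
    if df["category"].nunique() < 2 or df["participant"].nunique() < 2:
        raise ValueError("need at least 2 categories and 2 participants")
    scaled = _scale_predictors(df, PRODUCTION_PREDICTORS, scaling)
    scaled = scaled.rename(
        columns={"draw_time_s": "draw_time", "ink_proportion": "ink"}
    )
    predictors = list(scaled.columns)
    if {"age", "draw_frequency"} <= set(predictors):
        scaled["age:draw_frequency"] = scaled["age"] * scaled["draw_frequency"]
        predictors.append("age:draw_frequency")
    data = scaled.copy()
    data[response] = df[response].to_numpy()
    data["participant"] = df["participant"].to_numpy()
    data["category"] = df["category"].to_numpy()
    return data, predictors


def fit_production_model(
    df: pd.DataFrame, scaling: str = "zscore", backend: str = "auto"
) -> ModelFit:
    """Logit GLMM of per-drawing recognizability (binary ``correct``).

    ``df`` needs columns ``correct``, ``participant``, ``category`` and the
    predictors of :data:`PRODUCTION_PREDICTORS`.
    """
    data, predictors = _production_design(df, "correct", scaling)
    data["correct"] = data["correct"].astype(int)
    if _choose_backend(backend) == "lme4":
        fe = " + ".join(predictors)
        formula = f"correct ~ {fe} + (1 | participant) + (1 | category)"
        return _fit_lme4(data, formula, "binomial")
    exog_cols = [c for c in predictors if ":" not in c] + [
        c for c in predictors if ":" in c
    ]
    exog = pd.concat(
        [pd.Series(1.0, index=data.index, name="Intercept"), data[exog_cols]], axis=1
    )
    part = pd.Categorical(data["participant"])
    cat = pd.Categorical(data["category"])
    vc = {
        "participant": _dummies(part.codes, len(part.categories)),
        "category": _dummies(cat.codes, len(cat.categories)),
    }
    return _fit_binomial_vb(data["correct"].to_numpy(dtype=float), exog, vc)


def fit_conditional_evidence_model(
    df: pd.DataFrame, scaling: str = "zscore", backend: str = "auto"
) -> ModelFit:
    """Linear mixed model of classifier evidence among correct classifications.

    Rows with ``correct == False`` (when the column is present) are dropped
    here, matching the model's conditioning.  The lme4 backend reports
    Satterthwaite-approximation p-values; the Python fallback uses the
    normal approximation.
    """
    if "correct" in df.columns:
        df = df[df["correct"].astype(bool)]
    data, predictors = _production_design(df, "evidence", scaling)
    if _choose_backend(backend) == "lme4":
        fe = " + ".join(predictors)
        formula = f"evidence ~ {fe} + (1 | participant) + (1 | category)"
        return _fit_lme4(data, formula, "gaussian")
    return _fit_lmm_statsmodels(data, "evidence", predictors)


def fit_recognition_model(
    trials: pd.DataFrame, scaling: str = "zscore", backend: str = "auto"
) -> ModelFit:
    """Logit GLMM of 4AFC recognition success.

    Fixed effects: classifier evidence of the presented drawing, recognizer
    age, and their interaction.  Random intercepts for subject
    (``session_id``) and intended ``category``, plus a random evidence
    slope by category.
    """
    _check_columns(
        trials,
        ["correct", "evidence", "recognizer_age_years", "session_id", "category"],
    )
    df = trials.copy()
    df["age"] = df["recognizer_age_years"].astype(float)
    scaled = _scale_predictors(df, ["evidence", "age"], scaling)
    scaled["evidence:age"] = scaled["evidence"] * scaled["age"]
    data = scaled.copy()
    data["correct"] = df["correct"].astype(int).to_numpy()
    data["session_id"] = df["session_id"].to_numpy()
    data["category"] = df["category"].to_numpy()
    if _choose_backend(backend) == "lme4":
        formula = (
            "correct ~ evidence + age + evidence:age"
            " + (1 | session_id) + (1 + evidence | category)"
        )
        return _fit_lme4(data, formula, "binomial")
    subj = pd.Categorical(data["session_id"])
    cat = pd.Categorical(data["category"])
    cat_dummies = _dummies(cat.codes, len(cat.categories))
    slope_block = cat_dummies.multiply(
        data["evidence"].to_numpy()[:, None]
    ).tocsr()
    exog = pd.concat(
        [
            pd.Series(1.0, index=data.index, name="Intercept"),
            data[["evidence", "age", "evidence:age"]],
        ],
        axis=1,
    )
    vc = {
        "subject": _dummies(subj.codes, len(subj.categories)),
        "category": cat_dummies,
        "evidence_by_category": slope_block,
    }
    return _fit_binomial_vb(data["correct"].to_numpy(dtype=float), exog, vc)


def production_recognition_correlation(
    production: pd.DataFrame,
    recognition_trials: pd.DataFrame,
    drawing_evidence: pd.Series,
    top_fraction: float = 0.3,
) -> tuple[float, tuple[float, float], float, pd.DataFrame]:
    """Category-level correlation between production and recognition scores.

    ``production`` has one row per (category, age_years) with a
    ``production_score`` (mean classification accuracy of that cell's
    drawings).  The recognition side keeps only the ``top_fraction`` most
    recognizable drawings of each category — ranked by ``drawing_evidence``
    (ties broken by drawing id) — and averages child 4AFC accuracy per
    category across ages.  Returns ``(r, (ci_low, ci_high), p, table)``
    where ``table`` is the per-(category, age) frame for plotting.
    """
    cats = sorted(production["category"].unique())
    if len(cats) < 3:
        raise ValueError("correlation is unstable with fewer than 3 categories")
    trials = recognition_trials[recognition_trials["trial_type"] == "drawing"].copy()
    keep_ids: list = []
    ev = drawing_evidence
    for cat in cats:
        ids = trials.loc[trials["category"] == cat, "drawing_id"].unique()
        ids = [i for i in ids if i in ev.index]
        ranked = sorted(ids, key=lambda i: (-ev.loc[i], i))
        k = max(1, int(round(top_fraction * len(ranked))))
        keep_ids.extend(ranked[:k])
    top = trials[trials["drawing_id"].isin(keep_ids)]

    rec_by_cat = top.groupby("category")["correct"].mean()
    prod_by_cat = production.groupby("category")["production_score"].mean()
    common = [c for c in cats if c in rec_by_cat.index and c in prod_by_cat.index]
    if len(common) < 3:
        raise ValueError("fewer than 3 categories with both scores")
    x = prod_by_cat.loc[common].to_numpy()
    y = rec_by_cat.loc[common].to_numpy()
    r, p = stats.pearsonr(x, y)
    n = len(common)
    zr = np.arctanh(np.clip(r, -0.999999, 0.999999))
    half = 1.96 / np.sqrt(n - 3)
    ci = (float(np.tanh(zr - half)), float(np.tanh(zr + half)))

    top = top.copy()
    top["age"] = top["recognizer_age_years"].astype(int)
    rec_cell = (
        top.groupby(["category", "age"])["correct"].mean().rename("recognition_score")
    )
    table = (
        production.rename(columns={"age_years": "age"})
        .merge(rec_cell.reset_index(), on=["category", "age"], how="left")
    )
    return float(r), ci, float(p), table


def _check_columns(df: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
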