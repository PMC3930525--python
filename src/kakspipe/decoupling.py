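"""Inferential layer: rank tests and the developmental-decoupling GLM.

Developmental decoupling predicts relaxed purifying selection on genes
expressed in only a subset of individuals each generation (one sex, or
one male morph).  The model regresses log(Ka/Ks) on overall expression,
alignment length, sequence length, number of tissues, sex-biased
expression, morph-biased expression, and the morph x sex interaction;
per-term explanatory power is reported as the partial r-squared
t^2 / (t^2 + residual df).  Horn-biased versus background Ka/Ks is
compared with a Mann-Whitney rank test, reporting the first-sample U
statistic as W (the convention in which W for sample x counts the
(x_i, y_j) pairs with x_i > y_j, ties half).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

EXACT_MAX_PRODUCT = 400


@dataclass(frozen=True)
class RankTestResult:
    """Two-sample Mann-Whitney result; u1 + u2 = n1 * n2 always."""

    w: float
    u1: float
    u2: float
    p_two_sided: float
    method: str  # "exact" | "normal-approximation"


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> RankTestResult:
    """Mann-Whitney test of two independent samples.

    W is the first-sample U statistic.  The p-value is exact (full
    null enumeration) when n1*n2 <= 400 and there are no ties, else a
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    has_ties = len(set(x.tolist()) | set(y.tolist())) < n1 + n2
    exact = (n1 * n2 <= EXACT_MAX_PRODUCT) and not has_ties
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="exact" if exact else "asymptotic",
                             use_continuity=True)
    u1 = float(res.statistic)
    return RankTestResult(w=u1, u1=u1, u2=n1 * n2 - u1,
                          p_two_sided=float(min(res.pvalue, 1.0)),
                          method="exact" if exact else "normal-approximation")


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    n_positive: int  # ratio > 1
    frac_positive: float


def _summarize_group(label: str, ratios: Sequence[float]) -> GroupSummary:
    arr = np.asarray(list(ratios), dtype=float)
    n_pos = int((arr > 1.0).sum())
    return GroupSummary(
        label=label, n=arr.size,
        mean=float(arr.mean()), sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        median=float(np.median(arr)),
        q1=float(np.percentile(arr, 25)), q3=float(np.percentile(arr, 75)),
        n_positive=n_pos, frac_positive=n_pos / arr.size)


@dataclass(frozen=True)
class StratifiedComparison:
    background: GroupSummary
    focal: Optional[GroupSummary]
    test: Optional[RankTestResult]


def stratified_kaks_compare(estimates: pd.DataFrame,
                            horn_biased_ids: set[str],
                            id_column: str = "id_a",
                            ratio_column: str = "ratio") -> StratifiedComparison:
    """Compare Ka/Ks between a focal (e.g. horn-biased) stratum and the
    background.

    Only rows with a defined ratio enter (status ok, including ratio 0).
    Focal ids absent from the table are skipped with a warning.
    """
    usable = estimates[estimates[ratio_column].notna()]
    present = set(usable[id_column])
    missing = horn_biased_ids - present
    for mid in sorted(missing):
        logger.warning("focal id %s has no usable Ka/Ks estimate; skipped", mid)
    focal_mask = usable[id_column].isin(horn_biased_ids)
    focal_ratios = usable.loc[focal_mask, ratio_column].to_numpy(dtype=float)
    background_ratios = usable.loc[~focal_mask, ratio_column].to_numpy(dtype=float)
    background = _summarize_group("background", background_ratios)
    if focal_ratios.size == 0:
        return StratifiedComparison(background=background, focal=None, test=None)
    focal = _summarize_group("focal", focal_ratios)
    test = mann_whitney(focal_ratios, background_ratios) if background_ratios.size else None
    return StratifiedComparison(background=background, focal=focal, test=test)


# ---------------------------------------------------------------------------
# The decoupling GLM

PROFILE_LOG_BIASES = "log-biases"
PROFILE_LOG_LENGTHS = "log-lengths"

#: Model terms in report order (intercept excluded).
GLM_TERMS = (
    "overall_expression",
    "alignment_length",
    "sequence_length",
    "n_tissues",
    "sex_bias",
    "morph_bias",
    "morph_x_sex",
)


class SingularFitError(ValueError):
    """Design matrix is rank-deficient; message names offending terms."""


@dataclass(frozen=True)
class TermFit:
    name: str
    estimate: float
    se: float
    t_value: float
    partial_r2: float


@dataclass(frozen=True)
class GlmFit:
    terms: tuple[TermFit, ...]
    intercept: float
    residual_df: int
    adjusted_r2: float
    n: int
    transform_profile: str
    n_excluded: int = 0

    def term(self, name: str) -> TermFit:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def _build_design(records: pd.DataFrame, profile: str) -> tuple[pd.DataFrame, pd.Series, int]:
    """Apply the transform profile, drop rows that cannot be
    log-transformed, and assemble the design matrix."""
    required = {"ratio", "overall_expression", "alignment_length",
                "sequence_length", "n_tissues", "sex_bias", "morph_bias"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    log_cols = ["ratio", "overall_expression", "sex_bias", "morph_bias"]
    if profile == PROFILE_LOG_LENGTHS:
        log_cols += ["sequence_length", "alignment_length"]
    elif profile != PROFILE_LOG_BIASES:
        raise ValueError(f"unknown transform profile {profile!r}")
    usable = records.dropna(subset=list(required))
    positive = np.ones(len(usable), dtype=bool)
    for col in log_cols:
        positive &= usable[col].to_numpy(dtype=float) > 0
    n_excluded = len(records) - int(positive.sum())
    if n_excluded:
        logger.info("%d rows excluded (missing or non-positive under log transform)",
                    n_excluded)
    usable = usable.loc[positive]
    design = pd.DataFrame(index=usable.index)
    log_sex = np.log(usable["sex_bias"].to_numpy(dtype=float))
    log_morph = np.log(usable["morph_bias"].to_numpy(dtype=float))
    design["overall_expression"] = np.log(usable["overall_expression"].to_numpy(dtype=float))
    for col in ("alignment_length", "sequence_length"):
        vals = usable[col].to_numpy(dtype=float)
        design[col] = np.log(vals) if col in log_cols else vals
    design["n_tissues"] = usable["n_tissues"].to_numpy(dtype=float)
    design["sex_bias"] = log_sex
    design["morph_bias"] = log_morph
    design["morph_x_sex"] = log_morph * log_sex
    y = pd.Series(np.log(usable["ratio"].to_numpy(dtype=float)), index=usable.index)
    return design, y, n_excluded


def _check_full_rank(design: pd.DataFrame) -> None:
    X = np.column_stack([np.ones(len(design)), design.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    offenders = []
    cols = [np.ones(len(design))]
    rank = 1
    for name in design.columns:
        cols.append(design[name].to_numpy(dtype=float))
        new_rank = np.linalg.matrix_rank(np.column_stack(cols))
        if new_rank == rank:
            offenders.append(name)
        rank = new_rank
    raise SingularFitError(f"design matrix is rank-deficient; offending terms: {offenders}")


def fit_decoupling_glm(records: pd.DataFrame,
                       transform_profile: str = PROFILE_LOG_BIASES,
                       zero_ratio_floor: bool = False) -> GlmFit:
    """Ordinary least squares of log(Ka/Ks) on the decoupling covariates.

    `zero_ratio_floor` substitutes half the smallest positive ratio for
    ratio-0 rows instead of excluding them.  Requires at least 10 more
    observations than model terms.
    """
    records = records.copy()
    if zero_ratio_floor:
        pos = records.loc[records["ratio"] > 0, "ratio"]
        if len(pos):
            records.loc[records["ratio"] == 0, "ratio"] = pos.min() / 2.0
    design, y, n_excluded = _build_design(records, transform_profile)
    n = len(design)
    n_params = len(GLM_TERMS) + 1
    if n < n_params + 10:
        raise ValueError(f"need at least {n_params + 10} usable observations, have {n}")
    _check_full_rank(design)
    X = sm.add_constant(design, prepend=True)
    fit = sm.OLS(y, X).fit()
    residual_df = int(fit.df_resid)
    terms = []
    for name in GLM_TERMS:
        t = float(fit.tvalues[name])
        terms.append(TermFit(
            name=name,
            estimate=float(fit.params[name]),
            se=float(fit.bse[name]),
            t_value=t,
            partial_r2=t * t / (t * t + residual_df)))
    return GlmFit(terms=tuple(terms),
                  intercept=float(fit.params["const"]),
                  residual_df=residual_df,
                  adjusted_r2=float(fit.rsquared_adj),
                  n=n,
                  transform_profile=transform_profile,
                  n_excluded=n_excluded)


def partial_r2(fit: GlmFit, term: str) -> float:
    """Partial r-squared of one model term: t^2 / (t^2 + residual df).

    Equals the relative SSE drop when exactly that term is removed
    from the model.  The intercept has no partial r-squared.
    """
    if term in ("const", "intercept"):
        raise ValueError("partial r-squared is not defined for the intercept")
    return fit.term(term).partial_r2


def glm_report(fit: GlmFit) -> pd.DataFrame:
    """Model report mirroring the published layout: term, estimate, SE,
    partial r^2, t."""
    return pd.DataFrame(
        [(t.name, t.estimate, t.se, t.partial_r2, t.t_value) for t in fit.terms],
        columns=["term", "estimate", "se", "partial_r2", "t_value"])
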