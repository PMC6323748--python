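"""Survival and tumor-grade association tests for low/middle/high modes.

The middle mode (expression similar to normal tissue) is always the reference
group.  Survival uses a Cox proportional-hazards model on two indicator
contrasts (low vs middle, high vs middle), administratively censored at 20
years, with one-sided Wald p values oriented so that a small p means the
contrast group has *worse* survival than middle.  Grade uses a
Cochran-Armitage trend test on the 2x3 (group x grade) table with scores
1,2,3, converted to a one-sided p via the sign of the trend, oriented so a
small p means the contrast group is enriched at higher grades.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from trimodal.mixture_em import ModeAssignment
from trimodal.preprocess import ClinicalTable

__all__ = [
    "SurvivalTestResult",
    "GradeTrendResult",
    "OverlapResult",
    "prepare_survival_frame",
    "trimodal_survival_test",
    "multivariable_survival",
    "grade_trend_test",
    "grade_trend_tests",
    "overlap_hypergeometric",
]

P_FLOOR = 1e-300
DEFAULT_CENSOR_YEARS = 20.0


@dataclass
class SurvivalTestResult:
    """One-sided Cox contrasts of low and high modes against middle."""

    p12: float  # low worse than middle
    p23: float  # high worse than middle
    coef_low: float
    coef_high: float
    n_per_mode: tuple[int, int, int]  # (low, middle, high)
    flags: list[str] = field(default_factory=list)


@dataclass
class GradeTrendResult:
    """One-sided grade-trend p values for the two contrasts."""

    p_low_vs_middle: float
    p_high_vs_middle: float
    trend_sign_low: int
    trend_sign_high: int


@dataclass
class OverlapResult:
    """Upper-tail hypergeometric significance of two gene-list overlaps."""

    n_listA: int
    n_listB: int
    n_overlap: int
    n_universe: int
    p_hyper: float


def _clip_p(p: float) -> float:
    return float(min(max(p, P_FLOOR), 1.0 - 1e-16))


def _labels_series(labels, clinical: ClinicalTable) -> pd.Series:
    """Coerce labels (ModeAssignment, array, or Series) to a Series aligned on sample id."""
    if isinstance(labels, ModeAssignment):
        labels = labels.labels
    if isinstance(labels, pd.Series):
        return labels.reindex(clinical.table.index)
    arr = np.asarray(labels)
    if len(arr) != len(clinical.table):
        raise ValueError(
            f"{len(arr)} labels for {len(clinical.table)} clinical rows; "
            "pass a Series indexed by sample_id to align explicitly"
        )
    return pd.Series(arr, index=clinical.table.index)


def prepare_survival_frame(
    labels,
    clinical: ClinicalTable,
    censor_years: float = DEFAULT_CENSOR_YEARS,
) -> pd.DataFrame:
    """Model frame with censoring applied: events after the horizon become censored."""
    lab = _labels_series(labels, clinical)
    df = pd.DataFrame(
        {
            "time": clinical.table["time_years"].astype(float),
            "event": clinical.table["event"].astype(float),
            "mode": lab,
        }
    )
    df = df.dropna(subset=["time", "event", "mode"])
    over = df["time"] > censor_years
    df.loc[over, "event"] = 0.0
    df.loc[over, "time"] = censor_years
    # zero-length times break the partial likelihood ordering
    df.loc[df["time"] <= 0, "time"] = 1e-6
    df["low"] = (df["mode"] == "low").astype(float)
    df["high"] = (df["mode"] == "high").astype(float)
    return df


def _one_sided_p(z: float) -> float:
    """Upper-tail p for 'contrast has higher hazard than middle'."""
    return _clip_p(stats.norm.sf(z))


def _encode_covariates(
    clinical: ClinicalTable, covariates: Sequence[str], reference_levels: dict | None = None
) -> pd.DataFrame:
    """Numeric covariates pass through; categoricals become dummies vs a reference.

    For a 'pam50' style subtype column the reference defaults to 'Basal' when
    present, otherwise the alphabetically first level.
    """
    reference_levels = reference_levels or {}
    out = {}
    for name in covariates:
        if name not in clinical.table.columns:
            raise ValueError(f"covariate {name!r} not in clinical table")
        col = clinical.table[name]
        if pd.api.types.is_numeric_dtype(col):
            out[name] = col.astype(float)
        else:
            levels = sorted(col.dropna().unique())
            ref = reference_levels.get(name)
            if ref is None:
                ref = "Basal" if "Basal" in levels else levels[0]
            for lev in levels:
                if lev == ref:
                    continue
                out[f"{name}_{lev}"] = (col == lev).astype(float).where(col.notna())
    return pd.DataFrame(out, index=clinical.table.index)


def _drop_collinear(df: pd.DataFrame, cols: list[str]) -> list[str]:
    """Greedily drop columns that do not increase design-matrix rank."""
    kept: list[str] = []
    for c in cols:
        trial = kept + [c]
        mat = np.column_stack([np.ones(len(df))] + [df[k].to_numpy() for k in trial])
        if np.linalg.matrix_rank(mat) == len(trial) + 1:
            kept.append(c)
        else:
            warnings.warn(f"dropping collinear covariate {c!r}")
    return kept


def _fit_cox(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame | None:
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df[["time", "event"] + columns], duration_col="time", event_col="event")
    except (ConvergenceError, ValueError, np.linalg.LinAlgError):
        return None
    return cph.summary


def trimodal_survival_test(
    labels,
    clinical: ClinicalTable,
    covariates: Sequence[str] | None = None,
    censor_years: float = DEFAULT_CENSOR_YEARS,
) -> SurvivalTestResult:
    """One-sided Cox contrasts: does each outer mode fare worse than middle?

    p12 is the upper-tail Wald p for the low-mode coefficient (positive =
    higher hazard than middle); p23 analogously for high.  A mode with zero
    members gets a missing p and a flag; a non-converging fit is flagged with
    both p missing.
    """
    df = prepare_survival_frame(labels, clinical, censor_years)
    flags: list[str] = []
    n_low = int(df["low"].sum())
    n_high = int(df["high"].sum())
    n_mid = int(len(df) - n_low - n_high)
    if df["event"].sum() < 1:
        return SurvivalTestResult(
            p12=float("nan"), p23=float("nan"), coef_low=float("nan"),
            coef_high=float("nan"), n_per_mode=(n_low, n_mid, n_high),
            flags=["no events"],
        )
    if n_mid == 0:
        return SurvivalTestResult(
            p12=float("nan"), p23=float("nan"), coef_low=float("nan"),
            coef_high=float("nan"), n_per_mode=(n_low, n_mid, n_high),
            flags=["empty middle mode"],
        )
    contrast_cols = []
    if n_low > 0:
        contrast_cols.append("low")
    else:
        flags.append("empty low mode")
    if n_high > 0:
        contrast_cols.append("high")
    else:
        flags.append("empty high mode")

    cov_cols: list[str] = []
    if covariates:
        cov = _encode_covariates(clinical, covariates).reindex(df.index)
        before = len(df)
        df = df.join(cov).dropna(subset=list(cov.columns))
        if len(df) < before:
            flags.append(f"listwise deletion: {before - len(df)} samples missing covariates")
        cov_cols = _drop_collinear(df, list(cov.columns))

    summary = _fit_cox(df, contrast_cols + cov_cols) if contrast_cols else None
    if summary is None:
        flags.append("cox fit failed" if contrast_cols else "no contrast groups")
        return SurvivalTestResult(
            p12=float("nan"), p23=float("nan"), coef_low=float("nan"),
            coef_high=float("nan"), n_per_mode=(n_low, n_mid, n_high), flags=flags,
        )
    p12 = coef_low = float("nan")
    p23 = coef_high = float("nan")
    if "low" in summary.index:
        coef_low = float(summary.loc["low", "coef"])
        p12 = _one_sided_p(float(summary.loc["low", "z"]))
    if "high" in summary.index:
        coef_high = float(summary.loc["high", "coef"])
        p23 = _one_sided_p(float(summary.loc["high", "z"]))
    return SurvivalTestResult(
        p12=p12, p23=p23, coef_low=coef_low, coef_high=coef_high,
        n_per_mode=(n_low, n_mid, n_high), flags=flags,
    )


def multivariable_survival(
    labels,
    clinical: ClinicalTable,
    covariate_spec: Sequence[str] | None = None,
    censor_years: float = DEFAULT_CENSOR_YEARS,
    reference_levels: dict | None = None,
) -> pd.DataFrame:
    """Full adjusted Cox model; one row per variable with coefficient and p.

    Mode contrasts report one-sided p values (worse-than-middle alternative);
    covariates report two-sided p values.  Samples missing any covariate are
    dropped listwise.
    """
    covariate_spec = list(covariate_spec or [])
    df = prepare_survival_frame(labels, clinical, censor_years)
    contrast_cols = [c for c in ("low", "high") if df[c].sum() > 0]
    cov_cols: list[str] = []
    if covariate_spec:
        cov = _encode_covariates(clinical, covariate_spec, reference_levels).reindex(df.index)
        df = df.join(cov).dropna(subset=list(cov.columns))
        cov_cols = _drop_collinear(df, list(cov.columns))
    summary = _fit_cox(df, contrast_cols + cov_cols)
    if summary is None:
        raise RuntimeError("multivariable Cox fit did not converge")
    rows = []
    for name in contrast_cols + cov_cols:
        z = float(summary.loc[name, "z"])
        one_sided = name in ("low", "high")
        p = _one_sided_p(z) if one_sided else _clip_p(2.0 * stats.norm.sf(abs(z)))
        rows.append(
            {
                "variable": name,
                "coef": float(summary.loc[name, "coef"]),
                "se": float(summary.loc[name, "se(coef)"]),
                "z": z,
                "p": p,
                "side": "one-sided" if one_sided else "two-sided",
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def grade_trend_test(
    labels,
    grades,
    contrast: Literal["low", "high"] = "low",
    scores: Sequence[float] = (1.0, 2.0, 3.0),
) -> float:
    """One-tailed Cochran-Armitage trend p for one contrast group vs middle.

    Restricted to contrast+middle samples, the 2x3 table of group membership
    by grade is scored (1,2,3); the trend chi-square is converted to a signed
    z and the returned p is the upper-tail probability that higher grades are
    enriched for the contrast group (small p = contrast group has *higher*
    grade tumors; flat trend gives p = 0.5).
    """
    if isinstance(labels, ModeAssignment):
        labels = labels.labels
    lab = np.asarray(labels)
    g = np.asarray(grades, dtype=float)
    if len(lab) != len(g):
        raise ValueError("labels and grades must align")
    mask = np.isin(lab, [contrast, "middle"]) & np.isfinite(g)
    lab, g = lab[mask], g[mask]
    if not (lab == contrast).any() or not (lab == "middle").any():
        raise ValueError(f"need non-empty {contrast!r} and 'middle' groups")
    levels = np.asarray(sorted(set(np.asarray(scores, dtype=float))))
    present = np.array([lev in set(g) for lev in levels])
    if not present.all():
        warnings.warn(
            f"grade level(s) {levels[~present].tolist()} absent; dropped (scores kept)"
        )
    levels = levels[present]
    n = np.array([(g == lev).sum() for lev in levels], dtype=float)
    x = np.array([((g == lev) & (lab == contrast)).sum() for lev in levels], dtype=float)
    s = levels  # integer grade scores
    p_bar = x.sum() / n.sum()
    if p_bar <= 0.0 or p_bar >= 1.0:
        return 0.5  # one group is empty at every grade: no trend information
    t_stat = float(np.sum(s * (x - n * p_bar)))
    var = float(p_bar * (1 - p_bar) * (np.sum(n * s**2) - np.sum(n * s) ** 2 / n.sum()))
    if var <= 0:
        return 0.5
    z = t_stat / np.sqrt(var)
    return _clip_p(stats.norm.sf(z))


def grade_trend_tests(labels, grades) -> GradeTrendResult:
    """Both one-tailed contrasts (low vs middle, high vs middle)."""
    p_low = grade_trend_test(labels, grades, contrast="low")
    p_high = grade_trend_test(labels, grades, contrast="high")
    return GradeTrendResult(
        p_low_vs_middle=p_low,
        p_high_vs_middle=p_high,
        trend_sign_low=int(np.sign(0.5 - p_low)),
        trend_sign_high=int(np.sign(0.5 - p_high)),
    )


def overlap_hypergeometric(listA: Iterable, listB: Iterable, universe: Iterable) -> OverlapResult:
    """Upper-tail hypergeometric p for the overlap of two gene lists."""
    uni = set(universe)
    a = set(listA)
    b = set(listB)
    if not a <= uni or not b <= uni:
        outside = (a | b) - uni
        raise ValueError(f"list elements outside universe: {sorted(outside)[:5]}")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, len(uni), len(a), len(b)))
    return OverlapResult(
        n_listA=len(a), n_listB=len(b), n_overlap=k, n_universe=len(uni),
        p_hyper=_clip_p(p),
    )
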