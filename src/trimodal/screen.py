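"""Genome-wide trimodality screen: fit, filter, test, replicate across cohorts.

For every gene the anchored mixture is fit against the cohort's normal
samples; trimodal genes whose smallest observed mode proportion reaches
``min_mode_prop`` are carried into the one-sided survival and grade-trend
tests.  A gene is a candidate when the low AND high modes are both
significantly worse than middle on both endpoints.  Cohorts without normal
samples are handled by rank-splitting each gene at fixed proportions
(e.g. the 10.0/81.1/8.8% splits carried over from cohorts that do have
normals).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from trimodal.association import grade_trend_test, trimodal_survival_test
from trimodal.mixture_em import (
    EMConfig,
    GeneVector,
    MixtureFit,
    ModeAssignment,
    MODE_LABELS,
    assign_modes,
    fit_em,
)
from trimodal.preprocess import ClinicalTable, ExpressionMatrix

__all__ = [
    "ScreenConfig",
    "screen_cohort",
    "split_by_proportions",
    "normalize_proportions",
    "cross_cohort_candidates",
]

logger = logging.getLogger(__name__)

RECORD_COLUMNS = [
    "gene_id", "fitted", "converged", "n_iter", "trimodal",
    "pi1", "pi2", "pi3", "mu1", "mu2", "mu3", "sigma", "loglik",
    "c12", "c23", "c12_fallback", "c23_fallback",
    "epi_low", "epi_middle", "epi_high",
    "p12_surv", "p23_surv", "p_grade_low", "p_grade_high",
    "pass_trimodal", "pass_min_prop",
    "pass_surv_low", "pass_surv_high", "pass_grade_low", "pass_grade_high",
    "candidate", "reason",
]


@dataclass
class ScreenConfig:
    """Filters and sub-module settings for one cohort screen."""

    min_mode_prop: float = 0.05
    alpha: float = 0.05
    censor_years: float = 20.0
    em: EMConfig = field(default_factory=EMConfig)
    proportions: tuple[float, float, float] | None = None  # for normal-free cohorts
    use_grade: bool = True


def normalize_proportions(proportions: Sequence[float]) -> np.ndarray:
    """Renormalize supplied split proportions to sum to 1, logging any adjustment."""
    p = np.asarray(proportions, dtype=float)
    if p.shape != (3,) or np.any(p < 0) or p.sum() <= 0:
        raise ValueError(f"proportions must be 3 non-negative values, got {proportions}")
    total = p.sum()
    if abs(total - 1.0) > 1e-6:
        logger.info("renormalizing proportions %s (sum %.4f) to sum to 1", p.tolist(), total)
        p = p / total
    return p


def split_by_proportions(x_tumor: np.ndarray, proportions: Sequence[float]) -> ModeAssignment:
    """Rank-split tumor values into low/middle/high at fixed proportions.

    Stratum sizes are floor(n * p_low) and floor(n * p_high); leftover
    samples go to the middle stratum.  Rank ties break by stable input order.
    """
    x = np.asarray(x_tumor, dtype=float)
    p = np.asarray(proportions, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(
            f"proportions must sum to 1 (got sum {p.sum():.6f}); "
            "use normalize_proportions first"
        )
    n = len(x)
    n_low = int(np.floor(n * p[0]))
    n_high = int(np.floor(n * p[2]))
    if n > 0 and (n_low == 0 or n_high == 0) and (p[0] > 0 or p[2] > 0):
        warnings.warn("too few samples for a non-empty stratum at the requested proportions")
    order = np.argsort(x, kind="stable")
    labels = np.full(n, "middle", dtype=object)
    if n_low:
        labels[order[:n_low]] = "low"
    if n_high:
        labels[order[n - n_high:]] = "high"
    counts = np.array([(labels == lab).sum() for lab in MODE_LABELS], dtype=float)
    empirical_pi = counts / n if n else np.zeros(3)
    return ModeAssignment(labels=np.asarray(labels, dtype=str), empirical_pi=empirical_pi)


def _blank_record(gene_id: str, reason: str = "") -> dict:
    rec = {c: np.nan for c in RECORD_COLUMNS}
    rec.update(
        gene_id=gene_id, fitted=False, converged=False, trimodal=False,
        pass_trimodal=False, pass_min_prop=False,
        pass_surv_low=False, pass_surv_high=False,
        pass_grade_low=False, pass_grade_high=False,
        candidate=False, reason=reason,
    )
    return rec


def _fit_fields(rec: dict, fit: MixtureFit) -> None:
    rec.update(
        fitted=True, converged=fit.converged, n_iter=fit.n_iter, trimodal=fit.trimodal,
        pi1=fit.params.pi[0], pi2=fit.params.pi[1], pi3=fit.params.pi[2],
        mu1=fit.params.mu[0], mu2=fit.params.mu[1], mu3=fit.params.mu[2],
        sigma=fit.params.sigma, loglik=fit.loglik,
    )
    if fit.cutoffs is not None:
        rec.update(
            c12=fit.cutoffs.c12, c23=fit.cutoffs.c23,
            c12_fallback=fit.cutoffs.c12_fallback, c23_fallback=fit.cutoffs.c23_fallback,
        )


def screen_cohort(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    config: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Run the full per-gene screen on one cohort; one ScreenRecord row per gene.

    With normal samples present, each gene is fit by the anchored EM and only
    trimodal fits proceed; without normals, ``config.proportions`` must be
    given and every gene is rank-split at those fixed proportions.
    Unfittable genes are recorded with a reason, never dropped.
    """
    config = config or ScreenConfig()
    tumor = expr.tumor
    normal = expr.normal
    tumor_ids = list(tumor.columns)
    has_normals = normal.shape[1] >= config.em.min_normal

    proportions = None
    if not has_normals:
        if config.proportions is None:
            raise ValueError(
                "cohort has no normal samples: supply ScreenConfig.proportions "
                "to use the fixed-proportion split (split_by_proportions)"
            )
        proportions = normalize_proportions(config.proportions)

    clin = ClinicalTable(table=clinical.table.reindex(tumor_ids))
    grades = (
        clin.table["grade"].to_numpy(dtype=float)
        if ("grade" in clin.table.columns and config.use_grade)
        else None
    )

    records: list[dict] = []
    for gene_id in expr.gene_ids:
        rec = _blank_record(gene_id)
        x_t = tumor.loc[gene_id].to_numpy(dtype=float)
        x_n = normal.loc[gene_id].to_numpy(dtype=float)
        if np.isnan(x_t).any() or (has_normals and np.isnan(x_n).any()):
            rec["reason"] = "missing expression values"
            records.append(rec)
            continue

        assignment = None
        if has_normals:
            try:
                fit = fit_em(GeneVector(gene_id, x_t, x_n), config.em)
            except ValueError as exc:
                rec["reason"] = str(exc)
                records.append(rec)
                continue
            _fit_fields(rec, fit)
            rec["pass_trimodal"] = bool(fit.trimodal)
            if fit.trimodal and fit.cutoffs is not None:
                assignment = assign_modes(x_t, fit.cutoffs)
            elif not fit.trimodal:
                rec["reason"] = fit.message or "not trimodal"
        else:
            assignment = split_by_proportions(x_t, proportions)
            rec.update(fitted=False, trimodal=np.nan, pass_trimodal=True,
                       reason="", converged=np.nan)

        if assignment is not None:
            epi = assignment.empirical_pi
            rec.update(epi_low=epi[0], epi_middle=epi[1], epi_high=epi[2])
            rec["pass_min_prop"] = bool(epi.min() >= config.min_mode_prop)
            if rec["pass_min_prop"]:
                labels = pd.Series(assignment.labels, index=tumor_ids)
                surv = trimodal_survival_test(
                    labels, clin, censor_years=config.censor_years
                )
                rec.update(p12_surv=surv.p12, p23_surv=surv.p23)
                rec["pass_surv_low"] = bool(surv.p12 < config.alpha) if np.isfinite(surv.p12) else False
                rec["pass_surv_high"] = bool(surv.p23 < config.alpha) if np.isfinite(surv.p23) else False
                if grades is not None and np.isfinite(grades).any():
                    p_gl = grade_trend_test(assignment.labels, grades, contrast="low")
                    p_gh = grade_trend_test(assignment.labels, grades, contrast="high")
                    rec.update(p_grade_low=p_gl, p_grade_high=p_gh)
                    rec["pass_grade_low"] = bool(p_gl < config.alpha)
                    rec["pass_grade_high"] = bool(p_gh < config.alpha)
            else:
                rec["reason"] = rec["reason"] or "mode below minimum proportion"

        rec["candidate"] = bool(
            rec["pass_trimodal"] and rec["pass_min_prop"]
            and rec["pass_surv_low"] and rec["pass_surv_high"]
            and rec["pass_grade_low"] and rec["pass_grade_high"]
        )
        records.append(rec)

    return pd.DataFrame(records, columns=RECORD_COLUMNS)


_P_COLUMNS = ["p12_surv", "p23_surv", "p_grade_low", "p_grade_high"]


def cross_cohort_candidates(
    records: Mapping[str, pd.DataFrame],
    policy: str = "strict",
    discovery: Sequence[str] | None = None,
) -> list[str]:
    """Genes surviving the candidate filters across cohorts.

    strict: the gene is a candidate (all four p below alpha plus the
    trimodality and proportion filters) in every cohort.  relaxed: the gene
    is a candidate in every *discovery* cohort and shows at least the correct
    trend (every available p < 0.5) everywhere else.
    """
    if len(records) < 2:
        raise ValueError("need records from >= 2 cohorts")
    if policy not in ("strict", "relaxed"):
        raise ValueError(f"unknown policy {policy!r}")
    names = list(records)
    if policy == "relaxed":
        discovery = list(discovery or names[:1])
        unknown = [d for d in discovery if d not in records]
        if unknown:
            raise ValueError(f"cohort name mismatch: {unknown} not in {names}")
    frames = {name: df.set_index("gene_id") for name, df in records.items()}
    common = [g for g in frames[names[0]].index if all(g in f.index for f in frames.values())]

    out: list[str] = []
    for gene in common:
        if policy == "strict":
            ok = all(bool(f.loc[gene, "candidate"]) for f in frames.values())
        else:
            ok = all(bool(frames[d].loc[gene, "candidate"]) for d in discovery)
            for name in names:
                if name in discovery or not ok:
                    continue
                ps = frames[name].loc[gene, _P_COLUMNS].astype(float)
                avail = ps.dropna()
                ok = len(avail) > 0 and bool((avail < 0.5).all())
        if ok:
            out.append(gene)
    return out
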