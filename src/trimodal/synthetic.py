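"""Synthetic cohorts with the statistical structure the screen assumes.

A planted "risk" gene has tumor expression drawn from the three-component
equal-variance Gaussian mixture (defaults: means (-4, 0, 3), sigma 1, mode
sizes 100/250/150) with the normal population drawn from the middle
component (50 samples from N(0, 1)).  Survival is exponential with elevated
hazard in the low and high modes; tumor grade follows a proportional-odds
model shifted toward higher grades in the outer modes.  Null genes are
unimodal N(0, 1) with no clinical linkage.

Every generator draws from a stream derived from ``(seed, gene index)`` so
per-gene results do not depend on generation order.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from trimodal.mixture_em import GeneVector, MODE_LABELS
from trimodal.preprocess import ClinicalTable, ExpressionMatrix, NORMAL, TUMOR

__all__ = [
    "SimConfig",
    "simulate_mixture_gene",
    "simulate_clinical",
    "simulate_screen_cohort",
]

_CLINICAL_STREAM = 2**20  # reserved stream index for the shared clinical table


@dataclass
class SimConfig:
    """Study conditions for the synthetic generators.

    Defaults reproduce the reference simulation used to validate the EM fit:
    tumor modes of 100/250/150 samples from N(-4,1), N(0,1), N(3,1) and 50
    normal samples from N(0,1).  Clinical defaults: exponential survival at
    0.05 events/year for the middle mode, hazard ratio 3 in each outer mode,
    20% random censoring plus administrative censoring at 20 years, and a
    +1.0 proportional-odds shift toward higher grade in the outer modes
    (baseline grade probabilities 0.25/0.45/0.30).
    """

    n_per_mode: tuple[int, int, int] = (100, 250, 150)
    n_normal: int = 50
    mu_true: tuple[float, float, float] = (-4.0, 0.0, 3.0)
    sigma_true: float = 1.0
    hazard_ratios: tuple[float, float] = (3.0, 3.0)  # (low, high) vs middle
    baseline_hazard: float = 0.05  # events per year in the middle mode
    censor_rate: float = 0.20  # fraction randomly censored before 20y
    admin_censor_years: float = 20.0
    grade_trend_strength: float = 1.0  # proportional-odds shift for outer modes
    grade_base_probs: tuple[float, float, float] = (0.25, 0.45, 0.30)
    n_null_genes: int = 200
    n_planted_genes: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_mode) <= 0 or self.n_normal <= 0:
            raise ValueError("sample counts must be positive")
        if not self.sigma_true > 0:
            raise ValueError("sigma_true must be positive")
        if min(self.hazard_ratios) < 1.0:
            raise ValueError("hazard ratios must be >= 1 for risk genes")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must be in [0, 1)")
        if abs(sum(self.grade_base_probs) - 1.0) > 1e-8:
            raise ValueError("grade_base_probs must sum to 1")

    @property
    def n_tumor(self) -> int:
        return int(sum(self.n_per_mode))


def _rng_for(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def simulate_mixture_gene(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    gene_id: str = "gene",
) -> tuple[GeneVector, np.ndarray]:
    """Draw one gene's tumor/normal values; returns the true mode labels too."""
    rng = rng or _rng_for(config, 0)
    parts, labels = [], []
    for n, mu, lab in zip(config.n_per_mode, config.mu_true, MODE_LABELS):
        parts.append(rng.normal(mu, config.sigma_true, size=n))
        labels.extend([lab] * n)
    x_tumor = np.concatenate(parts)
    x_normal = rng.normal(config.mu_true[1], config.sigma_true, size=config.n_normal)
    return GeneVector(gene_id=gene_id, x_tumor=x_tumor, x_normal=x_normal), np.array(labels)


def _mode_hazards(config: SimConfig) -> dict[str, float]:
    hr_low, hr_high = config.hazard_ratios
    return {
        "low": config.baseline_hazard * hr_low,
        "middle": config.baseline_hazard,
        "high": config.baseline_hazard * hr_high,
    }


def simulate_clinical(
    labels: Sequence[str],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    sample_ids: Sequence[str] | None = None,
) -> ClinicalTable:
    """Survival and grade driven by the true mode labels.

    Event times are exponential with rate baseline_hazard x HR(mode); random
    censoring is exponential at the rate giving the configured censored
    fraction within each mode, and everything is administratively censored at
    ``admin_censor_years``.  Grade comes from a 3-level proportional-odds
    model whose linear predictor adds ``grade_trend_strength`` for low/high
    modes.
    """
    rng = rng or _rng_for(config, _CLINICAL_STREAM)
    labels = np.asarray(labels)
    n = len(labels)
    hazards = _mode_hazards(config)
    lam = np.array([hazards[lab] for lab in labels])
    t_event = rng.exponential(1.0 / lam)
    if config.censor_rate > 0:
        c_rate = lam * config.censor_rate / (1.0 - config.censor_rate)
        t_cens = rng.exponential(1.0 / c_rate)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    over = time > config.admin_censor_years
    time[over] = config.admin_censor_years
    event[over] = 0

    # proportional odds on grade: P(grade <= k) = expit(alpha_k - eta)
    p1, p2, _ = config.grade_base_probs
    alpha = np.array([logit(p1), logit(p1 + p2)])
    eta = np.where(np.isin(labels, ["low", "high"]), config.grade_trend_strength, 0.0)
    cum1 = expit(alpha[0] - eta)
    cum2 = expit(alpha[1] - eta)
    u = rng.uniform(size=n)
    grade = np.where(u < cum1, 1, np.where(u < cum2, 2, 3))

    if sample_ids is None:
        sample_ids = [f"T{i + 1:04d}" for i in range(n)]
    table = pd.DataFrame(
        {"time_years": time, "event": event, "grade": grade},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ClinicalTable(table=table)


def simulate_screen_cohort(
    config: SimConfig,
) -> tuple[ExpressionMatrix, ClinicalTable, dict]:
    """Expression matrix + clinical table + truth record for a whole cohort.

    Planted risk genes come first (ids ``planted_1``...), then
    ``config.n_null_genes`` null genes (unimodal N(0,1), no clinical
    linkage).  The shared clinical table is driven by the true modes of the
    first planted gene; with no planted genes it is null-calibrated (all
    samples behave like the middle mode).
    """
    n_tumor = config.n_tumor
    tumor_ids = [f"T{i + 1:04d}" for i in range(n_tumor)]
    normal_ids = [f"N{i + 1:04d}" for i in range(config.n_normal)]

    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    planted_labels: dict[str, list[str]] = {}
    stream = 0
    for k in range(config.n_planted_genes):
        gid = f"planted_{k + 1}"
        gene, labels = simulate_mixture_gene(config, rng=_rng_for(config, stream), gene_id=gid)
        gene_ids.append(gid)
        rows.append(np.concatenate([gene.x_tumor, gene.x_normal]))
        planted_labels[gid] = labels.tolist()
        stream += 1
    for k in range(config.n_null_genes):
        gid = f"null_{k + 1}"
        rng = _rng_for(config, stream)
        rows.append(rng.normal(0.0, 1.0, size=n_tumor + config.n_normal))
        gene_ids.append(gid)
        stream += 1

    data = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, n_tumor + config.n_normal)),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=tumor_ids + normal_ids,
    )
    sample_class = pd.Series(
        [TUMOR] * n_tumor + [NORMAL] * config.n_normal, index=data.columns
    )
    expr = ExpressionMatrix(data=data, sample_class=sample_class)

    if planted_labels:
        driver = next(iter(planted_labels))
        labels = np.array(planted_labels[driver])
    else:
        driver = None
        labels = np.array(["middle"] * n_tumor)
    clinical = simulate_clinical(
        labels, config, rng=_rng_for(config, _CLINICAL_STREAM), sample_ids=tumor_ids
    )
    truth = {
        "planted_genes": list(planted_labels),
        "driver_gene": driver,
        "true_labels": planted_labels,
        "config": asdict(config),
    }
    return expr, clinical, truth
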