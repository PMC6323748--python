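"""Normal-anchored, ordered, shared-variance three-component Gaussian mixture EM.

Model
-----
For one gene, tumor expression values are a mixture of three Gaussians with
ordered means ``mu_1 <= mu_2 <= mu_3`` and a single shared standard deviation
``sigma``; expression values of normal (non-tumor) samples are modeled as
draws from the middle component ``N(mu_2, sigma^2)``.  Anchoring the middle
component to the normal population makes "middle" mean "similar to normal",
so the low and high modes capture tumors whose expression deviates downward
or upward from the normal state.

The log-likelihood is

    LL = sum_i log( sum_j pi_j f(x_tumor_i; mu_j, sigma) )
       + sum_i log f(x_normal_i; mu_2, sigma)

with ``f`` the Gaussian density.  The M-step mean updates are
responsibility-weighted tumor means, with every normal sample contributing to
the middle component; when an unconstrained update violates the mean
ordering, the offending adjacent components are pooled to their common
weighted mean (three cases: pool 1-2, pool 2-3, pool all three).  ``sigma``
pools tumor residuals (responsibility weighted) with normal residuals around
``mu_2``.

A fitted gene is called trimodal when the means are strictly increasing and
every mixing proportion exceeds 0.01.  Hard low/middle/high assignment uses
the two expression values where adjacent components' pi-weighted densities
cross, falling back to the 10%/90% empirical tumor quantiles when a
closed-form cutoff escapes the bracketing means.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "GeneVector",
    "MixtureParams",
    "Responsibilities",
    "MixtureFit",
    "Cutoffs",
    "ModeAssignment",
    "EMConfig",
    "log_likelihood",
    "e_step",
    "m_step",
    "fit_em",
    "check_trimodality",
    "compute_cutoffs",
    "assign_modes",
    "fit_record",
]

MODE_LABELS = ("low", "middle", "high")

_PI_SUM_TOL = 1e-8
_STRICT_TOL = 1e-8  # tolerance for "strictly increasing" means
_MIN_PI = 0.01  # trimodality proportion floor


@dataclass
class GeneVector:
    """One gene's tumor and normal expression values (log scale)."""

    gene_id: str
    x_tumor: np.ndarray
    x_normal: np.ndarray

    def __post_init__(self) -> None:
        self.x_tumor = np.asarray(self.x_tumor, dtype=float)
        self.x_normal = np.asarray(self.x_normal, dtype=float)
        if not (np.all(np.isfinite(self.x_tumor)) and np.all(np.isfinite(self.x_normal))):
            raise ValueError(f"gene {self.gene_id}: non-finite expression values")


@dataclass(frozen=True)
class MixtureParams:
    """Mixture parameter triple (pi, mu, sigma) for one gene."""

    pi: np.ndarray
    mu: np.ndarray
    sigma: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "pi", np.asarray(self.pi, dtype=float))
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        if self.pi.shape != (3,) or self.mu.shape != (3,):
            raise ValueError("pi and mu must be 3-vectors")
        if np.any(self.pi < -_PI_SUM_TOL) or abs(self.pi.sum() - 1.0) > _PI_SUM_TOL:
            raise ValueError(f"pi must be non-negative and sum to 1, got {self.pi}")
        if not (self.mu[0] <= self.mu[1] <= self.mu[2]):
            raise ValueError(f"means must be ordered, got {self.mu}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


@dataclass
class Responsibilities:
    """Posterior membership weights of tumor samples (n x 3, rows sum to 1)."""

    gamma: np.ndarray


@dataclass
class Cutoffs:
    """Mode boundaries: low/middle at c12, middle/high at c23."""

    c12: float
    c23: float
    c12_fallback: bool = False
    c23_fallback: bool = False


@dataclass
class ModeAssignment:
    """Hard low/middle/high labels with observed mode proportions."""

    labels: np.ndarray  # dtype object/str, values in MODE_LABELS
    empirical_pi: np.ndarray  # (low, middle, high) fractions


@dataclass
class MixtureFit:
    """Converged parameters plus trimodality verdict and diagnostics."""

    gene_id: str
    params: MixtureParams
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    trimodal: bool
    cutoffs: Cutoffs | None = None
    empirical_pi: np.ndarray | None = None
    message: str = ""

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1]) if len(self.loglik_trace) else float("nan")


@dataclass
class EMConfig:
    """Tunables for the per-gene EM fit.

    weighting
        "standard": classic EM responsibilities pi_j f_j / sum_k pi_k f_k
        (guarantees likelihood ascent).  "paper_literal": plain density ratio
        f_j / sum_k f_k without mixing-proportion weighting.
    tol / max_iter
        stop when |delta LL| < tol (absolute) or after max_iter iterations.
    restarts
        number of additional randomly jittered initializations; the run with
        the best final log-likelihood is kept.  0 = single deterministic
        start from the (10th, 50th, 90th) pooled percentiles.
    sigma_floor_frac
        sigma is floored at this fraction of the pooled value range to
        prevent degenerate zero-variance spikes.
    """

    weighting: Literal["standard", "paper_literal"] = "standard"
    tol: float = 1e-6
    max_iter: int = 500
    restarts: int = 0
    seed: int = 0
    sigma_floor_frac: float = 1e-3
    min_tumor: int = 10
    min_normal: int = 2


_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _log_density_matrix(x: np.ndarray, params: MixtureParams) -> np.ndarray:
    """(n, 3) matrix of log f(x_i; mu_j, sigma)."""
    z = (x[:, None] - params.mu[None, :]) / params.sigma
    return -0.5 * z * z - np.log(params.sigma) - _LOG_SQRT_2PI


def _log_density(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    z = (x - mu) / sigma
    return -0.5 * z * z - np.log(sigma) - _LOG_SQRT_2PI


def log_likelihood(gene: GeneVector, params: MixtureParams) -> float:
    """Joint log-likelihood of tumor (mixture) and normal (middle component) data."""
    if not params.sigma > 0:
        raise ValueError("sigma must be positive")
    ll = 0.0
    if len(gene.x_tumor):
        logf = _log_density_matrix(gene.x_tumor, params)
        with np.errstate(divide="ignore"):
            logpi = np.log(params.pi)
        ll += float(logsumexp(logf + logpi[None, :], axis=1).sum())
    if len(gene.x_normal):
        ll += float(_log_density(gene.x_normal, params.mu[1], params.sigma).sum())
    return ll


def e_step(
    gene: GeneVector,
    params: MixtureParams,
    weighting: Literal["standard", "paper_literal"] = "standard",
) -> Responsibilities:
    """Posterior membership weights for each tumor sample.

    "standard" weights densities by the mixing proportions; "paper_literal"
    is the plain ratio of component densities.  Computed in log space; if all
    three log weights underflow to -inf for a sample, it is assigned to the
    component with the nearest mean.
    """
    if weighting not in ("standard", "paper_literal"):
        raise ValueError(f"unknown weighting {weighting!r}")
    gamma, _ = _gamma_and_ll_arrays(
        gene.x_tumor, gene.x_normal, params.pi, params.mu, params.sigma,
        standard=(weighting == "standard"),
    )
    return Responsibilities(gamma=gamma)


def _m_step_arrays(
    x: np.ndarray, xn: np.ndarray, g: np.ndarray, sigma_floor: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """M-step on raw arrays; returns (pi, mu, sigma) without wrapping."""
    n_tumor, n_normal = len(x), len(xn)
    col = g.sum(axis=0)
    # clip tiny negatives from float noise, renormalize
    pi = np.clip(col / n_tumor, 0.0, None)
    pi = pi / pi.sum()

    num = g.T @ x
    den = col.copy()
    num[1] += xn.sum()
    den[1] += n_normal
    pooled_all = (x.sum() + xn.sum()) / (n_tumor + n_normal)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = num / den
    mu[~np.isfinite(mu)] = pooled_all  # empty component: global pooled mean

    def pooled(idx: Sequence[int]) -> float:
        return float(num[list(idx)].sum() / den[list(idx)].sum())

    v12 = mu[0] > mu[1]
    v23 = mu[1] > mu[2]
    if v12 and v23:
        mu[:] = pooled([0, 1, 2])
    elif v12:
        mu[0] = mu[1] = pooled([0, 1])
    elif v23:
        mu[1] = mu[2] = pooled([1, 2])
    if not (mu[0] <= mu[1] <= mu[2]):
        # pairwise pooling left the remaining pair out of order
        mu[:] = pooled([0, 1, 2])

    diff = x[:, None] - mu[None, :]
    resid = float((g * diff * diff).sum())
    if n_normal:
        resid += float(((xn - mu[1]) ** 2).sum())
    sigma = np.sqrt(resid / (n_tumor + n_normal))
    return pi, mu, max(sigma, sigma_floor)


def m_step(gene: GeneVector, gamma: Responsibilities, sigma_floor: float = 1e-12) -> MixtureParams:
    """Constrained maximizer of the expected complete-data log-likelihood.

    pi_j = column sums of gamma / #tumor; mu_j = gamma-weighted tumor means
    with all normal values contributing to j=2; adjacent ordering violations
    pooled to the common weighted mean; sigma pools tumor residuals
    (gamma-weighted) and normal residuals around mu_2, then is floored.
    """
    g = np.asarray(gamma.gamma, dtype=float)
    pi, mu, sigma = _m_step_arrays(gene.x_tumor, gene.x_normal, g, sigma_floor)
    return MixtureParams(pi=pi, mu=mu, sigma=sigma)


def check_trimodality(params: MixtureParams, min_pi: float = _MIN_PI, tol: float = _STRICT_TOL) -> bool:
    """True iff means are strictly increasing and all proportions exceed min_pi."""
    return bool(
        params.mu[1] - params.mu[0] > tol
        and params.mu[2] - params.mu[1] > tol
        and np.all(params.pi > min_pi)
    )


def _density_crossing(pi_a: float, mu_a: float, pi_b: float, mu_b: float, sigma: float) -> float:
    """x where pi_a f(x; mu_a, sigma) = pi_b f(x; mu_b, sigma)."""
    if abs(mu_a - mu_b) < 1e-12:
        return float("nan")
    with np.errstate(divide="ignore", invalid="ignore"):
        return float(
            (mu_a**2 - mu_b**2 - 2.0 * sigma**2 * np.log(pi_a / pi_b))
            / (2.0 * (mu_a - mu_b))
        )


def compute_cutoffs(params: MixtureParams, x_tumor: np.ndarray) -> Cutoffs:
    """Mode boundaries from the pi-weighted density crossing points.

    If the closed-form c12 falls outside [mu_1, mu_2] it is replaced by the
    10% empirical quantile of the tumor values (flagged); likewise c23
    outside [mu_2, mu_3] is replaced by the 90% quantile.
    """
    x_tumor = np.asarray(x_tumor, dtype=float)
    mu, pi, sigma = params.mu, params.pi, params.sigma
    c12 = _density_crossing(pi[0], mu[0], pi[1], mu[1], sigma)
    c23 = _density_crossing(pi[1], mu[1], pi[2], mu[2], sigma)
    c12_fb = not (mu[0] <= c12 <= mu[1])  # True also when c12 is nan
    c23_fb = not (mu[1] <= c23 <= mu[2])
    if c12_fb:
        c12 = float(np.quantile(x_tumor, 0.10))
    if c23_fb:
        c23 = float(np.quantile(x_tumor, 0.90))
    if not c12 < c23:
        # pathological overlap: force to the quantile fallbacks
        c12 = float(np.quantile(x_tumor, 0.10))
        c23 = float(np.quantile(x_tumor, 0.90))
        c12_fb = c23_fb = True
    return Cutoffs(c12=float(c12), c23=float(c23), c12_fallback=c12_fb, c23_fallback=c23_fb)


def assign_modes(x_tumor: np.ndarray, cutoffs: Cutoffs) -> ModeAssignment:
    """Hard labels: x < c12 -> low, x > c23 -> high, otherwise middle.

    Values exactly equal to a cutoff go to the middle mode.
    """
    x = np.asarray(x_tumor, dtype=float)
    if not cutoffs.c12 < cutoffs.c23:
        raise ValueError("require c12 < c23")
    labels = np.where(x < cutoffs.c12, "low", np.where(x > cutoffs.c23, "high", "middle"))
    n = len(x)
    counts = np.array([(labels == lab).sum() for lab in MODE_LABELS], dtype=float)
    return ModeAssignment(labels=labels, empirical_pi=counts / n)


def _initial_params(pooled: np.ndarray, rng: np.random.Generator | None = None) -> MixtureParams:
    mu0 = np.percentile(pooled, [10.0, 50.0, 90.0])
    sigma0 = float(np.std(pooled))
    if rng is not None:
        spread = np.ptp(pooled)
        mu0 = np.sort(mu0 + rng.normal(0.0, 0.15 * spread + 1e-12, size=3))
    sigma0 = max(sigma0, 1e-6 * (abs(float(np.mean(pooled))) + 1.0))
    return MixtureParams(pi=np.array([0.15, 0.70, 0.15]), mu=np.sort(mu0), sigma=sigma0)


def _logsumexp_rows(a: np.ndarray) -> np.ndarray:
    """Row-wise logsumexp for an (n, 3) matrix; -inf rows stay -inf."""
    amax = np.max(a, axis=1)
    finite = np.isfinite(amax)
    safe = np.where(finite, amax, 0.0)
    with np.errstate(divide="ignore"):
        out = safe + np.log(np.exp(a - safe[:, None]).sum(axis=1))
    out[~finite] = -np.inf
    return out


def _gamma_and_ll_arrays(
    x: np.ndarray, xn: np.ndarray, pi: np.ndarray, mu: np.ndarray, sigma: float, standard: bool
) -> tuple[np.ndarray, float]:
    """Responsibilities and log-likelihood from a single density evaluation."""
    z = (x[:, None] - mu[None, :]) / sigma
    logf = -0.5 * z * z - (np.log(sigma) + _LOG_SQRT_2PI)
    with np.errstate(divide="ignore"):
        logpi = np.log(pi)
    log_mix = _logsumexp_rows(logf + logpi[None, :])  # per-sample mixture loglik
    logw = logf + logpi[None, :] if standard else logf
    denom = log_mix if standard else _logsumexp_rows(logw)
    bad = ~np.isfinite(denom)
    if bad.any():
        gamma = np.exp(logw - np.where(bad, 0.0, denom)[:, None])
        gamma[bad] = 0.0
        nearest = np.argmin(np.abs(x[bad, None] - mu[None, :]), axis=1)
        gamma[np.flatnonzero(bad), nearest] = 1.0
    else:
        gamma = np.exp(logw - denom[:, None])
    ll = float(log_mix.sum())
    if len(xn):
        ll += float(_log_density(xn, mu[1], sigma).sum())
    return gamma, ll


def _run_em(
    gene: GeneVector, init: MixtureParams, config: EMConfig, sigma_floor: float
) -> tuple[MixtureParams, np.ndarray, bool, int, str]:
    standard = config.weighting == "standard"
    x, xn = gene.x_tumor, gene.x_normal
    pi, mu, sigma = init.pi, init.mu, init.sigma
    gamma, ll = _gamma_and_ll_arrays(x, xn, pi, mu, sigma, standard)
    trace = [ll]
    converged = False
    message = ""
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        pi, mu, sigma = _m_step_arrays(x, xn, gamma, sigma_floor)
        gamma, ll = _gamma_and_ll_arrays(x, xn, pi, mu, sigma, standard)
        trace.append(ll)
        if not np.isfinite(ll):
            message = "non-finite log-likelihood"
            break
        if abs(ll - trace[-2]) < config.tol:
            converged = True
            break
    return MixtureParams(pi=pi, mu=mu, sigma=sigma), np.asarray(trace), converged, n_iter, message


def fit_em(gene: GeneVector, config: EMConfig | None = None) -> MixtureFit:
    """Fit the anchored mixture to one gene and evaluate trimodality.

    Alternates E and M steps from a deterministic percentile initialization
    (plus optional jittered restarts) until the absolute change in
    log-likelihood drops below ``config.tol``.  When the fit is trimodal the
    cutoffs, hard mode assignment and empirical mode proportions are
    computed from the tumor values.
    """
    config = config or EMConfig()
    if len(gene.x_tumor) < config.min_tumor:
        raise ValueError(
            f"gene {gene.gene_id}: need >= {config.min_tumor} tumor samples, got {len(gene.x_tumor)}"
        )
    if len(gene.x_normal) < config.min_normal:
        raise ValueError(
            f"gene {gene.gene_id}: need >= {config.min_normal} normal samples, got {len(gene.x_normal)}"
        )
    pooled = np.concatenate([gene.x_tumor, gene.x_normal])
    sigma_floor = config.sigma_floor_frac * float(np.ptp(pooled))
    if sigma_floor <= 0:
        sigma_floor = 1e-12

    rng = np.random.default_rng(config.seed)
    starts = [_initial_params(pooled)]
    starts += [_initial_params(pooled, rng) for _ in range(config.restarts)]

    best: tuple[MixtureParams, np.ndarray, bool, int, str] | None = None
    for init in starts:
        result = _run_em(gene, init, config, sigma_floor)
        trace = result[1]
        if best is None or (
            np.isfinite(trace[-1])
            and (not np.isfinite(best[1][-1]) or trace[-1] > best[1][-1])
        ):
            best = result
    assert best is not None
    params, trace, converged, n_iter, message = best

    if not np.isfinite(trace[-1]):
        return MixtureFit(
            gene_id=gene.gene_id,
            params=params,
            loglik_trace=trace,
            converged=False,
            n_iter=n_iter,
            trimodal=False,
            message=message or "unfittable",
        )

    trimodal = check_trimodality(params)
    cutoffs = None
    empirical_pi = None
    if trimodal:
        cutoffs = compute_cutoffs(params, gene.x_tumor)
        empirical_pi = assign_modes(gene.x_tumor, cutoffs).empirical_pi
    return MixtureFit(
        gene_id=gene.gene_id,
        params=params,
        loglik_trace=trace,
        converged=converged,
        n_iter=n_iter,
        trimodal=trimodal,
        cutoffs=cutoffs,
        empirical_pi=empirical_pi,
        message=message,
    )


def fit_record(fit: MixtureFit) -> dict:
    """Flatten a MixtureFit into one JSON-serializable record."""
    rec = {
        "gene_id": fit.gene_id,
        "pi": [float(v) for v in fit.params.pi],
        "mu": [float(v) for v in fit.params.mu],
        "sigma": float(fit.params.sigma),
        "loglik": fit.loglik,
        "n_iter": int(fit.n_iter),
        "converged": bool(fit.converged),
        "trimodal": bool(fit.trimodal),
        "c12": None,
        "c23": None,
        "c12_fallback": None,
        "c23_fallback": None,
        "empirical_pi": None,
    }
    if fit.cutoffs is not None:
        rec.update(
            c12=float(fit.cutoffs.c12),
            c23=float(fit.cutoffs.c23),
            c12_fallback=bool(fit.cutoffs.c12_fallback),
            c23_fallback=bool(fit.cutoffs.c23_fallback),
        )
    if fit.empirical_pi is not None:
        rec["empirical_pi"] = [float(v) for v in fit.empirical_pi]
    if fit.message:
        rec["message"] = fit.message
    return rec


def write_fit_records(fits: Sequence[MixtureFit], path) -> None:
    """Serialize fits as one JSON object per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for fit in fits:
            fh.write(json.dumps(fit_record(fit)) + "\n")
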