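"""Genomic relationship matrices from continuous genotypes.

The relationship matrix is the centered cross-product of the continuous
genotype matrix divided by a scaling factor h:

    G = (F - 1 fbar')(F - 1 fbar')' / h

Three scalings are supported.  The naive scaling assumes Binomial read
sampling and divides the per-marker frequency variance by the ploidy k:
h = (1/k) * sum_j fbar_j (1 - fbar_j).  The de-biased variant keeps the
naive scaling but shrinks each diagonal element by an individual-specific
factor 1 - w_i with w_i = (k-1)/(mean-depth_i + k-1).  The Beta-Binomial
scaling models the latent per-individual allele sampling probability as
p_ij ~ Beta(mu_j, tau_j) (mean/dispersion parameterization), so the
frequency estimate f_ij has variance mu_j(1-mu_j) * omega_j with the
heterogeneity factor

    omega_j = [1 + (mean-depth_j - 1) * tau_j] / mean-depth_j,

giving h = sum_j fbar_j (1 - fbar_j) omega_j.  No ploidy term appears:
ploidy is absorbed by the overdispersion.  tau_j is estimated per marker by
bounded maximum likelihood under the Beta-Binomial with the location fixed
at the observed mean frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize, stats, special

__all__ = [
    "GRM",
    "BetaBinomialFit",
    "betabinomial_loglik",
    "estimate_tau",
    "fit_betabinomial",
    "heterogeneity_factor",
    "scaling_naive",
    "scaling_betabinomial",
    "build_grm",
    "debias_grm",
    "grm_summary",
    "grm_from_genotypes",
    "write_grm",
]

TAU_BOUNDS = (1e-6, 1.0 - 1e-6)

Method = Literal["naive", "debiased", "betabinomial"]


@dataclass
class GRM:
    """A genomic relationship matrix and the provenance of its scaling."""

    G: np.ndarray
    h: float
    method: Method
    ploidy: int
    individual_ids: list[str]
    indiv_mean_depth: np.ndarray | None = None
    marker_mean_depth: np.ndarray | None = None
    tau: np.ndarray | None = None
    omega: np.ndarray | None = None
    w: np.ndarray | None = None  # diagonal adjustment, debiased only

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        if self.h <= 0:
            raise ValueError("scaling factor h must be positive")
        if not np.allclose(self.G, self.G.T, atol=1e-10):
            raise ValueError("G must be symmetric")

    @property
    def n(self) -> int:
        return self.G.shape[0]


@dataclass
class BetaBinomialFit:
    """Per-marker Beta-Binomial dispersion fit (location fixed at fbar)."""

    mu: np.ndarray
    tau: np.ndarray
    loglik: np.ndarray
    converged: np.ndarray


def _betabinom_ab(mu: float, tau: float) -> tuple[float, float]:
    # mean/dispersion -> standard (alpha, beta): concentration (1-tau)/tau
    conc = (1.0 - tau) / tau
    return mu * conc, (1.0 - mu) * conc


def betabinomial_loglik(
    tau: float, R_A: np.ndarray, R_T: np.ndarray, mu: float
) -> float:
    """Beta-Binomial log-likelihood of reference read counts at one marker.

    Sum over individuals of log BetaBinomial(R_A | R_T, alpha, beta) with
    alpha = mu(1-tau)/tau and beta = (1-mu)(1-tau)/tau.  As tau -> 0 the
    likelihood approaches the Binomial log-likelihood continuously; at
    tau below ~1e-10 the Binomial limit is evaluated directly for numerical
    stability.  Entries with zero total reads must be excluded upstream.
    """
    if not 0.0 < mu < 1.0:
        raise ValueError("mu must lie in (0, 1); filter such markers upstream")
    if not 0.0 <= tau < 1.0:
        raise ValueError("tau must lie in [0, 1)")
    R_A = np.asarray(R_A, dtype=np.int64)
    R_T = np.asarray(R_T, dtype=np.int64)
    if (R_A > R_T).any():
        raise ValueError("R_A must not exceed R_T")
    if (R_T <= 0).any():
        raise ValueError("entries with R_T = 0 carry no likelihood information")
    if tau < 1e-10:
        return float(stats.binom.logpmf(R_A, R_T, mu).sum())
    a, b = _betabinom_ab(mu, tau)
    return float(stats.betabinom.logpmf(R_A, R_T, a, b).sum())


def _grid_tau(R_A: np.ndarray, R_T: np.ndarray, mu: float, step: float = 1e-3) -> float:
    """Dense grid search over tau; used as a fallback and as a test oracle."""
    taus = np.arange(TAU_BOUNDS[0], TAU_BOUNDS[1], step)
    conc = (1.0 - taus) / taus
    a = mu * conc
    b = (1.0 - mu) * conc
    # vectorized logpmf: grid x observations
    ll = (
        special.betaln(R_A[None, :] + a[:, None], R_T[None, :] - R_A[None, :] + b[:, None])
        - special.betaln(a[:, None], b[:, None])
    ).sum(axis=1)
    return float(taus[np.argmax(ll)])


def estimate_tau(
    R_A: np.ndarray,
    R_T: np.ndarray,
    mu: float,
    bounds: tuple[float, float] = TAU_BOUNDS,
) -> tuple[float, float, bool]:
    """Maximum-likelihood overdispersion for one marker.

    Bounded 1-D maximization of :func:`betabinomial_loglik` over tau with the
    location fixed at the marker's mean frequency.  Returns
    ``(tau_hat, loglik, converged)``; on optimizer failure a dense grid
    search supplies the estimate and the flag is False.
    """
    R_A = np.asarray(R_A, dtype=np.int64)
    R_T = np.asarray(R_T, dtype=np.int64)
    keep = R_T > 0
    R_A, R_T = R_A[keep], R_T[keep]
    if R_A.size < 2:
        raise ValueError("tau estimation needs at least two observations with reads")

    def nll(t: float) -> float:
        return -betabinomial_loglik(t, R_A, R_T, mu)

    res = optimize.minimize_scalar(nll, bounds=bounds, method="bounded")
    if res.success:
        tau = float(np.clip(res.x, *bounds))
        return tau, -float(res.fun), True
    tau = _grid_tau(R_A, R_T, mu)
    return tau, betabinomial_loglik(tau, R_A, R_T, mu), False


def fit_betabinomial(R_A: np.ndarray, R_B: np.ndarray, fbar: np.ndarray) -> BetaBinomialFit:
    """Estimate tau marker by marker from merged read counts.

    ``fbar`` supplies the location parameter per marker (the mean observed
    frequency).  Entries with zero total reads are excluded from each
    marker's likelihood.
    """
    R_T = R_A + R_B
    m = R_A.shape[1]
    tau = np.empty(m)
    ll = np.empty(m)
    conv = np.empty(m, dtype=bool)
    for j in range(m):
        tau[j], ll[j], conv[j] = estimate_tau(R_A[:, j], R_T[:, j], float(fbar[j]))
    return BetaBinomialFit(np.asarray(fbar, dtype=float), tau, ll, conv)


def heterogeneity_factor(tau: float | np.ndarray, mean_depth: float | np.ndarray) -> float | np.ndarray:
    """omega = [1 + (mean_depth - 1) tau] / mean_depth.

    Converts the per-marker frequency variance mu(1-mu) into the variance of
    the read-based frequency estimate.  At tau = 0 this is 1/depth (pure
    Binomial read sampling); as depth grows it tends to tau.
    """
    tau = np.asarray(tau, dtype=float)
    mean_depth = np.asarray(mean_depth, dtype=float)
    if (mean_depth < 1).any():
        raise ValueError("mean depth must be >= 1")
    if ((tau < 0) | (tau >= 1)).any():
        raise ValueError("tau must lie in [0, 1)")
    out = (1.0 + (mean_depth - 1.0) * tau) / mean_depth
    return float(out) if out.ndim == 0 else out


def scaling_naive(fbar: np.ndarray, k: int) -> float:
    """Naive scaling h = (1/k) sum_j fbar_j (1 - fbar_j)."""
    if k < 2:
        raise ValueError("ploidy must be >= 2")
    fbar = np.asarray(fbar, dtype=float)
    if ((fbar <= 0) | (fbar >= 1)).any():
        raise ValueError("fbar entries must lie strictly in (0, 1); filter fixed markers")
    h = float(np.sum(fbar * (1.0 - fbar)) / k)
    if h <= 0:
        raise ValueError("scaling factor is zero; G is undefined")
    return h


def scaling_betabinomial(
    fbar: np.ndarray, marker_mean_depth: np.ndarray, tau: np.ndarray
) -> float:
    """Beta-Binomial scaling h = sum_j fbar_j (1 - fbar_j) omega_j."""
    fbar = np.asarray(fbar, dtype=float)
    if ((fbar <= 0) | (fbar >= 1)).any():
        raise ValueError("fbar entries must lie strictly in (0, 1); filter fixed markers")
    omega = heterogeneity_factor(np.asarray(tau), np.asarray(marker_mean_depth))
    h = float(np.sum(fbar * (1.0 - fbar) * omega))
    if h <= 0:
        raise ValueError("scaling factor is zero; G is undefined")
    return h


def build_grm(
    F: np.ndarray,
    h: float,
    method: Method,
    ploidy: int,
    individual_ids: list[str],
    **extra: np.ndarray,
) -> GRM:
    """G = (F - 1 fbar')(F - 1 fbar')' / h with fbar the column means of F.

    F must be complete (post-imputation).  The centering vector is recomputed
    from F itself so that every row of G sums to zero exactly.
    """
    F = np.asarray(F, dtype=float)
    if np.isnan(F).any():
        raise ValueError("F must be complete; impute missing genotypes first")
    if h <= 0:
        raise ValueError("scaling factor h must be positive")
    Fc = F - F.mean(axis=0, keepdims=True)
    G = (Fc @ Fc.T) / h
    G = (G + G.T) / 2.0
    return GRM(G, h, method, ploidy, individual_ids, **extra)


def debias_grm(grm_naive: GRM, indiv_mean_depth: np.ndarray, k: int) -> GRM:
    """Diagonal de-biasing of the naive-scaled G.

    Each diagonal element is multiplied by 1 - w_i with
    w_i = (k - 1) / (mean-depth_i + k - 1); off-diagonals are unchanged.
    Note the corrected matrix intentionally no longer has zero row sums.
    """
    if grm_naive.method != "naive":
        raise ValueError("debiasing applies to the naive-scaled G")
    depth = np.asarray(indiv_mean_depth, dtype=float)
    w = (k - 1.0) / (depth + k - 1.0)
    G = grm_naive.G.copy()
    np.fill_diagonal(G, np.diag(G) * (1.0 - w))
    return GRM(
        G,
        grm_naive.h,
        "debiased",
        k,
        list(grm_naive.individual_ids),
        indiv_mean_depth=depth,
        marker_mean_depth=grm_naive.marker_mean_depth,
        w=w,
    )


def grm_summary(grm: GRM) -> dict[str, float]:
    """Mean diagonal/off-diagonal of G and the implied genomic inbreeding.

    Mean diagonal minus one is reported as the average genomic inbreeding
    coefficient of the population.
    """
    d = np.diag(grm.G)
    n = grm.n
    off = grm.G[~np.eye(n, dtype=bool)]
    return {
        "mean_diag": float(d.mean()),
        "mean_offdiag": float(off.mean()) if off.size else 0.0,
        "mean_inbreeding": float(d.mean() - 1.0),
        "scaling_h": grm.h,
    }


def grm_from_genotypes(
    cg_complete,
    rd,
    method: Method = "betabinomial",
    ploidy: int = 6,
) -> GRM:
    """Convenience: build a GRM of the requested scaling from pipeline objects.

    ``cg_complete`` is an imputed ContinuousGenotypes; ``rd`` the aligned
    (merged) ReadDepthMatrix supplying depths for the de-biasing and
    Beta-Binomial scalings.
    """
    F = cg_complete.F
    fbar = F.mean(axis=0)
    rt = rd.R_T.astype(float)
    obs = rt > 0
    marker_depth = np.where(obs, rt, np.nan)
    with np.errstate(invalid="ignore"):
        marker_mean_depth = np.nanmean(marker_depth, axis=0)
        indiv_mean_depth = np.nanmean(marker_depth, axis=1)
    ids = list(cg_complete.sample_ids)
    if method == "naive":
        h = scaling_naive(fbar, ploidy)
        return build_grm(F, h, "naive", ploidy, ids,
                         indiv_mean_depth=indiv_mean_depth,
                         marker_mean_depth=marker_mean_depth)
    if method == "debiased":
        h = scaling_naive(fbar, ploidy)
        naive = build_grm(F, h, "naive", ploidy, ids,
                          indiv_mean_depth=indiv_mean_depth,
                          marker_mean_depth=marker_mean_depth)
        return debias_grm(naive, indiv_mean_depth, ploidy)
    if method == "betabinomial":
        fit = fit_betabinomial(rd.R_A, rd.R_B, fbar)
        omega = heterogeneity_factor(fit.tau, marker_mean_depth)
        h = scaling_betabinomial(fbar, marker_mean_depth, fit.tau)
        return build_grm(F, h, "betabinomial", ploidy, ids,
                         indiv_mean_depth=indiv_mean_depth,
                         marker_mean_depth=marker_mean_depth,
                         tau=fit.tau, omega=np.asarray(omega))
    raise ValueError(f"unknown GRM method: {method!r}")


def write_grm(grm: GRM, path: str | Path) -> None:
    """Write G as a TSV square matrix with individual IDs as header/index."""
    pd.DataFrame(grm.G, index=grm.individual_ids, columns=grm.individual_ids).to_csv(
        path, sep="\t", index_label="individual"
    )
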