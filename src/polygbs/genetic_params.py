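"""Heritability, repeatability, and genetic/phenotypic correlations.

The mixed model estimates a mother (half-sib family) variance, which is one
quarter of the additive variance on the progeny scale: sigma2_A = 4 sigma2_M.
Because the genomic relationship matrix is scaled such that its mean
diagonal need not be 1, the additive variance entering heritability is
multiplied by the mean diagonal of G:

    h2 = mean_diag_G * sigma2_A / (sigma2_M * mean_diag_G + sigma2_C + sigma2_e)
    c2 = (mean_diag_G * sigma2_A + sigma2_C) / (same denominator)

Note h2 is NOT clamped to [0, 1]: with sigma2_C + sigma2_e small the formula
exceeds 1 (the numerator uses 4 sigma2_M while only sigma2_M appears in the
denominator).  Correlations use V_A = 4 V_M (the factor cancels, so the
additive correlation equals the correlation of V_M) and
V_P = V_M + V_C + V_E.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from polygbs.mixed_model import VarianceComponents

__all__ = [
    "GeneticParams",
    "heritability",
    "repeatability",
    "genetic_correlations",
    "phenotypic_correlations",
    "derive_genetic_params",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Half-up decimal rounding for report display."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _denominator(sigma2_M: float, sigma2_C: float, sigma2_e: float, mean_diag_G: float) -> float:
    den = sigma2_M * mean_diag_G + sigma2_C + sigma2_e
    if den <= 0:
        raise ZeroDivisionError("phenotypic variance denominator must be positive")
    return den


def heritability(
    sigma2_M: float, sigma2_C: float, sigma2_e: float, mean_diag_G: float = 1.0
) -> float:
    """Narrow-sense heritability from mother-level variance components."""
    if min(sigma2_M, sigma2_C, sigma2_e) < 0:
        raise ValueError("variance components must be non-negative")
    sigma2_A = 4.0 * sigma2_M
    return mean_diag_G * sigma2_A / _denominator(sigma2_M, sigma2_C, sigma2_e, mean_diag_G)


def repeatability(
    sigma2_M: float, sigma2_C: float, sigma2_e: float, mean_diag_G: float = 1.0
) -> float:
    """Repeatability: additive plus permanent-environment share of variance."""
    if min(sigma2_M, sigma2_C, sigma2_e) < 0:
        raise ValueError("variance components must be non-negative")
    sigma2_A = 4.0 * sigma2_M
    return (mean_diag_G * sigma2_A + sigma2_C) / _denominator(
        sigma2_M, sigma2_C, sigma2_e, mean_diag_G
    )


def _cov_to_corr(V: np.ndarray, what: str, labels: list[str] | None = None) -> np.ndarray:
    d = np.diag(V)
    if (d <= 0).any():
        bad = labels[int(np.argmin(d))] if labels else int(np.argmin(d))
        raise ValueError(f"{what} has non-positive variance for trait {bad!r}")
    s = np.sqrt(d)
    return V / np.outer(s, s)


def genetic_correlations(V_M: np.ndarray, labels: list[str] | None = None) -> np.ndarray:
    """Additive genetic correlation matrix.

    Computed from V_A = 4 V_M; the scalar cancels, so this equals the
    correlation matrix of V_M itself.
    """
    V_M = np.asarray(V_M, dtype=float)
    return _cov_to_corr(4.0 * V_M, "V_M", labels)


def phenotypic_correlations(
    V_M: np.ndarray, V_C: np.ndarray, V_E: np.ndarray, labels: list[str] | None = None
) -> np.ndarray:
    """Phenotypic correlation matrix of V_P = V_M + V_C + V_E."""
    V_P = np.asarray(V_M, float) + np.asarray(V_C, float) + np.asarray(V_E, float)
    return _cov_to_corr(V_P, "V_P", labels)


@dataclass
class GeneticParams:
    """Derived genetic parameters per trait and trait pair."""

    trait_names: list[str]
    h2: np.ndarray
    c2: np.ndarray
    r_A: np.ndarray
    r_P: np.ndarray
    V_A: np.ndarray
    V_P: np.ndarray
    mean_diag_G: float

    def table(self, ndigits: int = 2) -> pd.DataFrame:
        """Report layout: h2 on the diagonal, genetic correlations below,
        phenotypic correlations above (all half-up rounded)."""
        T = len(self.trait_names)
        out = np.empty((T, T))
        for j in range(T):
            for k in range(T):
                if j == k:
                    out[j, k] = round_half_up(self.h2[j], ndigits)
                elif j > k:
                    out[j, k] = round_half_up(self.r_A[j, k], ndigits)
                else:
                    out[j, k] = round_half_up(self.r_P[j, k], ndigits)
        return pd.DataFrame(out, index=self.trait_names, columns=self.trait_names)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trait": self.trait_names,
                "h2": self.h2,
                "c2": self.c2,
                "se": ["NA"] * len(self.trait_names),  # REML SEs not computed
            }
        )

    def to_files(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.summary().to_csv(prefix.with_suffix(".summary.tsv"), sep="\t", index=False)
        self.table().to_csv(prefix.with_suffix(".table.tsv"), sep="\t")


def derive_genetic_params(
    vc: VarianceComponents,
    mean_diag_G: float,
    mother_scale: bool = True,
) -> GeneticParams:
    """Convert variance components into genetic parameters.

    ``mother_scale`` states the convention of ``vc.V_M``: True means
    mother-level (co)variances (the estimator's native scale), False means
    additive-scale matrices which are divided by 4 internally.  The mixing
    of additive variances with mother-level covariances in published tables
    makes the convention worth being explicit about.
    """
    V_M = vc.V_M if mother_scale else vc.V_M / 4.0
    T = vc.n_traits
    h2 = np.array(
        [
            heritability(V_M[t, t], vc.V_C[t, t], vc.V_E[t, t], mean_diag_G)
            for t in range(T)
        ]
    )
    c2 = np.array(
        [
            repeatability(V_M[t, t], vc.V_C[t, t], vc.V_E[t, t], mean_diag_G)
            for t in range(T)
        ]
    )
    return GeneticParams(
        trait_names=list(vc.trait_names),
        h2=h2,
        c2=c2,
        r_A=genetic_correlations(V_M, vc.trait_names),
        r_P=phenotypic_correlations(V_M, vc.V_C, vc.V_E, vc.trait_names),
        V_A=4.0 * V_M,
        V_P=V_M + vc.V_C + vc.V_E,
        mean_diag_G=mean_diag_G,
    )
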