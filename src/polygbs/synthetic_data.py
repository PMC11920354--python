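"""Synthetic hexaploid GBS data with half-sib family and trial structure.

No public dataset exists for this breeding program, so this module generates
populations with exactly the statistical structure the pipeline assumes:

* hexaploid allele dosages (0..6) per mother clone, with half-sib families
  created by sharing one simulated parent's gametes;
* sequencing reads per sample and marker: a right-skewed (negative-binomial)
  total depth, a latent allele sampling probability drawn from a Beta with
  per-marker overdispersion tau, and Binomial reference reads given both —
  i.e. marginally Beta-Binomial read counts.  Zero total depth is the one
  and only source of missingness;
* multi-trait phenotypes from the GBLUP generative model: trial-by-year
  fixed effects, mother genetic effects with covariance V_M (x) G,
  progeny-within-trial permanent-environment effects with V_C, and
  residuals with V_E.

Default parameter magnitudes mirror the Finnish timothy breeding program
the package targets: 1764 mother clones in 18 half-sib families, mean read
depth ~38 with a long right tail, per-marker overdispersion averaging 0.26,
reference-allele frequencies averaging 0.77, 23 trial years, and six traits
(three yield cuts, winter damage, two digestibility values) with the
published covariance magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from polygbs.gbs_io import ReadDepthMatrix
from polygbs.grm import GRM
from polygbs.mixed_model import TraitData, VarianceComponents, _check_psd

__all__ = [
    "TrueGenotypes",
    "SimulationConfig",
    "timothy_variance_components",
    "simulate_population",
    "simulate_reads",
    "simulate_phenotypes",
    "write_vcf",
    "write_sample_map",
]

TRAITS = [
    "yield_cut1",
    "yield_cut2",
    "yield_cut3",
    "winter_damage",
    "dvalue_cut1",
    "dvalue_cut2",
]

#: trait means on their natural scales (kg DM/ha, %, %)
TRAIT_MEANS = np.array([6460.7, 4159.8, 2623.8, 12.1, 68.2, 67.6])


def _nearest_psd(mat: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues to zero (symmetric projection)."""
    vals, vecs = np.linalg.eigh((mat + mat.T) / 2)
    vals = np.clip(vals, 0.0, None)
    return (vecs * vals) @ vecs.T


def timothy_variance_components() -> VarianceComponents:
    """Published-magnitude six-trait (co)variance matrices.

    Mother variances are additive variances divided by four; mother
    covariances are reconstructed from the genetic correlations, and
    residual covariances from the phenotypic correlations with a diagonal
    permanent-environment matrix.  Each matrix is projected to the nearest
    positive semi-definite matrix, since correlations reported to two
    decimals need not form an exactly PSD matrix.
    """
    sigma2_A = np.array([60342.8, 102520.8, 21229.6, 6.60, 0.72, 1.24])
    vM = sigma2_A / 4.0
    # genetic correlations (lower triangle of the published parameter table)
    rA = np.eye(6)
    lower = {
        (1, 0): 0.13, (2, 0): 0.26, (3, 0): -0.72, (4, 0): -0.42, (5, 0): 0.04,
        (2, 1): 0.45, (3, 1): 0.37, (4, 1): -0.26, (5, 1): -0.64,
        (3, 2): -0.09, (4, 2): 0.03, (5, 2): -0.08,
        (4, 3): -0.08, (5, 3): -0.52,
        (5, 4): 0.59,
    }
    for (j, k), r in lower.items():
        rA[j, k] = rA[k, j] = r
    V_M = _nearest_psd(rA * np.sqrt(np.outer(vM, vM)))

    vC = np.array([79075.3, 29488.8, 11370.6, 5.88, 0.03, 0.10])
    V_C = np.diag(vC)

    vE = np.array([482725.8, 179893.3, 82912.9, 35.44, 0.89, 1.32])
    rP = np.eye(6)
    upper = {
        (0, 1): 0.10, (0, 2): 0.11, (0, 3): -0.45, (0, 4): -0.17, (0, 5): 0.11,
        (1, 2): 0.23, (1, 3): -0.01, (1, 4): -0.04, (1, 5): -0.29,
        (2, 3): -0.01, (2, 4): 0.01, (2, 5): -0.05,
        (3, 4): 0.19, (3, 5): -0.15,
        (4, 5): 0.12,
    }
    for (j, k), r in upper.items():
        rP[j, k] = rP[k, j] = r
    vP = vM + vC + vE
    V_P = rP * np.sqrt(np.outer(vP, vP))
    V_E = _nearest_psd(V_P - V_M - V_C)
    return VarianceComponents(V_M, V_C, V_E, list(TRAITS))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic population, sequencing, and phenotypes.

    Defaults reproduce the magnitudes of the target breeding program; tests
    and demos pass smaller sizes explicitly.  ``tau`` may be a scalar (one
    overdispersion for all markers), a per-marker array, or None to draw
    per-marker values from Beta(1.7, 4.8) (mean 0.26, SD 0.16).
    """

    n_mothers: int = 1764
    n_markers: int = 58816
    n_families: int = 18
    ploidy: int = 6
    freq_beta: tuple[float, float] = (2.6, 0.8)  # reference-allele frequency prior
    true_freq: np.ndarray | None = None          # per-marker override of the prior
    tau: float | np.ndarray | None = None
    depth_mean: float = 37.88
    depth_shape: float = 1.36       # negative-binomial dispersion (r)
    missing_rate: float = 0.0       # extra zero-inflation of total depth
    n_repeat_samples: int = 107     # mothers genotyped a second time
    n_years: int = 23
    trials_per_year: int = 9
    n_locations: int = 4
    progeny_per_mother: int = 3
    records_per_progeny: int = 2
    fixed_effect_scale: float = 0.5  # trial-year effect SD in phenotypic SDs
    V_M: np.ndarray | None = None
    V_C: np.ndarray | None = None
    V_E: np.ndarray | None = None
    trait_names: list[str] = field(default_factory=lambda: list(TRAITS))
    ridge: float = 1e-8             # added to G before factorization if needed
    seed: int = 20250101

    def __post_init__(self) -> None:
        if self.n_families > self.n_mothers:
            raise ValueError("n_families must not exceed n_mothers")
        if self.ploidy % 2:
            raise ValueError("ploidy must be even (gametes carry ploidy/2 alleles)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        defaults = timothy_variance_components() if (
            self.V_M is None or self.V_C is None or self.V_E is None
        ) else None
        if self.V_M is None:
            self.V_M = defaults.V_M
        if self.V_C is None:
            self.V_C = defaults.V_C
        if self.V_E is None:
            self.V_E = defaults.V_E
        self.V_M = _check_psd(np.atleast_2d(self.V_M), "V_M")
        self.V_C = _check_psd(np.atleast_2d(self.V_C), "V_C")
        self.V_E = _check_psd(np.atleast_2d(self.V_E), "V_E")
        T = len(self.trait_names)
        if not (self.V_M.shape == self.V_C.shape == self.V_E.shape == (T, T)):
            raise ValueError("V_M, V_C, V_E must all be T x T for T trait names")
        if self.tau is not None:
            t = np.asarray(self.tau, dtype=float)
            if ((t < 0) | (t >= 1)).any():
                raise ValueError("tau values must lie in [0, 1)")

    def variance_components(self) -> VarianceComponents:
        return VarianceComponents(self.V_M, self.V_C, self.V_E, list(self.trait_names))


@dataclass
class TrueGenotypes:
    """Latent integer dosages with family structure and true frequencies."""

    dosage: np.ndarray              # individuals x markers, integers 0..k
    ploidy: int
    true_freq: np.ndarray           # per-marker frequency in [0, 1]
    family: pd.Series               # individual id -> family label
    marker_tau: np.ndarray          # per-marker overdispersion used for reads

    def __post_init__(self) -> None:
        if ((self.dosage < 0) | (self.dosage > self.ploidy)).any():
            raise ValueError("dosages must lie in [0, ploidy]")
        if ((self.true_freq < 0) | (self.true_freq > 1)).any():
            raise ValueError("true frequencies must lie in [0, 1]")

    @property
    def individual_ids(self) -> list[str]:
        return list(self.family.index)

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]


def simulate_population(config: SimulationConfig) -> TrueGenotypes:
    """Draw hexaploid dosages for mothers grouped into half-sib families.

    Per marker, a true frequency p_j is drawn from the configured Beta
    prior.  Each family shares one simulated parent with dosage
    d_fj ~ Binomial(k, p_j); an individual's dosage is the sum of k/2
    alleles sampled from that parent's allele pool (Binomial(k/2, d_fj/k))
    and k/2 alleles from the population at large (Binomial(k/2, p_j)), so
    half-sibs are more related than non-sibs while the expected dosage
    remains k p_j.
    """
    rng = np.random.default_rng(config.seed)
    k = config.ploidy
    m = config.n_markers
    n = config.n_mothers
    if config.true_freq is not None:
        p = np.broadcast_to(np.asarray(config.true_freq, dtype=float), (m,)).copy()
    else:
        a, b = config.freq_beta
        p = np.clip(rng.beta(a, b, size=m), 0.01, 0.99)

    fam_labels = [f"F{f + 1:03d}" for f in range(config.n_families)]
    fam_of = np.arange(n) % config.n_families
    parent_dosage = rng.binomial(k, p[None, :], size=(config.n_families, m))

    half = k // 2
    from_parent = rng.binomial(half, parent_dosage[fam_of] / k)
    from_pop = rng.binomial(half, p[None, :], size=(n, m))
    dosage = from_parent + from_pop

    ids = [f"M{i + 1:04d}" for i in range(n)]
    family = pd.Series([fam_labels[f] for f in fam_of], index=ids, name="family")

    if config.tau is None:
        tau = rng.beta(1.7, 4.8, size=m)
    else:
        tau = np.broadcast_to(np.asarray(config.tau, dtype=float), (m,)).copy()
    return TrueGenotypes(dosage, k, p, family, tau)


def _beta_binomial_reads(
    rng: np.random.Generator,
    depth: np.ndarray,
    mu: np.ndarray,
    tau: np.ndarray,
) -> np.ndarray:
    """Reference reads R_A | depth with Beta(mu, tau) latent probability.

    tau = 0 collapses to pure Binomial sampling; boundary locations
    (mu exactly 0 or 1) take p = mu without a Beta draw.
    """
    p = np.array(np.broadcast_to(mu, depth.shape), dtype=float)
    tau_b = np.broadcast_to(tau, depth.shape)
    inner = (tau_b > 0) & (p > 0) & (p < 1)
    if inner.any():
        conc = (1.0 - tau_b[inner]) / tau_b[inner]
        p[inner] = rng.beta(p[inner] * conc, (1.0 - p[inner]) * conc)
    return rng.binomial(depth, p)


def simulate_reads(
    genos: TrueGenotypes, config: SimulationConfig
) -> tuple[ReadDepthMatrix, dict[str, str]]:
    """Draw per-sample read counts; returns the depth matrix and sample map.

    Total depth per sample x marker is negative-binomial with the configured
    mean and shape (optionally zero-inflated by ``missing_rate``); zero total
    depth is the definition of a missing genotype.  Given the total depth,
    reference reads are Beta-Binomial with location dosage/k and the
    marker's overdispersion.  The first ``n_repeat_samples`` mothers get a
    second, independently sequenced sample; the returned map sends sample
    IDs to individual IDs.
    """
    rng = np.random.default_rng(config.seed + 1)
    ids = genos.individual_ids
    n_rep = min(config.n_repeat_samples, len(ids))
    sample_ids = [f"{i}_s1" for i in ids] + [f"{i}_s2" for i in ids[:n_rep]]
    sample_map = {s: s.rsplit("_s", 1)[0] for s in sample_ids}
    owner = np.concatenate([np.arange(len(ids)), np.arange(n_rep)])

    r = config.depth_shape
    mean = config.depth_mean
    shape = (len(sample_ids), genos.n_markers)
    depth = rng.negative_binomial(r, r / (r + mean), size=shape)
    if config.missing_rate > 0:
        depth[rng.random(shape) < config.missing_rate] = 0

    mu = genos.dosage[owner] / genos.ploidy
    R_A = _beta_binomial_reads(rng, depth, mu, genos.marker_tau[None, :])
    R_B = depth - R_A
    marker_ids = [f"chr1:{j + 1}:A:T" for j in range(genos.n_markers)]
    return ReadDepthMatrix(R_A, R_B, sample_ids, marker_ids), sample_map


def simulate_phenotypes(
    genos: TrueGenotypes, grm: GRM, config: SimulationConfig
) -> tuple[TraitData, pd.DataFrame]:
    """Generate multi-trait records and the true GEBV used to produce them.

    Mother effects are matrix-normal with row covariance G and column
    covariance V_M; each progeny-within-trial level gets a permanent-
    environment draw from V_C; residuals come from V_E; trial-by-year fixed
    effects are Gaussian with SD ``fixed_effect_scale`` x phenotypic SD.
    If G is not factorizable a small ridge is added (and recorded in the
    config) before the Cholesky.
    """
    if list(grm.individual_ids) != genos.individual_ids:
        raise ValueError("GRM individuals must match the simulated population")
    rng = np.random.default_rng(config.seed + 2)
    n = genos.n_individuals
    T = len(config.trait_names)

    G = grm.G
    try:
        L_G = np.linalg.cholesky(G)
    except np.linalg.LinAlgError:
        ridge = config.ridge * float(np.mean(np.diag(G)) + 1.0)
        L_G = np.linalg.cholesky(G + ridge * np.eye(n))
    L_M = _psd_sqrt(config.V_M)
    M = L_G @ rng.standard_normal((n, T)) @ L_M.T
    true_gebv = pd.DataFrame(M, index=genos.individual_ids, columns=config.trait_names)

    L_C = _psd_sqrt(config.V_C)
    L_E = _psd_sqrt(config.V_E)
    vP = np.sqrt(np.diag(config.V_M) + np.diag(config.V_C) + np.diag(config.V_E))

    years = np.arange(2001, 2001 + config.n_years)
    trials = [f"T{t + 1:02d}" for t in range(config.trials_per_year * config.n_locations)]
    ty_effect: dict[tuple[str, int], np.ndarray] = {}

    rows = []
    rec = 0
    for i, mother in enumerate(genos.individual_ids):
        for pg in range(config.progeny_per_mother):
            progeny = f"{mother}_p{pg + 1}"
            year = int(rng.choice(years))
            trial = trials[int(rng.integers(len(trials)))]
            location = f"L{(trials.index(trial) % config.n_locations) + 1}"
            key = (trial, year)
            if key not in ty_effect:
                ty_effect[key] = rng.standard_normal(T) * config.fixed_effect_scale * vP
            c = L_C @ rng.standard_normal(T)
            for _ in range(config.records_per_progeny):
                e = L_E @ rng.standard_normal(T)
                y = TRAIT_MEANS[: T] if T == len(TRAITS) else np.zeros(T)
                y = y + ty_effect[key] + M[i] + c + e
                rows.append(
                    [f"R{rec + 1:06d}", mother, progeny, trial, year, location, *y]
                )
                rec += 1
    df = pd.DataFrame(
        rows,
        columns=["record", "mother", "progeny", "trial", "year", "location"]
        + list(config.trait_names),
    )
    return TraitData(df, list(config.trait_names)), true_gebv


def _psd_sqrt(mat: np.ndarray) -> np.ndarray:
    """Symmetric square root tolerant of PSD-singular matrices."""
    vals, vecs = np.linalg.eigh(mat)
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def write_vcf(rd: ReadDepthMatrix, path: str | Path) -> None:
    """Write read depths as a minimal biallelic-SNP VCF with per-sample AD."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=chr1>\n")
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(rd.sample_ids)
            + "\n"
        )
        for j, mid in enumerate(rd.marker_ids):
            chrom, pos, ref, alt = mid.split(":")
            cells = [
                f"./.:{rd.R_A[i, j]},{rd.R_B[i, j]}" for i in range(rd.n_samples)
            ]
            fh.write(
                f"{chrom}\t{pos}\t{mid}\t{ref}\t{alt}\t.\tPASS\t.\tGT:AD\t"
                + "\t".join(cells)
                + "\n"
            )


def write_sample_map(sample_map: Mapping[str, str], path: str | Path) -> None:
    """Two-column TSV: sample ID, individual ID."""
    with Path(path).open("w") as fh:
        fh.write("sample\tindividual\n")
        for s, ind in sample_map.items():
            fh.write(f"{s}\t{ind}\n")
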