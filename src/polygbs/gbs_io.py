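"""Read-depth ingestion and continuous genotypes.

Genotypes are represented not as integer allele dosages but as per-individual
reference-allele frequencies estimated directly from sequencing reads:

    f_ij = R_A_ij / (R_A_ij + R_B_ij)

where ``R_A`` and ``R_B`` are the reference and alternate read depths of
individual *i* at biallelic SNP *j*.  An entry is missing when both depths
are zero.  This module reads allelic depths from VCF, forms the continuous
genotype matrix, averages repeated samples of the same individual, applies
the marker filters (minor allele frequency, mean total depth window, call
rate) and mean-imputes missing entries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

__all__ = [
    "ReadDepthMatrix",
    "ContinuousGenotypes",
    "read_vcf_depths",
    "continuous_genotypes",
    "merge_repeated_samples",
    "merge_repeated_depths",
    "filter_markers",
    "impute_missing",
    "write_genotype_matrix",
]


@dataclass
class ReadDepthMatrix:
    """Reference/alternate read counts per sample x marker.

    ``R_T = R_A + R_B`` is derived, never stored independently, so the
    additivity invariant holds by construction.
    """

    R_A: np.ndarray
    R_B: np.ndarray
    sample_ids: list[str]
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.R_A = np.asarray(self.R_A, dtype=np.int64)
        self.R_B = np.asarray(self.R_B, dtype=np.int64)
        if self.R_A.shape != self.R_B.shape:
            raise ValueError("R_A and R_B must have identical shape")
        if (self.R_A < 0).any() or (self.R_B < 0).any():
            raise ValueError("read counts must be non-negative")
        if self.R_A.shape != (len(self.sample_ids), len(self.marker_ids)):
            raise ValueError("count matrix shape does not match ID lists")

    @property
    def R_T(self) -> np.ndarray:
        return self.R_A + self.R_B

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def subset_markers(self, idx: np.ndarray) -> "ReadDepthMatrix":
        return ReadDepthMatrix(
            self.R_A[:, idx],
            self.R_B[:, idx],
            list(self.sample_ids),
            [self.marker_ids[i] for i in np.atleast_1d(idx)],
        )


@dataclass
class ContinuousGenotypes:
    """Allele-frequency genotype matrix with per-marker summaries.

    ``F`` holds the continuous genotypes in [0, 1] with NaN for missing
    (zero total reads).  ``fbar`` and ``call_rate`` are computed over
    observed entries; ``filter_log`` records the ordered marker attrition.
    """

    F: np.ndarray
    sample_ids: list[str]
    marker_ids: list[str]
    filter_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        obs = ~np.isnan(self.F)
        if obs.any() and ((self.F[obs] < 0) | (self.F[obs] > 1)).any():
            raise ValueError("observed genotype frequencies must lie in [0, 1]")

    @property
    def fbar(self) -> np.ndarray:
        """Per-marker mean frequency over observed entries (NaN if none)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.F, axis=0)

    @property
    def call_rate(self) -> np.ndarray:
        return (~np.isnan(self.F)).mean(axis=0)

    @property
    def n_individuals(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def is_complete(self) -> bool:
        return not np.isnan(self.F).any()


def read_vcf_depths(path: str | Path) -> ReadDepthMatrix:
    """Read per-sample allelic depths from a VCF into a ReadDepthMatrix.

    Only biallelic SNP records carrying a per-sample AD format field are
    kept; multi-allelic records and records without depth information are
    skipped with a logged count.  Marker identity is CHROM:POS:REF:ALT
    (1-based coordinates per the VCF standard); sample and record order are
    preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"VCF not found: {path}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ra_cols: list[np.ndarray] = []
    rb_cols: list[np.ndarray] = []
    marker_ids: list[str] = []
    n_multi = 0
    n_nodepth = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        if ad is None or ad.shape[1] < 2:
            n_nodepth += 1
            continue
        ad = np.asarray(ad, dtype=np.int64)
        ad[ad < 0] = 0  # cyvcf2 encodes missing AD as negative sentinels
        ra_cols.append(ad[:, 0])
        rb_cols.append(ad[:, 1])
        marker_ids.append(f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}")
    if n_multi:
        logger.info("skipped %d multi-allelic record(s)", n_multi)
    if n_nodepth:
        logger.info("skipped %d record(s) without AD depth information", n_nodepth)
    if marker_ids:
        R_A = np.column_stack(ra_cols)
        R_B = np.column_stack(rb_cols)
    else:
        R_A = np.zeros((len(samples), 0), dtype=np.int64)
        R_B = np.zeros((len(samples), 0), dtype=np.int64)
    return ReadDepthMatrix(R_A, R_B, samples, marker_ids)


def continuous_genotypes(rd: ReadDepthMatrix) -> ContinuousGenotypes:
    """Form continuous genotypes f = R_A / R_T, missing where R_T = 0."""
    rt = rd.R_T
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(rt > 0, rd.R_A / np.where(rt > 0, rt, 1), np.nan)
    return ContinuousGenotypes(F, list(rd.sample_ids), list(rd.marker_ids))


def _individual_order(sample_map: Mapping[str, str], sample_ids: Sequence[str]) -> list[str]:
    seen: dict[str, None] = {}
    for s in sample_ids:
        seen.setdefault(sample_map[s], None)
    return list(seen)


def merge_repeated_samples(
    cg: ContinuousGenotypes, sample_map: Mapping[str, str]
) -> ContinuousGenotypes:
    """Average replicate samples of the same individual into one row.

    Per marker the merged frequency is the mean over the individual's
    non-missing replicate values; the merged entry is missing only when all
    replicates are missing.  Output rows are in first-appearance order of the
    individuals.
    """
    unmapped = [s for s in cg.sample_ids if s not in sample_map]
    if unmapped:
        raise KeyError(f"samples missing from sample map: {unmapped}")
    individuals = _individual_order(sample_map, cg.sample_ids)
    idx = {ind: i for i, ind in enumerate(individuals)}
    sums = np.zeros((len(individuals), cg.n_markers))
    counts = np.zeros_like(sums)
    obs = ~np.isnan(cg.F)
    for row, s in enumerate(cg.sample_ids):
        i = idx[sample_map[s]]
        sums[i] += np.where(obs[row], cg.F[row], 0.0)
        counts[i] += obs[row]
    with np.errstate(invalid="ignore"):
        merged = np.where(counts > 0, sums / np.where(counts > 0, counts, 1), np.nan)
    return ContinuousGenotypes(
        merged, individuals, list(cg.marker_ids), list(cg.filter_log)
    )


def merge_repeated_depths(
    rd: ReadDepthMatrix, sample_map: Mapping[str, str]
) -> ReadDepthMatrix:
    """Sum replicate read counts per individual.

    The merged counts are the per-individual read support used by the
    Beta-Binomial overdispersion likelihood; frequencies are merged by
    averaging (see :func:`merge_repeated_samples`), counts by summation.
    """
    unmapped = [s for s in rd.sample_ids if s not in sample_map]
    if unmapped:
        raise KeyError(f"samples missing from sample map: {unmapped}")
    individuals = _individual_order(sample_map, rd.sample_ids)
    idx = {ind: i for i, ind in enumerate(individuals)}
    R_A = np.zeros((len(individuals), rd.n_markers), dtype=np.int64)
    R_B = np.zeros_like(R_A)
    for row, s in enumerate(rd.sample_ids):
        i = idx[sample_map[s]]
        R_A[i] += rd.R_A[row]
        R_B[i] += rd.R_B[row]
    return ReadDepthMatrix(R_A, R_B, individuals, list(rd.marker_ids))


def filter_markers(
    cg: ContinuousGenotypes,
    rd: ReadDepthMatrix,
    maf_min: float = 0.05,
    depth_min: float = 10.0,
    depth_max: float = 200.0,
    call_rate_min: float = 0.7,
) -> tuple[ContinuousGenotypes, ReadDepthMatrix]:
    """Apply the conjunctive marker filters: MAF, mean depth window, call rate.

    A marker survives iff min(fbar, 1-fbar) >= maf_min, depth_min <= mean
    R_T <= depth_max, and call rate >= call_rate_min.  Mean depth is averaged
    over individuals with at least one read (non-missing entries).  The
    filter log records sequential attrition in the order MAF, depth, call
    rate, though the surviving set is order-independent.
    """
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must lie in [0, 0.5]")
    if depth_min > depth_max:
        raise ValueError("depth_min must not exceed depth_max")
    if not 0 < call_rate_min <= 1:
        raise ValueError("call_rate_min must lie in (0, 1]")
    if cg.marker_ids != rd.marker_ids or cg.sample_ids != rd.sample_ids:
        raise ValueError("genotypes and read depths must be aligned")

    fbar = cg.fbar
    rt = rd.R_T.astype(float)
    observed = rt > 0
    with np.errstate(invalid="ignore"):
        mean_depth = np.where(
            observed.any(axis=0),
            np.where(observed, rt, np.nan).mean(axis=0, where=observed),
            0.0,
        )
    call = cg.call_rate

    with np.errstate(invalid="ignore"):
        pass_maf = np.minimum(fbar, 1 - fbar) >= maf_min
        pass_depth = (mean_depth >= depth_min) & (mean_depth <= depth_max)
        pass_call = call >= call_rate_min
    pass_maf &= ~np.isnan(fbar)

    keep = pass_maf & pass_depth & pass_call
    log = list(cg.filter_log)
    m0 = cg.n_markers
    log.append(f"input markers: {m0}")
    log.append(f"after MAF >= {maf_min}: {int(pass_maf.sum())}")
    log.append(
        f"after mean depth in [{depth_min}, {depth_max}]: {int((pass_maf & pass_depth).sum())}"
    )
    log.append(f"after call rate >= {call_rate_min}: {int(keep.sum())}")
    if not keep.any():
        table = "\n".join(log)
        raise ValueError(f"all markers removed by filtering:\n{table}")
    idx = np.flatnonzero(keep)
    out = ContinuousGenotypes(
        cg.F[:, idx],
        list(cg.sample_ids),
        [cg.marker_ids[i] for i in idx],
        log,
    )
    return out, rd.subset_markers(idx)


def impute_missing(cg: ContinuousGenotypes) -> ContinuousGenotypes:
    """Replace missing entries by the marker mean of observed entries.

    Imputation preserves per-marker means exactly; observed entries are
    untouched.  Requires every marker to have at least one observed value
    (guaranteed after call-rate filtering).
    """
    obs = ~np.isnan(cg.F)
    empty = ~obs.any(axis=0)
    if empty.any():
        bad = [cg.marker_ids[i] for i in np.flatnonzero(empty)[:10]]
        raise ValueError(f"markers with no observed genotype cannot be imputed: {bad}")
    fbar = cg.fbar
    F = np.where(obs, cg.F, fbar[None, :])
    return ContinuousGenotypes(F, list(cg.sample_ids), list(cg.marker_ids), list(cg.filter_log))


def write_genotype_matrix(cg: ContinuousGenotypes, path: str | Path) -> None:
    """Write the genotype matrix as TSV (individuals x markers)."""
    df = pd.DataFrame(cg.F, index=cg.sample_ids, columns=cg.marker_ids)
    df.to_csv(path, sep="\t", index_label="individual")
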