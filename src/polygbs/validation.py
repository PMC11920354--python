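"""Validation of genomic breeding values.

Two splitting strategies are provided: family cross-validation (leave out
the progeny records of all mothers in one half-sib family) and forward
prediction (leave out the last years of recording).  In both cases the
genomic data of every mother stays in the evaluation; only phenotypic
records are withheld, so validation mothers obtain GEBV purely through
their genomic relationships with recorded mothers.

Accuracy measures: predictive ability (correlation between GEBV and mean
progeny performance adjusted for fixed and permanent-environment effects)
and the Legarra-Reverter statistics comparing a full against a reduced
evaluation over the validation mothers — their GEBV correlation, and the
slope ("dispersion"; < 1 flags over-prediction, > 1 under-prediction) and
coefficient of determination from regressing full-data GEBV on reduced-data
GEBV.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from polygbs.mixed_model import GEBVResult, TraitData

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationSplit",
    "LRStatistics",
    "family_cv_splits",
    "forward_split",
    "adjusted_progeny_means",
    "predictive_ability",
    "lr_statistics",
    "reduced_data",
]


@dataclass
class ValidationSplit:
    """A disjoint estimation/validation partition of the records."""

    strategy: str                      # "family_cv" | "forward"
    estimation_records: list[str]
    validation_records: list[str]
    validation_mothers: list[str]
    label: str                         # family label or cutoff year

    def __post_init__(self) -> None:
        if set(self.estimation_records) & set(self.validation_records):
            raise ValueError("estimation and validation records must be disjoint")

    def to_file(self, path) -> None:
        """Serialize as a two-column TSV of record ID and set membership."""
        rows = [(r, "estimation") for r in self.estimation_records]
        rows += [(r, "validation") for r in self.validation_records]
        df = pd.DataFrame(rows, columns=["record", "set"])
        with open(path, "w") as fh:
            fh.write(f"# strategy={self.strategy}\tlabel={self.label}\n")
            df.to_csv(fh, sep="\t", index=False)


@dataclass
class LRStatistics:
    correlation: float
    slope: float
    r_squared: float
    n_mothers: int

    @property
    def dispersion_label(self) -> str:
        if self.slope < 1.0:
            return "over-prediction"
        if self.slope > 1.0:
            return "under-prediction"
        return "none"


def family_cv_splits(
    data: TraitData,
    mother_families: Mapping[str, str],
    min_family_size: int = 50,
) -> list[ValidationSplit]:
    """One split per half-sib family with at least ``min_family_size`` mothers.

    The validation set of a split is all progeny records of that family's
    mothers.  Splits are ordered by family label.
    """
    mothers = data.df["mother"].astype(str)
    missing = sorted(set(mothers) - set(mother_families))
    if missing:
        raise KeyError(f"mothers without family labels: {missing[:5]}")
    fam = pd.Series(mother_families)
    sizes = fam.value_counts()
    eligible = sorted(sizes.index[sizes >= min_family_size])
    if not eligible:
        raise ValueError(
            f"no family reaches {min_family_size} mothers; sizes:\n{sizes.to_string()}"
        )
    splits = []
    rec = data.df["record"].astype(str)
    for label in eligible:
        fam_mothers = set(fam.index[fam == label])
        in_val = mothers.isin(fam_mothers)
        splits.append(
            ValidationSplit(
                strategy="family_cv",
                estimation_records=list(rec[~in_val]),
                validation_records=list(rec[in_val]),
                validation_mothers=sorted(fam_mothers & set(mothers)),
                label=str(label),
            )
        )
    return splits


def forward_split(data: TraitData, cutoff_year: int) -> ValidationSplit:
    """Records from ``cutoff_year`` on form the validation set.

    ``validation_mothers`` are the mothers having records only in the
    validation period (no records before the cutoff), the set whose GEBV are
    purely genomically predicted in the reduced evaluation.
    """
    years = data.df["year"].astype(int)
    if not (years.min() < cutoff_year <= years.max()):
        raise ValueError(
            f"cutoff {cutoff_year} outside usable range "
            f"({years.min() + 1}..{years.max()})"
        )
    in_val = years >= cutoff_year
    mothers = data.df["mother"].astype(str)
    only_val = sorted(set(mothers[in_val]) - set(mothers[~in_val]))
    rec = data.df["record"].astype(str)
    return ValidationSplit(
        strategy="forward",
        estimation_records=list(rec[~in_val]),
        validation_records=list(rec[in_val]),
        validation_mothers=only_val,
        label=str(cutoff_year),
    )


def reduced_data(data: TraitData, split: ValidationSplit) -> TraitData:
    """The estimation-side records as a TraitData for the reduced evaluation."""
    keep = data.df["record"].astype(str).isin(split.estimation_records)
    return TraitData(data.df.loc[keep].reset_index(drop=True), list(data.trait_names))


def adjusted_progeny_means(
    data: TraitData,
    fit: GEBVResult,
    trait: str,
    records: Sequence[str] | None = None,
) -> pd.Series:
    """Per-mother mean progeny performance adjusted for b and c estimates.

    Each record's phenotype is reduced by its fitted trial-by-year effect
    and its permanent-environment estimate, then averaged within mother.
    Records whose fixed-effect level is absent from the fit are dropped with
    a warning (the level was not estimable in the fit).
    """
    df = data.df
    if records is not None:
        df = df[df["record"].astype(str).isin(set(map(str, records)))]
    df = df[~df[trait].isna()]
    ty = df["trial"].astype(str) + ":" + df["year"].astype(str)
    pt = df["progeny"].astype(str) + ":" + df["trial"].astype(str)

    b = fit.fixed_effects[trait]
    known = ty.isin(b.index)
    if (~known).any():
        logger.warning(
            "%d record(s) dropped: trial-year level absent from the fit",
            int((~known).sum()),
        )
        df, ty, pt = df[known], ty[known], pt[known]
    adj = df[trait].to_numpy(dtype=float) - b.loc[ty].to_numpy()
    c = fit.pe_effects[trait]
    if len(c):
        adj = adj - c.reindex(pt).fillna(0.0).to_numpy()
    return pd.Series(adj, index=df["mother"].astype(str)).groupby(level=0).mean()


def predictive_ability(gebv: pd.Series, adjusted_means: pd.Series) -> float:
    """Correlation between GEBV and adjusted progeny means over mothers."""
    common = gebv.index.intersection(adjusted_means.index)
    if len(common) < 3:
        raise ValueError("predictive ability needs at least 3 mothers with both values")
    x = gebv.loc[common].to_numpy(dtype=float)
    y = adjusted_means.loc[common].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        return math.nan  # undefined: zero variance on one side
    return float(np.corrcoef(x, y)[0, 1])


def lr_statistics(
    gebv_full: pd.Series,
    gebv_reduced: pd.Series,
    validation_mothers: Sequence[str],
) -> LRStatistics:
    """Legarra-Reverter statistics over the validation mothers.

    Correlation between the two GEBV sets, plus ordinary-least-squares slope
    and R^2 of full regressed on reduced.
    """
    idx = pd.Index(map(str, validation_mothers))
    missing = idx.difference(gebv_full.index).union(idx.difference(gebv_reduced.index))
    if len(missing):
        raise KeyError(f"validation mothers missing from an evaluation: {list(missing)[:5]}")
    f = gebv_full.loc[idx].to_numpy(dtype=float)
    r = gebv_reduced.loc[idx].to_numpy(dtype=float)
    if np.array_equal(f, r) and r.std() > 0:
        return LRStatistics(1.0, 1.0, 1.0, len(idx))
    if r.std() == 0:
        return LRStatistics(math.nan, math.nan, math.nan, len(idx))
    slope = float(np.cov(f, r, ddof=1)[0, 1] / np.var(r, ddof=1))
    if f.std() == 0:
        return LRStatistics(math.nan, slope, math.nan, len(idx))
    corr = float(np.corrcoef(f, r)[0, 1])
    return LRStatistics(corr, slope, corr ** 2, len(idx))
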