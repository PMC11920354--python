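"""Single- and multi-trait GBLUP with permanent-environment effects.

The model for stacked trait records is

    y = X b + Z_m m + Z_c c + e

with b the trial-by-year fixed effects (one cell mean per level and trait),
m ~ N(0, V_M (x) G) the genetic effects of the mother clones (GEBV),
c ~ N(0, V_C (x) I) the permanent-environment effects of progeny within
trial, and e ~ N(0, R) the residual, where R couples traits measured on the
same record through V_E.  G is a genomic relationship matrix; V_M, V_C and
V_E are trait-by-trait covariance matrices.  Genotyped mothers without
records obtain GEBV through their genomic relationships with recorded
mothers.  Variance components are estimated by deterministic EM-REML using
the exact conditional expectations from the inverted mixed-model-equation
coefficient matrix.

The mother variance refers to half-sib family means, so the additive
variance on the progeny scale is four times the mother variance; the
conversion lives in :mod:`polygbs.genetic_params`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import sparse

from polygbs.grm import GRM

logger = logging.getLogger(__name__)

__all__ = [
    "TraitData",
    "VarianceComponents",
    "GEBVResult",
    "solve_gblup",
    "em_reml",
    "reml_standard_errors",
    "write_variance_components",
    "read_variance_components",
]

#: columns every phenotype table must carry besides the trait columns
ID_COLUMNS = ["record", "mother", "progeny", "trial", "year", "location"]


@dataclass
class TraitData:
    """Phenotype records with their pedigree/trial structure.

    ``df`` has one row per performance record with the identifier columns in
    :data:`ID_COLUMNS` plus one column per trait (NaN = trait not recorded).
    Derived factors: ``trial_year`` (fixed-effect level) and
    ``progeny_trial`` (permanent-environment level).
    """

    df: pd.DataFrame
    trait_names: list[str]

    def __post_init__(self) -> None:
        missing = [c for c in ID_COLUMNS + self.trait_names if c not in self.df.columns]
        if missing:
            raise ValueError(f"phenotype table lacks columns: {missing}")

    @property
    def trial_year(self) -> pd.Series:
        return self.df["trial"].astype(str) + ":" + self.df["year"].astype(str)

    @property
    def progeny_trial(self) -> pd.Series:
        return self.df["progeny"].astype(str) + ":" + self.df["trial"].astype(str)

    @property
    def n_records(self) -> int:
        return len(self.df)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_csv(cls, path: str | Path, trait_names: Sequence[str]) -> "TraitData":
        return cls(pd.read_csv(path, sep="\t"), list(trait_names))


def _check_psd(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    ev = np.linalg.eigvalsh(mat)
    if ev.min() < -1e-8 * max(1.0, abs(ev).max()):
        raise ValueError(f"{name} is not positive semi-definite (min eigenvalue {ev.min():.3g})")
    return mat


@dataclass
class VarianceComponents:
    """Trait-by-trait mother, permanent-environment and residual covariances."""

    V_M: np.ndarray
    V_C: np.ndarray
    V_E: np.ndarray
    trait_names: list[str]

    def __post_init__(self) -> None:
        T = len(self.trait_names)
        self.V_M = _check_psd(self.V_M, "V_M")
        self.V_C = _check_psd(self.V_C, "V_C")
        self.V_E = _check_psd(self.V_E, "V_E")
        for name, m in (("V_M", self.V_M), ("V_C", self.V_C), ("V_E", self.V_E)):
            if m.shape != (T, T):
                raise ValueError(f"{name} must be {T}x{T} to match trait labels")

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def subset(self, traits: Sequence[str]) -> "VarianceComponents":
        """Sub-covariances for a trait subset (diagonal blocks for one trait)."""
        idx = [self.trait_names.index(t) for t in traits]
        sub = np.ix_(idx, idx)
        return VarianceComponents(
            self.V_M[sub], self.V_C[sub], self.V_E[sub], list(traits)
        )


@dataclass
class GEBVResult:
    """Solutions of the mixed-model equations.

    ``gebv`` holds one row per genotyped mother (including record-free
    mothers) and one column per fitted trait.  ``fixed_effects`` and
    ``pe_effects`` map each trait to a Series of estimates indexed by
    trial-year and progeny-within-trial level, respectively.
    """

    gebv: pd.DataFrame
    fixed_effects: dict[str, pd.Series]
    pe_effects: dict[str, pd.Series]
    mode: str
    vc: VarianceComponents

    def to_csv(self, path: str | Path) -> None:
        long = self.gebv.stack().rename("gebv").reset_index()
        long.columns = ["mother", "trait", "gebv"]
        long["model"] = self.mode
        long.to_csv(path, sep="\t", index=False)


_ridge_warned: set[str] = set()


def _inv_psd(mat: np.ndarray, name: str, ridge: float = 1e-6) -> tuple[np.ndarray, float]:
    """Inverse of a PD matrix, adding a logged ridge if ill-conditioned.

    A rank-deficient matrix can pass the Cholesky through roundoff alone
    (e.g. a centered relationship matrix, singular by construction), so
    near-zero pivots trigger the ridge as well as outright failure.
    """
    try:
        L = np.linalg.cholesky(mat)
        d = np.diag(L)
        if d.min() < 1e-6 * d.max():
            raise np.linalg.LinAlgError("near-singular")
    except np.linalg.LinAlgError:
        scale = ridge * float(np.mean(np.diag(mat)))
        if name not in _ridge_warned:
            logger.warning(
                "%s singular or near-singular; adding ridge %.3g to its diagonal "
                "(warning shown once per matrix name)",
                name, scale,
            )
            _ridge_warned.add(name)
        L = np.linalg.cholesky(mat + scale * np.eye(mat.shape[0]))
    Linv = np.linalg.inv(L)
    inv = Linv.T @ Linv
    logdet = 2.0 * float(np.log(np.diag(L)).sum())
    return inv, logdet


@dataclass
class _MME:
    """Assembled mixed-model equations and the bookkeeping to read solutions."""

    C: np.ndarray            # coefficient matrix
    rhs: np.ndarray
    W: sparse.csr_matrix     # [X Z_m Z_c] over stacked observations
    Rinv: sparse.csr_matrix
    y: np.ndarray
    obs_trait: np.ndarray    # trait index (within subset) of each observation
    obs_record: np.ndarray   # record row of each observation
    traits: list[str]
    fixed_levels: dict[str, list[str]]
    pe_levels: list[str]
    mothers: list[str]
    n_fixed: int
    Ginv: np.ndarray
    logdet_G: float
    logdet_R: float
    has_pe: bool

    @property
    def n_mothers(self) -> int:
        return len(self.mothers)


def _assemble(
    data: TraitData,
    grm: GRM,
    vc: VarianceComponents,
    traits: Sequence[str],
    require_complete: bool = False,
) -> _MME:
    T = len(traits)
    vcs = vc.subset(traits) if vcs_needed(vc, traits) else vc
    df = data.df
    tn = list(traits)

    mothers = list(grm.individual_ids)
    unknown = set(df["mother"].astype(str)) - set(mothers)
    if unknown:
        raise ValueError(
            f"records reference ungenotyped mothers (first few): {sorted(unknown)[:5]}"
        )

    Y = df[tn].to_numpy(dtype=float)
    obs_mask = ~np.isnan(Y)
    if require_complete:
        complete = obs_mask.all(axis=1)
        if not complete.all():
            logger.warning(
                "EM-REML drops %d record(s) incomplete for traits %s",
                int((~complete).sum()), tn,
            )
        df = df.loc[complete].reset_index(drop=True)
        Y = Y[complete]
        obs_mask = ~np.isnan(Y)
    if obs_mask.sum() == 0:
        raise ValueError(f"no observations for traits {tn}")

    trial_year = (df["trial"].astype(str) + ":" + df["year"].astype(str)).to_numpy()
    progeny_trial = (df["progeny"].astype(str) + ":" + df["trial"].astype(str)).to_numpy()
    mother = df["mother"].astype(str).to_numpy()
    m_index = {m: i for i, m in enumerate(mothers)}

    V_E = vcs.V_E
    has_pe = bool(np.any(np.diag(vcs.V_C) > 0))
    zero_vm = not np.any(np.diag(vcs.V_M) > 0)

    # per-trait fixed-effect levels (cell means per trial-year; a level with
    # no records for a trait simply gets no equation)
    fixed_levels: dict[str, list[str]] = {}
    for t_i, t in enumerate(tn):
        lv = sorted(set(trial_year[obs_mask[:, t_i]]))
        fixed_levels[t] = lv
    n_fixed_per = [len(fixed_levels[t]) for t in tn]
    fixed_offset = np.concatenate([[0], np.cumsum(n_fixed_per)])
    n_fixed = int(fixed_offset[-1])

    pe_levels = sorted(set(progeny_trial)) if has_pe else []
    n_m = len(mothers)
    n_pe = len(pe_levels)
    pe_index = {p: i for i, p in enumerate(pe_levels)}
    p_total = n_fixed + T * n_m + T * n_pe

    # stacked observations: record-major is irrelevant; build trait-major lists
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    y_list: list[float] = []
    obs_trait: list[int] = []
    obs_record: list[int] = []
    obs_id = 0
    fixed_lookup = [
        {lv: fixed_offset[t_i] + j for j, lv in enumerate(fixed_levels[t])}
        for t_i, t in enumerate(tn)
    ]
    for r in range(len(df)):
        for t_i in range(T):
            if not obs_mask[r, t_i]:
                continue
            y_list.append(Y[r, t_i])
            obs_trait.append(t_i)
            obs_record.append(r)
            rows.append(obs_id); cols.append(fixed_lookup[t_i][trial_year[r]]); vals.append(1.0)
            rows.append(obs_id); cols.append(n_fixed + t_i * n_m + m_index[mother[r]]); vals.append(1.0)
            if has_pe:
                rows.append(obs_id)
                cols.append(n_fixed + T * n_m + t_i * n_pe + pe_index[progeny_trial[r]])
                vals.append(1.0)
            obs_id += 1
    n_obs = obs_id
    W = sparse.coo_matrix((vals, (rows, cols)), shape=(n_obs, p_total)).tocsr()
    y = np.asarray(y_list)
    obs_trait_a = np.asarray(obs_trait)
    obs_record_a = np.asarray(obs_record)

    # residual inverse: block per record over its observed traits
    r_rows: list[int] = []
    r_cols: list[int] = []
    r_vals: list[float] = []
    logdet_R = 0.0
    obs_by_record: dict[int, list[int]] = {}
    for o in range(n_obs):
        obs_by_record.setdefault(int(obs_record_a[o]), []).append(o)
    einv_cache: dict[tuple[int, ...], tuple[np.ndarray, float]] = {}
    for r, olist in obs_by_record.items():
        pattern = tuple(int(obs_trait_a[o]) for o in olist)
        if pattern not in einv_cache:
            sub = V_E[np.ix_(pattern, pattern)]
            inv, ld = _inv_psd(sub, "V_E")
            einv_cache[pattern] = (inv, ld)
        inv, ld = einv_cache[pattern]
        logdet_R += ld
        for a, oa in enumerate(olist):
            for b, ob in enumerate(olist):
                r_rows.append(oa); r_cols.append(ob); r_vals.append(inv[a, b])
    Rinv = sparse.coo_matrix((r_vals, (r_rows, r_cols)), shape=(n_obs, n_obs)).tocsr()

    C = (W.T @ Rinv @ W).toarray()
    rhs = W.T @ (Rinv @ y)

    Ginv, logdet_G = _inv_psd(grm.G, "G")
    if zero_vm:
        # zero genetic variance: pin m at 0 by a huge precision (limit model)
        VMinv = np.eye(T) * 1e12
    else:
        VMinv, _ = _inv_psd(vcs.V_M, "V_M")
    sl_m = slice(n_fixed, n_fixed + T * n_m)
    C[sl_m, sl_m] += np.kron(VMinv, Ginv)
    if has_pe:
        VCinv, _ = _inv_psd(vcs.V_C, "V_C")
        sl_c = slice(n_fixed + T * n_m, p_total)
        C[sl_c, sl_c] += np.kron(VCinv, np.eye(n_pe))

    return _MME(
        C=C, rhs=rhs, W=W, Rinv=Rinv, y=y,
        obs_trait=obs_trait_a, obs_record=obs_record_a,
        traits=tn, fixed_levels=fixed_levels, pe_levels=pe_levels,
        mothers=mothers, n_fixed=n_fixed, Ginv=Ginv,
        logdet_G=logdet_G, logdet_R=logdet_R, has_pe=has_pe,
    )


def vcs_needed(vc: VarianceComponents, traits: Sequence[str]) -> bool:
    return list(traits) != vc.trait_names


def solve_gblup(
    data: TraitData,
    grm: GRM,
    vc: VarianceComponents,
    traits: Sequence[str] | None = None,
) -> GEBVResult:
    """Solve the mixed-model equations for fixed, genetic and PE effects.

    ``traits`` selects the traits to fit jointly; a single-element list fits
    the single-trait model using the corresponding diagonal elements of the
    covariance matrices.  Every genotyped mother receives a GEBV per trait,
    record-free mothers through their genomic relationships.
    """
    tn = list(traits) if traits is not None else list(vc.trait_names)
    bad = [t for t in tn if t not in vc.trait_names]
    if bad:
        raise ValueError(f"traits without variance components: {bad}")
    vcs = vc.subset(tn)
    mme = _assemble(data, grm, vcs, tn)
    sol = np.linalg.solve(mme.C, mme.rhs)
    return _solutions(mme, sol, vcs, "single" if len(tn) == 1 else "multi")


def _solutions(mme: _MME, sol: np.ndarray, vcs: VarianceComponents, mode: str) -> GEBVResult:
    T = len(mme.traits)
    n_m = mme.n_mothers
    n_pe = len(mme.pe_levels)
    fixed: dict[str, pd.Series] = {}
    off = 0
    for t in mme.traits:
        lv = mme.fixed_levels[t]
        fixed[t] = pd.Series(sol[off:off + len(lv)], index=lv, name=t)
        off += len(lv)
    m_block = sol[mme.n_fixed:mme.n_fixed + T * n_m].reshape(T, n_m)
    gebv = pd.DataFrame(m_block.T, index=mme.mothers, columns=mme.traits)
    pe: dict[str, pd.Series] = {}
    if mme.has_pe:
        c_block = sol[mme.n_fixed + T * n_m:].reshape(T, n_pe)
        for t_i, t in enumerate(mme.traits):
            pe[t] = pd.Series(c_block[t_i], index=mme.pe_levels, name=t)
    else:
        for t in mme.traits:
            pe[t] = pd.Series(dtype=float, name=t)
    return GEBVResult(gebv, fixed, pe, mode, vcs)


def _reml_loglik(mme: _MME, vcs: VarianceComponents, sol: np.ndarray) -> float:
    """Restricted log-likelihood (constants omitted consistently)."""
    T = len(mme.traits)
    n_m = mme.n_mothers
    sign, logdet_C = np.linalg.slogdet(mme.C)
    if sign <= 0:
        return -np.inf
    _, ld_VM = _inv_psd(vcs.V_M, "V_M")
    ld_G_part = n_m * ld_VM + T * mme.logdet_G
    ld_c = 0.0
    if mme.has_pe:
        _, ld_VC = _inv_psd(vcs.V_C, "V_C")
        ld_c = len(mme.pe_levels) * ld_VC
    yPy = float(mme.y @ (mme.Rinv @ mme.y) - sol @ mme.rhs)
    return -0.5 * (mme.logdet_R + ld_G_part + ld_c + logdet_C + yPy)


def em_reml(
    data: TraitData,
    grm: GRM,
    init: VarianceComponents,
    tol: float = 1e-6,
    max_iter: int = 200,
    traits: Sequence[str] | None = None,
) -> tuple[VarianceComponents, pd.DataFrame]:
    """Deterministic EM-REML for V_M, V_C and V_E.

    Each round solves the mixed-model equations at the current components
    and updates them from the exact conditional expectations (quadratic
    forms of the solutions plus trace terms from the inverted coefficient
    matrix).  Iteration stops when the maximum relative round-to-round
    change drops below ``tol`` or after ``max_iter`` rounds.  The restricted
    likelihood is non-decreasing across rounds; it is recorded per round in
    the returned trajectory.

    Multi-trait estimation uses records complete for the selected traits
    (incomplete records are dropped with a warning).  V_C and V_E are only
    separable when some progeny-within-trial levels carry repeated records.
    """
    tn = list(traits) if traits is not None else list(init.trait_names)
    vcs = init.subset(tn)
    T = len(tn)
    if not np.all(np.diag(vcs.V_M) > 0) or not np.all(np.diag(vcs.V_E) > 0):
        raise ValueError("initial V_M and V_E must have positive diagonals")
    fit_pe = bool(np.all(np.diag(vcs.V_C) > 0))

    # identifiability: V_C needs repeated records per progeny-trial level
    pt = data.progeny_trial
    if fit_pe and pt.value_counts().max() < 2:
        logger.warning(
            "no progeny-within-trial level has repeated records; "
            "V_C and V_E are confounded"
        )

    traj: list[dict[str, float]] = []
    for it in range(max_iter):
        mme = _assemble(data, grm, vcs, tn, require_complete=True)
        Cinv = np.linalg.inv(mme.C)
        sol = Cinv @ mme.rhs
        ll = _reml_loglik(mme, vcs, sol)

        n_m = mme.n_mothers
        n_pe = len(mme.pe_levels)
        m_hat = sol[mme.n_fixed:mme.n_fixed + T * n_m].reshape(T, n_m)

        VM_new = np.empty((T, T))
        for j in range(T):
            for k in range(j, T):
                blk = Cinv[
                    mme.n_fixed + j * n_m: mme.n_fixed + (j + 1) * n_m,
                    mme.n_fixed + k * n_m: mme.n_fixed + (k + 1) * n_m,
                ]
                VM_new[j, k] = VM_new[k, j] = (
                    m_hat[j] @ mme.Ginv @ m_hat[k] + np.sum(mme.Ginv * blk.T)
                ) / n_m

        if fit_pe:
            c_off = mme.n_fixed + T * n_m
            c_hat = sol[c_off:].reshape(T, n_pe)
            VC_new = np.empty((T, T))
            for j in range(T):
                for k in range(j, T):
                    blk = Cinv[
                        c_off + j * n_pe: c_off + (j + 1) * n_pe,
                        c_off + k * n_pe: c_off + (k + 1) * n_pe,
                    ]
                    VC_new[j, k] = VC_new[k, j] = (
                        c_hat[j] @ c_hat[k] + np.trace(blk)
                    ) / n_pe
        else:
            VC_new = vcs.V_C

        # residual update from conditional residual moments per record
        e_hat = mme.y - mme.W @ sol
        W_by_trait = [mme.W[mme.obs_trait == t_i] for t_i in range(T)]
        e_by_trait = [e_hat[mme.obs_trait == t_i] for t_i in range(T)]
        n_rec = len(e_by_trait[0])
        VE_new = np.empty((T, T))
        A = [np.asarray(Wt @ Cinv) for Wt in W_by_trait]
        for j in range(T):
            for k in range(j, T):
                quad = float(e_by_trait[j] @ e_by_trait[k])
                trace = float(np.sum(A[j] * W_by_trait[k].toarray()))
                VE_new[j, k] = VE_new[k, j] = (quad + trace) / n_rec

        denom = max(
            np.abs(vcs.V_M).max(), np.abs(vcs.V_C).max() if fit_pe else 0.0,
            np.abs(vcs.V_E).max(), 1e-12,
        )
        delta = max(
            np.abs(VM_new - vcs.V_M).max(),
            np.abs(VC_new - vcs.V_C).max() if fit_pe else 0.0,
            np.abs(VE_new - vcs.V_E).max(),
        ) / denom
        traj.append({"iteration": it, "loglik": ll, "delta": delta})
        vcs = VarianceComponents(VM_new, VC_new, VE_new, tn)
        if delta < tol:
            break
    return vcs, pd.DataFrame(traj)


def reml_standard_errors(*args, **kwargs):
    """Standard errors of REML estimates are not computed by this package."""
    raise NotImplementedError(
        "standard errors of variance components are not computed; "
        "reports show 'NA' for them"
    )


def write_variance_components(vc: VarianceComponents, path: str | Path) -> None:
    payload = {
        "traits": vc.trait_names,
        "V_M": vc.V_M.tolist(),
        "V_C": vc.V_C.tolist(),
        "V_E": vc.V_E.tolist(),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_variance_components(path: str | Path) -> VarianceComponents:
    payload = yaml.safe_load(Path(path).read_text())
    return VarianceComponents(
        np.asarray(payload["V_M"], dtype=float),
        np.asarray(payload["V_C"], dtype=float),
        np.asarray(payload["V_E"], dtype=float),
        list(payload["traits"]),
    )
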