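"""GBLUP solver against a dense GLS oracle, and EM-REML behaviour."""

import numpy as np
import pandas as pd
import pytest

from polygbs import mixed_model as mm
from polygbs.grm import GRM
from polygbs.mixed_model import TraitData, VarianceComponents, em_reml, solve_gblup
from tests.conftest import dense_gblup_oracle, simulated_dataset, single_trait_config
from polygbs import synthetic_data


def toy_data(records, traits=("t",)):
    """records: list of (mother, progeny, trial, year, values...)."""
    rows = []
    for i, (mother, progeny, trial, year, *vals) in enumerate(records):
        rows.append([f"r{i}", mother, progeny, trial, year, "L1", *vals])
    df = pd.DataFrame(
        rows,
        columns=["record", "mother", "progeny", "trial", "year", "location"]
        + list(traits),
    )
    return TraitData(df, list(traits))


def pd_grm(G, ids):
    return GRM(np.asarray(G, dtype=float), 1.0, "naive", 6, list(ids))


def design_matrices(data: TraitData, trait: str, mothers: list[str]):
    """Independent construction of X (trial-year cell means), Zm, Zc."""
    df = data.df[~data.df[trait].isna()]
    ty = (df["trial"].astype(str) + ":" + df["year"].astype(str)).to_numpy()
    pt = (df["progeny"].astype(str) + ":" + df["trial"].astype(str)).to_numpy()
    ty_levels = sorted(set(ty))
    pt_levels = sorted(set(pt))
    X = (ty[:, None] == np.array(ty_levels)[None, :]).astype(float)
    Zm = (
        df["mother"].astype(str).to_numpy()[:, None] == np.array(mothers)[None, :]
    ).astype(float)
    Zc = (pt[:, None] == np.array(pt_levels)[None, :]).astype(float)
    return X, Zm, Zc, df[trait].to_numpy(dtype=float)


class TestSolveGblupOracle:
    @pytest.fixture
    def small_problem(self, rng):
        n = 12
        mothers = [f"M{i}" for i in range(n)]
        A = rng.random((n, n))
        G = 0.9 * ((A @ A.T) / n) + 0.4 * np.eye(n)  # safely PD, no ridge path
        records = []
        for i, mother in enumerate(mothers[:-2]):  # last two mothers record-free
            for p in range(2):
                trial = f"T{p % 2}"
                for _ in range(2):
                    records.append(
                        (mother, f"{mother}p{p}", trial, 2001 + (i % 3),
                         float(rng.normal(10 + i, 2)))
                    )
        data = toy_data(records)
        vc = VarianceComponents(
            np.array([[4.0]]), np.array([[2.0]]), np.array([[6.0]]), ["t"]
        )
        return data, pd_grm(G, mothers), vc

    def test_matches_dense_gls_single_trait(self, small_problem):
        data, grm, vc = small_problem
        fit = solve_gblup(data, grm, vc, traits=["t"])
        X, Zm, Zc, y = design_matrices(data, "t", grm.individual_ids)
        b, m, c = dense_gblup_oracle(
            X, Zm, y,
            Sigma_m=vc.V_M[0, 0] * grm.G,
            R=vc.V_E[0, 0] * np.eye(len(y)),
            Zc=Zc, Sigma_c=vc.V_C[0, 0] * np.eye(Zc.shape[1]),
        )
        np.testing.assert_allclose(fit.gebv["t"].to_numpy(), m, atol=1e-8)

    def test_record_free_mothers_predicted_through_g(self, small_problem):
        data, grm, vc = small_problem
        fit = solve_gblup(data, grm, vc, traits=["t"])
        # the two record-free mothers must get the G-regression of the
        # recorded mothers' information, generally nonzero
        free = fit.gebv["t"].iloc[-2:]
        assert (free != 0).all()
        X, Zm, Zc, y = design_matrices(data, "t", grm.individual_ids)
        _, m, _ = dense_gblup_oracle(
            X, Zm, y, vc.V_M[0, 0] * grm.G, vc.V_E[0, 0] * np.eye(len(y)),
            Zc, vc.V_C[0, 0] * np.eye(Zc.shape[1]),
        )
        np.testing.assert_allclose(free.to_numpy(), m[-2:], atol=1e-8)

    def test_matches_dense_gls_multi_trait(self, rng):
        n = 8
        mothers = [f"M{i}" for i in range(n)]
        A = rng.random((n, n))
        G = 0.9 * (A @ A.T) / n + 0.4 * np.eye(n)
        records = []
        for i, mother in enumerate(mothers):
            records.append((mother, f"{mother}p", "T1", 2001,
                            float(rng.normal(0, 2)), float(rng.normal(0, 3))))
            records.append((mother, f"{mother}p", "T1", 2002,
                            float(rng.normal(0, 2)), float(rng.normal(0, 3))))
        data = toy_data(records, traits=("a", "b"))
        VM = np.array([[3.0, 1.0], [1.0, 2.0]])
        VC = np.array([[1.0, 0.2], [0.2, 1.5]])
        VE = np.array([[4.0, -0.5], [-0.5, 5.0]])
        vc = VarianceComponents(VM, VC, VE, ["a", "b"])
        fit = solve_gblup(data, grm_ := pd_grm(G, mothers), vc)

        # dense oracle on the trait-stacked system with R = I (x) VE permuted
        # to trait-major observation order
        Xa, Zma, Zca, ya = design_matrices(data, "a", mothers)
        Xb, Zmb, Zcb, yb = design_matrices(data, "b", mothers)
        nobs = len(ya)
        X = np.block([
            [Xa, np.zeros((nobs, Xb.shape[1]))],
            [np.zeros((nobs, Xa.shape[1])), Xb],
        ])
        Zm = np.block([
            [Zma, np.zeros((nobs, n))], [np.zeros((nobs, n)), Zmb],
        ])
        npe = Zca.shape[1]
        Zc = np.block([
            [Zca, np.zeros((nobs, npe))], [np.zeros((nobs, npe)), Zcb],
        ])
        y = np.concatenate([ya, yb])
        R = np.zeros((2 * nobs, 2 * nobs))
        for r in range(nobs):  # records align across traits here
            for ti in range(2):
                for tj in range(2):
                    R[ti * nobs + r, tj * nobs + r] = VE[ti, tj]
        _, m, _ = dense_gblup_oracle(
            X, Zm, y, np.kron(VM, grm_.G), R, Zc, np.kron(VC, np.eye(npe))
        )
        np.testing.assert_allclose(fit.gebv["a"].to_numpy(), m[:n], atol=1e-8)
        np.testing.assert_allclose(fit.gebv["b"].to_numpy(), m[n:], atol=1e-8)

    def test_zero_genetic_variance_gives_zero_gebv(self, small_problem):
        data, grm, _ = small_problem
        vc = VarianceComponents(
            np.zeros((1, 1)), np.array([[2.0]]), np.array([[6.0]]), ["t"]
        )
        fit = solve_gblup(data, grm, vc, traits=["t"])
        np.testing.assert_allclose(fit.gebv["t"].to_numpy(), 0.0, atol=1e-6)

    def test_scaling_invariance(self, small_problem):
        data, grm, vc = small_problem
        fit1 = solve_gblup(data, grm, vc, traits=["t"])
        k = 7.3
        grm2 = pd_grm(grm.G * k, grm.individual_ids)
        vc2 = VarianceComponents(vc.V_M / k, vc.V_C, vc.V_E, ["t"])
        fit2 = solve_gblup(data, grm2, vc2, traits=["t"])
        np.testing.assert_allclose(
            fit1.gebv["t"].to_numpy(), fit2.gebv["t"].to_numpy(), atol=1e-9
        )

    def test_single_equals_multi_with_zero_covariances(self, rng):
        n = 10
        mothers = [f"M{i}" for i in range(n)]
        A = rng.random((n, n))
        G = 0.9 * (A @ A.T) / n + 0.4 * np.eye(n)
        records = []
        for i, mother in enumerate(mothers):
            for rep in range(2):
                records.append((mother, f"{mother}p", "T1", 2001 + rep,
                                float(rng.normal(0, 2)), float(rng.normal(5, 3))))
        data = toy_data(records, traits=("a", "b"))
        vc = VarianceComponents(
            np.diag([3.0, 2.0]), np.diag([1.0, 1.5]), np.diag([4.0, 5.0]), ["a", "b"]
        )
        grm = pd_grm(G, mothers)
        multi = solve_gblup(data, grm, vc)
        single_a = solve_gblup(data, grm, vc, traits=["a"])
        np.testing.assert_allclose(
            multi.gebv["a"].to_numpy(), single_a.gebv["a"].to_numpy(), atol=1e-8
        )

    def test_missing_trait_records_handled(self, rng):
        n = 6
        mothers = [f"M{i}" for i in range(n)]
        G = np.eye(n)
        records = []
        for i, mother in enumerate(mothers):
            a = float(rng.normal(0, 2))
            b = float(rng.normal(0, 2)) if i % 2 == 0 else np.nan
            records.append((mother, f"{mother}p", "T1", 2001, a, b))
            records.append((mother, f"{mother}p", "T1", 2002, a + 1, np.nan))
        data = toy_data(records, traits=("a", "b"))
        vc = VarianceComponents(
            np.array([[2.0, 0.5], [0.5, 2.0]]),
            np.diag([1.0, 1.0]), np.diag([3.0, 3.0]), ["a", "b"],
        )
        fit = solve_gblup(data, pd_grm(G, mothers), vc)
        assert np.isfinite(fit.gebv.to_numpy()).all()

    def test_ungenotyped_mother_fatal(self, small_problem):
        data, grm, vc = small_problem
        df = data.df.copy()
        df.loc[0, "mother"] = "STRANGER"
        with pytest.raises(ValueError, match="ungenotyped"):
            solve_gblup(TraitData(df, ["t"]), grm, vc, traits=["t"])


class TestEmReml:
    def test_likelihood_monotone_and_fixed_point_near_truth(self):
        config, grm, data, _ = simulated_dataset(42, n_mothers=120)
        truth = config.variance_components()
        vc, traj = em_reml(data, grm, truth, tol=0.0, max_iter=8)
        ll = traj["loglik"].to_numpy()
        assert (np.diff(ll) >= -1e-6 * np.abs(ll[:-1])).all()
        # initialized at the generating values, the first EM steps move little
        assert traj["delta"].iloc[0] < 0.25
        assert traj["delta"].iloc[7] <= traj["delta"].iloc[0]

    def test_confounded_pe_warning(self, caplog):
        records = [(f"M{i}", f"P{i}", "T1", 2001, float(i)) for i in range(6)]
        data = toy_data(records)
        grm = pd_grm(np.eye(6) * 1.2, [f"M{i}" for i in range(6)])
        init = VarianceComponents(
            np.array([[1.0]]), np.array([[1.0]]), np.array([[1.0]]), ["t"]
        )
        import logging
        with caplog.at_level(logging.WARNING, logger="polygbs.mixed_model"):
            em_reml(data, grm, init, tol=0.0, max_iter=2)
        assert any("confounded" in r.message for r in caplog.records)

    def test_standard_errors_refuse_explicitly(self):
        with pytest.raises(NotImplementedError, match="not computed"):
            mm.reml_standard_errors()


def test_variance_components_file_roundtrip(tmp_path):
    vc = VarianceComponents(
        np.array([[2.0, 0.1], [0.1, 3.0]]), np.diag([1.0, 1.0]),
        np.diag([4.0, 5.0]), ["a", "b"],
    )
    mm.write_variance_components(vc, tmp_path / "vc.yaml")
    back = mm.read_variance_components(tmp_path / "vc.yaml")
    np.testing.assert_allclose(back.V_M, vc.V_M)
    assert back.trait_names == ["a", "b"]
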