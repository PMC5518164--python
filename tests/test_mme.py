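import numpy as np
import pytest
import scipy.sparse as sp

from gcmtblup.genecov import GeneTraitCovariance
from gcmtblup.mme import (
    MixedModelSystem,
    RecordSet,
    ResidualSpec,
    animal_model_blup,
    build_mme,
    solve_mme,
    write_solutions,
)
from gcmtblup.pedigree import Pedigree

from conftest import random_pedigree

# printed worked-example values (truncated at two decimals in the source)
RHS_EXPECTED = np.array(
    [35.79, 3000, 0, 1000, 15.79, 0, 7.37, 0, 0, 2000, 12.63, 0]
)
SOLUTION_EXPECTED = np.array(
    [11.42, 1.05, -0.06, -0.05, 0.06, 0.05, -0.11, -0.25, 0.21, 0.94, -0.22, -1.05]
)


class TestRecordSet:
    def test_contents_must_be_counts(self):
        with pytest.raises(ValueError, match="counts"):
            RecordSet(y=np.array([1.0]), z=np.array([0.5]))

    def test_contents_sum_bound(self):
        with pytest.raises(ValueError, match="sum"):
            RecordSet(y=np.array([1.0]), z=np.array([[2.0, 1.0]]))


class TestWorkedExample:
    def test_rhs_matches_printed_vector(self, table1):
        ped, rec, g0, resid = table1
        sys_ = build_mme(ped, rec, g0, resid)
        assert np.abs(sys_.rhs - RHS_EXPECTED).max() < 0.01

    def test_lhs_entries_match_printed_values(self, table1):
        ped, rec, g0, resid = table1
        L = build_mme(ped, rec, g0, resid).lhs.toarray()
        assert abs(L[0, 0] - 3.15) < 0.01  # 3 / 0.95
        assert abs(L[1, 1] - 3000) < 0.01
        assert abs(L[2, 2] - 96.89) < 0.011
        assert abs(L[2, 3] - (-21.31)) < 0.011
        assert abs(L[3, 3] - 1009.68) < 0.011
        assert abs(L[5, 5] - 9.68) < 0.011
        assert np.abs(L - L.T).max() < 1e-12  # symmetric despite the typo row

    def test_solutions_match_printed_vector(self, table1):
        ped, rec, g0, resid = table1
        sys_ = build_mme(ped, rec, g0, resid)
        x, diag = solve_mme(sys_)
        assert diag["relative_residual"] < 1e-10
        assert np.abs(x - SOLUTION_EXPECTED).max() < 0.01

    def test_all_observations_missing_leaves_zero_rhs(self, table1):
        ped, _, g0, resid = table1
        empty = RecordSet(y=np.full(5, np.nan), z=np.full(5, np.nan))
        sys_ = build_mme(ped, empty, g0, resid)
        assert np.all(sys_.rhs == 0)
        # LHS reduces to Ainv (x) G0inv (zero data blocks)
        from gcmtblup.pedigree import additive_relationship_inverse

        ainv = additive_relationship_inverse(ped).toarray()
        g0inv = np.linalg.inv(g0.matrix)
        assert np.abs(
            sys_.lhs.toarray()[2:, 2:] - np.kron(ainv, g0inv)
        ).max() < 1e-10


class TestSolver:
    def test_identity_system(self):
        sys_ = MixedModelSystem(
            sp.eye(4, format="csc"), np.arange(4.0), 0, 1, 4, np.array([0])
        )
        x, _ = solve_mme(sys_)
        assert x == pytest.approx(np.arange(4.0))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_pcg_matches_direct(self, seed):
        rng = np.random.default_rng(seed)
        n = 400
        B = sp.random(n, n, density=0.01, random_state=rng)
        A = (B @ B.T + sp.eye(n) * 5).tocsc()
        b = rng.normal(size=n)
        sys_ = MixedModelSystem(A, b, 0, 1, n, np.array([0]))
        xd, _ = solve_mme(sys_, "direct")
        xp, diag = solve_mme(sys_, "pcg", tol=1e-10)
        assert diag["iterations"] > 0
        assert np.abs(xd - xp).max() < 1e-8

    def test_pcg_nonconvergence_reports_history(self, table1):
        ped, rec, g0, resid = table1
        sys_ = build_mme(ped, rec, g0, resid)
        with pytest.raises(RuntimeError, match="residual"):
            solve_mme(sys_, "pcg", tol=1e-14, max_iter=2)


class TestInvariances:
    def test_unrelated_recordless_animal_changes_nothing(self, table1):
        ped, rec, g0, resid = table1
        x0, _ = solve_mme(build_mme(ped, rec, g0, resid))
        ped2 = Pedigree.from_parents(
            [1, 2, 3, 4, 5, 6], [0, 0, 1, 1, 1, 0], [0, 0, 2, 2, 2, 0]
        )
        rec2 = RecordSet(
            y=np.append(rec.y, np.nan), z=np.append(rec.z[:, 0], np.nan)
        )
        x1, _ = solve_mme(build_mme(ped2, rec2, g0, resid))
        assert np.abs(x1[: x0.size] - x0).max() < 1e-8

    def test_record_order_is_irrelevant(self, rng):
        # records are keyed by animal, so permuting input rows of the
        # pedigree file (handled upstream) cannot change solutions;
        # here: two equivalent record sets built in different order
        ped = random_pedigree(rng, n_founders=8, n_generations=2,
                              per_generation=12)
        n = ped.n
        y = np.where(rng.random(n) < 0.5, rng.normal(size=n), np.nan)
        z = np.where(rng.random(n) < 0.5, rng.integers(0, 3, n), np.nan)
        g0 = GeneTraitCovariance([[0.6, 0.1], [0.1, 0.4]])
        resid = ResidualSpec(0.7)
        x0, _ = solve_mme(build_mme(ped, RecordSet(y, z), g0, resid))
        x1, _ = solve_mme(build_mme(ped, RecordSet(y.copy(), z.copy()), g0, resid))
        assert np.abs(x0 - x1).max() == 0

    def test_tiny_content_residual_pins_observed_genotypes(self, table1):
        ped, rec, g0, _ = table1
        sys_ = build_mme(ped, rec, g0, ResidualSpec(0.95, 1e-6))
        x, _ = solve_mme(sys_)
        bz = x[1]
        obs = [0, 3, 4]
        zhat = np.array([bz + x[2 + 2 * i + 1] for i in obs])
        assert np.abs(zhat - np.array([1.0, 2.0, 0.0])).max() < 1e-3


class TestAnimalModel:
    def test_mean_only_blup_on_observed_data(self, rng):
        ped = random_pedigree(rng, n_founders=10, n_generations=2,
                              per_generation=20)
        y = rng.normal(size=ped.n)
        b, u, cinv = animal_model_blup(ped, y, 0.4, 0.6)
        assert b.shape == (1,) and u.shape == (ped.n,)
        assert cinv.shape == (1, 1) and cinv[0, 0] > 0

    def test_constant_covariate_rejected(self, rng):
        ped = random_pedigree(rng, n_founders=6, n_generations=1,
                              per_generation=6)
        y = rng.normal(size=ped.n)
        with pytest.raises(np.linalg.LinAlgError, match="inestimable"):
            animal_model_blup(ped, y, 0.4, 0.6, covariates=np.zeros(ped.n))


def test_solutions_writer_roundtrip(tmp_path, table1):
    import pandas as pd

    ped, rec, g0, resid = table1
    sys_ = build_mme(ped, rec, g0, resid)
    x, _ = solve_mme(sys_)
    out = tmp_path / "sol.txt"
    write_solutions(out, ped, sys_, x)
    df = pd.read_csv(out, sep=" ")
    assert len(df) == 12
    assert df["estimate"].to_numpy() == pytest.approx(x)
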