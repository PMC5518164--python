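"""Multi-trait Henderson mixed-model equations for trait + gene content.

The model has one quantitative trait y and m gene-content pseudo-traits
z (m = 1 for a biallelic gene), each with a general mean, optional
extra categorical fixed effects for y, and animal effects with
covariance ``G0 (x) A`` (traits ordered within animal).  Residuals are
independent across traits; gene content gets a small nominal residual
variance so the equations stay well posed.

Missing observations simply contribute nothing (row deletion of the
incidence matrices), which is valid because the trait/content residuals
are uncorrelated and missingness is assumed ignorable.

Equation ordering matches the conventional layout: fixed effects first
(trait mean, content mean(s), then extra trait factor levels), then
animals with traits nested within animal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import cg as _cg

from ._spinv import SelectedInverse, factorize_spd
from .genecov import GeneTraitCovariance
from .pedigree import (
    Pedigree,
    RelationshipMatrix,
    additive_relationship_inverse,
    inbreeding_and_mendelian_variance,
)

__all__ = [
    "RecordSet",
    "ResidualSpec",
    "MixedModelSystem",
    "build_mme",
    "solve_mme",
    "MMEWorkspace",
    "animal_model_blup",
    "write_solutions",
]


@dataclass
class ResidualSpec:
    """Residual variances: trait and (nominal, small) gene content."""

    sigma2_ey: float
    sigma2_ez: float = 0.001

    def __post_init__(self):
        if self.sigma2_ey <= 0 or self.sigma2_ez <= 0:
            raise ValueError("residual variances must be positive")


@dataclass
class RecordSet:
    """Per-animal observations aligned with a pedigree's internal order.

    y : (n,) float, NaN = missing trait phenotype.
    z : (n,) or (n, m) float, NaN = missing; observed gene contents are
        counts in {0, 1, 2} and, multiallelic, sum to at most 2 per
        animal.
    fixed_y : optional (n, k) integer level codes of extra categorical
        fixed effects for the trait (the general mean is always fitted).
    """

    y: np.ndarray
    z: np.ndarray
    fixed_y: np.ndarray | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim == 1:
            self.z = self.z[:, None]
        if self.z.shape[0] != self.y.shape[0]:
            raise ValueError("y and z must cover the same animals")
        zobs = self.z[~np.isnan(self.z)]
        if zobs.size and (np.any(zobs < 0) or np.any(zobs > 2)
                          or np.any(zobs != np.round(zobs))):
            raise ValueError("observed gene contents must be counts in {0, 1, 2}")
        with np.errstate(invalid="ignore"):
            sums = np.nansum(self.z, axis=1)
        if np.any(sums > 2 + 1e-9):
            raise ValueError("per-animal gene contents must sum to at most 2")
        if self.fixed_y is not None:
            self.fixed_y = np.atleast_2d(np.asarray(self.fixed_y, dtype=np.int64))
            if self.fixed_y.shape[0] != self.y.shape[0]:
                self.fixed_y = self.fixed_y.T
            if self.fixed_y.shape[0] != self.y.shape[0]:
                raise ValueError("fixed_y must have one row per animal")

    @property
    def n_animals(self) -> int:
        return self.y.shape[0]

    @property
    def n_contents(self) -> int:
        return self.z.shape[1]


@dataclass
class MixedModelSystem:
    """Assembled sparse symmetric MME: ``lhs @ x = rhs``."""

    lhs: sp.csc_matrix
    rhs: np.ndarray
    n_fixed: int
    n_traits: int
    n_animals: int
    mean_eq: np.ndarray  # equation index of each trait's general mean
    fixed_labels: list = field(default_factory=list)

    @property
    def n_equations(self) -> int:
        return self.rhs.shape[0]

    def animal_eq(self, animal, trait) -> np.ndarray:
        """Equation index of animal x trait (traits within animal)."""
        return self.n_fixed + np.asarray(animal) * self.n_traits + trait


def _incidence_columns(records: RecordSet, n_extra_levels):
    """Fixed-effect (column, weight) pairs hit by each animal's y record.

    Extra categorical factors use treatment coding: level 0 is the
    reference absorbed into the general mean (weight 0), levels l >= 1
    get their own equation.
    """
    T = 1 + records.n_contents
    n = records.n_animals
    cols = [(np.zeros(n, dtype=np.int64), np.ones(n))]  # y mean at eq 0
    base = T
    if records.fixed_y is not None:
        for k in range(records.fixed_y.shape[1]):
            if n_extra_levels[k] == 0:  # factor entirely at reference
                continue
            lev = records.fixed_y[:, k]
            cols.append(
                (base + np.maximum(lev - 1, 0), (lev >= 1).astype(float))
            )
            base += n_extra_levels[k]
    return cols


def build_mme(
    ped: Pedigree,
    records: RecordSet,
    g0: GeneTraitCovariance,
    resid: ResidualSpec,
    ainv: RelationshipMatrix | None = None,
) -> MixedModelSystem:
    """Assemble the multi-trait MME (see module docstring for layout)."""
    ws = MMEWorkspace(ped, records, resid.sigma2_ez, ainv=ainv)
    return ws.system(g0, resid.sigma2_ey)


def solve_mme(system: MixedModelSystem, method: str = "direct", tol: float = 1e-10,
              max_iter: int = 10000):
    """Solve the MME; returns ``(x, diagnostics)``.

    ``direct`` uses a sparse symmetric factorization; ``pcg`` runs
    Jacobi-preconditioned conjugate gradients and raises if the relative
    residual does not reach ``tol`` within ``max_iter`` iterations.
    """
    A, b = system.lhs, system.rhs
    bnorm = np.linalg.norm(b)
    if method == "direct":
        factor, _, _ = factorize_spd(A)
        x = factor.solve(b)
        res = np.linalg.norm(A @ x - b) / max(bnorm, 1.0)
        return x, {"method": "direct", "relative_residual": res}
    if method == "pcg":
        hist: list[float] = []
        M = sp.diags(1.0 / A.diagonal())
        x, info = _cg(
            A, b, rtol=tol * 1e-2, atol=0.0, maxiter=max_iter, M=M,
            callback=lambda xk: hist.append(float(np.linalg.norm(A @ xk - b))),
        )
        res = np.linalg.norm(A @ x - b) / max(bnorm, 1.0)
        if info != 0 or res > tol:
            raise RuntimeError(
                f"PCG did not converge (info={info}, relative residual "
                f"{res:.3e}); residual history: {hist[-5:]}"
            )
        return x, {"method": "pcg", "relative_residual": res, "iterations": len(hist)}
    raise ValueError(f"unknown solver method {method!r}")


class MMEWorkspace:
    """Reusable assembly/factorization state for one dataset.

    Precomputes the COO index structure of the MME so that systems for
    new variance components share the pattern (needed both for speed in
    EM-REML and so that structurally-zero ``G0^-1`` entries stay in the
    pattern of the factorization).
    """

    def __init__(self, ped: Pedigree, records: RecordSet, sigma2_ez: float = 0.001,
                 ainv: RelationshipMatrix | None = None):
        if records.n_animals != ped.n:
            raise ValueError(
                f"records cover {records.n_animals} animals but the pedigree "
                f"has {ped.n}"
            )
        self.ped = ped
        self.records = records
        self.sigma2_ez = float(sigma2_ez)
        if ainv is None:
            ainv = additive_relationship_inverse(ped)
        self.ainv = ainv
        _, dvar = inbreeding_and_mendelian_variance(ped)
        self.logdet_a = float(np.log(dvar).sum())

        T = 1 + records.n_contents
        self.n_traits = T
        n = ped.n
        self.n_extra_levels = []
        if records.fixed_y is not None:
            for k in range(records.fixed_y.shape[1]):
                # treatment coding: level 0 is the reference
                self.n_extra_levels.append(int(records.fixed_y[:, k].max()))
        self.n_fixed = T + sum(self.n_extra_levels)
        self.n_eq = self.n_fixed + n * T
        self.mean_eq = np.arange(T, dtype=np.int64)
        self.obs_y = np.flatnonzero(~np.isnan(records.y))
        self.obs_z = [np.flatnonzero(~np.isnan(records.z[:, k])) for k in range(T - 1)]
        self.n_records = self.obs_y.size + sum(o.size for o in self.obs_z)

        # --- data-part COO (unit residual weights; scaled at assembly).
        # Besides the true incidence (fixed columns + the trait's own
        # animal equation), zero-coefficient entries tie each record to
        # the animal's OTHER trait equations: they do not change the
        # numbers but force those positions into the factor's symbolic
        # pattern, where EM-REML's selected-inverse lookups need them.
        ycols = _incidence_columns(records, self.n_extra_levels)
        oy = self.obs_y
        ycols_obs = [(c[oy], w[oy]) for c, w in ycols] + [
            (self.animal_eq(oy, t),
             np.full(oy.size, 1.0 if t == 0 else 0.0))
            for t in range(T)
        ]
        ry, cy, wy_ = [], [], []
        for a, wa in ycols_obs:
            for b, wb in ycols_obs:
                ry.append(a)
                cy.append(b)
                wy_.append(wa * wb)
        self._y_rows = np.concatenate(ry) if ry else np.empty(0, np.int64)
        self._y_cols = np.concatenate(cy) if cy else np.empty(0, np.int64)
        self._y_wts = np.concatenate(wy_) if wy_ else np.empty(0)
        self._y_rhs_cols = [(c[oy], w[oy]) for c, w in ycols] + [
            (self.animal_eq(oy, 0), np.ones(oy.size))
        ]
        self.ycols_observed = [(c[oy], w[oy]) for c, w in ycols]
        zr, zc, wz_ = [], [], []
        self._z_rhs_cols = []
        for k, obs in enumerate(self.obs_z):
            cols = [np.full(obs.size, self.mean_eq[1 + k])] + [
                self.animal_eq(obs, t) for t in range(T)
            ]
            wts = [1.0] + [1.0 if t == 1 + k else 0.0 for t in range(T)]
            for a, wa in zip(cols, wts):
                for b, wb in zip(cols, wts):
                    zr.append(a)
                    zc.append(b)
                    wz_.append(np.full(a.size, wa * wb))
            self._z_rhs_cols.append(
                [
                    (np.full(obs.size, self.mean_eq[1 + k]), np.ones(obs.size)),
                    (self.animal_eq(obs, 1 + k), np.ones(obs.size)),
                ]
            )
        self._z_rows = np.concatenate(zr) if zr else np.empty(0, np.int64)
        self._z_cols = np.concatenate(zc) if zc else np.empty(0, np.int64)
        self._z_wts = np.concatenate(wz_) if wz_ else np.empty(0)

        # --- genetic-part COO: Ainv (x) G0inv over all trait pairs ---
        acoo = sp.coo_matrix(ainv.matrix)
        self._ainv_coo = (acoo.row.astype(np.int64), acoo.col.astype(np.int64),
                          acoo.data.copy())
        gr, gc, self._g_pair = [], [], []
        for t in range(T):
            for t2 in range(T):
                gr.append(self.n_fixed + acoo.row * T + t)
                gc.append(self.n_fixed + acoo.col * T + t2)
                self._g_pair.append((t, t2))
        self._g_rows = np.concatenate(gr)
        self._g_cols = np.concatenate(gc)
        self._rows = np.concatenate([self._y_rows, self._z_rows, self._g_rows])
        self._cols = np.concatenate([self._y_cols, self._z_cols, self._g_cols])
        self._perm = None

    # -- index helpers -----------------------------------------------------

    def animal_eq(self, animal, trait):
        return self.n_fixed + np.asarray(animal, dtype=np.int64) * self.n_traits + trait

    # -- assembly ----------------------------------------------------------

    def _values(self, g0inv: np.ndarray, sigma2_ey: float):
        wy = 1.0 / sigma2_ey
        wz = 1.0 / self.sigma2_ez
        vy = self._y_wts * wy
        vz = self._z_wts * wz
        # structurally-zero G0^-1 coefficients (e.g. the trait-content
        # block of the no-covariance model) are assembled as explicit
        # zeros: the LDL' symbolic pattern must contain those positions
        # for the selected inverse used by EM-REML
        vg = np.concatenate(
            [self._ainv_coo[2] * g0inv[t, t2] for (t, t2) in self._g_pair]
        )
        return np.concatenate([vy, vz, vg])

    def _rhs(self, sigma2_ey: float):
        rhs = np.zeros(self.n_eq)
        yv = self.records.y[self.obs_y] / sigma2_ey
        for cols, wts in self._y_rhs_cols:
            np.add.at(rhs, cols, yv * wts)
        for k, cols in enumerate(self._z_rhs_cols):
            zv = self.records.z[self.obs_z[k], k] / self.sigma2_ez
            for c, w in cols:
                np.add.at(rhs, c, zv * w)
        return rhs

    def system(self, g0: GeneTraitCovariance, sigma2_ey: float) -> MixedModelSystem:
        g0 = g0 if isinstance(g0, GeneTraitCovariance) else GeneTraitCovariance(g0)
        if g0.n_traits != self.n_traits:
            raise ValueError("G0 dimension does not match the record set")
        if not g0.is_positive_definite():
            raise np.linalg.LinAlgError("G0 must be positive definite")
        g0inv = np.linalg.inv(g0.matrix)
        vals = self._values(g0inv, sigma2_ey)
        rows, cols = self._rows, self._cols
        # a fixed effect with no records has an empty equation (its mean
        # is inestimable); pin it to zero with a unit diagonal so the
        # system stays nonsingular without touching any other solution
        empty = [t for t in range(self.n_traits)
                 if (self.obs_y if t == 0 else self.obs_z[t - 1]).size == 0]
        if empty:
            rows = np.concatenate([rows, self.mean_eq[empty]])
            cols = np.concatenate([cols, self.mean_eq[empty]])
            vals = np.concatenate([vals, np.ones(len(empty))])
        lhs = sp.coo_matrix(
            (vals, (rows, cols)), shape=(self.n_eq, self.n_eq)
        ).tocsc()
        labels = [("mean", "y" if t == 0 else f"z{t}") for t in range(self.n_traits)]
        for k, nl in enumerate(self.n_extra_levels):
            # treatment coding: level 0 is absorbed into the mean
            labels += [(f"factor{k + 1}", f"level{l + 1}") for l in range(nl)]
        return MixedModelSystem(
            lhs, self._rhs(sigma2_ey), self.n_fixed, self.n_traits, self.ped.n,
            self.mean_eq, labels,
        )

    # -- factorization reuse ----------------------------------------------

    def factorize(self, g0, sigma2_ey):
        """Factorize the MME for these components; returns a solver state.

        The fill-reducing (minimum-degree) ordering is computed on the
        first call and reused: the pattern is identical across
        component values.
        """
        sys_ = self.system(g0, sigma2_ey)
        factor, perm, logdet = factorize_spd(sys_.lhs, self._perm)
        self._perm = perm
        return _Factorized(self, sys_, factor, logdet)


class _Factorized:
    """A factorized MME: solutions, log-likelihood, selected inverse."""

    def __init__(self, ws: MMEWorkspace, system: MixedModelSystem, factor, logdet):
        self.ws = ws
        self.system = system
        self.factor = factor
        self.logdet_c = logdet
        self._x = None
        self._sel = None

    @property
    def solution(self) -> np.ndarray:
        if self._x is None:
            self._x = self.factor.solve(self.system.rhs)
        return self._x

    @property
    def selected_inverse(self) -> SelectedInverse:
        if self._sel is None:
            self._sel = SelectedInverse(self.factor)
        return self._sel

    def solutions_by_trait(self):
        """(b_fixed, U) with U of shape (n_animals, n_traits)."""
        x = self.solution
        nf, T = self.ws.n_fixed, self.ws.n_traits
        return x[:nf], x[nf:].reshape(self.ws.ped.n, T)

    def minus2_restricted_loglik(self, g0, sigma2_ey) -> float:
        """-2 log restricted likelihood, constants included.

        ``-2 l = (n - p) log 2pi + T log|A| + N log|G0| + sum log
        sigma2_e + log|C| + y'Py`` with ``y'Py = y'R^-1 y - x'RHS``.
        """
        ws = self.ws
        g0m = g0.matrix if isinstance(g0, GeneTraitCovariance) else np.asarray(g0)
        y = ws.records.y[ws.obs_y]
        ypy = float(y @ y) / sigma2_ey
        for k, obs in enumerate(ws.obs_z):
            zk = ws.records.z[obs, k]
            ypy += float(zk @ zk) / ws.sigma2_ez
        ypy -= float(self.solution @ self.system.rhs)
        n_minus_p = ws.n_records - ws.n_fixed
        logr = ws.obs_y.size * np.log(sigma2_ey) + sum(
            obs.size for obs in ws.obs_z
        ) * np.log(ws.sigma2_ez)
        sign, logdet_g0 = np.linalg.slogdet(g0m)
        if sign <= 0:
            raise np.linalg.LinAlgError("G0 must be positive definite")
        return (
            n_minus_p * np.log(2.0 * np.pi)
            + ws.n_traits * ws.logdet_a
            + ws.ped.n * logdet_g0
            + logr
            + self.logdet_c
            + ypy
        )


def animal_model_blup(
    ped: Pedigree,
    y: np.ndarray,
    genetic_variance: float,
    residual_variance: float,
    covariates: np.ndarray | None = None,
    ainv: RelationshipMatrix | None = None,
):
    """Single-trait animal model BLUP with optional fixed covariates.

    Fits ``y = 1 mu + X_c beta + u + e`` with ``Var(u) = A * s2u`` and
    returns ``(b, u, cinv_fixed)`` where ``b`` stacks the mean and
    covariate coefficients and ``cinv_fixed`` is the fixed-effect block
    of the inverse coefficient matrix (for standard errors).
    """
    y = np.asarray(y, dtype=float)
    if ainv is None:
        ainv = additive_relationship_inverse(ped)
    obs = np.flatnonzero(~np.isnan(y))
    if obs.size == 0:
        raise ValueError("no observed records")
    X = np.ones((obs.size, 1))
    if covariates is not None:
        Xc = np.atleast_2d(np.asarray(covariates, dtype=float))
        if Xc.shape[0] != ped.n:
            Xc = Xc.T
        if np.isnan(Xc[obs]).any():
            raise ValueError("covariate missing for a phenotyped animal")
        X = np.hstack([X, Xc[obs]])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise np.linalg.LinAlgError(
                "covariate is constant/collinear: effect inestimable"
            )
    nf = X.shape[1]
    n = ped.n
    we = 1.0 / residual_variance
    lam = 1.0 / genetic_variance
    W = sp.csr_matrix((np.ones(obs.size), (np.arange(obs.size), obs)), shape=(obs.size, n))
    Xs = sp.csr_matrix(X)
    top = sp.hstack([Xs.T @ Xs * we, Xs.T @ W * we])
    bot = sp.hstack([W.T @ Xs * we, W.T @ W * we + ainv.matrix * lam])
    lhs = sp.vstack([top, bot]).tocsc()
    rhs = np.concatenate([X.T @ y[obs] * we, W.T @ y[obs] * we])
    factor, _, _ = factorize_spd(lhs)
    x = factor.solve(rhs)
    b, u = x[:nf], x[nf:]
    # fixed-effect block of the inverse coefficient matrix (dense, tiny)
    cinv_fixed = np.empty((nf, nf))
    for k in range(nf):
        ek = np.zeros(lhs.shape[0])
        ek[k] = 1.0
        cinv_fixed[:, k] = factor.solve(ek)[:nf]
    return b, u, cinv_fixed


def write_solutions(path, ped: Pedigree, system: MixedModelSystem, x: np.ndarray):
    """Write solutions as delimited text: effect, trait, level, estimate."""
    rows = []
    for eq, (effect, trait) in enumerate(system.fixed_labels):
        rows.append((effect, trait, "", x[eq]))
    T = system.n_traits
    for i, animal in enumerate(ped.ids):
        for t in range(T):
            trait = "y" if t == 0 else f"z{t}"
            rows.append(("animal", trait, animal, x[system.n_fixed + i * T + t]))
    pd.DataFrame(rows, columns=["effect", "trait", "level", "estimate"]).to_csv(
        path, sep=" ", index=False
    )
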