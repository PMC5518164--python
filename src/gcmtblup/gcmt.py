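"""Gene-content multiple-trait BLUP (GCMTBLUP) and REML (GCMTREML).

The quantitative trait y and the gene content z at a major gene are
analysed jointly as correlated traits with genetic covariance
``G0 (x) A``.  With known components, solving the mixed-model
equations yields total breeding values ``u_y`` (major gene included),
gene-content breeding values ``u_z`` — hence predicted genotypes
``z_hat = b_z + u_z`` for non-genotyped animals, informed by the trait
phenotypes — and the polygenic component ``eps = u_y - u_z * alpha``.

GCMTREML estimates G0 and the trait residual variance by EM, holding
the nominal gene-content residual fixed (gene content has heritability
1 by construction, so that component sits on the boundary and is not
estimable).  From ``G0_hat``, the substitution effect is
``alpha_hat = cov(u_z, u_y) / var(u_z)``, the base allele frequency
follows from ``var(u_z) = 2p(1-p)`` or from the content mean
``b_z = 2p``, the gene effect is tested by a likelihood-ratio test
against a model with zero trait-content covariance (chi-square, 1 df,
the covariance being unbounded), and a delta-method confidence interval
for ``alpha_hat`` uses a finite-difference observed information matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy import stats
from sklearn.base import BaseEstimator

from .genecov import GeneParams, GeneTraitCovariance, build_g0, decompose_g0
from .mme import MMEWorkspace, RecordSet, ResidualSpec
from .pedigree import Pedigree, RelationshipMatrix

__all__ = [
    "Predictions",
    "VarianceEstimates",
    "GeneContentBLUP",
    "GeneContentREML",
    "gcmtblup",
    "gcmtreml",
    "gene_effect_lrt",
    "estimate_allele_frequency",
    "alpha_confidence_interval",
    "xlinked_gcmtblup",
]


@dataclass
class Predictions:
    """Per-animal GCMTBLUP solutions.

    u_y : total breeding value for the trait (major gene included).
    u_z : (n, m) gene-content breeding values.
    epsilon : polygenic component ``u_y - u_z @ alpha``.
    z_hat : predicted gene content ``b_z + u_z``.
    """

    b_y: float
    b_z: np.ndarray
    u_y: np.ndarray
    u_z: np.ndarray
    epsilon: np.ndarray
    z_hat: np.ndarray
    alpha: np.ndarray
    solution: np.ndarray = field(repr=False, default=None)


@dataclass
class VarianceEstimates:
    """GCMTREML output: converged components and likelihood diagnostics."""

    g0: GeneTraitCovariance
    sigma2_ey: float
    sigma2_ez: float
    loglik: float
    loglik_path: np.ndarray
    n_iter: int
    converged: bool
    params: GeneParams | None = None
    b_z: np.ndarray | None = None
    vcov_components: np.ndarray | None = None  # (s2uy, cov, s2uz, s2ey)

    @property
    def alpha(self) -> float:
        return float(self.g0.matrix[0, 1] / self.g0.matrix[1, 1])


class GeneContentBLUP(BaseEstimator):
    """Multi-trait pedigree BLUP of a trait and major-gene content(s).

    Parameters
    ----------
    g0 : (1+m) x (1+m) genetic covariance (trait first) or
        :class:`GeneTraitCovariance` or :class:`GeneParams`.
    sigma2_ey : trait residual variance.
    sigma2_ez : nominal gene-content residual variance (small).
    method, tol : passed to the sparse solver.

    Any pattern of missing phenotypes/genotypes is allowed; animals
    without records are still predicted through the pedigree.
    """

    def __init__(self, g0=None, sigma2_ey=1.0, sigma2_ez=0.001, method="direct",
                 tol=1e-10):
        self.g0 = g0
        self.sigma2_ey = sigma2_ey
        self.sigma2_ez = sigma2_ez
        self.method = method
        self.tol = tol

    def _g0(self) -> GeneTraitCovariance:
        if isinstance(self.g0, GeneParams):
            return build_g0(self.g0)
        if isinstance(self.g0, GeneTraitCovariance):
            return self.g0
        return GeneTraitCovariance(np.asarray(self.g0, dtype=float))

    def fit(self, pedigree: Pedigree, records: RecordSet,
            ainv: RelationshipMatrix | None = None):
        g0 = self._g0()
        ws = MMEWorkspace(pedigree, records, self.sigma2_ez, ainv=ainv)
        if self.method == "direct":
            fac = ws.factorize(g0, self.sigma2_ey)
            x = fac.solution
            self.diagnostics_ = {"method": "direct"}
        else:
            from .mme import solve_mme

            sys_ = ws.system(g0, self.sigma2_ey)
            x, self.diagnostics_ = solve_mme(sys_, self.method, self.tol)
        nf, T = ws.n_fixed, ws.n_traits
        U = x[nf:].reshape(pedigree.n, T)
        m = g0.matrix
        alpha = m[0, 1:] / np.diag(m)[1:]
        self.workspace_ = ws
        self.b_y_ = float(x[0])
        self.b_z_ = x[1:T].copy()
        self.u_y_ = U[:, 0].copy()
        self.u_z_ = U[:, 1:].copy()
        self.alpha_ = alpha
        self.epsilon_ = self.u_y_ - self.u_z_ @ alpha
        self.z_hat_ = self.b_z_[None, :] + self.u_z_
        self.solution_ = x
        self.predictions_ = Predictions(
            self.b_y_, self.b_z_, self.u_y_,
            self.u_z_[:, 0] if T == 2 else self.u_z_,
            self.epsilon_,
            self.z_hat_[:, 0] if T == 2 else self.z_hat_,
            alpha, x,
        )
        return self

    def predict_gene_content(self) -> np.ndarray:
        """Predicted gene contents ``b_z + u_z`` for every animal."""
        return self.z_hat_[:, 0] if self.z_hat_.shape[1] == 1 else self.z_hat_


class GeneContentREML(BaseEstimator):
    """EM-REML estimation of G0 and the trait residual variance.

    Each EM iteration solves the MME at the current components and
    updates ``G0[t, t'] <- (u_t' Ainv u_t' + tr(Ainv C^{tt'})) / N`` and
    ``s2_ey <- (e'e + sum_i PEV_i) / n_y``, where the trace and
    prediction-error-variance terms come from a sparse selected inverse
    of the coefficient matrix.  The restricted log-likelihood is
    monotone non-decreasing along the path.  ``sigma2_ez`` is held
    fixed.  ``constrain_null=True`` fits the no-gene-effect model
    (trait-content covariances fixed at zero, everything else free).
    """

    def __init__(self, sigma2_ez=0.001, tol=1e-8, max_iter=1000, init=None,
                 constrain_null=False, compute_se=False, accelerate="px",
                 verbose=False):
        self.sigma2_ez = sigma2_ez
        self.tol = tol
        self.max_iter = max_iter
        self.init = init
        self.constrain_null = constrain_null
        self.compute_se = compute_se
        self.accelerate = accelerate
        self.verbose = verbose

    # -- initial values ----------------------------------------------------

    def _init_components(self, records: RecordSet):
        if self.init is not None:
            g0, s2ey = self.init
            g0 = g0.matrix if isinstance(g0, GeneTraitCovariance) else np.asarray(g0)
            return g0.copy().astype(float), float(s2ey)
        vy = np.nanvar(records.y)
        if not np.isfinite(vy) or vy <= 0:
            vy = 1.0
        m = records.n_contents
        g0 = np.zeros((1 + m, 1 + m))
        g0[0, 0] = 0.5 * vy
        for k in range(m):
            vz = np.nanvar(records.z[:, k])
            if not np.isfinite(vz) or vz <= 1e-4:
                vz = 0.25
            g0[1 + k, 1 + k] = min(max(vz, 0.05), 0.5)
        return g0, 0.5 * vy

    def fit(self, pedigree: Pedigree, records: RecordSet,
            ainv: RelationshipMatrix | None = None):
        if not np.any(~np.isnan(records.y)):
            raise ValueError("REML needs at least one phenotyped animal")
        if not np.any(~np.isnan(records.z)):
            raise ValueError("REML needs at least one genotyped animal")
        for k in range(records.n_contents):
            zo = records.z[~np.isnan(records.z[:, k]), k]
            if zo.size and np.ptp(zo) == 0:
                raise ValueError(
                    "monomorphic gene: no gene-content variance in the "
                    "observed genotypes"
                )
        ws = MMEWorkspace(pedigree, records, self.sigma2_ez, ainv=ainv)
        T = ws.n_traits
        N = pedigree.n
        g0, s2ey = self._init_components(records)
        if self.constrain_null:
            g0[0, 1:] = g0[1:, 0] = 0.0

        ar, ac, av = ws._ainv_coo
        y = records.y
        obs_y = ws.obs_y
        ycols = ws.ycols_observed  # (column, weight) pairs per record
        yanimal = ws.animal_eq(obs_y, 0)
        inc_cols = ycols + [(yanimal, np.ones(obs_y.size))]

        if self.accelerate not in ("px", "none"):
            raise ValueError("accelerate must be 'px' or 'none'")
        path = []
        prev = np.inf
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            fac = ws.factorize(GeneTraitCovariance(g0), s2ey)
            m2ll = fac.minus2_restricted_loglik(GeneTraitCovariance(g0), s2ey)
            path.append(-0.5 * m2ll)
            if self.verbose:
                print(f"EM iter {it}: logL_R = {-0.5 * m2ll:.6f}")
            if m2ll > prev + 1e-6 * max(1.0, abs(prev)):
                warnings.warn(
                    f"restricted log-likelihood decreased at iteration {it} "
                    f"({-0.5 * prev:.6f} -> {-0.5 * m2ll:.6f})"
                )
            prev = m2ll
            b, U = fac.solutions_by_trait()
            sel = fac.selected_inverse
            AU = ws.ainv.matrix @ U
            S = np.empty((T, T))
            for t in range(T):
                for t2 in range(t, T):
                    quad = float(U[:, t] @ AU[:, t2])
                    tr = float(
                        av @ sel.entries(ws.animal_eq(ar, t), ws.animal_eq(ac, t2))
                    )
                    S[t, t2] = S[t2, t] = quad + tr
            if self.accelerate == "px":
                g0_new, s2ey_new = _px_mstep_impl(
                    ws, fac, sel, U, S, ycols, records, self.constrain_null
                )
            else:
                g0_new = S / N
                if self.constrain_null:
                    g0_new[0, 1:] = g0_new[1:, 0] = 0.0
                # residual update: E[e'e | data] / n_y
                fixed_part = np.zeros(obs_y.size)
                x = fac.solution
                for c, wt in ycols:
                    fixed_part += x[c] * wt
                e = y[obs_y] - fixed_part - U[obs_y, 0]
                pev = np.zeros(obs_y.size)
                for a, wa in inc_cols:
                    for bcol, wb in inc_cols:
                        pev += sel.entries(a, bcol) * wa * wb
                s2ey_new = float(e @ e + pev.sum()) / obs_y.size
            w = np.linalg.eigvalsh(g0_new)
            if w.min() <= 1e-10 * max(w.max(), 1.0):
                warnings.warn(
                    "EM produced a (near-)singular G0 update; projecting "
                    "to the nearest well-conditioned positive-definite matrix"
                )
                g0_new = _nearest_pd(g0_new)
            if not np.isfinite(s2ey_new) or s2ey_new <= 0:
                warnings.warn(
                    "EM produced a non-positive residual variance update; "
                    "flooring it"
                )
                s2ey_new = max(1e-8, 0.01 * abs(s2ey))
            delta = max(
                np.max(np.abs(g0_new - g0)) / max(np.max(np.abs(g0)), 1e-12),
                abs(s2ey_new - s2ey) / max(abs(s2ey), 1e-12),
            )
            g0, s2ey = g0_new, s2ey_new
            if delta < self.tol:
                converged = True
                break
        self._last_em_state = (g0.copy(), float(s2ey))
        if not converged:
            warnings.warn(
                f"EM-REML did not converge in {it} iterations "
                f"(last relative change {delta:.2e}); returning best estimates"
            )
        fac = ws.factorize(GeneTraitCovariance(g0), s2ey)
        m2ll = fac.minus2_restricted_loglik(GeneTraitCovariance(g0), s2ey)
        path.append(-0.5 * m2ll)
        bfix, U = fac.solutions_by_trait()

        self.workspace_ = ws
        self.g0_ = GeneTraitCovariance(g0)
        self.sigma2_ey_ = float(s2ey)
        self.loglik_ = -0.5 * m2ll
        self.loglik_path_ = np.array(path)
        self.n_iter_ = it
        self.converged_ = converged
        self.b_z_ = bfix[1:T].copy()
        self.u_ = U
        params = None
        if T == 2 and not self.constrain_null:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                params = decompose_g0(self.g0_)
        self.params_ = params
        self.vcov_ = None
        if self.compute_se and T == 2:
            self.vcov_ = _component_vcov(ws, g0, s2ey)
        self.estimates_ = VarianceEstimates(
            self.g0_, self.sigma2_ey_, self.sigma2_ez, self.loglik_,
            self.loglik_path_, self.n_iter_, self.converged_, params,
            self.b_z_, self.vcov_,
        )
        return self


def _px_mstep_impl(ws, fac, sel, U, S, ycols, records, constrain_null):
    """Parameter-expanded M-step.

    The breeding values are expanded as ``u = (Lambda (x) I) v`` with
    ``v ~ N(0, G0v (x) A)``; the M-step maximizes the complete-data
    likelihood jointly over the fixed effects, the expansion matrix
    Lambda (one weighted regression of each trait's records on the
    current BLUPs of all traits, with prediction-error second moments
    from the selected inverse), and ``G0v = S / N``; the reduction step
    then sets ``G0 <- Lambda G0v Lambda'``.  This is the standard PX-EM
    scheme, monotone in the restricted likelihood but far faster than
    plain EM when most gene contents or phenotypes are missing.  The
    trait residual update falls out of the same regression; the content
    residual stays fixed.  Under the no-covariance constraint Lambda
    and G0v are kept diagonal.
    """
    T = ws.n_traits
    N = ws.ped.n
    x = fac.solution
    Lam = np.zeros((T, T))
    s2ey_new = None
    for t in range(T):
        if t == 0:
            obs = ws.obs_y
            vals = records.y[obs]
            fcols = ycols
        else:
            obs = ws.obs_z[t - 1]
            vals = records.z[obs, t - 1]
            fcols = [
                (np.full(obs.size, ws.mean_eq[t], dtype=np.int64),
                 np.ones(obs.size))
            ]
        sidx = [t] if constrain_null else list(range(T))
        q = len(sidx)
        # the fixed part stays integrated out (REML): c_i = x_i' b with
        # posterior mean chat and variance from the selected inverse
        chat = np.zeros(obs.size)
        for arr, wt in fcols:
            chat += x[arr] * wt
        var_c = np.zeros(obs.size)
        for arr, wt in fcols:
            for arr2, wt2 in fcols:
                var_c += sel.entries(arr, arr2) * wt * wt2
        V = U[np.ix_(obs, sidx)]
        A22 = np.zeros((q, q))
        PEVw = np.zeros((q, q))
        cross = np.zeros(q)  # sum_i Cov(v_i, c_i)
        for a, sa in enumerate(sidx):
            ea = ws.animal_eq(obs, sa)
            for b_, sb in enumerate(sidx[a:], start=a):
                pev = float(sel.entries(ea, ws.animal_eq(obs, sb)).sum())
                PEVw[a, b_] = PEVw[b_, a] = pev
                A22[a, b_] = A22[b_, a] = float(V[:, a] @ V[:, b_]) + pev
            for arr, wt in fcols:
                cross[a] += float((sel.entries(ea, arr) * wt).sum())
        resid0 = vals - chat
        rhs = V.T @ resid0 - cross
        try:
            lam = np.linalg.solve(A22, rhs)
        except np.linalg.LinAlgError:
            lam = np.linalg.lstsq(A22, rhs, rcond=None)[0]
        Lam[t, sidx] = lam
        if t == 0:
            e = resid0 - V @ lam
            ss = float(e @ e) + float(var_c.sum())
            ss += 2.0 * float(lam @ cross) + float(lam @ PEVw @ lam)
            s2ey_new = ss / obs.size
    if constrain_null:
        g0_new = np.diag(np.diag(Lam) ** 2 * np.diag(S) / N)
    else:
        g0_new = Lam @ (S / N) @ Lam.T
        g0_new = 0.5 * (g0_new + g0_new.T)
    return g0_new, s2ey_new


def _nearest_pd(m: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    w, v = np.linalg.eigh(m)
    w = np.maximum(w, floor * max(w.max(), 1.0))
    return (v * w) @ v.T


def _component_vcov(ws: MMEWorkspace, g0: np.ndarray, s2ey: float) -> np.ndarray:
    """Asymptotic covariance of (s2_uy, cov_uzy, s2_uz, s2_ey).

    Observed information by central finite differences of the restricted
    log-likelihood; the inverse information is the variance estimate.
    """
    theta0 = np.array([g0[0, 0], g0[0, 1], g0[1, 1], s2ey])

    def m2ll(theta):
        g = np.array([[theta[0], theta[1]], [theta[1], theta[2]]])
        if np.linalg.eigvalsh(g).min() <= 0 or theta[3] <= 0:
            return np.nan
        fac = ws.factorize(GeneTraitCovariance(g), theta[3])
        return fac.minus2_restricted_loglik(GeneTraitCovariance(g), theta[3])

    h = np.maximum(np.abs(theta0), 1e-3) * 1e-4
    n = theta0.size
    H = np.full((n, n), np.nan)
    f0 = m2ll(theta0)
    for i in range(n):
        for j in range(i, n):
            hi, hj = h[i], h[j]
            if i == j:
                fp = m2ll(theta0 + hi * _e(n, i))
                fm = m2ll(theta0 - hi * _e(n, i))
                H[i, i] = (fp - 2 * f0 + fm) / hi**2
            else:
                fpp = m2ll(theta0 + hi * _e(n, i) + hj * _e(n, j))
                fpm = m2ll(theta0 + hi * _e(n, i) - hj * _e(n, j))
                fmp = m2ll(theta0 - hi * _e(n, i) + hj * _e(n, j))
                fmm = m2ll(theta0 - hi * _e(n, i) - hj * _e(n, j))
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * hi * hj)
    info = 0.5 * H  # Hessian of -logL
    if np.isnan(info).any():
        warnings.warn("information matrix could not be evaluated (boundary)")
        return None
    try:
        return np.linalg.inv(info)
    except np.linalg.LinAlgError:
        warnings.warn("information matrix is singular; SEs unavailable")
        return None


def _e(n, i):
    v = np.zeros(n)
    v[i] = 1.0
    return v


# -- module-level convenience wrappers ------------------------------------


def gcmtblup(ped, records, g0, resid: ResidualSpec, ainv=None) -> Predictions:
    """One-shot GCMTBLUP run; returns :class:`Predictions`."""
    est = GeneContentBLUP(g0=g0, sigma2_ey=resid.sigma2_ey,
                          sigma2_ez=resid.sigma2_ez).fit(ped, records, ainv=ainv)
    return est.predictions_


def gcmtreml(ped, records, init=None, tol=1e-8, max_iter=1000, sigma2_ez=0.001,
             compute_se=False, ainv=None) -> VarianceEstimates:
    """One-shot GCMTREML run; returns :class:`VarianceEstimates`."""
    est = GeneContentREML(sigma2_ez=sigma2_ez, tol=tol, max_iter=max_iter,
                          init=init, compute_se=compute_se).fit(ped, records,
                                                                ainv=ainv)
    return est.estimates_


def gene_effect_lrt(ped, records, sigma2_ez=0.001, tol=1e-8, max_iter=1000,
                    ainv=None):
    """Likelihood-ratio test of the gene effect (H0: cov(u_z, u_y) = 0).

    Returns ``(statistic, p_value, alt_fit, null_fit)``; the statistic
    is referred to chi-square with 1 df (the covariance is unbounded, so
    no boundary mixture applies).
    """
    alt = GeneContentREML(sigma2_ez=sigma2_ez, tol=tol, max_iter=max_iter).fit(
        ped, records, ainv=ainv
    )
    null = GeneContentREML(sigma2_ez=sigma2_ez, tol=tol, max_iter=max_iter,
                           constrain_null=True).fit(ped, records, ainv=ainv)
    stat = 2.0 * (alt.loglik_ - null.loglik_)
    if stat < -1e-6:
        raise RuntimeError(
            f"negative LRT statistic ({stat:.3e}): REML convergence failure"
        )
    stat = max(stat, 0.0)
    return stat, float(stats.chi2.sf(stat, df=1)), alt.estimates_, null.estimates_


def estimate_allele_frequency(fit: VarianceEstimates, predictions=None):
    """Base-population allele frequency, two ways.

    ``p_var`` solves ``2p(1-p) = var_hat(u_z)`` (root <= 0.5, orientation
    resolved against the mean-based estimate); ``p_mean = b_z / 2``.
    Returns ``((p_var, se_var), (p_mean, se_mean))``; SEs are NaN when
    the component covariance matrix is unavailable.
    """
    var_uz = float(fit.g0.matrix[1, 1])
    bz = float(fit.b_z[0]) if fit.b_z is not None else np.nan
    if np.isfinite(bz) and not 0.0 <= bz <= 2.0:
        warnings.warn(f"content mean {bz:.3f} outside [0, 2]; clamped")
        bz = float(np.clip(bz, 0.0, 2.0))
    p_mean = bz / 2.0
    pv = 0.5 * (1.0 - np.sqrt(max(1.0 - 2.0 * min(var_uz, 0.5), 0.0)))
    if np.isfinite(p_mean) and p_mean > 0.5:
        pv = 1.0 - pv
    se_var = np.nan
    if fit.vcov_components is not None and abs(pv - 0.5) > 1e-8:
        dvdp = 2.0 - 4.0 * pv  # d(2p(1-p))/dp
        se_var = abs(1.0 / dvdp) * np.sqrt(fit.vcov_components[2, 2])
    se_mean = np.nan
    return (float(pv), float(se_var)), (float(p_mean), float(se_mean))


def alpha_confidence_interval(fit: VarianceEstimates, level: float = 0.95):
    """Delta-method CI for ``alpha_hat = cov_hat / var_hat(u_z)``.

    ``Var(c/v) ~= Var(c)/v^2 + c^2 Var(v)/v^4 - 2 c Cov(c, v)/v^3``.
    Returns ``(alpha_hat, se, (lo, hi))``; ``se`` is NaN when the
    information matrix was singular or not computed.
    """
    c = float(fit.g0.matrix[0, 1])
    v = float(fit.g0.matrix[1, 1])
    alpha = c / v
    V = fit.vcov_components
    if V is None:
        return alpha, float("nan"), (float("nan"), float("nan"))
    grad = np.array([0.0, 1.0 / v, -c / v**2, 0.0])
    var = float(grad @ V @ grad)
    se = np.sqrt(max(var, 0.0))
    zq = stats.norm.ppf(0.5 + level / 2.0)
    return alpha, se, (alpha - zq * se, alpha + zq * se)


def xlinked_gcmtblup(ped: Pedigree, records: RecordSet, params: GeneParams,
                     resid: ResidualSpec, s_matrix: RelationshipMatrix):
    """GCMTBLUP for a major gene on the X chromosome.

    X-linked gene contents do not follow the autosomal A, so the joint
    Kronecker structure breaks.  Using the exact reparameterization
    ``u_y = eps + u_z * alpha`` with ``Cov(eps, u_z) = 0``, the model
    splits into a polygenic effect with covariance ``A s2_eps`` and a
    content effect with covariance ``S * 2pq`` (S = X relationship
    matrix), which yields ordinary mixed-model equations.  Gene
    parameters must be supplied (BLUP only; no X-linked REML).
    """
    from .pedigree import additive_relationship_inverse

    n = ped.n
    y, z = records.y, records.z[:, 0]
    if records.n_contents != 1:
        raise ValueError("X-linked analysis supports a single biallelic gene")
    obs_y = np.flatnonzero(~np.isnan(y))
    obs_z = np.flatnonzero(~np.isnan(z))
    ainv = additive_relationship_inverse(ped).matrix
    S = s_matrix.toarray()
    sinv = np.linalg.inv(S)
    wy, wz = 1.0 / resid.sigma2_ey, 1.0 / resid.sigma2_ez
    a = params.alpha
    nf = 2  # mu_y, mu_z
    neq = nf + 2 * n
    eps_eq = lambda i: nf + i  # noqa: E731
    uz_eq = lambda i: nf + n + i  # noqa: E731
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(np.asarray(r, dtype=np.int64))
        cols.append(np.asarray(c, dtype=np.int64))
        vals.append(np.asarray(v, dtype=float))

    # y records: columns (mu_y, eps_i, alpha * u_zi)
    cy = [np.zeros(obs_y.size, np.int64), eps_eq(obs_y), uz_eq(obs_y)]
    wts = [np.ones(obs_y.size), np.ones(obs_y.size), np.full(obs_y.size, a)]
    for c1, w1 in zip(cy, wts):
        for c2, w2 in zip(cy, wts):
            add(c1, c2, wy * w1 * w2)
    # z records: columns (mu_z, u_zi)
    cz = [np.full(obs_z.size, 1, np.int64), uz_eq(obs_z)]
    for c1 in cz:
        for c2 in cz:
            add(c1, c2, np.full(obs_z.size, wz))
    acoo = sp.coo_matrix(ainv)
    add(nf + acoo.row, nf + acoo.col, acoo.data / params.sigma2_eps)
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    add(uz_eq(ii.ravel()), uz_eq(jj.ravel()), sinv.ravel() / params.het)
    lhs = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(neq, neq),
    ).tocsc()
    rhs = np.zeros(neq)
    np.add.at(rhs, 0, (y[obs_y] * wy).sum())
    np.add.at(rhs, eps_eq(obs_y), y[obs_y] * wy)
    np.add.at(rhs, uz_eq(obs_y), y[obs_y] * wy * a)
    np.add.at(rhs, 1, (z[obs_z] * wz).sum())
    np.add.at(rhs, uz_eq(obs_z), z[obs_z] * wz)
    from ._spinv import factorize_spd

    factor, _, _ = factorize_spd(lhs)
    x = factor.solve(rhs)
    eps = x[nf:nf + n]
    uz = x[nf + n:]
    uy = eps + a * uz
    return Predictions(
        float(x[0]), np.array([x[1]]), uy, uz, eps, x[1] + uz,
        np.array([a]), x,
    )
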