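"""Trait x gene-content genetic covariance structures.

The additive value of a quantitative trait influenced by one major gene
decomposes as ``u_y = eps + u_z * alpha``: a polygenic part with
variance ``sigma2_eps`` and a gene part driven by the centred gene
content ``u_z`` (variance ``2pq`` for a biallelic gene with reference
allele frequency ``p``).  Treating gene content as a second trait, the
per-animal genetic covariance matrix is::

    G0 = [[sigma2_eps + 2pq a^2,  2pq a],
          [2pq a,                 2pq  ]]

with closed-form inverse ``[[1/se2, -a/se2], [-a/se2, (se2 + 2pq a^2) /
(2pq se2)]]`` (``se2 = sigma2_eps``, ``a = alpha``).  For a gene with n
alleles the vector of per-allele gene contents is twice a multinomial
draw, giving the (singular) covariance ``2 (diag(p) - p p')``; one
allele is dropped as reference and G0 has dimension ``n``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeneParams",
    "GeneTraitCovariance",
    "build_g0",
    "invert_g0",
    "decompose_g0",
    "multiallelic_content_covariance",
    "build_multi_g0",
]


@dataclass
class GeneParams:
    """Biallelic major-gene parameters.

    alpha : substitution effect, trait units per copy of the reference
        allele.
    p : reference-allele frequency in the base population (0 < p < 1).
    sigma2_eps : polygenic variance (trait units squared).
    """

    alpha: float
    p: float
    sigma2_eps: float
    negative_polygenic: bool = field(default=False, compare=False)

    def __post_init__(self):
        if not 0.0 < self.p < 1.0:
            raise ValueError("monomorphic gene: no gene-content variance")
        if self.sigma2_eps < 0 and not self.negative_polygenic:
            self.negative_polygenic = True

    @property
    def q(self) -> float:
        return 1.0 - self.p

    @property
    def het(self) -> float:
        """Base-population heterozygosity 2pq = variance of gene content."""
        return 2.0 * self.p * self.q

    @property
    def sigma2_gene(self) -> float:
        """Genetic variance explained by the gene, 2pq * alpha^2."""
        return self.het * self.alpha**2

    @property
    def sigma2_uy(self) -> float:
        """Total additive variance of the trait."""
        return self.sigma2_eps + self.sigma2_gene

    @property
    def cov_zy(self) -> float:
        """Genetic covariance between trait and gene content, 2pq * alpha."""
        return self.het * self.alpha


@dataclass
class GeneTraitCovariance:
    """Genetic covariance matrix G0, trait first then gene content(s)."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        m = self.matrix
        if m.shape[0] != m.shape[1] or not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("G0 must be square and symmetric")

    @property
    def n_traits(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_contents(self) -> int:
        return self.n_traits - 1

    def is_positive_definite(self, tol: float = 0.0) -> bool:
        return bool(np.linalg.eigvalsh(self.matrix).min() > tol)


def build_g0(params: GeneParams) -> GeneTraitCovariance:
    """G0 for one trait and one biallelic gene content."""
    return GeneTraitCovariance(
        np.array(
            [
                [params.sigma2_uy, params.cov_zy],
                [params.cov_zy, params.het],
            ]
        )
    )


def invert_g0(g0: GeneTraitCovariance, params: GeneParams | None = None) -> GeneTraitCovariance:
    """Inverse of G0.

    For the biallelic 2x2 case with known parameters the closed form
    ``[[1/se2, -a/se2], [-a/se2, (se2 + 2pq a^2)/(2pq se2)]]`` is used;
    otherwise a numeric inverse.  The result is symmetrized and checked
    against ``G0 @ G0inv = I``.
    """
    m = g0.matrix
    if params is not None and m.shape == (2, 2):
        se2 = params.sigma2_eps
        if se2 <= 0:
            raise np.linalg.LinAlgError("singular G0: non-positive polygenic variance")
        het = params.het
        inv = np.array(
            [
                [1.0 / se2, -params.alpha / se2],
                [-params.alpha / se2, (se2 + het * params.alpha**2) / (het * se2)],
            ]
        )
    else:
        try:
            inv = np.linalg.inv(m)
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(f"singular G0: {e}") from None
        inv = 0.5 * (inv + inv.T)
    resid = np.abs(m @ inv - np.eye(m.shape[0])).max()
    if not resid < 1e-6:
        raise np.linalg.LinAlgError(f"G0 inverse inaccurate (residual {resid:.2e})")
    return GeneTraitCovariance(inv)


def decompose_g0(g0hat: GeneTraitCovariance | np.ndarray) -> GeneParams:
    """Back out gene parameters from an estimated 2x2 G0.

    ``alpha_hat = cov / var(u_z)``; ``p_hat`` is the root of
    ``2p(1-p) = var(u_z)`` with ``p_hat <= 0.5`` by convention (the
    mean-based estimate ``b_z / 2`` resolves the orientation);
    ``sigma2_eps_hat = var(u_y) - var(u_z) alpha^2`` and is flagged
    (not truncated) when negative.
    """
    m = g0hat.matrix if isinstance(g0hat, GeneTraitCovariance) else np.asarray(g0hat)
    if m.shape != (2, 2):
        raise ValueError("decompose_g0 expects a 2x2 biallelic G0")
    var_uz = float(m[1, 1])
    cov = float(m[0, 1])
    if var_uz <= 0:
        raise ValueError("monomorphic gene: no gene-content variance")
    if var_uz > 0.5 + 1e-12:
        warnings.warn(
            f"gene-content variance {var_uz:.4g} exceeds the biallelic maximum "
            "0.5; p-hat clamped to 0.5"
        )
        p = 0.5
    else:
        p = 0.5 * (1.0 - np.sqrt(max(1.0 - 2.0 * var_uz, 0.0)))
    alpha = cov / var_uz
    sigma2_eps = float(m[0, 0]) - var_uz * alpha**2
    params = GeneParams(alpha=alpha, p=float(p), sigma2_eps=sigma2_eps)
    if sigma2_eps < 0:
        warnings.warn(
            f"decomposed polygenic variance is negative ({sigma2_eps:.4g}); "
            "G0 estimate is inconsistent with the single-gene model"
        )
    return params


def multiallelic_content_covariance(freqs) -> np.ndarray:
    """Covariance of the n per-allele gene contents, ``2(diag(p) - pp')``.

    Rows sum to zero (contents sum to 2), so the full matrix is
    singular; models drop one reference allele.
    """
    p = np.asarray(freqs, dtype=float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("need at least two allele frequencies")
    if np.any(p <= 0):
        raise ValueError("allele frequencies must be positive")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"allele frequencies sum to {p.sum():.10g}, not 1")
    return 2.0 * (np.diag(p) - np.outer(p, p))


def build_multi_g0(freqs, alphas, sigma2_eps: float) -> GeneTraitCovariance:
    """G0 for one trait and a multiallelic gene (last allele = reference).

    With C the full n x n content covariance and ``a`` the allele
    effects, the trait's genic variance is ``a' C a`` (invariant to a
    constant shift of ``a``), the trait-content covariances are ``C a``
    restricted to the n-1 retained contents, and the content block is
    the leading (n-1) x (n-1) submatrix of C.  The reference allele's
    effect is absorbed into the model mean.
    """
    C = multiallelic_content_covariance(freqs)
    a = np.asarray(alphas, dtype=float)
    if a.shape != (C.shape[0],):
        raise ValueError("alphas must match the number of alleles")
    ca = C @ a
    n = C.shape[0]
    g = np.empty((n, n))
    g[0, 0] = sigma2_eps + a @ ca
    g[0, 1:] = ca[: n - 1]
    g[1:, 0] = ca[: n - 1]
    g[1:, 1:] = C[: n - 1, : n - 1]
    g0 = GeneTraitCovariance(g)
    w = np.linalg.eigvalsh(g)
    if w.min() <= 0:
        raise np.linalg.LinAlgError(
            f"multiallelic G0 is not positive definite; eigenvalues {w}"
        )
    return g0
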