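"""Sparse LDL' factorization and selected inverse for SPD systems.

EM-REML needs entries of the inverse of the mixed-model coefficient
matrix C at the sparsity pattern of C itself (traces against the sparse
A-inverse; prediction-error variances of records).  The full inverse is
dense and unaffordable, but every entry lying inside the *symbolic*
filled pattern of a no-pivoting symmetric factorization is cheaply
available from the Takahashi recurrences

    C = L D L'   (L unit lower triangular)
    Z_ij = -sum_k L_kj Z_(i,k)            i in struct(col j), i > j
    Z_jj = 1/d_j - sum_k L_kj Z_kj

run from the last column to the first (k ranges over struct(col j); by
the elimination-tree closure property every referenced Z entry lies in
the pattern).

The factorization here is an up-looking sparse LDL' (elimination-tree
symbolic analysis, then one sparse triangular solve per column) — the
textbook algorithm of Davis's LDL — compiled with numba.  Keeping the
full symbolic pattern matters: general LU codes prune entries that
cancel to exact zero, which breaks the closure property the Takahashi
recurrences rely on.  Fill-in is controlled by a symmetric
minimum-degree ordering harvested from SuperLU's MMD(A'+A).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from numba import njit
from scipy.sparse.linalg import splu

__all__ = ["LDLFactor", "SelectedInverse", "factorize_spd", "selected_inverse"]


@njit(cache=True)
def _ldl_symbolic(n, Ap, Ai):
    """Elimination tree and column counts of L for upper-triangular A."""
    parent = np.full(n, -1, dtype=np.int64)
    flag = np.empty(n, dtype=np.int64)
    lnz = np.zeros(n, dtype=np.int64)
    for k in range(n):
        flag[k] = k
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            while i < k:
                if flag[i] == k:
                    break
                flag[i] = k
                lnz[i] += 1
                if parent[i] == -1:
                    parent[i] = k
                i = parent[i]
    return parent, lnz


@njit(cache=True)
def _ldl_numeric(n, Ap, Ai, Ax, parent, Lp):
    """Numeric up-looking LDL'; returns (Li, Lx, D) or D[k] <= 0 signal."""
    Li = np.empty(Lp[n], dtype=np.int64)
    Lx = np.empty(Lp[n])
    D = np.zeros(n)
    Y = np.zeros(n)
    pattern = np.empty(n, dtype=np.int64)
    flag = np.full(n, -1, dtype=np.int64)
    lnz = np.zeros(n, dtype=np.int64)
    for k in range(n):
        top = n
        flag[k] = k
        Y[k] = 0.0
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            Y[i] += Ax[p]
            length = 0
            while flag[i] != k:
                pattern[length] = i
                length += 1
                flag[i] = k
                i = parent[i]
            while length > 0:
                length -= 1
                top -= 1
                pattern[top] = pattern[length]
        D[k] = Y[k]
        Y[k] = 0.0
        for t in range(top, n):
            j = pattern[t]
            yj = Y[j]
            Y[j] = 0.0
            p2 = Lp[j] + lnz[j]
            for p in range(Lp[j], p2):
                Y[Li[p]] -= Lx[p] * yj
            l_kj = yj / D[j]
            D[k] -= l_kj * yj
            Li[p2] = k
            Lx[p2] = l_kj
            lnz[j] += 1
        if D[k] <= 0.0:
            return Li, Lx, D, k
    return Li, Lx, D, -1


@njit(cache=True)
def _lsolve(n, Lp, Li, Lx, x):
    for j in range(n):
        xj = x[j]
        if xj != 0.0:
            for p in range(Lp[j], Lp[j + 1]):
                x[Li[p]] -= Lx[p] * xj


@njit(cache=True)
def _ltsolve(n, Lp, Li, Lx, x):
    for j in range(n - 1, -1, -1):
        acc = x[j]
        for p in range(Lp[j], Lp[j + 1]):
            acc -= Lx[p] * x[Li[p]]
        x[j] = acc


@njit(cache=True)
def _takahashi(n, indptr, indices, lvals, dvals):
    """Takahashi recurrences over the (sorted) CSC pattern of L.

    Per column j the needed inverse entries Z[s, s] (s = struct(col j))
    are gathered into a dense symmetric block by merging the sorted
    index lists of the later columns — every required entry exists by
    the elimination-tree closure of the symbolic pattern — after which
    the column update is a dense matrix-vector product.
    """
    zdiag = np.zeros(n)
    zvals = np.zeros(lvals.shape[0])
    maxm = 0
    for j in range(n):
        m = indptr[j + 1] - indptr[j]
        if m > maxm:
            maxm = m
    Zsub = np.empty((maxm, maxm))
    for j in range(n - 1, -1, -1):
        lo, hi = indptr[j], indptr[j + 1]
        m = hi - lo
        if m == 0:
            zdiag[j] = 1.0 / dvals[j]
            continue
        for a in range(m):
            k = indices[lo + a]
            Zsub[a, a] = zdiag[k]
            p = indptr[k]
            pb = indptr[k + 1]
            b = a + 1
            while b < m and p < pb:
                r = indices[lo + b]
                ik = indices[p]
                if ik == r:
                    Zsub[b, a] = zvals[p]
                    Zsub[a, b] = zvals[p]
                    b += 1
                    p += 1
                elif ik < r:
                    p += 1
                else:  # unreachable for a closed pattern; defensive
                    Zsub[b, a] = 0.0
                    Zsub[a, b] = 0.0
                    b += 1
            while b < m:  # likewise unreachable
                Zsub[b, a] = 0.0
                Zsub[a, b] = 0.0
                b += 1
        diag = 1.0 / dvals[j]
        for a in range(m):
            acc = 0.0
            for b in range(m):
                acc += Zsub[a, b] * lvals[lo + b]
            zvals[lo + a] = -acc
        for a in range(m):
            diag -= lvals[lo + a] * zvals[lo + a]
        zdiag[j] = diag
    return zdiag, zvals


@njit(cache=True)
def _lookup(indptr, indices, zvals, zdiag, rows, cols):
    out = np.empty(rows.shape[0])
    for t in range(rows.shape[0]):
        i, j = rows[t], cols[t]
        if i == j:
            out[t] = zdiag[i]
            continue
        if i < j:
            i, j = j, i
        a, b = indptr[j], indptr[j + 1]
        val = np.nan
        while a < b:
            m = (a + b) // 2
            if indices[m] == i:
                val = zvals[m]
                break
            elif indices[m] < i:
                a = m + 1
            else:
                b = m
        out[t] = val
    return out


class LDLFactor:
    """``C[perm][:, perm] = L D L'`` for a sparse SPD matrix C.

    ``perm`` maps permuted index -> original index; solves are exposed
    in the original ordering.
    """

    def __init__(self, C: sp.spmatrix, perm: np.ndarray):
        n = C.shape[0]
        self.n = n
        self.perm = perm
        pinv = np.empty(n, dtype=np.int64)
        pinv[perm] = np.arange(n)
        self._pinv = pinv
        coo = C.tocoo()
        r = pinv[coo.row]
        c = pinv[coo.col]
        upper = r <= c
        A = sp.csc_matrix(
            (coo.data[upper], (r[upper], c[upper])), shape=(n, n)
        )
        A.sum_duplicates()
        A.sort_indices()
        Ap = A.indptr.astype(np.int64)
        Ai = A.indices.astype(np.int64)
        parent, lnz = _ldl_symbolic(n, Ap, Ai)
        Lp = np.zeros(n + 1, dtype=np.int64)
        Lp[1:] = np.cumsum(lnz)
        Li, Lx, D, bad = _ldl_numeric(n, Ap, Ai, A.data, parent, Lp)
        if bad >= 0:
            raise np.linalg.LinAlgError(
                f"matrix is not positive definite (pivot {bad})"
            )
        self._Lp, self._Li, self._Lx, self._D = Lp, Li, Lx, D
        self.logdet = float(np.log(D).sum())

    def solve(self, b: np.ndarray) -> np.ndarray:
        x = np.asarray(b, dtype=float)[self.perm].copy()
        _lsolve(self.n, self._Lp, self._Li, self._Lx, x)
        x /= self._D
        _ltsolve(self.n, self._Lp, self._Li, self._Lx, x)
        out = np.empty_like(x)
        out[self.perm] = x
        return out


def _mmd_ordering(C: sp.csc_matrix) -> np.ndarray:
    """Symmetric minimum-degree ordering via SuperLU's MMD(A' + A)."""
    lu = splu(
        C,
        permc_spec="MMD_AT_PLUS_A",
        diag_pivot_thresh=0.0,
        options={"SymmetricMode": True, "Equil": False},
    )
    return np.argsort(np.asarray(lu.perm_c)).astype(np.int64)


def factorize_spd(C: sp.spmatrix, perm: np.ndarray | None = None):
    """LDL' of an SPD matrix with minimum-degree ordering.

    Returns ``(factor, perm, logdet)``; pass ``perm`` back in to reuse
    the ordering across factorizations with an identical pattern.
    """
    C = sp.csc_matrix(C)
    if perm is None:
        perm = _mmd_ordering(C)
    factor = LDLFactor(C, perm)
    return factor, perm, factor.logdet


class SelectedInverse:
    """Entries of ``C^-1`` on the symbolic filled pattern of L."""

    def __init__(self, factor: LDLFactor):
        self._f = factor
        zdiag, zvals = _takahashi(
            factor.n, factor._Lp, factor._Li, factor._Lx, factor._D
        )
        self._zdiag = zdiag
        self._zvals = zvals

    def entries(self, rows, cols) -> np.ndarray:
        """``C^-1[rows, cols]`` (original indexing), elementwise.

        Positions outside the filled pattern come back NaN; callers
        only request positions structurally nonzero in C, which are
        always inside the pattern.
        """
        f = self._f
        r = f._pinv[np.asarray(rows, dtype=np.int64)]
        c = f._pinv[np.asarray(cols, dtype=np.int64)]
        return _lookup(f._Lp, f._Li, self._zvals, self._zdiag, r, c)


def selected_inverse(C: sp.spmatrix, perm: np.ndarray | None = None) -> SelectedInverse:
    """Selected inverse of an SPD sparse matrix (see module docstring)."""
    factor, _, _ = factorize_spd(C, perm)
    return SelectedInverse(factor)
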