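"""Pedigree handling and pedigree-based relationship matrices.

A pedigree is a list of animals with (possibly unknown) sire and dam.
This module validates and topologically orders pedigrees and builds

* the numerator relationship matrix ``A`` (tabular method),
* its sparse inverse via Henderson's rules with inbreeding taken into
  account (Meuwissen & Luo Mendelian-sampling variances), and
* the X-chromosomal relationship matrix, defined as the covariance of
  X-linked gene contents scaled by the base-population heterozygosity
  ``2pq`` (founder females have diagonal 1, males 0.5 because a male
  carries a single X copy).

Animals with an unknown parent are treated as drawn from a single base
population (no unknown-parent groups).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "Pedigree",
    "PedigreeError",
    "RelationshipMatrix",
    "read_pedigree",
    "additive_relationship_matrix",
    "additive_relationship_inverse",
    "inbreeding_and_mendelian_variance",
    "x_relationship_matrix",
]

UNKNOWN = -1

MALE = "M"
FEMALE = "F"


class PedigreeError(ValueError):
    """Raised for invalid pedigrees (cycles, duplicates, missing data)."""


@dataclass
class Pedigree:
    """Topologically ordered pedigree.

    Attributes
    ----------
    ids : list
        External identifiers, in internal (topological) order: every
        known parent appears before its offspring.
    sire, dam : ndarray of int
        Internal index of each animal's parents, ``-1`` when unknown.
    sex : ndarray of str or None
        ``"M"``/``"F"`` per animal; only required for X-chromosome work.
    generation : ndarray of int or None
        Optional cohort label.
    """

    ids: list
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray | None = None
    generation: np.ndarray | None = None
    id_to_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self.id_to_index:
            self.id_to_index = {a: i for i, a in enumerate(self.ids)}
        if len(self.id_to_index) != len(self.ids):
            raise PedigreeError("duplicate animal identifiers in pedigree")
        self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_parents(cls, ids, sires, dams, sex=None, generation=None):
        """Build a pedigree from parallel id/sire/dam sequences.

        Parents never declared as animals are auto-added as founders
        (with a warning).  Unknown parents are ``0``, ``"0"``, ``None``
        or NA.  The result is topologically sorted; a cycle raises
        :class:`PedigreeError` naming an animal on the cycle.
        """
        ids = list(ids)
        sires = [_norm_parent(s) for s in sires]
        dams = [_norm_parent(d) for d in dams]
        known = set(ids)
        if len(known) != len(ids):
            raise PedigreeError("duplicate animal identifiers in pedigree")
        extra = []
        for p in list(sires) + list(dams):
            if p is not None and p not in known:
                known.add(p)
                extra.append(p)
        if extra:
            warnings.warn(
                f"{len(extra)} parent(s) never declared as animals; "
                f"added as founders: {extra[:5]}{'...' if len(extra) > 5 else ''}"
            )
        sex_map = dict(zip(ids, sex)) if sex is not None else None
        gen_map = dict(zip(ids, generation)) if generation is not None else None
        par = {a: (s, d) for a, s, d in zip(ids, sires, dams)}
        for p in extra:
            par[p] = (None, None)
        order = _toposort(list(par), par)
        idx = {a: i for i, a in enumerate(order)}
        sire_ix = np.array(
            [idx[par[a][0]] if par[a][0] is not None else UNKNOWN for a in order],
            dtype=np.int64,
        )
        dam_ix = np.array(
            [idx[par[a][1]] if par[a][1] is not None else UNKNOWN for a in order],
            dtype=np.int64,
        )
        sex_arr = None
        if sex_map is not None:
            sex_arr = np.array([sex_map.get(a, "") for a in order], dtype=object)
        gen_arr = None
        if gen_map is not None:
            gen_arr = np.array(
                [gen_map.get(a, -1) for a in order], dtype=np.int64
            )
        return cls(order, sire_ix, dam_ix, sex_arr, gen_arr, idx)

    # -- basic API ---------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.ids)

    def __len__(self) -> int:
        return self.n

    def indices_of(self, animals) -> np.ndarray:
        try:
            return np.array([self.id_to_index[a] for a in animals], dtype=np.int64)
        except KeyError as e:  # pragma: no cover - message only
            raise PedigreeError(f"animal {e.args[0]!r} not in pedigree") from None

    def founders(self) -> np.ndarray:
        return np.flatnonzero((self.sire == UNKNOWN) & (self.dam == UNKNOWN))

    def _validate(self):
        n = self.n
        for name, arr in (("sire", self.sire), ("dam", self.dam)):
            bad = np.flatnonzero((arr >= np.arange(n)) & (arr != UNKNOWN))
            if bad.size:
                raise PedigreeError(
                    f"{name} of animal {self.ids[bad[0]]!r} does not precede it"
                )


def _norm_parent(p):
    if p is None:
        return None
    if isinstance(p, float) and np.isnan(p):
        return None
    if p in (0, "0", "NA", "na", ""):
        return None
    return p


def _toposort(nodes, parents):
    """Stable topological sort (Kahn's algorithm, input order preserved).

    Animals become available once both parents are placed; among
    available animals the original input order decides, so two files
    listing the same pedigree in different row orders give the same
    ordered pedigree.  Raises on cycles, naming an animal on one.
    """
    import heapq

    pos = {a: i for i, a in enumerate(nodes)}
    children: dict = {a: [] for a in nodes}
    npar = {}
    for a in nodes:
        k = 0
        for p in parents[a]:
            if p is not None:
                children[p].append(a)
                k += 1
        npar[a] = k
    heap = [pos[a] for a in nodes if npar[a] == 0]
    heapq.heapify(heap)
    order = []
    while heap:
        a = nodes[heapq.heappop(heap)]
        order.append(a)
        for c in children[a]:
            npar[c] -= 1
            if npar[c] == 0:
                heapq.heappush(heap, pos[c])
    if len(order) < len(nodes):
        left = set(nodes) - set(order)
        raise PedigreeError(
            f"pedigree cycle detected through animal {sorted(left, key=lambda x: pos[x])[0]!r}"
        )
    return order


def read_pedigree(path) -> Pedigree:
    """Read a delimited pedigree file (animal sire dam [sex] [generation]).

    Whitespace- or comma-separated; ``0`` or ``NA`` denote an unknown
    parent.  Rows may appear in any order; the returned pedigree is
    topologically sorted and keeps the original identifiers.
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None, dtype=str,
                     comment="#", skip_blank_lines=True)
    if df.shape[1] < 3:
        raise PedigreeError("pedigree file needs >= 3 columns (animal sire dam)")
    ids = df.iloc[:, 0].tolist()
    sires = df.iloc[:, 1].tolist()
    dams = df.iloc[:, 2].tolist()
    sex = df.iloc[:, 3].tolist() if df.shape[1] > 3 else None
    gen = (
        df.iloc[:, 4].astype(float).astype(int).tolist() if df.shape[1] > 4 else None
    )
    return Pedigree.from_parents(ids, sires, dams, sex=sex, generation=gen)


@dataclass
class RelationshipMatrix:
    """A relationship matrix over the animals of a pedigree.

    ``matrix`` is dense (``kind`` autosomal / x-linked) or sparse CSC
    (``kind`` autosomal-inverse).  ``inbreeding`` holds per-animal F.
    """

    matrix: object
    kind: str
    inbreeding: np.ndarray | None = None

    def toarray(self) -> np.ndarray:
        m = self.matrix
        return m.toarray() if sp.issparse(m) else np.asarray(m)


def additive_relationship_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Dense numerator relationship matrix A by the tabular method.

    ``A[i, j] = 0.5 * (A[i, sire(j)] + A[i, dam(j)])`` for ``i < j`` and
    ``A[j, j] = 1 + 0.5 * A[sire(j), dam(j)]``.
    """
    n = ped.n
    A = np.zeros((n, n))
    s, d = ped.sire, ped.dam
    for j in range(n):
        sj, dj = s[j], d[j]
        row = np.zeros(j)
        if sj != UNKNOWN:
            row += 0.5 * A[sj, :j]
        if dj != UNKNOWN:
            row += 0.5 * A[dj, :j]
        A[j, :j] = row
        A[:j, j] = row
        A[j, j] = 1.0 + (0.5 * A[sj, dj] if sj != UNKNOWN and dj != UNKNOWN else 0.0)
    F = np.diag(A) - 1.0
    return RelationshipMatrix(A, "autosomal", F)


def inbreeding_and_mendelian_variance(ped: Pedigree):
    """Inbreeding coefficients F and Mendelian-sampling variances d.

    Uses the decomposition ``A = T D T'`` where row i of T holds the
    expected gene contributions of the ancestors of i.  Rows are built
    in topological order as ``T_i = e_i + (T_sire + T_dam) / 2`` (sparse
    dicts), giving ``F_i = 0.5 * sum_a T_s[a] T_d[a] d_a`` (Meuwissen &
    Luo) and ``d_i = 0.5 - 0.25 (F_s + F_d)`` with the usual adjustments
    for unknown parents.
    """
    n = ped.n
    s, d = ped.sire, ped.dam
    F = np.zeros(n)
    dvar = np.ones(n)
    rows: list[dict] = []
    for i in range(n):
        si, di = s[i], d[i]
        if si != UNKNOWN and di != UNKNOWN:
            rs, rd = rows[si], rows[di]
            # a(s,d) = sum_a T_s[a] T_d[a] d_a
            if len(rs) > len(rd):
                rs, rd = rd, rs
            a_sd = sum(c * rd.get(a, 0.0) * dvar[a] for a, c in rs.items())
            F[i] = 0.5 * a_sd
            dvar[i] = 0.5 - 0.25 * (F[si] + F[di])
        elif si != UNKNOWN or di != UNKNOWN:
            p = si if si != UNKNOWN else di
            F[i] = 0.0
            dvar[i] = 0.75 - 0.25 * F[p]
        else:
            F[i] = 0.0
            dvar[i] = 1.0
        row: dict = {}
        for p in (si, di):
            if p != UNKNOWN:
                for a, c in rows[p].items():
                    row[a] = row.get(a, 0.0) + 0.5 * c
        row[i] = row.get(i, 0.0) + 1.0
        rows.append(row)
    return F, dvar


def additive_relationship_inverse(ped: Pedigree) -> RelationshipMatrix:
    """Sparse A-inverse by Henderson's rules with inbreeding.

    Each animal contributes at most 9 entries involving itself and its
    parents, scaled by the inverse Mendelian-sampling variance.
    """
    n = ped.n
    F, dvar = inbreeding_and_mendelian_variance(ped)
    s, d = ped.sire, ped.dam
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        k = 1.0 / dvar[i]
        si, di = s[i], d[i]
        add(i, i, k)
        for p in (si, di):
            if p != UNKNOWN:
                add(i, p, -0.5 * k)
                add(p, i, -0.5 * k)
                add(p, p, 0.25 * k)
        if si != UNKNOWN and di != UNKNOWN:
            add(si, di, 0.25 * k)
            add(di, si, 0.25 * k)
    Ainv = sp.csc_matrix(
        (np.array(vals), (np.array(rows), np.array(cols))), shape=(n, n)
    )
    return RelationshipMatrix(Ainv, "autosomal-inverse", F)


def x_relationship_matrix(ped: Pedigree) -> RelationshipMatrix:
    """X-chromosomal relationship matrix S (gametic dosage convention).

    ``Cov(z_i, z_j) = S_ij * 2pq`` for X-linked gene contents z (males
    carry one maternal copy, females one copy from each parent).
    Founder females have ``S_ii = 1``; every male has ``S_ii = 0.5``
    because a single allele copy is Bernoulli(p) with variance pq.
    Recursions (j later than i)::

        male j   : S_ij = S_{i, dam}/2                S_jj = 0.5
        female j : S_ij = S_{i, sire} + S_{i, dam}/2  S_jj = 1 + S_{sire, dam}

    Unknown parents contribute nothing (base-population founders).
    The gene-dropping covariance of simulated gene contents is the
    reference definition for this matrix.
    """
    if ped.sex is None:
        raise PedigreeError("sex is required for the X relationship matrix")
    sex = np.asarray(ped.sex)
    if not np.all(np.isin(sex, [MALE, FEMALE])):
        bad = ped.ids[int(np.flatnonzero(~np.isin(sex, [MALE, FEMALE]))[0])]
        raise PedigreeError(f"missing or invalid sex for animal {bad!r}")
    n = ped.n
    s, d = ped.sire, ped.dam
    S = np.zeros((n, n))
    for j in range(n):
        sj, dj = s[j], d[j]
        row = np.zeros(j)
        if sex[j] == MALE:
            if dj != UNKNOWN:
                row += 0.5 * S[dj, :j]
            S[j, j] = 0.5
        else:
            if sj != UNKNOWN:
                row += S[sj, :j]
            if dj != UNKNOWN:
                row += 0.5 * S[dj, :j]
            S[j, j] = 1.0
            if sj != UNKNOWN and dj != UNKNOWN:
                S[j, j] += S[sj, dj]
        S[j, :j] = row
        S[:j, j] = row
    return RelationshipMatrix(S, "x-linked")
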