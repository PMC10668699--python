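"""Pedigree parsing, inbreeding coefficients, and additive-relationship algebra.

The additive (numerator) relationship matrix ``A`` encodes the expected
proportion of alleles shared identical-by-descent between every pair of
animals; its diagonal is ``1 + F`` where ``F`` is Wright's inbreeding
coefficient.  The animal model only ever needs the sparse inverse of ``A``,
which Henderson's rules build in a single pedigree pass, with the
Quaas correction so inbred parents are handled exactly.

F is computed with the Meuwissen & Luo recursion (each animal's diagonal of
``A`` accumulated over its ancestor paths), which scales to studbook-size
pedigrees without ever forming ``A``.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "Pedigree",
    "PedigreeError",
    "parse_pedigree",
    "read_pedigree_csv",
    "inbreeding",
    "relationship_matrix",
    "a_inverse",
    "mendelian_sampling_variance",
    "write_inbreeding_csv",
    "write_ainverse_csv",
]

UNKNOWN = -1
#: codes accepted in input files for an unknown parent
_UNKNOWN_TOKENS = {"", "0", "0.0", "nan", "none", "na", "."}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicate ids...)."""


@dataclass(frozen=True)
class Pedigree:
    """A topologically sorted pedigree.

    Animals are stored so that every parent precedes its offspring;
    ``sire``/``dam`` hold positional indices into that order, ``UNKNOWN``
    (-1) marking an unknown parent. ``ids`` keeps the external identifiers,
    so the positional remapping is always recoverable.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    birth_year: np.ndarray | None = None
    sex: np.ndarray | None = None
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(
            self, "_index", {a: i for i, a in enumerate(self.ids)}
        )

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, animal_id) -> int:
        return self._index[animal_id]

    def is_founder(self) -> np.ndarray:
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    def generation_depth(self) -> np.ndarray:
        """Longest ancestor-path length per animal (founders = 0)."""
        depth = np.zeros(self.n, dtype=np.int64)
        for i in range(self.n):
            d = 0
            if self.sire[i] != UNKNOWN:
                d = depth[self.sire[i]] + 1
            if self.dam[i] != UNKNOWN:
                d = max(d, depth[self.dam[i]] + 1)
            depth[i] = d
        return depth

    def complete_generation_equivalents(self) -> np.ndarray:
        """Pedigree-completeness metadata: sum over ancestors of (1/2)^depth."""
        cge = np.zeros(self.n)
        for i in range(self.n):
            acc = 0.0
            for p in (self.sire[i], self.dam[i]):
                if p != UNKNOWN:
                    acc += 0.5 * (1.0 + cge[p])
            cge[i] = acc
        return cge


def _is_unknown(token) -> bool:
    if token is None:
        return True
    if isinstance(token, float) and np.isnan(token):
        return True
    return str(token).strip().lower() in _UNKNOWN_TOKENS


def parse_pedigree(table: pd.DataFrame) -> Pedigree:
    """Build a validated, topologically sorted :class:`Pedigree`.

    Parameters
    ----------
    table
        Rows with columns ``id, sire, dam`` and optionally ``birth_year``
        and ``sex``.  ``0``/empty/NaN in a parent field means unknown.
        Animals appearing only as parents are added as founders.

    Raises
    ------
    PedigreeError
        On duplicate ids or a parentage cycle (the error names one member
        of the cycle).
    """
    table = table.reset_index(drop=True)
    raw_ids = [str(v).strip() for v in table["id"]]
    if len(set(raw_ids)) != len(raw_ids):
        seen, dup = set(), None
        for a in raw_ids:
            if a in seen:
                dup = a
                break
            seen.add(a)
        raise PedigreeError(f"duplicate animal id: {dup!r}")

    parents: dict[str, tuple[str | None, str | None]] = {}
    meta_year: dict[str, int] = {}
    meta_sex: dict[str, str] = {}
    has_year = "birth_year" in table.columns
    has_sex = "sex" in table.columns
    for pos, row in table.iterrows():
        a = raw_ids[pos]
        s = None if _is_unknown(row["sire"]) else str(row["sire"]).strip()
        d = None if _is_unknown(row["dam"]) else str(row["dam"]).strip()
        parents[a] = (s, d)
        if has_year and not _is_unknown(row["birth_year"]):
            meta_year[a] = int(float(row["birth_year"]))
        if has_sex and not _is_unknown(row["sex"]):
            meta_sex[a] = str(row["sex"]).strip()

    # animals referenced only as parents become founders
    for a, (s, d) in list(parents.items()):
        for p in (s, d):
            if p is not None and p not in parents:
                parents[p] = (None, None)

    # Kahn topological sort; ties resolved by input order for determinism
    order_hint = {a: i for i, a in enumerate(parents)}
    children: dict[str, list[str]] = {a: [] for a in parents}
    n_par = {}
    for a, (s, d) in parents.items():
        deps = {p for p in (s, d) if p is not None}
        n_par[a] = len(deps)
        for p in deps:
            children[p].append(a)
    ready = [(order_hint[a], a) for a, k in n_par.items() if k == 0]
    heapq.heapify(ready)
    topo: list[str] = []
    while ready:
        _, a = heapq.heappop(ready)
        topo.append(a)
        for c in children[a]:
            n_par[c] -= 1
            if n_par[c] == 0:
                heapq.heappush(ready, (order_hint[c], c))
    if len(topo) != len(parents):
        stuck = next(a for a, k in n_par.items() if k > 0)
        raise PedigreeError(f"pedigree cycle detected involving animal {stuck!r}")

    idx = {a: i for i, a in enumerate(topo)}
    sire = np.full(len(topo), UNKNOWN, dtype=np.int64)
    dam = np.full(len(topo), UNKNOWN, dtype=np.int64)
    for a in topo:
        s, d = parents[a]
        if s is not None:
            sire[idx[a]] = idx[s]
        if d is not None:
            dam[idx[a]] = idx[d]
    year = None
    if meta_year:
        year = np.array([meta_year.get(a, -1) for a in topo], dtype=np.int64)
    sex = None
    if meta_sex:
        sex = np.array([meta_sex.get(a, "") for a in topo], dtype=object)
    return Pedigree(np.array(topo, dtype=object), sire, dam, year, sex)


def read_pedigree_csv(path) -> Pedigree:
    """Read a ``id,sire,dam[,birth_year,sex]`` CSV (header required)."""
    return parse_pedigree(pd.read_csv(path, dtype=str))


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Wright's inbreeding coefficients via the Meuwissen–Luo recursion.

    For each animal the diagonal of A is accumulated as
    ``A_ii = sum_j L_ij^2 D_j`` by walking its ancestor paths from the
    animal upwards, where ``D_j`` is the Mendelian-sampling variance of
    ancestor ``j``.  Founders (both parents unknown) have F = 0; an
    unknown parent side contributes nothing (treated as an unrelated,
    non-inbred founder).
    """
    n = ped.n
    F = np.zeros(n)
    D = np.ones(n)  # Mendelian sampling variance, filled in topological order
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        Di = 1.0
        if s != UNKNOWN:
            Di -= 0.25 * (1.0 + F[s])
        if d != UNKNOWN:
            Di -= 0.25 * (1.0 + F[d])
        D[i] = Di
        if s == UNKNOWN and d == UNKNOWN:
            F[i] = 0.0
            continue
        # accumulate A_ii over ancestor paths, processing ancestors in
        # decreasing topological index so each is expanded exactly once
        contrib: dict[int, float] = {i: 1.0}
        heap = [-i]
        a_ii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            lj = contrib.pop(j, 0.0)
            if lj == 0.0:
                continue
            a_ii += lj * lj * D[j]
            for p in (sire[j], dam[j]):
                if p != UNKNOWN:
                    if p not in contrib:
                        heapq.heappush(heap, -p)
                        contrib[p] = 0.0
                    contrib[p] += 0.5 * lj
        F[i] = a_ii - 1.0
    return F


def mendelian_sampling_variance(ped: Pedigree, F: np.ndarray | None = None) -> np.ndarray:
    """Within-family segregation variance ``d_i`` (as a fraction of sigma_u^2).

    1 for both parents unknown, ``0.75 - 0.25 F_s`` for one known parent,
    ``0.5 - 0.25 (F_s + F_d)`` for both known.
    """
    if F is None:
        F = inbreeding(ped)
    d = np.ones(ped.n)
    for i in range(ped.n):
        for p in (ped.sire[i], ped.dam[i]):
            if p != UNKNOWN:
                d[i] -= 0.25 * (1.0 + F[p])
    return d


def relationship_matrix(ped: Pedigree, dense_limit: int = 5000) -> np.ndarray:
    """Dense numerator relationship matrix A by the tabular method.

    ``a_{i,j} = 0.5 (a_{sire(i),j} + a_{dam(i),j})`` for ``j`` earlier in
    the order, and ``a_{i,i} = 1 + 0.5 a_{sire(i),dam(i)}``.

    Only for small pedigrees; above ``dense_limit`` animals use
    :func:`a_inverse`, which is what the sampler consumes anyway.
    """
    n = ped.n
    if n > dense_limit:
        raise ValueError(
            f"pedigree has {n} animals, above the dense limit {dense_limit}; "
            "use a_inverse() for the sparse inverse instead"
        )
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        row = np.zeros(i)
        if s != UNKNOWN:
            row += 0.5 * A[s, :i]
        if d != UNKNOWN:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        aii = 1.0
        if s != UNKNOWN and d != UNKNOWN:
            aii += 0.5 * A[s, d]
        A[i, i] = aii
    return A


def a_inverse(ped: Pedigree, F: np.ndarray | None = None) -> sparse.csr_matrix:
    """Sparse inverse of A by Henderson's rules with inbreeding (Quaas).

    Each animal contributes ``alpha = 1/d_i`` (the reciprocal of its
    Mendelian-sampling variance) to at most nine entries involving itself
    and its known parents.  A single pedigree pass, O(n) storage.

    Raises
    ------
    ValueError
        If any Mendelian-sampling variance is numerically <= 0 (only
        possible with a corrupt F vector).
    """
    if F is None:
        F = inbreeding(ped)
    d = mendelian_sampling_variance(ped, F)
    if np.any(d <= 1e-12):
        bad = ped.ids[int(np.argmax(d <= 1e-12))]
        raise ValueError(
            f"non-positive Mendelian sampling variance for animal {bad!r}"
        )
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(ped.n):
        alpha = 1.0 / d[i]
        add(i, i, alpha)
        pars = [p for p in (ped.sire[i], ped.dam[i]) if p != UNKNOWN]
        for p in pars:
            add(i, p, -0.5 * alpha)
            add(p, i, -0.5 * alpha)
        for p in pars:
            for q in pars:
                add(p, q, 0.25 * alpha)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(ped.n, ped.n))
    return Ainv.tocsr()


def write_inbreeding_csv(ped: Pedigree, F: np.ndarray, path) -> None:
    pd.DataFrame({"id": ped.ids, "F": F}).to_csv(path, index=False)


def write_ainverse_csv(ped: Pedigree, a_inv: sparse.spmatrix, path) -> None:
    """Lower-triangle coordinate triplets ``row,col,value`` with 0-based
    indices in pedigree order (id mapping recoverable from the pedigree CSV).
    """
    coo = sparse.tril(a_inv.tocoo())
    pd.DataFrame(
        {"row": coo.row, "col": coo.col, "value": coo.data}
    ).to_csv(path, index=False)
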