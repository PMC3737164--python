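"""Pedigrees, inbreeding, and the additive relationship matrix.

The additive genetic covariance between individuals implied by a pedigree is
``sigma_u^2 * A``, where ``A`` is the (numerator) relationship matrix.  Its
inverse is sparse — an individual's breeding value is conditionally
independent of everyone except its parents, offspring, and mates — and can be
assembled directly from the pedigree with Henderson's rules, extended by
Quaas to account for inbreeding.  This module provides:

* :class:`Pedigree` — validated, topologically ordered pedigree container;
* :func:`inbreeding_coefficients` — per-individual inbreeding coefficient
  ``F`` and Mendelian-sampling variance fraction ``d`` (Meuwissen–Luo);
* :func:`relationship_matrix` — dense ``A`` by the tabular method, intended
  as the small-pedigree oracle;
* :func:`a_inverse` — sparse ``A^{-1}`` used as the breeding-value prior
  precision;
* :func:`replicate_pedigree` — disjoint union of relabeled copies, useful
  for scaling studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

MISSING = -1

__all__ = [
    "MISSING",
    "Pedigree",
    "RelationshipFactors",
    "PedigreeError",
    "read_pedigree",
    "pedigree_from_parents",
    "inbreeding_coefficients",
    "relationship_matrix",
    "a_inverse",
    "replicate_pedigree",
    "write_a_inverse",
]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (duplicates, cycles, ...)."""


@dataclass(frozen=True)
class Pedigree:
    """A validated pedigree.

    ``ids`` preserves input order; ``sire_index``/``dam_index`` hold integer
    positions into ``ids`` (or :data:`MISSING`); ``generation_order`` is a
    topological permutation placing every parent before its offspring.
    """

    ids: tuple[str, ...]
    sire_index: np.ndarray
    dam_index: np.ndarray
    generation_order: np.ndarray
    index: dict[str, int] = field(repr=False, default_factory=dict)

    @property
    def n_p(self) -> int:
        return len(self.ids)

    def parents(self, i: int) -> tuple[int, int]:
        return int(self.sire_index[i]), int(self.dam_index[i])

    @property
    def founder_mask(self) -> np.ndarray:
        return (self.sire_index == MISSING) & (self.dam_index == MISSING)

    def to_frame(self) -> pd.DataFrame:
        ids = np.asarray(self.ids, dtype=object)
        sire = np.where(self.sire_index == MISSING, "0", ids[np.clip(self.sire_index, 0, None)])
        dam = np.where(self.dam_index == MISSING, "0", ids[np.clip(self.dam_index, 0, None)])
        return pd.DataFrame({"id": ids, "sire": sire, "dam": dam})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _toposort(sire: np.ndarray, dam: np.ndarray, ids) -> np.ndarray:
    """Kahn's algorithm over the parent->offspring DAG; raises on cycles."""
    n = len(sire)
    indeg = np.zeros(n, dtype=int)
    children: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        for p in (sire[i], dam[i]):
            if p != MISSING:
                children[p].append(i)
                indeg[i] += 1
    stack = [i for i in range(n) if indeg[i] == 0]
    order = []
    while stack:
        i = stack.pop()
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                stack.append(c)
    if len(order) != n:
        bad = min((i for i in range(n) if indeg[i] > 0), default=0)
        raise PedigreeError(
            f"pedigree contains a cycle involving individual {ids[bad]!r}"
        )
    return np.asarray(order, dtype=int)


def pedigree_from_parents(ids, sires, dams) -> Pedigree:
    """Build a :class:`Pedigree` from parallel id/sire/dam sequences.

    Unknown parents are ``None``, ``""``, ``"0"``, ``"NA"`` or ``nan``.
    """
    ids = [str(x) for x in ids]
    index: dict[str, int] = {}
    for i, name in enumerate(ids):
        if name in index:
            raise PedigreeError(f"duplicate individual id {name!r}")
        index[name] = i

    def resolve(values, role):
        out = np.full(len(ids), MISSING, dtype=int)
        for i, v in enumerate(values):
            if v is None or (isinstance(v, float) and np.isnan(v)):
                continue
            s = str(v).strip()
            if s in ("", "0", "NA", "nan"):
                continue
            if s not in index:
                raise PedigreeError(
                    f"{role} {s!r} of individual {ids[i]!r} is not in the id column"
                )
            out[i] = index[s]
        return out

    sire = resolve(sires, "sire")
    dam = resolve(dams, "dam")
    order = _toposort(sire, dam, ids)
    return Pedigree(tuple(ids), sire, dam, order, index)


def read_pedigree(path) -> Pedigree:
    """Read a pedigree CSV with columns ``id,sire,dam``.

    Unknown parents may be coded ``0``, empty, or ``NA``.  Input row order is
    preserved in ``ids``; offspring listed before their parents are fine.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"id", "sire", "dam"}
    if not required.issubset(df.columns):
        raise PedigreeError(f"pedigree file must have columns id,sire,dam; got {list(df.columns)}")
    return pedigree_from_parents(df["id"], df["sire"], df["dam"])


@dataclass(frozen=True)
class RelationshipFactors:
    """Inbreeding coefficients ``F`` and Mendelian-sampling fractions ``d``.

    ``d_i`` is the variance of individual *i*'s breeding value around its
    parent average, as a fraction of ``sigma_u^2``:

    * both parents unknown: ``d = 1``;
    * one known parent ``p``: ``d = 3/4 − F_p / 4``;
    * both known: ``d = 1/2 − (F_s + F_d) / 4``.
    """

    F: np.ndarray
    d: np.ndarray


def inbreeding_coefficients(ped: Pedigree) -> RelationshipFactors:
    """Compute ``F`` and ``d`` in one pass over ``generation_order``.

    Uses the Meuwissen–Luo decomposition ``A = L D L'``: for each individual
    the relevant row of ``L`` is accumulated over its ancestors, giving
    ``A_ii = sum_j L_ij^2 d_j`` and ``F_i = A_ii − 1`` without forming ``A``.
    """
    n = ped.n_p
    F = np.zeros(n)
    d = np.ones(n)
    # position in topological order, for descending ancestor traversal
    pos = np.empty(n, dtype=int)
    pos[ped.generation_order] = np.arange(n)
    sire, dam = ped.sire_index, ped.dam_index

    for i in ped.generation_order:
        s, dm = sire[i], dam[i]
        if s == MISSING and dm == MISSING:
            d[i] = 1.0
            F[i] = 0.0
            continue
        if s == MISSING or dm == MISSING:
            p = dm if s == MISSING else s
            d[i] = 0.75 - 0.25 * F[p]
        else:
            d[i] = 0.5 - 0.25 * (F[s] + F[dm])
        # accumulate row i of L over its ancestor set, visiting in descending
        # topological position so each coefficient is complete when expanded
        vals: dict[int, float] = {i: 1.0}
        frontier = [i]
        while frontier:
            j = frontier.pop()
            for p in (sire[j], dam[j]):
                if p != MISSING and p not in vals:
                    vals[p] = 0.0
                    frontier.append(p)
        for j in sorted(vals, key=lambda k: -pos[k]):
            lj = vals[j]
            if lj == 0.0:
                continue
            for p in (sire[j], dam[j]):
                if p != MISSING:
                    vals[p] += 0.5 * lj
        F[i] = sum(v * v * d[j] for j, v in vals.items()) - 1.0
    return RelationshipFactors(F=F, d=d)


def relationship_matrix(ped: Pedigree, *, max_n: int = 2000) -> np.ndarray:
    """Dense relationship matrix ``A`` by the tabular method (oracle use).

    ``A_ii = 1 + A_{s(i),d(i)}/2`` and, for j earlier than i,
    ``A_ij = (A_{j,s(i)} + A_{j,d(i)}) / 2``.  Guarded to small pedigrees.
    """
    n = ped.n_p
    if n > max_n:
        raise PedigreeError(f"dense relationship matrix guarded to n_p <= {max_n}; got {n}")
    A = np.zeros((n, n))
    sire, dam = ped.sire_index, ped.dam_index
    for i in ped.generation_order:
        s, dm = sire[i], dam[i]
        row = np.zeros(n)
        if s != MISSING:
            row += 0.5 * A[s]
        if dm != MISSING:
            row += 0.5 * A[dm]
        A[i, :] = row
        A[:, i] = row
        aii = 1.0
        if s != MISSING and dm != MISSING:
            aii += 0.5 * A[s, dm]
        A[i, i] = aii
    return A


def a_inverse(ped: Pedigree, factors: RelationshipFactors | None = None) -> sp.csc_matrix:
    """Sparse ``A^{-1}`` by Henderson/Quaas rules with inbreeding.

    For each individual ``i`` with Mendelian-sampling fraction ``d_i`` and
    ``alpha_i = 1/d_i``: add ``alpha_i`` at ``(i,i)``, ``−alpha_i/2`` at each
    (i, known parent) pair (both triangles), and ``alpha_i/4`` at each ordered
    pair of known parents (the diagonal when sire = dam).
    """
    if factors is None:
        factors = inbreeding_coefficients(ped)
    n = ped.n_p
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    sire, dam = ped.sire_index, ped.dam_index
    alpha = 1.0 / factors.d
    for i in range(n):
        a = alpha[i]
        parents = [p for p in (sire[i], dam[i]) if p != MISSING]
        rows.append(i)
        cols.append(i)
        vals.append(a)
        for p in parents:
            rows += [i, p]
            cols += [p, i]
            vals += [-a / 2.0, -a / 2.0]
        for p in parents:
            for q in parents:
                rows.append(p)
                cols.append(q)
                vals.append(a / 4.0)
    M = sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
    return M.tocsc()


def replicate_pedigree(ped: Pedigree, k: int) -> Pedigree:
    """Disjoint union of ``k`` relabeled copies (copy tag appended to ids)."""
    if k < 1:
        raise ValueError(f"replication factor must be >= 1, got {k}")
    if k == 1:
        return ped
    n = ped.n_p
    ids: list[str] = []
    sire = np.empty(n * k, dtype=int)
    dam = np.empty(n * k, dtype=int)
    order = np.empty(n * k, dtype=int)
    for c in range(k):
        off = c * n
        ids.extend(f"{name}#r{c + 1}" for name in ped.ids)
        sire[off:off + n] = np.where(ped.sire_index == MISSING, MISSING, ped.sire_index + off)
        dam[off:off + n] = np.where(ped.dam_index == MISSING, MISSING, ped.dam_index + off)
        order[off:off + n] = ped.generation_order + off
    index = {name: i for i, name in enumerate(ids)}
    return Pedigree(tuple(ids), sire, dam, order, index)


def write_a_inverse(path, Ainv: sp.spmatrix) -> None:
    """Export A^{-1} as coordinate text: 1-based ``row col value``, upper triangle."""
    coo = sp.triu(Ainv).tocoo()
    with open(path, "w") as fh:
        fh.write(f"% symmetric {Ainv.shape[0]} x {Ainv.shape[1]}\n")
        for r, c, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{r + 1} {c + 1} {v:.12g}\n")
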