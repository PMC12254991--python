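"""Pedigree handling and the numerator relationship matrix A.

The polygenic term of the GWAS model is ``u ~ N(0, A (x) U)`` where A is the
pedigree-expected additive relationship matrix.  A is built by the tabular
(recursive) method:

    a(i, j) = 1/2 [a(j, s_i) + a(j, d_i)]      for j < i
    a(i, i) = 1 + 1/2 a(s_i, d_i)

with unknown parents contributing zero (missing parent = unrelated base
individual; no genetic groups).  The matrix is kept dense: the pedigrees this
package targets are desk-scale (a few thousand animals), where dense algebra
is simpler and exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "PedigreeError",
    "Pedigree",
    "read_pedigree",
    "build_numerator_relationship",
    "factor_relationship",
]


class PedigreeError(ValueError):
    """Malformed pedigree: cycles, missing parents, duplicate animals."""


@dataclass
class Pedigree:
    """Topologically sorted pedigree.

    ``sire_idx``/``dam_idx`` are positions into ``animals`` (-1 = unknown),
    with every parent preceding its offspring.
    """

    animals: list = field(default_factory=list)
    sire_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    dam_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __len__(self) -> int:
        return len(self.animals)

    def index_of(self, animal_ids) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.animals)}
        try:
            return np.array([lookup[a] for a in animal_ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message path
            raise PedigreeError(f"animal {exc.args[0]!r} not in pedigree") from exc

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire_idx < 0) & (self.dam_idx < 0)

    def to_frame(self) -> pd.DataFrame:
        def name(ix):
            return [self.animals[i] if i >= 0 else 0 for i in ix]

        return pd.DataFrame(
            {"animal": self.animals, "sire": name(self.sire_idx), "dam": name(self.dam_idx)}
        )

    @classmethod
    def from_records(cls, records) -> "Pedigree":
        """Build from (animal, sire, dam) triples; 0/None/NaN/'' = unknown.

        Records may arrive in any order; they are topologically sorted.
        Parents that appear only as parents are added as founders.
        """

        def is_unknown(x):
            if x is None:
                return True
            if isinstance(x, float) and np.isnan(x):
                return True
            return x in (0, "0", "")

        triples = []
        seen = set()
        for animal, sire, dam in records:
            if is_unknown(animal):
                raise PedigreeError("animal id may not be the unknown marker")
            if animal in seen:
                raise PedigreeError(f"duplicate animal id {animal!r}")
            seen.add(animal)
            triples.append(
                (animal, None if is_unknown(sire) else sire, None if is_unknown(dam) else dam)
            )
        parents = {p for _, s, d in triples for p in (s, d) if p is not None}
        for p in sorted(parents - seen, key=repr):
            triples.append((p, None, None))
            seen.add(p)

        # Kahn topological sort: parents before offspring.
        par = {a: (s, d) for a, s, d in triples}
        children = {a: [] for a in par}
        indeg = {a: sum(p is not None for p in par[a]) for a in par}
        for a, (s, d) in par.items():
            for p in (s, d):
                if p is not None:
                    children[p].append(a)
        queue = sorted((a for a in par if indeg[a] == 0), key=repr)
        order = []
        while queue:
            a = queue.pop(0)
            order.append(a)
            for ch in children[a]:
                indeg[ch] -= 1
                if indeg[ch] == 0:
                    queue.append(ch)
        if len(order) != len(par):
            raise PedigreeError("pedigree contains a cycle (an animal is its own ancestor)")

        pos = {a: i for i, a in enumerate(order)}
        sire_ix = np.array([pos[par[a][0]] if par[a][0] is not None else -1 for a in order])
        dam_ix = np.array([pos[par[a][1]] if par[a][1] is not None else -1 for a in order])
        return cls(order, sire_ix.astype(np.int64), dam_ix.astype(np.int64))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        cols = [c for c in ("animal", "sire", "dam") if c in df.columns]
        if len(cols) != 3:
            raise PedigreeError("pedigree table needs columns animal, sire, dam")
        return cls.from_records(df[["animal", "sire", "dam"]].itertuples(index=False))


def read_pedigree(path) -> Pedigree:
    """Read a pedigree CSV (animal, sire, dam; 0 or empty = unknown)."""
    df = pd.read_csv(path)
    return Pedigree.from_frame(df)


@njit(cache=True)
def _tabular_A(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    n = sire.shape[0]
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        for j in range(i):
            a = 0.0
            if s >= 0:
                a += A[j, s]
            if d >= 0:
                a += A[j, d]
            A[i, j] = A[j, i] = 0.5 * a
        aii = 1.0
        if s >= 0 and d >= 0:
            aii += 0.5 * A[s, d]
        A[i, i] = aii
    return A


def build_numerator_relationship(ped: Pedigree) -> np.ndarray:
    """Numerator relationship matrix over ``ped.animals`` (tabular method)."""
    if len(ped) == 0:
        return np.zeros((0, 0))
    return _tabular_A(ped.sire_idx, ped.dam_idx)


def factor_relationship(A: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Matrix square root L with L @ L.T == A.

    Cholesky when A is positive definite; symmetric-eigendecomposition
    fallback (negative eigenvalues clipped at zero) for the semi-definite
    case.  Raises on asymmetry beyond ``tol``.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise PedigreeError("relationship matrix must be square")
    if A.size and np.max(np.abs(A - A.T)) > tol:
        raise PedigreeError("relationship matrix is not symmetric")
    try:
        return np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh((A + A.T) / 2.0)
        if w.size and w.min() < -1e-6 * max(1.0, abs(w.max())):
            raise PedigreeError("relationship matrix has substantially negative eigenvalues")
        return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
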