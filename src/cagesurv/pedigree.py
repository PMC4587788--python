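"""Pedigree container and numerator relationship matrix (A) machinery.

The numerator relationship matrix A holds expected additive genetic
relationships between individuals derived from a sire/dam pedigree:
founders are taken as unrelated and non-inbred, a_ii = 1 + F_i with F_i the
inbreeding coefficient, and off-diagonals follow the tabular method.  The
sparse inverse of A is built directly from pedigree structure using
Henderson's rules with exact inbreeding (Meuwissen & Luo style diagonal
computation), which is what mixed-model equations consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

#: Reserved id for an unknown parent in external tables.
UNKNOWN_PARENT = 0


class PedigreeError(ValueError):
    """Structural pedigree problem: cycle, missing parent, duplicate id."""


@dataclass
class Pedigree:
    """Topologically sorted pedigree.

    Attributes
    ----------
    ids:
        Individual ids in processing order (parents precede offspring).
    sire_idx, dam_idx:
        Positional index of each individual's sire/dam, ``-1`` if unknown.
    generation:
        Integer generation index per individual (0 = founders).
    sex:
        ``"M"``/``"F"`` per individual.
    """

    ids: np.ndarray
    sire_idx: np.ndarray
    dam_idx: np.ndarray
    generation: np.ndarray
    sex: np.ndarray
    _pos: dict = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self._pos:
            self._pos = {i: k for k, i in enumerate(self.ids)}
        if len(self._pos) != len(self.ids):
            raise PedigreeError("duplicate individual ids in pedigree")

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, ids) -> np.ndarray:
        """Positional indices of ``ids`` (raises KeyError if absent)."""
        return np.asarray([self._pos[i] for i in np.atleast_1d(ids)])

    # -- construction ---------------------------------------------------

    @classmethod
    def from_records(cls, records) -> "Pedigree":
        """Build from (id, sire, dam, generation, sex) tuples.

        Input order is arbitrary: a stable topological sort is applied, so
        unsorted files are accepted rather than rejected.  ``0`` marks an
        unknown parent.
        """
        df = pd.DataFrame(
            records, columns=["id", "sire", "dam", "generation", "sex"]
        )
        return cls.from_frame(df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        required = ["id", "sire", "dam"]
        for col in required:
            if col not in df.columns:
                raise PedigreeError(f"pedigree table lacks column {col!r}")
        df = df.copy()
        if "generation" not in df.columns:
            df["generation"] = 0
        if "sex" not in df.columns:
            df["sex"] = "F"
        ids = df["id"].to_numpy()
        if len(set(ids)) != len(ids):
            raise PedigreeError("duplicate individual ids in pedigree")
        known = set(ids)
        for col in ("sire", "dam"):
            bad = set(df[col]) - known - {UNKNOWN_PARENT}
            if bad:
                raise PedigreeError(
                    f"{col} ids absent from pedigree: {sorted(bad)[:5]}"
                )
        order = _topological_order(df)
        df = df.iloc[order].reset_index(drop=True)
        pos = {i: k for k, i in enumerate(df["id"])}
        sire_idx = np.asarray(
            [pos.get(s, -1) if s != UNKNOWN_PARENT else -1 for s in df["sire"]],
            dtype=np.int64,
        )
        dam_idx = np.asarray(
            [pos.get(d, -1) if d != UNKNOWN_PARENT else -1 for d in df["dam"]],
            dtype=np.int64,
        )
        return cls(
            ids=df["id"].to_numpy(),
            sire_idx=sire_idx,
            dam_idx=dam_idx,
            generation=df["generation"].to_numpy(dtype=np.int64),
            sex=df["sex"].to_numpy(dtype=object),
            _pos=pos,
        )

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        """Read the pedigree CSV dialect: ``id,sire,dam,generation,sex``."""
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        sire = np.where(
            self.sire_idx >= 0, self.ids[np.maximum(self.sire_idx, 0)], UNKNOWN_PARENT
        )
        dam = np.where(
            self.dam_idx >= 0, self.ids[np.maximum(self.dam_idx, 0)], UNKNOWN_PARENT
        )
        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": sire,
                "dam": dam,
                "generation": self.generation,
                "sex": self.sex,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def subset_closure(self, ids) -> "Pedigree":
        """Sub-pedigree of ``ids`` and all their ancestors.

        The subset is ancestor-closed, so relationships computed on it agree
        with those computed on the full pedigree.
        """
        keep = np.zeros(len(self), dtype=bool)
        stack = list(self.index_of(ids))
        while stack:
            k = stack.pop()
            if keep[k]:
                continue
            keep[k] = True
            for p in (self.sire_idx[k], self.dam_idx[k]):
                if p >= 0 and not keep[p]:
                    stack.append(p)
        frame = self.to_frame().iloc[np.flatnonzero(keep)]
        return Pedigree.from_frame(frame.reset_index(drop=True))

    # -- quantities -----------------------------------------------------

    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients F_i = kinship(sire_i, dam_i).

        Memoised pairwise-kinship recursion; exact for arbitrary depth.
        """
        sire, dam = self.sire_idx, self.dam_idx
        F = np.zeros(len(self))
        memo: dict = {}

        def kin(a: int, b: int) -> float:
            if a < 0 or b < 0:
                return 0.0
            if a < b:
                a, b = b, a
            key = (a, b)
            got = memo.get(key)
            if got is not None:
                return got
            if a == b:
                val = 0.5 * (1.0 + F[a])
            else:
                val = 0.5 * (kin(sire[a], b) + kin(dam[a], b))
            memo[key] = val
            return val

        for i in range(len(self)):
            F[i] = kin(sire[i], dam[i])
        return F


def _topological_order(df: pd.DataFrame) -> np.ndarray:
    """Stable Kahn topological order; raises on cycles (self-ancestry)."""
    ids = list(df["id"])
    pos = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    indeg = np.zeros(n, dtype=np.int64)
    children: list[list[int]] = [[] for _ in range(n)]
    for k, (s, d) in enumerate(zip(df["sire"], df["dam"])):
        for p in (s, d):
            if p != UNKNOWN_PARENT:
                children[pos[p]].append(k)
                indeg[k] += 1
    from collections import deque

    queue = deque(sorted(np.flatnonzero(indeg == 0)))
    out = []
    while queue:
        k = queue.popleft()
        out.append(k)
        for c in children[k]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(out) != n:
        raise PedigreeError("pedigree contains a cycle (individual is its own ancestor)")
    return np.asarray(out)


@dataclass
class RelationshipMatrix:
    """Square symmetric additive-relationship matrix over an ordered id set.

    ``values`` is dense (A itself) or ``scipy.sparse`` (its inverse, which
    is structurally sparse under Henderson's rules).
    """

    ids: np.ndarray
    values: object

    def toarray(self) -> np.ndarray:
        v = self.values
        return v.toarray() if sparse.issparse(v) else np.asarray(v)

    @property
    def shape(self):
        return self.values.shape


def build_A(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    a_ij = 0.5 (a_{s(i)j} + a_{d(i)j}) for j preceding i, and
    a_ii = 1 + 0.5 a_{s(i)d(i)}; unknown-parent contributions are zero
    (founders unrelated and non-inbred).
    """
    n = len(pedigree)
    A = np.zeros((n, n))
    s, d = pedigree.sire_idx, pedigree.dam_idx
    for i in range(n):
        row = np.zeros(i)
        if s[i] >= 0:
            row += 0.5 * A[s[i], :i]
        if d[i] >= 0:
            row += 0.5 * A[d[i], :i]
        A[i, :i] = row
        A[:i, i] = row
        asd = A[s[i], d[i]] if (s[i] >= 0 and d[i] >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * asd
    return RelationshipMatrix(ids=pedigree.ids, values=A)


def build_A_inverse(pedigree: Pedigree) -> RelationshipMatrix:
    """Sparse inverse of A by Henderson's rules with exact inbreeding.

    The Mendelian-sampling variance of individual i is
    d_i = 0.5 − 0.25 (F_s + F_d) with both parents known,
    0.75 − 0.25 F_p with one parent known, and 1 for founders; each
    individual contributes the usual {1, −1/2, 1/4} pattern scaled by 1/d_i.
    """
    F = pedigree.inbreeding()
    s, d = pedigree.sire_idx, pedigree.dam_idx
    n = len(pedigree)
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        parents = [p for p in (s[i], d[i]) if p >= 0]
        if len(parents) == 2:
            dv = 0.5 - 0.25 * (F[s[i]] + F[d[i]])
        elif len(parents) == 1:
            dv = 0.75 - 0.25 * F[parents[0]]
        else:
            dv = 1.0
        alpha = 1.0 / dv
        add(i, i, alpha)
        for p in parents:
            add(i, p, -alpha / 2.0)
            add(p, i, -alpha / 2.0)
        for p in parents:
            for q in parents:
                add(p, q, alpha / 4.0)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
    return RelationshipMatrix(ids=pedigree.ids, values=Ainv)
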