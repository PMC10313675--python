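"""Pedigree ingestion, validation, trimming and relationship-matrix algebra.

A :class:`Pedigree` is the substrate for every genetic computation in this
package: the numerator relationship matrix **A** used by the animal model,
inbreeding coefficients used by gene dropping, and the structural summaries
(pedigree depth, half-sibship sizes) that describe a racehorse population.

Individuals are stored topologically sorted (parents before offspring), with
unknown parents treated as founders drawn from the base population.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: tokens accepted as "unknown parent" in pedigree files
UNKNOWN_TOKENS = {"", "0", "NA", "na", "nan", "None"}

#: above this size the relationship matrix is returned in sparse storage
DENSE_LIMIT = 5000


class PedigreeError(ValueError):
    """Structural error in a pedigree (cycle, duplicate id, sex conflict...)."""


# ---------------------------------------------------------------------------
# core container
# ---------------------------------------------------------------------------


@dataclass
class Pedigree:
    """Topologically sorted pedigree.

    Attributes
    ----------
    ids : ndarray of str
        Individual identifiers, parents always before offspring.
    sire, dam : ndarray of int
        Positional index of each individual's sire/dam, ``-1`` if unknown.
    birth_year : ndarray of float
        Year of birth, ``nan`` if missing.
    sex : ndarray of str
        ``"M"``, ``"F"`` or ``"U"``.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    birth_year: np.ndarray
    sex: np.ndarray
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {i: k for k, i in enumerate(self.ids)}

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, item) -> bool:
        return item in self._index

    def position(self, ident) -> int:
        return self._index[ident]

    def positions(self, idents: Iterable) -> np.ndarray:
        return np.array([self._index[i] for i in idents], dtype=np.int64)

    @property
    def n(self) -> int:
        return len(self.ids)

    def is_founder(self) -> np.ndarray:
        return (self.sire < 0) & (self.dam < 0)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_records(
        cls,
        ids: Sequence,
        sires: Sequence,
        dams: Sequence,
        birth_years: Sequence | None = None,
        sexes: Sequence | None = None,
    ) -> "Pedigree":
        """Validate, topologically sort and build a pedigree.

        Parents referenced but not listed as individuals are appended as
        founders (standard treatment, logged).  Raises :class:`PedigreeError`
        on duplicate ids, an id used both as sire and dam, or a cycle.
        """
        ids = [str(i) for i in ids]
        sires = [None if _is_unknown(s) else str(s) for s in sires]
        dams = [None if _is_unknown(d) else str(d) for d in dams]

        seen: dict[str, int] = {}
        for k, i in enumerate(ids):
            if i in seen:
                raise PedigreeError(f"duplicate individual id {i!r}")
            seen[i] = k

        sire_set = {s for s in sires if s is not None}
        dam_set = {d for d in dams if d is not None}
        both = sire_set & dam_set
        if both:
            raise PedigreeError(
                f"ids used both as sire and as dam: {sorted(both)[:5]}"
            )

        n0 = len(ids)
        birth_years = list(birth_years) if birth_years is not None else [None] * n0
        sexes = list(sexes) if sexes is not None else [None] * n0

        # implicit founders for parents never listed as individuals
        phantom = [p for p in list(sire_set | dam_set) if p not in seen]
        if phantom:
            logger.info("adding %d parents not listed as individuals as founders",
                        len(phantom))
            for p in sorted(phantom):
                seen[p] = len(ids)
                ids.append(p)
                sires.append(None)
                dams.append(None)
                birth_years.append(None)
                sexes.append("M" if p in sire_set else "F")

        n = len(ids)
        sire_idx = np.array([-1 if s is None else seen[s] for s in sires])
        dam_idx = np.array([-1 if d is None else seen[d] for d in dams])
        for k in range(n):
            if sire_idx[k] == k or dam_idx[k] == k:
                raise PedigreeError(f"individual {ids[k]!r} is its own parent")

        order = _toposort(ids, sire_idx, dam_idx)

        remap = np.empty(n, dtype=np.int64)
        remap[order] = np.arange(n)

        sex_arr = np.array(
            [_norm_sex(sexes[k]) for k in order], dtype=object
        )
        by_arr = np.array(
            [np.nan if birth_years[k] is None or (isinstance(birth_years[k], float) and np.isnan(birth_years[k]))
             else float(birth_years[k]) for k in order]
        )
        ped = cls(
            ids=np.array([ids[k] for k in order], dtype=object),
            sire=np.array([-1 if sire_idx[k] < 0 else remap[sire_idx[k]] for k in order]),
            dam=np.array([-1 if dam_idx[k] < 0 else remap[dam_idx[k]] for k in order]),
            birth_year=by_arr,
            sex=sex_arr,
        )
        # fill unknown sexes from parental roles
        used_as_sire = set(ped.sire[ped.sire >= 0])
        used_as_dam = set(ped.dam[ped.dam >= 0])
        for k in range(ped.n):
            if ped.sex[k] == "U":
                if k in used_as_sire:
                    ped.sex[k] = "M"
                elif k in used_as_dam:
                    ped.sex[k] = "F"
        return ped

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        cols = {c.lower(): c for c in df.columns}
        for required in ("id", "sire", "dam"):
            if required not in cols:
                raise PedigreeError(f"pedigree table lacks column {required!r}")
        return cls.from_records(
            df[cols["id"]].tolist(),
            df[cols["sire"]].tolist(),
            df[cols["dam"]].tolist(),
            df[cols["birth_year"]].tolist() if "birth_year" in cols else None,
            df[cols["sex"]].tolist() if "sex" in cols else None,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": [self.ids[s] if s >= 0 else "" for s in self.sire],
                "dam": [self.ids[d] if d >= 0 else "" for d in self.dam],
                "birth_year": [
                    "" if np.isnan(y) else int(y) for y in self.birth_year
                ],
                "sex": self.sex,
            }
        )


def _is_unknown(x) -> bool:
    if x is None:
        return True
    if isinstance(x, float) and np.isnan(x):
        return True
    return str(x).strip() in UNKNOWN_TOKENS


def _norm_sex(s) -> str:
    if s is None or (isinstance(s, float) and np.isnan(s)):
        return "U"
    s = str(s).strip().upper()
    if s in {"M", "MALE", "1"}:
        return "M"
    if s in {"F", "FEMALE", "2"}:
        return "F"
    return "U"


def _toposort(ids, sire_idx, dam_idx) -> list[int]:
    """Kahn's algorithm, stable in input order; raises on cycles."""
    n = len(ids)
    indeg = np.zeros(n, dtype=np.int64)
    children: list[list[int]] = [[] for _ in range(n)]
    for k in range(n):
        for p in (sire_idx[k], dam_idx[k]):
            if p >= 0:
                children[p].append(k)
                indeg[k] += 1
    heap = [k for k in range(n) if indeg[k] == 0]
    heapq.heapify(heap)
    order: list[int] = []
    while heap:
        k = heapq.heappop(heap)
        order.append(k)
        for c in children[k]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(heap, c)
    if len(order) < n:
        member = ids[min(k for k in range(n) if indeg[k] > 0)]
        raise PedigreeError(
            f"pedigree contains a cycle involving individual {member!r}"
        )
    return order


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def read_pedigree(path, sep: str = ",") -> Pedigree:
    """Read a delimited pedigree file (columns id,sire,dam[,birth_year,sex]).

    Empty string, ``0`` and ``NA`` all denote an unknown parent.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if not {"id", "sire", "dam"} <= {c.lower() for c in df.columns}:
        raise PedigreeError(
            f"{path}: header must name id, sire and dam columns, got {list(df.columns)}"
        )
    return Pedigree.from_frame(df)


def write_pedigree(ped: Pedigree, path, sep: str = ",") -> None:
    ped.to_frame().to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# trimming
# ---------------------------------------------------------------------------


def trim_pedigree(ped: Pedigree, phenotyped: Iterable) -> Pedigree:
    """Restrict a pedigree to informative individuals.

    Keeps every phenotyped individual together with all of its ancestors
    (the unobserved horses providing pedigree links), and nothing else.
    """
    phenotyped = set(map(str, phenotyped))
    missing = phenotyped - set(ped.ids)
    if missing:
        raise PedigreeError(
            f"phenotyped ids absent from pedigree: {sorted(missing)[:10]}"
        )
    keep = np.zeros(ped.n, dtype=bool)
    # reverse topological order: marking an individual marks its parents next
    for k in range(ped.n - 1, -1, -1):
        if ped.ids[k] in phenotyped:
            keep[k] = True
        if keep[k]:
            if ped.sire[k] >= 0:
                keep[ped.sire[k]] = True
            if ped.dam[k] >= 0:
                keep[ped.dam[k]] = True
    idx = np.flatnonzero(keep)
    remap = {old: new for new, old in enumerate(idx)}
    return Pedigree(
        ids=ped.ids[idx].copy(),
        sire=np.array([remap[s] if s >= 0 else -1 for s in ped.sire[idx]]),
        dam=np.array([remap[d] if d >= 0 else -1 for d in ped.dam[idx]]),
        birth_year=ped.birth_year[idx].copy(),
        sex=ped.sex[idx].copy(),
    )


# ---------------------------------------------------------------------------
# relationship matrix / inbreeding
# ---------------------------------------------------------------------------


@dataclass
class RelationshipMatrix:
    """Numerator relationship matrix A in pedigree order.

    ``a_ij = 2 * kinship(i, j)``; the diagonal is ``1 + F_i``.  Stored dense
    up to :data:`DENSE_LIMIT` individuals, sparse (CSR) above — the values
    are identical either way.
    """

    matrix: np.ndarray | sp.csr_matrix
    ids: np.ndarray

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def is_sparse(self) -> bool:
        return sp.issparse(self.matrix)

    def toarray(self) -> np.ndarray:
        return self.matrix.toarray() if self.is_sparse else self.matrix

    def diagonal(self) -> np.ndarray:
        return (
            np.asarray(self.matrix.diagonal())
            if self.is_sparse
            else np.diag(self.matrix).copy()
        )

    def inbreeding(self) -> np.ndarray:
        return self.diagonal() - 1.0


def relationship_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    ``a_ii = 1 + 0.5 * a_{sire,dam}``;  ``a_ij = 0.5 * (a_{j,sire(i)} +
    a_{j,dam(i)})``; unknown parents contribute zero (base-population
    founders).
    """
    A = _tabular_a(ped.sire, ped.dam)
    if ped.n > DENSE_LIMIT:
        return RelationshipMatrix(sp.csr_matrix(A), ped.ids.copy())
    return RelationshipMatrix(A, ped.ids.copy())


def _tabular_a(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    n = len(sire)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if i:
            v = np.zeros(i)
            if s >= 0:
                v += A[s, :i]
            if d >= 0:
                v += A[d, :i]
            v *= 0.5
            A[i, :i] = v
            A[:i, i] = v
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A


def inbreeding(ped: Pedigree) -> pd.Series:
    """Inbreeding coefficients ``F_i = a_ii - 1`` (founders have F = 0).

    Computed without building the full matrix: only kinships among actual
    mated pairs and their ancestors are evaluated.
    """
    memo: dict = {}
    F = np.array([kinship(ped, s, d, memo) if (s >= 0 and d >= 0) else 0.0
                  for s, d in zip(ped.sire, ped.dam)])
    return pd.Series(F, index=ped.ids, name="F")


def kinship(ped: Pedigree, i: int, j: int, _memo: dict | None = None) -> float:
    """Coefficient of kinship between positions i and j (recursive)."""
    if _memo is None:
        _memo = {}

    def f(a: int, b: int) -> float:
        if a < 0 or b < 0:
            return 0.0
        if a > b:
            a, b = b, a
        key = (a, b)
        if key in _memo:
            return _memo[key]
        if a == b:
            val = 0.5 * (1.0 + f(ped.sire[a], ped.dam[a]))
        else:
            # b is the later-born individual: recurse on its parents
            val = 0.5 * (f(a, ped.sire[b]) + f(a, ped.dam[b]))
        _memo[key] = val
        return val

    return f(i, j)


# ---------------------------------------------------------------------------
# structural summary
# ---------------------------------------------------------------------------


@dataclass
class PedigreeSummary:
    """Structural summary of a pedigree and its link to performance data."""

    n_individuals: int
    n_sires: int
    n_dams: int
    max_depth: int
    max_paternal_halfsib: int
    max_maternal_halfsib: int
    n_sires_with_offspring_records: int

    def to_series(self) -> pd.Series:
        return pd.Series(vars(self))


def pedigree_depth(ped: Pedigree) -> np.ndarray:
    """Generation number per individual; founders are generation 1."""
    depth = np.ones(ped.n, dtype=np.int64)
    for k in range(ped.n):
        for p in (ped.sire[k], ped.dam[k]):
            if p >= 0:
                depth[k] = max(depth[k], depth[p] + 1)
    return depth


def summarize_pedigree(
    ped: Pedigree, records: pd.DataFrame | None = None
) -> PedigreeSummary:
    """Table-1 style summary: counts, depth, largest half-sibships."""
    sire_counts = np.bincount(ped.sire[ped.sire >= 0], minlength=ped.n)
    dam_counts = np.bincount(ped.dam[ped.dam >= 0], minlength=ped.n)
    n_sires = int((sire_counts > 0).sum())
    n_dams = int((dam_counts > 0).sum())
    depth = int(pedigree_depth(ped).max()) if ped.n else 0

    n_sires_rec = 0
    if records is not None and len(records):
        rec_ids = set(map(str, records["horse"].unique()))
        rec_pos = {ped.position(i) for i in rec_ids if i in ped}
        sires_of_rec = {ped.sire[k] for k in rec_pos if ped.sire[k] >= 0}
        n_sires_rec = len(sires_of_rec)

    return PedigreeSummary(
        n_individuals=ped.n,
        n_sires=n_sires,
        n_dams=n_dams,
        max_depth=depth,
        max_paternal_halfsib=int(sire_counts.max()) if ped.n else 0,
        max_maternal_halfsib=int(dam_counts.max()) if ped.n else 0,
        n_sires_with_offspring_records=n_sires_rec,
    )
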