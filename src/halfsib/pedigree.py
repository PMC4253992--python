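"""Pedigree parsing and the additive (numerator) relationship matrix.

The additive relationship matrix A gives, for each pair of individuals,
twice the expected fraction of alleles shared identical by descent; its
diagonal is 1 + F where F is the inbreeding coefficient.  A (and its
inverse) defines the covariance of the polygenic random effect in the
animal models of :mod:`halfsib.models`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

UNKNOWN = "0"


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, duplicate id, ...)."""


@dataclass(frozen=True)
class PedigreeRecord:
    individual: str
    sire: str | None
    dam: str | None


@dataclass
class Pedigree:
    """Topologically sorted pedigree (parents always precede offspring).

    Unknown parents are stored as ``None``; individuals that appear only
    as parents are materialized as founder records.
    """

    records: list[PedigreeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index = {r.individual: i for i, r in enumerate(self.records)}
        if len(self._index) != len(self.records):
            raise PedigreeError("duplicate individual id in pedigree")

    @property
    def ids(self) -> list[str]:
        return [r.individual for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, individual: str) -> bool:
        return individual in self._index

    def index_of(self, individual: str) -> int:
        return self._index[individual]

    @classmethod
    def from_tuples(
        cls, triples: Iterable[tuple[str, str | None, str | None]], unknown: str = UNKNOWN
    ) -> "Pedigree":
        """Build a sorted pedigree from (individual, sire, dam) triples.

        Parents referenced but never listed as individuals are added as
        founders.  Raises :class:`PedigreeError` on duplicates or cycles
        (the error message names the individuals on the cycle).
        """
        triples = [
            (
                str(i),
                None if s in (unknown, None, "") else str(s),
                None if d in (unknown, None, "") else str(d),
            )
            for i, s, d in triples
        ]
        ids = [t[0] for t in triples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise PedigreeError(f"duplicate individual id(s): {', '.join(dup)}")
        parents: dict[str, tuple[str | None, str | None]] = {i: (s, d) for i, s, d in triples}
        referenced = {p for _, s, d in triples for p in (s, d) if p is not None}
        for p in sorted(referenced - set(parents)):
            parents[p] = (None, None)

        # Kahn's algorithm; anything left over sits on a cycle.
        order: list[str] = []
        remaining = dict(parents)
        placed: set[str] = set()
        while remaining:
            ready = [i for i, (s, d) in remaining.items() if
                     (s is None or s in placed) and (d is None or d in placed)]
            if not ready:
                raise PedigreeError(
                    "pedigree contains a cycle involving: " + ", ".join(sorted(remaining))
                )
            for i in sorted(ready, key=lambda x: (x not in parents, x)):
                order.append(i)
                placed.add(i)
                del remaining[i]
        return cls([PedigreeRecord(i, *parents[i]) for i in order])

    def with_founders(self, extra_ids: Sequence[str]) -> "Pedigree":
        """Return a pedigree extended with ``extra_ids`` added as founders."""
        new = [i for i in extra_ids if i not in self]
        if not new:
            return self
        log.warning("adding %d individual(s) absent from the pedigree as founders", len(new))
        return Pedigree(self.records + [PedigreeRecord(i, None, None) for i in new])

    def drop(self, individual: str) -> "Pedigree":
        """Remove a childless individual (used by pruning invariants)."""
        for r in self.records:
            if individual in (r.sire, r.dam):
                raise PedigreeError(f"{individual} has offspring and cannot be dropped")
        return Pedigree([r for r in self.records if r.individual != individual])


def read_pedigree(
    path: str | Path,
    unknown: str = UNKNOWN,
    columns: tuple[str, str, str] | tuple[int, int, int] = (0, 1, 2),
) -> Pedigree:
    """Read a whitespace/TSV pedigree with individual, sire, dam columns.

    A header line is detected when the first row's configured columns are
    non-numeric tokens repeated nowhere else as ids; alternatively pass
    column names in ``columns``.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if all(isinstance(c, str) for c in columns):
        header = [str(v).lower() for v in df.iloc[0]]
        wanted = [str(c).lower() for c in columns]
        if not set(wanted) <= set(header):
            raise PedigreeError(f"columns {columns} not found in header {header}")
        idx = [header.index(w) for w in wanted]
        df = df.iloc[1:]
    else:
        idx = list(columns)
        first = [str(v).lower() for v in df.iloc[0, idx]]
        if {"id", "individual", "animal"} & set(first):
            df = df.iloc[1:]
    triples = df.iloc[:, idx].itertuples(index=False, name=None)
    return Pedigree.from_tuples(triples, unknown=unknown)


def write_pedigree(ped: Pedigree, path: str | Path, unknown: str = UNKNOWN) -> None:
    with open(path, "w") as fh:
        fh.write("id\tsire\tdam\n")
        for r in ped.records:
            fh.write(f"{r.individual}\t{r.sire or unknown}\t{r.dam or unknown}\n")


@dataclass
class KinshipMatrix:
    """Additive relationship matrix (or its inverse) over ordered ids."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self._index = {v: i for i, v in enumerate(self.ids)}

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, ids: Sequence[str]) -> np.ndarray:
        idx = np.array([self._index[i] for i in ids])
        return self.values[np.ix_(idx, idx)]

    def indices(self, ids: Sequence[str]) -> np.ndarray:
        return np.array([self._index[i] for i in ids])


def build_A(ped: Pedigree) -> KinshipMatrix:
    """Tabular-method additive relationship matrix.

    a_ii = 1 + a(sire,dam)/2; a_ij = (a(j,sire_i) + a(j,dam_i))/2 for j
    preceding i; unknown parents contribute zero relationship.
    """
    n = len(ped)
    A = np.zeros((n, n))
    idx = ped._index
    for i, rec in enumerate(ped.records):
        s = idx[rec.sire] if rec.sire is not None else -1
        d = idx[rec.dam] if rec.dam is not None else -1
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return KinshipMatrix(ped.ids, A)


def inbreeding_coefficients(ped: Pedigree, A: KinshipMatrix | None = None) -> np.ndarray:
    """F per individual (pedigree order), F = a_ii - 1."""
    if A is None:
        A = build_A(ped)
    return np.diag(A.values) - 1.0


def build_A_inverse(ped: Pedigree, A: KinshipMatrix | None = None) -> KinshipMatrix:
    """Direct A-inverse by Henderson's rules with inbreeding.

    The Mendelian-sampling variance d_i uses parental inbreeding
    coefficients (0.5 - 0.25(F_s + F_d) with both parents known, 0.75 -
    0.25 F_p with one, 1 with none), so the result matches the dense
    inverse of :func:`build_A` exactly for any valid pedigree.
    """
    F = inbreeding_coefficients(ped, A)
    n = len(ped)
    Ainv = np.zeros((n, n))
    idx = ped._index
    for i, rec in enumerate(ped.records):
        s = idx[rec.sire] if rec.sire is not None else -1
        d = idx[rec.dam] if rec.dam is not None else -1
        if s >= 0 and d >= 0:
            di = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            di = 0.75 - 0.25 * F[p]
        else:
            di = 1.0
        if di <= 0:
            raise np.linalg.LinAlgError(
                f"non-positive Mendelian sampling variance for {rec.individual}"
            )
        alpha = 1.0 / di
        Ainv[i, i] += alpha
        for p in (s, d):
            if p >= 0:
                Ainv[p, i] -= alpha / 2
                Ainv[i, p] -= alpha / 2
        for p in (s, d):
            for q in (s, d):
                if p >= 0 and q >= 0:
                    Ainv[p, q] += alpha / 4
    return KinshipMatrix(ped.ids, Ainv)
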