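"""Pedigree structures, LINKAGE/PED I/O, relationship matrices, and bit complexity.

A pedigree is a directed family graph in which every member either has both
parents in the pedigree (a *nonfounder*) or neither (a *founder*).  The
numerator relationship matrix ``A`` holds twice the kinship coefficient
between every pair of members; it is the covariance structure of an additive
polygenic trait and the oracle against which gene-drop allele sharing is
checked.  The Lander-Green bit complexity ``2n - f`` (n nonfounders, f
founders) measures how expensive exact-likelihood algorithms are on the
pedigree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Member",
    "Pedigree",
    "PedigreeError",
    "RelationshipMatrix",
    "read_ped",
    "write_ped",
    "relationship_matrix",
    "pedigree_bits",
]

MISSING_PARENT = "0"

_SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}
_SEX_TO_CODE = {v: k for k, v in _SEX_CODES.items()}


class PedigreeError(ValueError):
    """Raised for malformed PED input or violated pedigree invariants."""


@dataclass(frozen=True)
class Member:
    """One pedigree member; ``father_id``/``mother_id`` are ``None`` for founders."""

    subject_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"

    @property
    def is_founder(self) -> bool:
        return self.father_id is None


@dataclass
class Pedigree:
    """A validated family structure.

    Invariants (enforced by :meth:`validate`, called on construction):

    * every member has both parents in the pedigree or neither;
    * the parent-child graph is acyclic;
    * subject ids are unique within the pedigree.
    """

    pedigree_id: str
    members: list[Member] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- basic queries -----------------------------------------------------

    @property
    def subject_ids(self) -> list[str]:
        return [m.subject_id for m in self.members]

    @property
    def founders(self) -> list[Member]:
        return [m for m in self.members if m.is_founder]

    @property
    def nonfounders(self) -> list[Member]:
        return [m for m in self.members if not m.is_founder]

    def __len__(self) -> int:
        return len(self.members)

    def member(self, subject_id: str) -> Member:
        return self._index[subject_id]

    @property
    def _index(self) -> dict[str, Member]:
        return {m.subject_id: m for m in self.members}

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        ids = [m.subject_id for m in self.members]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PedigreeError(
                f"pedigree {self.pedigree_id!r}: duplicate subject ids {dupes}"
            )
        known = set(ids)
        for m in self.members:
            has_f, has_m = m.father_id is not None, m.mother_id is not None
            if has_f != has_m:
                raise PedigreeError(
                    f"pedigree {self.pedigree_id!r}: subject {m.subject_id!r} "
                    "has one parent missing (parents must be both present or both absent)"
                )
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in known:
                    raise PedigreeError(
                        f"pedigree {self.pedigree_id!r}: subject {m.subject_id!r} "
                        f"references parent {pid!r} not in the pedigree"
                    )
        self.topological_order()  # raises on cycles

    def topological_order(self) -> list[str]:
        """Subject ids ordered so parents precede children.

        Preserves file order among subjects whose parents are already placed.
        """
        placed: set[str] = set()
        order: list[str] = []
        pending = list(self.members)
        while pending:
            progressed = False
            remaining = []
            for m in pending:
                if m.is_founder or (m.father_id in placed and m.mother_id in placed):
                    placed.add(m.subject_id)
                    order.append(m.subject_id)
                    progressed = True
                else:
                    remaining.append(m)
            if not progressed:
                stuck = sorted(m.subject_id for m in remaining)
                raise PedigreeError(
                    f"pedigree {self.pedigree_id!r}: cycle involving subjects {stuck}"
                )
            pending = remaining
        return order

    def generation_depth(self) -> dict[str, int]:
        """Depth 0 for founders, 1 + max(parent depth) otherwise."""
        depth: dict[str, int] = {}
        for sid in self.topological_order():
            m = self.member(sid)
            if m.is_founder:
                depth[sid] = 0
            else:
                depth[sid] = 1 + max(depth[m.father_id], depth[m.mother_id])
        return depth

    @property
    def n_generations(self) -> int:
        return max(self.generation_depth().values()) + 1


@dataclass
class RelationshipMatrix:
    """Numerator relationship matrix (twice the kinship coefficient)."""

    A: np.ndarray
    subject_order: list[str]

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape != (len(self.subject_order),) * 2:
            raise ValueError("matrix shape does not match subject_order length")

    def loc(self, i: str, j: str) -> float:
        idx = {s: k for k, s in enumerate(self.subject_order)}
        return float(self.A[idx[i], idx[j]])

    def reindex(self, subject_order: Sequence[str]) -> "RelationshipMatrix":
        idx = {s: k for k, s in enumerate(self.subject_order)}
        sel = [idx[s] for s in subject_order]
        return RelationshipMatrix(self.A[np.ix_(sel, sel)], list(subject_order))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("subject_id\t" + "\t".join(self.subject_order) + "\n")
            for sid, row in zip(self.subject_order, self.A):
                fh.write(sid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def block_diag_relationship(peds: Iterable[Pedigree]) -> RelationshipMatrix:
    """Relationship matrix of several pedigrees; across-pedigree entries are 0."""
    mats = [relationship_matrix(p) for p in peds]
    order = [s for m in mats for s in m.subject_order]
    n = len(order)
    A = np.zeros((n, n))
    off = 0
    for m in mats:
        k = len(m.subject_order)
        A[off : off + k, off : off + k] = m.A
        off += k
    return RelationshipMatrix(A, order)


# ---------------------------------------------------------------------------
# PED file I/O (6-column LINKAGE: famID indID father mother sex phenotype)
# ---------------------------------------------------------------------------


def read_ped(path: str | Path) -> list[Pedigree]:
    """Read a 6-column whitespace-delimited LINKAGE/PED file.

    ``0`` denotes a missing parent; member order within each family is
    preserved.  Raises :class:`PedigreeError` naming the offending line or
    subject on malformed input.
    """
    families: dict[str, list[Member]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise PedigreeError(
                    f"{path}: line {lineno}: expected 6 columns, got {len(fields)}"
                )
            fam, ind, father, mother, sex = fields[:5]
            families.setdefault(fam, []).append(
                Member(
                    subject_id=ind,
                    father_id=None if father == MISSING_PARENT else father,
                    mother_id=None if mother == MISSING_PARENT else mother,
                    sex=_SEX_CODES.get(sex, "unknown"),
                )
            )
    return [Pedigree(fam, members) for fam, members in families.items()]


def write_ped(peds: Iterable[Pedigree], path: str | Path) -> None:
    """Write pedigrees in 6-column LINKAGE format (phenotype written as 0)."""
    with open(path, "w") as fh:
        for ped in peds:
            for m in ped.members:
                fh.write(
                    f"{ped.pedigree_id}\t{m.subject_id}\t"
                    f"{m.father_id or MISSING_PARENT}\t{m.mother_id or MISSING_PARENT}\t"
                    f"{_SEX_TO_CODE.get(m.sex, '0')}\t0\n"
                )


# ---------------------------------------------------------------------------
# Relationship matrix and bit complexity
# ---------------------------------------------------------------------------


def relationship_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular recursion.

    Processing subjects in generation order with founders unrelated and
    non-inbred:

    * ``A_ii = 1 + 0.5 * A[father(i), mother(i)]``
    * ``A_ij = 0.5 * (A[j, father(i)] + A[j, mother(i)])`` for previously
      processed ``j``.
    """
    order = ped.topological_order()
    idx = {s: k for k, s in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for i, sid in enumerate(order):
        m = ped.member(sid)
        if m.is_founder:
            A[i, i] = 1.0
            continue
        fa, mo = idx[m.father_id], idx[m.mother_id]
        A[i, i] = 1.0 + 0.5 * A[fa, mo]
        contrib = 0.5 * (A[:i, fa] + A[:i, mo])
        A[i, :i] = contrib
        A[:i, i] = contrib
    # return in the pedigree's member order, not topological order
    mat = RelationshipMatrix(A, order)
    return mat.reindex(ped.subject_ids)


def pedigree_bits(ped: Pedigree) -> int:
    """Lander-Green bit complexity: ``2 * n_nonfounders - n_founders``."""
    return 2 * len(ped.nonfounders) - len(ped.founders)
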