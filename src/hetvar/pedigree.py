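"""Pedigree validation and additive-relationship algebra.

The additive genetic effect of the animal model is distributed
``a ~ N(0, A * sigma2_a)`` where ``A`` is the numerator relationship matrix
of the pedigree.  The samplers only ever touch the sparse inverse of ``A``,
built directly from the pedigree by Henderson's rules; the dense tabular
``A`` is kept for small instances as an oracle and for inbreeding checks.

Unknown parents are encoded with the sentinel ``"0"`` (an empty field in a
pedigree file means the same).  Unknown-parent groups are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

UNKNOWN = "0"

__all__ = [
    "UNKNOWN",
    "Pedigree",
    "RelationshipStructure",
    "sort_pedigree",
    "relationship_matrix",
    "inbreeding",
    "a_inverse",
    "read_pedigree",
    "write_pedigree",
]


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, duplicate id, ...)."""


@dataclass
class Pedigree:
    """Animal/sire/dam triples plus per-animal Murrah breed fraction.

    ``entries`` is a list of ``(animal, sire, dam)`` id triples; ``UNKNOWN``
    marks a missing parent.  ``breed_fraction`` maps animal id to the
    proportion of Murrah genes in [0, 1] (used for the heterozygosity
    covariate of offspring records); animals without a known fraction are
    simply absent from the mapping.
    """

    entries: list[tuple[str, str, str]]
    breed_fraction: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for aid, frac in self.breed_fraction.items():
            if not (0.0 <= frac <= 1.0):
                raise PedigreeError(
                    f"breed fraction for {aid!r} is {frac}, outside [0, 1]"
                )

    @property
    def animals(self) -> list[str]:
        return [a for a, _, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class RelationshipStructure:
    """Relationship algebra for one sorted pedigree.

    ``order`` is the topological animal order shared by every array here:
    ``A`` (dense numerator relationship matrix, small instances only),
    ``Ainv`` (sparse symmetric inverse) and ``F`` (inbreeding coefficients,
    ``F = diag(A) - 1``).
    """

    order: list[str]
    A: np.ndarray | None = None
    Ainv: sparse.csr_matrix | None = None
    F: np.ndarray | None = None

    @property
    def index(self) -> dict[str, int]:
        return {a: i for i, a in enumerate(self.order)}


def _parent_indices(ped: Pedigree) -> tuple[np.ndarray, np.ndarray]:
    """Sire/dam positions (-1 for unknown) for a sorted pedigree."""
    idx = {a: i for i, (a, _, _) in enumerate(ped.entries)}
    sires = np.empty(len(ped), dtype=np.int64)
    dams = np.empty(len(ped), dtype=np.int64)
    for i, (_, s, d) in enumerate(ped.entries):
        sires[i] = idx[s] if s != UNKNOWN else -1
        dams[i] = idx[d] if d != UNKNOWN else -1
    return sires, dams


def sort_pedigree(ped: Pedigree) -> Pedigree:
    """Topologically sort entries so every parent precedes its offspring.

    Parents that have no row of their own get founder rows
    (``UNKNOWN x UNKNOWN``) inserted.  Animals of equal pedigree depth are
    ordered lexicographically by id, which makes the output deterministic.

    Raises
    ------
    PedigreeError
        If an animal id occurs twice, or the parentage graph has a cycle
        (an animal is its own ancestor).
    """
    parents: dict[str, tuple[str, str]] = {}
    for a, s, d in ped.entries:
        if a == UNKNOWN:
            raise PedigreeError(f"{UNKNOWN!r} is reserved for unknown parents")
        if a in parents:
            raise PedigreeError(f"duplicate animal id {a!r}")
        parents[a] = (s, d)
    # ancestor closure: parents without rows become founders
    for a in list(parents):
        for p in parents[a]:
            if p != UNKNOWN and p not in parents:
                parents[p] = (UNKNOWN, UNKNOWN)

    depth: dict[str, int] = {}

    def _depth(a: str, trail: set[str]) -> int:
        if a in depth:
            return depth[a]
        if a in trail:
            raise PedigreeError(f"pedigree cycle involving animal {a!r}")
        trail.add(a)
        s, d = parents[a]
        dep = 1 + max(
            _depth(s, trail) if s != UNKNOWN else -1,
            _depth(d, trail) if d != UNKNOWN else -1,
        )
        trail.remove(a)
        depth[a] = dep
        return dep

    # iterative wrapper is unnecessary: pedigrees are shallow (depth << 1000)
    for a in parents:
        _depth(a, set())

    order = sorted(parents, key=lambda a: (depth[a], a))
    entries = [(a, *parents[a]) for a in order]
    return Pedigree(entries=entries, breed_fraction=dict(ped.breed_fraction))


def relationship_matrix(ped: Pedigree) -> RelationshipStructure:
    """Dense numerator relationship matrix by the tabular method.

    For a sorted pedigree: ``A[i,i] = 1 + 0.5*A[s,d]`` and
    ``A[i,j] = 0.5*(A[j,s] + A[j,d])`` for ``j < i``, with unknown parents
    contributing zero.  ``F = diag(A) - 1``.  Intended for oracle-scale
    pedigrees (a few thousand animals at most).
    """
    ped = sort_pedigree(ped)
    n = len(ped)
    sires, dams = _parent_indices(ped)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sires[i], dams[i]
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
        for j in range(i):
            aij = 0.0
            if s >= 0:
                aij += 0.5 * A[j, s]
            if d >= 0:
                aij += 0.5 * A[j, d]
            A[i, j] = A[j, i] = aij
    return RelationshipStructure(order=ped.animals, A=A, F=np.diag(A) - 1.0)


def inbreeding(ped: Pedigree) -> tuple[Pedigree, np.ndarray]:
    """Inbreeding coefficients by the Meuwissen-Luo algorithm.

    Returns the sorted pedigree together with ``F``.  The algorithm tracks,
    per animal, the within-animal row ``L`` of the Cholesky decomposition
    ``A = L D L'``: ``F_i + 1 = sum_j L_ij^2 * D_j`` over the ancestors ``j``
    of ``i``.  Cost is linear in the number of animal-ancestor pairs, so it
    scales far beyond the dense tabular method.
    """
    ped = sort_pedigree(ped)
    n = len(ped)
    sires, dams = _parent_indices(ped)
    F = np.zeros(n)
    D = np.zeros(n)
    L = np.zeros(n)
    for i in range(n):
        s, d = sires[i], dams[i]
        fs = F[s] if s >= 0 else -1.0  # convention: unknown parent F = -1
        fd = F[d] if d >= 0 else -1.0
        D[i] = 0.5 - 0.25 * (fs + fd)
        if s < 0 and d < 0:
            F[i] = 0.0
            continue
        # accumulate L-row of animal i over its ancestors, newest first
        L[: i + 1] = 0.0
        L[i] = 1.0
        fi = -1.0  # F_i = sum L_j^2 D_j - 1
        for j in range(i, -1, -1):
            lj = L[j]
            if lj == 0.0:
                continue
            sj, dj = sires[j], dams[j]
            if sj >= 0:
                L[sj] += 0.5 * lj
            if dj >= 0:
                L[dj] += 0.5 * lj
            fi += lj * lj * D[j]
        F[i] = fi
    return ped, F


def a_inverse(ped: Pedigree, use_inbreeding: bool = True) -> RelationshipStructure:
    """Sparse inverse of the relationship matrix by Henderson's rules.

    Each animal contributes ``alpha = 1 / d_i`` (the inverse Mendelian
    sampling variance) to at most nine cells of ``A^{-1}``.  With
    ``use_inbreeding`` (default) the ``d_i`` use parental inbreeding from the
    Meuwissen-Luo pass, giving the exact inverse of the tabular ``A``; with
    it off, parents are treated as non-inbred (Henderson's original
    approximation, exact only for non-inbred pedigrees).
    """
    ped, F_true = inbreeding(ped)
    F = F_true if use_inbreeding else np.zeros_like(F_true)
    n = len(ped)
    sires, dams = _parent_indices(ped)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def _add(i: int, j: int, v: float) -> None:
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, d = sires[i], dams[i]
        fs = F[s] if s >= 0 else -1.0
        fd = F[d] if d >= 0 else -1.0
        alpha = 1.0 / (0.5 - 0.25 * (fs + fd))
        _add(i, i, alpha)
        for p in (s, d):
            if p >= 0:
                _add(i, p, -0.5 * alpha)
                _add(p, i, -0.5 * alpha)
        for p in (s, d):
            if p >= 0:
                _add(p, p, 0.25 * alpha)
        if s >= 0 and d >= 0:
            _add(s, d, 0.25 * alpha)
            _add(d, s, 0.25 * alpha)

    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return RelationshipStructure(order=ped.animals, Ainv=Ainv, F=F_true)


def read_pedigree(path) -> Pedigree:
    """Read a pedigree file: CSV with header ``animal,sire,dam[,murrah_fraction]``."""
    df = pd.read_csv(path, dtype={0: str, 1: str, 2: str}, comment="#")
    required = ["animal", "sire", "dam"]
    if list(df.columns[:3]) != required:
        raise PedigreeError(
            f"pedigree file {path} must start with columns {required}, "
            f"got {list(df.columns[:3])}"
        )
    entries = []
    fractions: dict[str, float] = {}
    has_frac = "murrah_fraction" in df.columns
    for row in df.itertuples(index=False):
        sire = row.sire if isinstance(row.sire, str) and row.sire else UNKNOWN
        dam = row.dam if isinstance(row.dam, str) and row.dam else UNKNOWN
        entries.append((row.animal, sire, dam))
        if has_frac and np.isfinite(row.murrah_fraction):
            fractions[row.animal] = float(row.murrah_fraction)
    return Pedigree(entries=entries, breed_fraction=fractions)


def write_pedigree(ped: Pedigree, path) -> None:
    df = pd.DataFrame(ped.entries, columns=["animal", "sire", "dam"])
    if ped.breed_fraction:
        df["murrah_fraction"] = [ped.breed_fraction.get(a) for a in df["animal"]]
    df.to_csv(path, index=False)
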