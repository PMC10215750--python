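"""Labeled symmetric relationship matrices.

A single container is used for every flavour of relationship matrix the
pipeline produces: the pedigree-based numerator relationship matrix ``A``
(twice the identity-by-descent kinship), its genotyped-block submatrix
``A22``, the genomic relationship matrix ``G`` (twice identity-by-state
under the observed allele frequencies), the blended ``Gstar`` and the
single-step matrix ``H``.  The ``kind`` tag carries provenance so that
downstream code can refuse, e.g., a genomic matrix where a full-pedigree
matrix is required.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_KINDS = ("A", "A22", "G", "Gstar", "H")


@dataclass
class RelationshipMatrix:
    """Symmetric matrix of relationship coefficients with row/column labels.

    Parameters
    ----------
    ids
        Ordered individual labels; ``values[i, j]`` is the relationship
        between ``ids[i]`` and ``ids[j]``.
    values
        Symmetric ``(n, n)`` float array.
    kind
        One of ``"A"``, ``"A22"``, ``"G"``, ``"Gstar"``, ``"H"``.
    """

    ids: list[str]
    values: np.ndarray
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown relationship-matrix kind {self.kind!r}")
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in relationship matrix")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("relationship matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, ids) -> np.ndarray:
        """Positions of ``ids`` in this matrix; error names any missing id."""
        pos = {a: k for k, a in enumerate(self.ids)}
        out = []
        for a in ids:
            a = str(a)
            if a not in pos:
                raise KeyError(f"id {a!r} not present in {self.kind} matrix")
            out.append(pos[a])
        return np.asarray(out, dtype=np.intp)

    def submatrix(self, ids, kind: str | None = None) -> "RelationshipMatrix":
        """Principal submatrix in the order of ``ids``."""
        idx = self.index_of(ids)
        return RelationshipMatrix(
            [self.ids[k] for k in idx],
            self.values[np.ix_(idx, idx)],
            kind or self.kind,
        )

    def diagonal(self) -> np.ndarray:
        return np.diag(self.values).copy()


def kinship(M: RelationshipMatrix, i: str, j: str) -> float:
    """Standardized kinship coefficient R_ij = m_ij / sqrt(m_ii * m_jj).

    This is the correlation-style standardization of the relationship
    coefficient, applied identically to pedigree (``A``) and genomic
    (``G``) matrices.  Note it is *not* the classical coancestry
    (half the numerator relationship): for a non-inbred parent-offspring
    pair in ``A`` it equals 0.5, and ``R_ii`` is 1 for every individual.
    For genomic matrices it can be negative.
    """
    ki, kj = M.index_of([i, j])
    return float(kinship_from_values(M.values, ki, kj))


def kinship_from_values(values: np.ndarray, i: int, j: int) -> float:
    dii = values[i, i]
    djj = values[j, j]
    if dii <= 0 or djj <= 0:
        raise ValueError(
            "non-positive diagonal element in relationship matrix; "
            "kinship standardization undefined (degenerate G?)"
        )
    return values[i, j] / np.sqrt(dii * djj)


def kinship_matrix(M: RelationshipMatrix) -> np.ndarray:
    """Full matrix of standardized kinship coefficients R_ij."""
    d = M.diagonal()
    if np.any(d <= 0):
        bad = M.ids[int(np.argmin(d))]
        raise ValueError(
            f"non-positive diagonal for id {bad!r}; kinship undefined"
        )
    s = 1.0 / np.sqrt(d)
    return M.values * np.outer(s, s)
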