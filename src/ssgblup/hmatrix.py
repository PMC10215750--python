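"""Blending of G with A22 and assembly of the single-step matrix H.

H merges pedigree and genomic information so that non-genotyped animals
are carried by the pedigree while genotyped animals contribute realized
(marker-based) relationships.  With animals partitioned into
non-genotyped (1) and genotyped (2) blocks,

    H = A + [ A12 A22^-1 (G* - A22) A22^-1 A21    A12 A22^-1 (G* - A22) ]
            [ (G* - A22) A22^-1 A21               G* - A22              ]

and its inverse needs only a sparse update of A^-1:

    H^-1 = A^-1 + [ 0   0                 ]
                  [ 0   G*^-1 - A22^-1    ]

where G* = tau * G + omega * A22 (default 0.95 / 0.05) guards against a
singular G.  No further compatibility scaling of G toward A22 is applied
by default; only the stated convex blend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .matrices import RelationshipMatrix


@dataclass
class BlendSpec:
    """Convex blend weights: tau on G, omega on A22 (tau + omega = 1)."""

    tau: float = 0.95
    omega: float = 0.05

    def __post_init__(self) -> None:
        if not np.isclose(self.tau + self.omega, 1.0):
            raise ValueError("blend weights must satisfy tau + omega = 1")
        if not (0.0 < self.tau <= 1.0):
            raise ValueError("tau must be in (0, 1]")


def blend_G(
    Gmat: RelationshipMatrix,
    A22: RelationshipMatrix,
    spec: BlendSpec | None = None,
) -> RelationshipMatrix:
    """G* = tau G + omega A22, requiring identical id order."""
    spec = spec or BlendSpec()
    if Gmat.ids != A22.ids:
        raise ValueError("G and A22 must have identical id ordering")
    vals = spec.tau * Gmat.values + spec.omega * A22.values
    return RelationshipMatrix(
        Gmat.ids, vals, "Gstar", meta={"tau": spec.tau, "omega": spec.omega}
    )


def _sym_inv(M: np.ndarray, what: str, hint: str) -> np.ndarray:
    """Inverse via symmetric (Cholesky) factorization; no pseudo-inverse."""
    try:
        c, low = linalg.cho_factor(M, check_finite=False)
    except linalg.LinAlgError:
        raise ValueError(f"{what} is singular or not positive definite; {hint}")
    return linalg.cho_solve((c, low), np.eye(M.shape[0]), check_finite=False)


def _partition(A: RelationshipMatrix, genotyped_ids) -> tuple[np.ndarray, np.ndarray]:
    """Indices of (non-genotyped, genotyped) animals in A's order."""
    g_idx = A.index_of(genotyped_ids)
    mask = np.zeros(A.n, dtype=bool)
    mask[g_idx] = True
    ng_idx = np.nonzero(~mask)[0]
    return ng_idx, g_idx


def build_H(
    A: RelationshipMatrix,
    Gstar: RelationshipMatrix,
    genotyped_ids=None,
) -> RelationshipMatrix:
    """Assemble H from A and the blended genomic matrix G*.

    ``genotyped_ids`` defaults to G*'s own ids; they must be a subset of
    A's ids and match G*'s order.  The result is labeled in A's id order.
    """
    genotyped_ids = list(map(str, genotyped_ids or Gstar.ids))
    if genotyped_ids != Gstar.ids:
        raise ValueError("genotyped_ids must match G*'s id order")
    ng_idx, g_idx = _partition(A, genotyped_ids)
    Av = A.values
    A12 = Av[np.ix_(ng_idx, g_idx)]
    A22 = Av[np.ix_(g_idx, g_idx)]
    A22inv = _sym_inv(A22, "A22", "check the pedigree or the genotyped subset")
    D = Gstar.values - A22  # genotyped-block correction
    B = A12 @ A22inv  # (n1, n2)
    H = Av.copy()
    H[np.ix_(ng_idx, ng_idx)] += B @ D @ B.T
    H[np.ix_(ng_idx, g_idx)] += B @ D
    H[np.ix_(g_idx, ng_idx)] += D @ B.T
    H[np.ix_(g_idx, g_idx)] += D
    H = 0.5 * (H + H.T)
    return RelationshipMatrix(
        A.ids, H, "H", meta={"genotyped_ids": genotyped_ids}
    )


def build_H_inverse(
    A_inv: np.ndarray,
    Gstar: RelationshipMatrix,
    A22: RelationshipMatrix,
    genotyped_idx,
) -> np.ndarray:
    """H^-1 = A^-1 plus the genotyped-block update G*^-1 - A22^-1.

    ``genotyped_idx`` gives the positions of the genotyped animals (in
    G*/A22 order) within the id order of A_inv.
    """
    if Gstar.ids != A22.ids:
        raise ValueError("G* and A22 must have identical id ordering")
    g_idx = np.asarray(genotyped_idx, dtype=np.intp)
    Gstar_inv = _sym_inv(
        Gstar.values, "G*", "increase the blend weight omega on A22"
    )
    A22_inv = _sym_inv(A22.values, "A22", "check the pedigree")
    H_inv = np.asarray(A_inv, dtype=float).copy()
    H_inv[np.ix_(g_idx, g_idx)] += Gstar_inv - A22_inv
    return 0.5 * (H_inv + H_inv.T)
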