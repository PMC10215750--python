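"""Two-trait repeatability animal model: design, MME solve, reliabilities.

The model for trait i is

    y_i = X_i b_i + Z_i a_i + W_i pe_i + e_i

with fixed effects (year, month, program, technician, linear and
quadratic age covariates), additive genetic effects a with
var(a) = Ga (x) K for a relationship matrix K (A or H), permanent
environmental effects pe with var(pe) = Gpe (x) I over cows, and
residuals with var(e) = Re (x) I over flush records (both traits are
observed on every flush, so residuals are correlated within a record).
Henderson's mixed-model equations are assembled trait-major
(trait (x) level ordering) and solved by dense Cholesky factorization;
prediction error variances come from the corresponding diagonal block of
the inverse coefficient matrix, and the reliability of cow i's EBV is

    rel_i = 1 - PEV_i / (k_ii * sigma2_a)

with k_ii the diagonal of the same K used for prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, sparse

from .matrices import RelationshipMatrix
from .pedigree import Pedigree

log = logging.getLogger(__name__)


@dataclass
class ModelSpec:
    """What goes into the linear model.

    ``traits`` name the phenotype columns modeled jointly; ``factors``
    the categorical fixed effects; ``age_col`` a covariate entered
    linearly and (if ``quadratic_age``) quadratically after centering at
    the sample mean.  ``include_pe`` switches the permanent
    environmental effect (needed whenever cows have repeated records).
    """

    traits: tuple = ("tne", "nge")
    factors: tuple = ("year", "month", "program", "technician")
    age_col: str | None = "age_months"
    quadratic_age: bool = True
    include_pe: bool = True


@dataclass
class VarianceComponents:
    """Trait covariance blocks: additive (Ga), permanent env. (Gpe), residual (Re)."""

    Ga: np.ndarray
    Gpe: np.ndarray | None
    Re: np.ndarray

    def __post_init__(self) -> None:
        self.Ga = np.atleast_2d(np.asarray(self.Ga, dtype=float))
        self.Re = np.atleast_2d(np.asarray(self.Re, dtype=float))
        if self.Gpe is not None:
            self.Gpe = np.atleast_2d(np.asarray(self.Gpe, dtype=float))

    @property
    def n_traits(self) -> int:
        return self.Ga.shape[0]

    def total(self) -> np.ndarray:
        tot = self.Ga + self.Re
        if self.Gpe is not None:
            tot = tot + self.Gpe
        return tot

    def heritability(self) -> np.ndarray:
        tot = np.diag(self.total())
        if np.any(tot <= 0):
            raise ValueError("non-positive phenotypic variance")
        return np.diag(self.Ga) / tot

    def repeatability(self) -> np.ndarray:
        tot = np.diag(self.total())
        if np.any(tot <= 0):
            raise ValueError("non-positive phenotypic variance")
        pe = np.zeros(self.n_traits) if self.Gpe is None else np.diag(self.Gpe)
        return (np.diag(self.Ga) + pe) / tot

    def genetic_correlation(self) -> float:
        if self.n_traits < 2:
            raise ValueError("genetic correlation needs two traits")
        d = self.Ga[0, 0] * self.Ga[1, 1]
        if d <= 0:
            raise ValueError("non-positive additive variance")
        return float(self.Ga[0, 1] / np.sqrt(d))


@dataclass
class DesignMatrices:
    """Record-level design: y (n, t), X0 (dense), Z0/W0 (sparse incidence).

    The same design applies to every trait (each flush records both
    traits), so only single-trait blocks are stored; the trait-major
    stacked system is assembled from them on demand.  Z0 spans *all*
    pedigree animals so that relatives without records receive EBVs.
    """

    y: np.ndarray
    X0: np.ndarray
    Z0: sparse.csr_matrix
    W0: sparse.csr_matrix | None
    fixed_names: list[str]
    animal_ids: list[str]
    cow_ids: list[str]
    traits: tuple
    record_cow: np.ndarray  # per record, index into cow_ids
    meta: dict = field(default_factory=dict)

    @property
    def n_records(self) -> int:
        return self.y.shape[0]

    @property
    def n_traits(self) -> int:
        return self.y.shape[1]

    @property
    def p(self) -> int:
        return self.X0.shape[1]

    @property
    def q(self) -> int:
        return len(self.animal_ids)

    @property
    def c(self) -> int:
        return 0 if self.W0 is None else len(self.cow_ids)

    def records_per_cow(self) -> dict[str, int]:
        counts = np.bincount(self.record_cow, minlength=len(self.cow_ids))
        return dict(zip(self.cow_ids, counts.tolist()))


def build_design(
    ph: pd.DataFrame, ped: Pedigree, spec: ModelSpec | None = None
) -> DesignMatrices:
    """Build y, X, Z, W from a flush-record table and a pedigree.

    X uses a single intercept with drop-first reference coding for every
    categorical factor; the age covariate is centered at its sample mean
    (recorded in ``meta``) with the quadratic term computed on the
    centered value.  Estimable functions, EBVs and the likelihood are
    invariant to these choices.
    """
    spec = spec or ModelSpec()
    ph = ph.copy()
    ph["cow_id"] = ph["cow_id"].astype(str)
    try:
        animal_idx = ped.index_of(ph["cow_id"])
    except KeyError as err:
        raise ValueError(f"phenotyped cow missing from pedigree: {err}") from None

    n = len(ph)
    cols = [np.ones((n, 1))]
    names = ["intercept"]
    for f in spec.factors:
        if f not in ph.columns:
            raise ValueError(f"fixed-effect column {f!r} missing from phenotypes")
        if ph[f].isna().any():
            row = int(ph[f].isna().idxmax())
            raise ValueError(f"missing {f!r} level in phenotype row {row}")
        levels = pd.unique(ph[f].astype(str))
        levels = sorted(levels)
        counts = ph[f].astype(str).value_counts()
        singletons = [l for l in levels if counts[l] < 2]
        if singletons:
            log.warning(
                "factor %r has levels with a single record: %s (kept)",
                f,
                singletons[:5],
            )
        for lev in levels[1:]:  # drop first level as reference
            cols.append((ph[f].astype(str) == lev).to_numpy(float)[:, None])
            names.append(f"{f}[{lev}]")
    meta: dict = {}
    if spec.age_col is not None:
        age = ph[spec.age_col].to_numpy(float)
        if not np.all(np.isfinite(age)):
            raise ValueError(f"non-finite {spec.age_col!r} covariate")
        mu = float(age.mean())
        meta["age_mean"] = mu
        ac = age - mu
        cols.append(ac[:, None])
        names.append(f"{spec.age_col}_c")
        if spec.quadratic_age:
            cols.append((ac**2)[:, None])
            names.append(f"{spec.age_col}_c2")
    X0 = np.hstack(cols)
    rank = np.linalg.matrix_rank(X0)
    if rank < X0.shape[1]:
        raise ValueError(
            f"fixed effects are confounded: X has rank {rank} < {X0.shape[1]} "
            "columns; check for aliased factor levels"
        )

    Z0 = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), animal_idx)), shape=(n, ped.n)
    )
    # permanent-environment levels: recorded cows, in pedigree order
    recorded = set(ph["cow_id"])
    cow_ids = [a for a in ped.ids if a in recorded]
    cow_pos = {a: k for k, a in enumerate(cow_ids)}
    record_cow = np.array([cow_pos[a] for a in ph["cow_id"]], dtype=np.intp)
    W0 = None
    if spec.include_pe:
        W0 = sparse.csr_matrix(
            (np.ones(n), (np.arange(n), record_cow)), shape=(n, len(cow_ids))
        )

    y = ph[list(spec.traits)].to_numpy(float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite trait value in phenotype table")
    return DesignMatrices(
        y=y,
        X0=X0,
        Z0=Z0,
        W0=W0,
        fixed_names=names,
        animal_ids=list(ped.ids),
        cow_ids=cow_ids,
        traits=tuple(spec.traits),
        record_cow=record_cow,
        meta=meta,
    )


class MMESystem:
    """Assembled cross-products for Henderson's equations.

    Precomputes the single-trait cross products X'X, X'Z, ..., W'W and
    right-hand sides; :meth:`build` produces the trait-major coefficient
    matrix and RHS for given variance components.  Shared by the BLUP
    solver and the REML estimator.
    """

    def __init__(
        self,
        d: DesignMatrices,
        K_inv: np.ndarray | None = None,
        logdet_K: float | None = None,
    ) -> None:
        self.d = d
        q = d.q
        if K_inv is None:
            K_inv = np.eye(q)
            logdet_K = 0.0
        K_inv = np.asarray(K_inv, dtype=float)
        if K_inv.shape != (q, q):
            raise ValueError("K inverse has wrong shape for the animal set")
        if logdet_K is None:
            sign, ld = np.linalg.slogdet(K_inv)
            if sign <= 0:
                raise ValueError("K inverse is not positive definite")
            logdet_K = -ld
        self.K_inv = K_inv
        self.logdet_K = float(logdet_K)

        X0, Z0, W0, Y = d.X0, d.Z0, d.W0, d.y
        self.effects = [("x", X0.shape[1]), ("z", q)]
        if W0 is not None:
            self.effects.append(("w", W0.shape[1]))
        mats = {"x": X0, "z": Z0, "w": W0}
        self.cross: dict[tuple[str, str], np.ndarray] = {}
        self.Ety: dict[str, np.ndarray] = {}
        for i, (e, _) in enumerate(self.effects):
            Me = mats[e]
            self.Ety[e] = np.asarray(Me.T @ Y)
            for f, _ in self.effects[i:]:
                Mf = mats[f]
                prod = Me.T @ Mf
                self.cross[(e, f)] = np.asarray(
                    prod.toarray() if sparse.issparse(prod) else prod
                )
        self.YtY = Y.T @ Y
        t = d.n_traits
        # trait-major offsets: block (effect e, trait a)
        self.offsets: dict[tuple[str, int], slice] = {}
        off = 0
        for e, de in self.effects:
            for a in range(t):
                self.offsets[(e, a)] = slice(off + a * de, off + (a + 1) * de)
            off += t * de
        self.dim = off

    def _blocks(self, vc: VarianceComponents):
        t = self.d.n_traits
        if vc.n_traits != t:
            raise ValueError("variance components do not match trait count")
        Rinv = np.linalg.inv(vc.Re)
        Ga_inv = np.linalg.inv(vc.Ga)
        Gpe_inv = None
        if self.d.W0 is not None:
            if vc.Gpe is None:
                raise ValueError("model includes pe but Gpe is missing")
            Gpe_inv = np.linalg.inv(vc.Gpe)
        return Rinv, Ga_inv, Gpe_inv

    def build(self, vc: VarianceComponents) -> tuple[np.ndarray, np.ndarray]:
        d = self.d
        t = d.n_traits
        Rinv, Ga_inv, Gpe_inv = self._blocks(vc)
        C = np.zeros((self.dim, self.dim))
        for i, (e, de) in enumerate(self.effects):
            for f, df in self.effects[i:]:
                Mef = self.cross[(e, f)]
                for a in range(t):
                    for b in range(t):
                        if e == f and b < a:
                            continue
                        blk = Rinv[a, b] * Mef
                        C[self.offsets[(e, a)], self.offsets[(f, b)]] += blk
                        if e != f or a != b:
                            C[self.offsets[(f, b)], self.offsets[(e, a)]] += blk.T
        # random-effect penalties
        for a in range(t):
            for b in range(t):
                C[self.offsets[("z", a)], self.offsets[("z", b)]] += (
                    Ga_inv[a, b] * self.K_inv
                )
                if Gpe_inv is not None:
                    sl = self.offsets[("w", a)], self.offsets[("w", b)]
                    idx = np.arange(sl[0].start, sl[0].stop)
                    C[idx, idx - sl[0].start + sl[1].start] += Gpe_inv[a, b]
        rhs = np.concatenate(
            [
                (self.Ety[e] @ Rinv).T.ravel()
                for e, _ in self.effects
            ]
        )
        return C, rhs

    def minus2_restricted_ll(
        self, vc: VarianceComponents, chol=None, rhs=None, sol=None
    ) -> float:
        """-2 log restricted likelihood up to an additive constant."""
        d = self.d
        if chol is None:
            C, rhs = self.build(vc)
            chol = linalg.cho_factor(C, lower=True, check_finite=False)
            sol = linalg.cho_solve(chol, rhs, check_finite=False)
        Rinv, _, _ = self._blocks(vc)
        yRy = float(np.sum(Rinv * self.YtY))
        yPy = yRy - float(rhs @ sol)
        logdetC = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
        t = d.n_traits
        m2 = (
            d.n_records * _logdet(vc.Re)
            + d.q * _logdet(vc.Ga)
            + t * self.logdet_K
            + logdetC
            + yPy
        )
        if d.W0 is not None:
            m2 += d.c * _logdet(vc.Gpe)
        return m2

    def solutions(self, sol: np.ndarray):
        """Split a solution vector into (beta, u, pe) level-by-trait arrays."""
        d = self.d
        t = d.n_traits
        out = {}
        for e, de in self.effects:
            mat = np.empty((de, t))
            for a in range(t):
                mat[:, a] = sol[self.offsets[(e, a)]]
            out[e] = mat
        return out["x"], out["z"], out.get("w")

    def residuals(self, sol: np.ndarray) -> np.ndarray:
        d = self.d
        beta, u, pe = self.solutions(sol)
        e = d.y - d.X0 @ beta - d.Z0 @ u
        if d.W0 is not None:
            e = e - d.W0 @ pe
        return e


def _logdet(M: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(np.atleast_2d(M))
    if sign <= 0:
        raise ValueError("covariance block is not positive definite")
    return float(ld)


@dataclass
class MMESolution:
    """Solved mixed-model equations for one (K, variance components) setting."""

    beta: np.ndarray  # (p, t)
    u: np.ndarray  # (q, t) EBVs for all pedigree animals
    pe: np.ndarray | None  # (c, t)
    pev: np.ndarray | None  # (q, t)
    fixed_names: list[str]
    animal_ids: list[str]
    cow_ids: list[str]
    traits: tuple
    vc: VarianceComponents
    k_kind: str
    k_diag: np.ndarray


def solve_mme(
    d: DesignMatrices,
    K: RelationshipMatrix,
    vc: VarianceComponents,
    K_inv: np.ndarray | None = None,
    compute_pev: bool = True,
) -> MMESolution:
    """Solve Henderson's equations for the given relationship matrix.

    ``K.ids`` must equal the design's animal ids (pedigree order).  The
    inverse may be supplied to avoid refactorizing K across settings.
    PEVs are read off the animal-block diagonal of the inverse
    coefficient matrix.
    """
    if list(K.ids) != list(d.animal_ids):
        raise ValueError("relationship matrix ids do not match design animals")
    if K_inv is None:
        K_inv = _invert_K(K)
    sys = MMESystem(d, K_inv=K_inv)
    C, rhs = sys.build(vc)
    try:
        chol = linalg.cho_factor(C, lower=True, check_finite=False)
    except linalg.LinAlgError:
        raise ValueError(
            "singular mixed-model coefficient matrix; fixed effects are "
            "confounded or a covariance block is degenerate"
        ) from None
    sol = linalg.cho_solve(chol, rhs, check_finite=False)
    resid = np.linalg.norm(C @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300)
    if resid > 1e-8:
        log.warning("MME relative residual %.2e exceeds 1e-8", resid)
    beta, u, pe = sys.solutions(sol)
    pev = None
    if compute_pev:
        Cinv = linalg.cho_solve(chol, np.eye(sys.dim), check_finite=False)
        t = d.n_traits
        pev = np.empty((d.q, t))
        for a in range(t):
            sl = sys.offsets[("z", a)]
            pev[:, a] = np.diag(Cinv[sl, sl])
    return MMESolution(
        beta=beta,
        u=u,
        pe=pe,
        pev=pev,
        fixed_names=d.fixed_names,
        animal_ids=list(d.animal_ids),
        cow_ids=list(d.cow_ids),
        traits=d.traits,
        vc=vc,
        k_kind=K.kind,
        k_diag=K.diagonal(),
    )


def _invert_K(K: RelationshipMatrix) -> np.ndarray:
    try:
        c = linalg.cho_factor(K.values, check_finite=False)
    except linalg.LinAlgError:
        raise ValueError(
            f"{K.kind} matrix is singular; cannot be used in the MME"
        ) from None
    return linalg.cho_solve(c, np.eye(K.n), check_finite=False)


def reliability(sol: MMESolution) -> np.ndarray:
    """Per-animal, per-trait reliability 1 - PEV / (k_ii * sigma2_a).

    Uses the diagonal of the same relationship matrix that produced the
    solve and the additive variances tagged in the solution.  Tiny
    negative values from floating-point roundoff (> -1e-10) are clamped
    to 0.
    """
    if sol.pev is None:
        raise ValueError("solution was computed without PEV")
    k_diag = sol.k_diag
    if np.any(k_diag <= 0):
        raise ValueError("non-positive relationship diagonal")
    denom = k_diag[:, None] * np.diag(sol.vc.Ga)[None, :]
    rel = 1.0 - sol.pev / denom
    rel = np.where((rel < 0) & (rel > -1e-10), 0.0, rel)
    return rel


@dataclass
class PredictionResult:
    """Tagged per-cow predictions for one of the four A/H settings."""

    blup_matrix: str  # matrix used in the MME: "A" or "H"
    reml_matrix: str  # matrix under which the components were estimated
    table: pd.DataFrame  # cow_id, trait, ebv, pev, reliability, n_records
    fixed: pd.DataFrame
    solution: MMESolution

    @property
    def tag(self) -> str:
        return f"{self.blup_matrix}-{self.reml_matrix}"


def prediction_result(
    sol: MMESolution,
    d: DesignMatrices,
    blup_matrix: str,
    reml_matrix: str,
) -> PredictionResult:
    rel = reliability(sol)
    counts = d.records_per_cow()
    rows = []
    idx = {a: k for k, a in enumerate(sol.animal_ids)}
    for cow in d.cow_ids:
        k = idx[cow]
        for a, trait in enumerate(sol.traits):
            rows.append(
                {
                    "cow_id": cow,
                    "trait": trait,
                    "ebv": sol.u[k, a],
                    "pev": sol.pev[k, a],
                    "reliability": rel[k, a],
                    "n_records": counts.get(cow, 0),
                }
            )
    fixed = pd.DataFrame(
        {
            "effect": sol.fixed_names,
            **{t: sol.beta[:, a] for a, t in enumerate(sol.traits)},
        }
    )
    return PredictionResult(
        blup_matrix=blup_matrix,
        reml_matrix=reml_matrix,
        table=pd.DataFrame(rows),
        fixed=fixed,
        solution=sol,
    )


def run_four_settings(
    ph: pd.DataFrame,
    ped: Pedigree,
    geno,
    model_spec: ModelSpec | None = None,
    blend=None,
    reml_kwargs: dict | None = None,
):
    """Cross {A, H} for BLUP with {A, H}-estimated variance components.

    Runs QC and matrix building, estimates components by AI-REML once
    per relationship matrix, then solves the MME for all four crossings.
    Returns ``(results, reml_results, matrices)`` where ``results`` maps
    (blup_matrix, reml_matrix) tags to :class:`PredictionResult`.
    """
    from . import genotype as gq
    from . import hmatrix as hm
    from . import pedigree as pedmod
    from .reml import ai_reml

    reml_kwargs = dict(reml_kwargs or {})
    A = pedmod.build_A(ped)
    A_inv = pedmod.build_A_inverse(ped)

    g1, _ = gq.qc_samples(geno)
    g2, _ = gq.qc_markers(g1)
    freqs = gq.allele_frequencies(g2)
    g3 = gq.impute_missing(g2, freqs)
    G = gq.build_G(g3, freqs)
    A22 = pedmod.extract_A22(A, G.ids)
    Gstar = hm.blend_G(G, A22, blend)
    H = hm.build_H(A, Gstar)
    g_idx = A.index_of(G.ids)
    H_inv = hm.build_H_inverse(A_inv, Gstar, A22, g_idx)

    d = build_design(ph, ped, model_spec)
    sign, ldA = np.linalg.slogdet(A.values)
    sign_h, ldH = np.linalg.slogdet(H.values)
    if sign <= 0 or sign_h <= 0:
        raise ValueError("relationship matrix is not positive definite")
    reml_results = {
        "A": ai_reml(d, K_inv=A_inv, logdet_K=ldA, **reml_kwargs),
        "H": ai_reml(d, K_inv=H_inv, logdet_K=ldH, **reml_kwargs),
    }
    mats = {"A": (A, A_inv), "H": (H, H_inv)}
    results = {}
    for blup_m in ("H", "A"):
        K, K_inv = mats[blup_m]
        for reml_m in ("H", "A"):
            sol = solve_mme(d, K, reml_results[reml_m].vc, K_inv=K_inv)
            results[(blup_m, reml_m)] = prediction_result(
                sol, d, blup_m, reml_m
            )
    return results, reml_results, {"A": A, "H": H, "G": G, "Gstar": Gstar}
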