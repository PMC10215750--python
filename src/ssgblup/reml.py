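"""AI-REML for the multi-trait repeatability animal model.

Restricted maximum likelihood with average-information (quasi-Newton)
updates, preceded by a few EM-REML warm-up iterations for robustness to
poor starting values.  The restricted likelihood, its gradient, and the
average-information matrix are all evaluated through the mixed-model
equations (log|C|, solutions and traces of blocks of C^-1) rather than
the record-level covariance matrix, so cost scales with the number of
equations, not records.

Parameters are the distinct entries of the trait covariance blocks
(additive Ga, permanent environmental Gpe, residual Re), stacked
lower-triangle first.  Step-halving guarantees the restricted likelihood
never decreases across accepted iterations; proposals whose blocks lose
positive definiteness are bent by eigenvalue flooring (logged).
Asymptotic standard errors come from the inverse AI matrix at
convergence; standard errors of derived parameters (heritability,
repeatability, genetic correlation) use the delta method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .matrices import RelationshipMatrix
from .mixed_model import DesignMatrices, MMESystem, VarianceComponents

log = logging.getLogger(__name__)


@dataclass
class REMLResult:
    vc: VarianceComponents
    converged: bool
    n_iter: int
    loglik_trace: list = field(default_factory=list)  # -2 logL per iteration
    param_names: list = field(default_factory=list)
    se: dict | None = None
    derived: dict | None = None
    derived_se: dict | None = None
    ai_matrix: np.ndarray | None = None
    score: np.ndarray | None = None
    gradient_norm: float = np.nan
    n_bends: int = 0


def _tri_indices(t: int):
    return [(i, j) for i in range(t) for j in range(i + 1)]


def _pack(vc: VarianceComponents, include_pe: bool) -> np.ndarray:
    t = vc.n_traits
    idx = _tri_indices(t)
    blocks = [vc.Ga] + ([vc.Gpe] if include_pe else []) + [vc.Re]
    return np.concatenate([[B[i, j] for i, j in idx] for B in blocks])


def _unpack(theta: np.ndarray, t: int, include_pe: bool) -> VarianceComponents:
    idx = _tri_indices(t)
    k = len(idx)
    mats = []
    for b in range(3 if include_pe else 2):
        M = np.zeros((t, t))
        for (i, j), v in zip(idx, theta[b * k : (b + 1) * k]):
            M[i, j] = M[j, i] = v
        mats.append(M)
    if include_pe:
        return VarianceComponents(Ga=mats[0], Gpe=mats[1], Re=mats[2])
    return VarianceComponents(Ga=mats[0], Gpe=None, Re=mats[1])


def _param_names(traits, include_pe: bool) -> list[str]:
    t = len(traits)
    idx = _tri_indices(t)
    names = []
    comps = ["a"] + (["pe"] if include_pe else []) + ["e"]
    for comp in comps:
        for i, j in idx:
            if i == j:
                names.append(f"var_{comp}_{traits[i]}")
            else:
                names.append(f"cov_{comp}_{traits[j]}.{traits[i]}")
    return names


def _is_pd(M: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        return False
    return np.linalg.eigvalsh(M)[0] > 1e-8 * max(float(np.trace(M)), 1e-8)


def _all_pd(vc: VarianceComponents, include_pe: bool) -> bool:
    blocks = [vc.Ga, vc.Re] + ([vc.Gpe] if include_pe else [])
    return all(_is_pd(B) for B in blocks)


def _bend_all(vc: VarianceComponents, include_pe: bool) -> VarianceComponents:
    Ga, _ = _bend(vc.Ga)
    Re, _ = _bend(vc.Re)
    Gpe = None
    if include_pe:
        Gpe, _ = _bend(vc.Gpe)
    return VarianceComponents(Ga=Ga, Gpe=Gpe, Re=Re)


def _bend(M: np.ndarray) -> tuple[np.ndarray, bool]:
    """Eigenvalue-floor a symmetric block at 1e-6 x trace."""
    w, V = np.linalg.eigh(M)
    floor = 1e-6 * max(float(np.trace(M)), 1e-8)
    if w[0] >= floor:
        return M, False
    w = np.maximum(w, floor)
    return (V * w) @ V.T, True


def default_start(d: DesignMatrices) -> VarianceComponents:
    """Equal thirds of the phenotypic variance per trait, zero covariances."""
    var = d.y.var(axis=0, ddof=1)
    t = d.n_traits
    third = np.diag(var / 3.0)
    if d.W0 is not None:
        return VarianceComponents(Ga=third, Gpe=third.copy(), Re=third.copy())
    return VarianceComponents(Ga=np.diag(var / 2.0), Gpe=None, Re=np.diag(var / 2.0))


class _REMLWork:
    """Per-iterate statistics from one factorization of the MME."""

    def __init__(self, sys: MMESystem, vc: VarianceComponents):
        self.sys = sys
        self.vc = vc
        d = sys.d
        C, rhs = sys.build(vc)
        self.chol = linalg.cho_factor(C, lower=True, check_finite=False)
        self.rhs = rhs
        self.sol = linalg.cho_solve(self.chol, rhs, check_finite=False)
        self.m2ll = sys.minus2_restricted_ll(vc, self.chol, rhs, self.sol)
        self._cinv = None

    @property
    def cinv(self) -> np.ndarray:
        if self._cinv is None:
            self._cinv = linalg.cho_solve(
                self.chol, np.eye(self.sys.dim), check_finite=False
            )
        return self._cinv

    def stats(self):
        """Quadratic forms and C^-1 traces entering EM updates and scores."""
        sys, d = self.sys, self.sys.d
        t = d.n_traits
        beta, u, pe = sys.solutions(self.sol)
        ehat = sys.residuals(self.sol)
        Kinv = sys.K_inv
        Ua = u.T @ (Kinv @ u)  # u_t' K^-1 u_s
        Ue = ehat.T @ ehat
        Upe = None if pe is None else pe.T @ pe
        cinv = self.cinv
        Ta = np.empty((t, t))
        Tpe = np.empty((t, t)) if pe is not None else None
        for a in range(t):
            for b in range(t):
                blk = cinv[sys.offsets[("z", a)], sys.offsets[("z", b)]]
                Ta[a, b] = float(np.sum(Kinv * blk.T))
                if Tpe is not None:
                    wblk = cinv[sys.offsets[("w", a)], sys.offsets[("w", b)]]
                    Tpe[a, b] = float(np.trace(wblk))
        # T[t,s] = sum_{e,f} tr( Cinv[(f,s),(e,t)] * (E_e' E_f) )
        TM = np.zeros((t, t))
        for a in range(t):
            for b in range(t):
                acc = 0.0
                for i, (e, _) in enumerate(sys.effects):
                    for f, _ in sys.effects[i:]:
                        Mef = sys.cross[(e, f)]
                        blk = cinv[sys.offsets[(f, b)], sys.offsets[(e, a)]]
                        acc += float(np.sum(blk * Mef.T))
                        if e != f:
                            blk2 = cinv[sys.offsets[(e, b)], sys.offsets[(f, a)]]
                            acc += float(np.sum(blk2 * Mef))
                TM[a, b] = acc
        return {
            "u": u,
            "pe": pe,
            "ehat": ehat,
            "Ua": Ua,
            "Upe": Upe,
            "Ue": Ue,
            "Ta": Ta,
            "Tpe": Tpe,
            "TM": TM,
        }

    def score_and_ai(self, st: dict) -> tuple[np.ndarray, np.ndarray]:
        sys, d = self.sys, self.sys.d
        t = d.n_traits
        vc = self.vc
        include_pe = d.W0 is not None
        Rinv = np.linalg.inv(vc.Re)
        Ga_inv = np.linalg.inv(vc.Ga)
        Gpe_inv = np.linalg.inv(vc.Gpe) if include_pe else None
        idx = _tri_indices(t)

        scores = []
        fvecs = []  # (n, t) arrays, one per parameter
        Z0, W0 = d.Z0, d.W0
        for comp in ["a"] + (["pe"] if include_pe else []) + ["e"]:
            for i, j in idx:
                E = np.zeros((t, t))
                E[i, j] = E[j, i] = 1.0
                if comp == "a":
                    M2 = Ga_inv @ E @ Ga_inv
                    tr = d.q * float(np.trace(E @ Ga_inv)) - float(
                        np.sum(M2 * st["Ta"])
                    )
                    qf = float(np.sum(M2 * st["Ua"]))
                    fvecs.append(np.asarray(Z0 @ (st["u"] @ (Ga_inv @ E))))
                elif comp == "pe":
                    M2 = Gpe_inv @ E @ Gpe_inv
                    tr = d.c * float(np.trace(E @ Gpe_inv)) - float(
                        np.sum(M2 * st["Tpe"])
                    )
                    qf = float(np.sum(M2 * st["Upe"]))
                    fvecs.append(np.asarray(W0 @ (st["pe"] @ (Gpe_inv @ E))))
                else:
                    S = Rinv @ E @ Rinv
                    tr = d.n_records * float(np.trace(E @ Rinv)) - float(
                        np.sum(S * st["TM"])
                    )
                    qf = float(np.sum(S * st["Ue"]))
                    fvecs.append(st["ehat"] @ (Rinv @ E))
                scores.append(-0.5 * (tr - qf))

        # average information: AI_ij = 0.5 * f_i' P f_j
        npar = len(fvecs)
        Pf = []
        mats = {"x": d.X0, "z": Z0, "w": W0}
        for f in fvecs:
            fR = f @ Rinv
            g = np.concatenate(
                [np.asarray(mats[e].T @ fR).T.ravel() for e, _ in sys.effects]
            )
            s = linalg.cho_solve(self.chol, g, check_finite=False)
            Ms = np.zeros_like(f)
            for e, de in sys.effects:
                se = np.empty((de, t))
                for a in range(t):
                    se[:, a] = s[sys.offsets[(e, a)]]
                Ms += np.asarray(mats[e] @ se)
            Pf.append((f - Ms) @ Rinv)
        AI = np.empty((npar, npar))
        for a in range(npar):
            for b in range(a, npar):
                AI[a, b] = AI[b, a] = 0.5 * float(np.sum(fvecs[a] * Pf[b]))
        return np.asarray(scores), 0.5 * (AI + AI.T)

    def em_update(self, st: dict) -> VarianceComponents:
        d = self.sys.d
        Ga = (st["Ua"] + st["Ta"]) / d.q
        Re = (st["Ue"] + st["TM"]) / d.n_records
        Gpe = None
        if st["Upe"] is not None:
            Gpe = (st["Upe"] + st["Tpe"]) / d.c
        return VarianceComponents(Ga=Ga, Gpe=Gpe, Re=Re)


def ai_reml(
    d: DesignMatrices,
    K: RelationshipMatrix | None = None,
    start: VarianceComponents | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    n_em: int = 3,
    K_inv: np.ndarray | None = None,
    logdet_K: float | None = None,
    compute_se: bool = True,
) -> REMLResult:
    """Estimate the covariance blocks by EM-warmed AI-REML.

    ``K`` (or its precomputed inverse plus log-determinant) is the
    relationship matrix of the additive effect; ``None`` means identity.
    Convergence is declared when the norm of the parameter update drops
    below ``tol`` relative to the parameter norm; the gradient norm is
    recorded in the result.  On non-convergence the result is flagged
    and the last iterate retained.
    """
    if K is not None and K_inv is None:
        try:
            c = linalg.cho_factor(K.values, check_finite=False)
        except linalg.LinAlgError:
            raise ValueError(f"{K.kind} matrix is not positive definite") from None
        K_inv = linalg.cho_solve(c, np.eye(K.n), check_finite=False)
        logdet_K = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
        if list(K.ids) != list(d.animal_ids):
            raise ValueError("relationship matrix ids do not match design")
    sys = MMESystem(d, K_inv=K_inv, logdet_K=logdet_K)
    include_pe = d.W0 is not None
    t = d.n_traits
    vc = start or default_start(d)
    names = _param_names(d.traits, include_pe)
    theta = _pack(vc, include_pe)
    trace = []
    n_bends = 0
    converged = False
    work = _REMLWork(sys, vc)
    trace.append(work.m2ll)
    grad_norm = np.nan
    score = ai = None
    flat_ll = 0
    it = 0
    for it in range(1, max_iter + 1):
        st = work.stats()
        if it <= n_em:
            vc_new = work.em_update(st)
            theta_new = _pack(vc_new, include_pe)
            work_new = _REMLWork(sys, vc_new)
            log.info(
                "REML iter %d (EM): -2logL = %.6f", it, work_new.m2ll
            )
        else:
            score, ai = work.score_and_ai(st)
            grad_norm = float(np.linalg.norm(score))
            try:
                delta = np.linalg.solve(ai, score)
            except np.linalg.LinAlgError:
                delta = np.linalg.lstsq(ai, score, rcond=None)[0]
            step = 1.0
            work_new = None
            for halving in range(11):  # up to 10 halvings
                theta_try = theta + step * delta
                vc_try = _unpack(theta_try, t, include_pe)
                if not _all_pd(vc_try, include_pe):
                    if halving < 10:
                        # keep iterates inside the PD cone: a shortened
                        # step from a PD point approaches any boundary
                        # optimum without wrecking conditioning
                        step *= 0.5
                        continue
                    vc_try = _bend_all(vc_try, include_pe)
                    n_bends += 1
                    log.info("REML iter %d: bent a non-PD proposal", it)
                try:
                    cand = _REMLWork(sys, vc_try)
                except (linalg.LinAlgError, ValueError):
                    step *= 0.5
                    continue
                if cand.m2ll <= work.m2ll + 1e-10:
                    work_new, vc_new = cand, vc_try
                    break
                step *= 0.5
            if work_new is None:
                # AI step failed to improve: fall back to an EM update,
                # which cannot decrease the restricted likelihood
                vc_new = work.em_update(st)
                work_new = _REMLWork(sys, vc_new)
                log.info(
                    "REML iter %d (AI rejected, EM fallback): -2logL = %.6f",
                    it,
                    work_new.m2ll,
                )
            else:
                log.info(
                    "REML iter %d (AI, step %.3g): -2logL = %.6f, |grad| = %.3g",
                    it,
                    step,
                    work_new.m2ll,
                    grad_norm,
                )
            theta_new = _pack(vc_new, include_pe)
        change = np.linalg.norm(theta_new - theta) / max(
            np.linalg.norm(theta), 1e-12
        )
        ll_gain = trace[-1] - work_new.m2ll
        theta, vc, work = theta_new, vc_new, work_new
        trace.append(work.m2ll)
        if it > n_em:
            # boundary optima (e.g. a genetic correlation pinned at +-1)
            # creep in parameter space while the likelihood is flat; two
            # consecutive near-zero gains also count as converged
            flat_ll = flat_ll + 1 if abs(ll_gain) < 1e-7 else 0
            if change < tol or flat_ll >= 2:
                converged = True
                break
    if not converged:
        log.warning("AI-REML did not converge in %d iterations", max_iter)

    result = REMLResult(
        vc=vc,
        converged=converged,
        n_iter=it,
        loglik_trace=trace,
        param_names=names,
        gradient_norm=grad_norm,
        n_bends=n_bends,
    )
    if compute_se:
        if score is None or ai is None:
            st = work.stats()
            score, ai = work.score_and_ai(st)
        result.score = score
        result.ai_matrix = ai
        result.se, result.derived, result.derived_se = se_from_ai(
            ai, vc, names, include_pe
        )
    else:
        result.derived = _derived_dict(vc, d.traits)
    return result


def _derived_dict(vc: VarianceComponents, traits) -> dict:
    out = {}
    h2 = vc.heritability()
    rep = vc.repeatability()
    for a, tr in enumerate(traits):
        out[f"h2_{tr}"] = float(h2[a])
        out[f"repeatability_{tr}"] = float(rep[a])
    if vc.n_traits >= 2:
        out["genetic_correlation"] = vc.genetic_correlation()
    return out


def derived_parameters(vc: VarianceComponents, traits=("tne", "nge")) -> dict:
    """Heritability and repeatability per trait plus the genetic correlation.

    h2 = var_a / (var_a + var_pe + var_e); repeatability adds var_pe to
    the numerator; the genetic correlation is the standardized additive
    covariance.
    """
    return _derived_dict(vc, traits[: vc.n_traits])


def se_from_ai(
    ai: np.ndarray,
    vc: VarianceComponents,
    names: list[str],
    include_pe: bool,
) -> tuple[dict | None, dict, dict | None]:
    """Component SEs from the inverse AI matrix; derived SEs by delta method."""
    t = vc.n_traits
    traits = (
        ("tne", "nge")[:t]
        if t <= 2
        else tuple(f"trait{i + 1}" for i in range(t))
    )
    derived = _derived_dict(vc, traits)
    try:
        cov = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        log.warning("singular AI matrix; standard errors unavailable")
        return None, derived, None
    dse = np.sqrt(np.maximum(np.diag(cov), 0.0))
    se = dict(zip(names, dse.tolist()))

    theta = _pack(vc, include_pe)
    keys = list(derived)

    def fvec(th):
        v = _unpack(th, t, include_pe)
        dd = _derived_dict(v, traits)
        return np.array([dd[k] for k in keys])

    # central-difference Jacobian of the derived parameters
    J = np.empty((len(keys), len(theta)))
    for k in range(len(theta)):
        h = 1e-6 * max(abs(theta[k]), 1.0)
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h
        tm[k] -= h
        J[:, k] = (fvec(tp) - fvec(tm)) / (2 * h)
    dvar = np.einsum("ik,kl,il->i", J, cov, J)
    derived_se = dict(zip(keys, np.sqrt(np.maximum(dvar, 0.0)).tolist()))
    return se, derived, derived_se
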