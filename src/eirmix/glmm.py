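"""Logistic mixed models with crossed random intercepts via Laplace approximation.

The model for a binary response of person ``j`` on item ``i`` is

    logit P(y_ji = 1) = x_ji' beta + theta_j + b_i,
    theta_j ~ N(0, sigma2_person),  b_i ~ N(0, sigma2_item),

with the two random-intercept factors crossed (every observation carries one
person effect and one item effect).  The marginal likelihood is approximated
by Laplace's method: for candidate variance parameters an inner Newton search
finds the joint mode of the random effects, exploiting the two-block sparsity
of the Hessian (the person block is diagonal; the item block is small), and an
outer optimizer maximizes the approximate marginal log-likelihood.

Fitting proceeds in two stages: a fast profile stage in which ``beta`` is
maximized jointly with the random-effect modes inside the penalized Newton
step, and a refinement stage in which ``beta`` is moved into the outer
optimization of the full Laplace objective (the convention of mainstream
mixed-model software), which shifts the estimates slightly because the
log-determinant term depends on ``beta`` through the IRLS weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize as sopt
import scipy.sparse as sp

from .errors import ConvergenceError, DesignError

LOGISTIC_VARIANCE = math.pi**2 / 3.0
_VAR_FLOOR = 1e-10
_BOUNDARY_TOL = 1e-8
_MU_EPS = 1e-10


def conditional_icc(sigma2: float) -> float:
    """Conditional intraclass correlation on the latent-response scale.

    For a logistic model the latent residual variance is pi^2/3, so the
    correlation between two latent responses sharing one random intercept of
    variance ``sigma2`` (conditional on the other factor's effects) is
    ``sigma2 / (sigma2 + pi^2/3)``.
    """
    if sigma2 < 0:
        raise ValueError("variance must be nonnegative")
    return sigma2 / (sigma2 + LOGISTIC_VARIANCE)


def _expit(eta):
    return 0.5 * (1.0 + np.tanh(0.5 * eta))


def _bernoulli_loglik(y, eta):
    # log p(y | eta) summed; numerically stable via logaddexp
    return float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))


@dataclass
class GlmmFit:
    beta: np.ndarray
    beta_cov: np.ndarray
    se: np.ndarray
    sigma2_person: float
    sigma2_item: float
    person_modes: np.ndarray
    item_modes: np.ndarray
    laplace_loglik: float
    converged: bool
    boundary: bool
    n_inner_iters: int
    n_outer_iters: int
    beta_names: list = field(default_factory=list)
    trace: list = field(default_factory=list)

    @property
    def icc_person(self) -> float:
        return conditional_icc(self.sigma2_person)

    @property
    def icc_item(self) -> float:
        return conditional_icc(self.sigma2_item)

    def summary(self) -> dict:
        z = np.divide(self.beta, self.se, out=np.full_like(self.beta, np.nan),
                      where=self.se > 0)
        return {
            "coefficients": [
                {"name": n, "estimate": float(b), "se": float(s), "z": float(zz)}
                for n, b, s, zz in zip(self.beta_names, self.beta, self.se, z)
            ],
            "sigma2_person": float(self.sigma2_person),
            "sigma2_item": float(self.sigma2_item),
            "icc_person": float(self.icc_person),
            "icc_item": float(self.icc_item),
            "laplace_loglik": float(self.laplace_loglik),
            "converged": bool(self.converged),
            "boundary": bool(self.boundary),
            "n_inner_iters": int(self.n_inner_iters),
            "n_outer_iters": int(self.n_outer_iters),
        }


class _Workspace:
    """Precomputed index structure for one (y, X, person, item) problem."""

    def __init__(self, y, X, person_index, item_index):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.n, self.p = self.X.shape
        self.pj = np.asarray(person_index, dtype=int)
        self.ii = np.asarray(item_index, dtype=int)
        self.J = int(self.pj.max()) + 1 if self.n else 0
        self.I = int(self.ii.max()) + 1 if self.n else 0
        if self.pj.min() < 0 or self.ii.min() < 0:
            raise DesignError("negative person/item indices")
        if np.linalg.matrix_rank(self.X) < self.p:
            raise DesignError("fixed-effect design matrix is rank deficient")

    def eta(self, beta, theta, b):
        out = self.X @ beta
        if theta is not None:
            out = out + theta[self.pj]
        if b is not None:
            out = out + b[self.ii]
        return out


def _penalized_loglik(ws, beta, theta, b, s2p, s2i):
    val = _bernoulli_loglik(ws.y, ws.eta(beta, theta, b))
    if theta is not None:
        val -= 0.5 * float(theta @ theta) / s2p
    if b is not None:
        val -= 0.5 * float(b @ b) / s2i
    return val


def _newton_joint(ws, s2p, s2i, beta, theta, b, include_beta,
                  tol=1e-8, max_iter=200):
    """Damped Newton for the penalized log-likelihood.

    Optimizes the random-effect modes (and ``beta`` when ``include_beta``)
    with exact block elimination: person block diagonal, item block dense
    (I x I), fixed-effect block dense (p x p).  Returns the mode, the pieces
    needed for the Laplace log-determinant, and an iteration count.
    """
    use_p = s2p is not None
    use_i = s2i is not None
    y, X, pj, ii = ws.y, ws.X, ws.pj, ws.ii
    n, p, J, I = ws.n, ws.p, ws.J, ws.I

    theta = np.zeros(J) if (use_p and theta is None) else theta
    b = np.zeros(I) if (use_i and b is None) else b

    f = _penalized_loglik(ws, beta, theta if use_p else None, b if use_i else None,
                          s2p, s2i)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        eta = ws.eta(beta, theta if use_p else None, b if use_i else None)
        mu = np.clip(_expit(eta), _MU_EPS, 1 - _MU_EPS)
        w = mu * (1 - mu)
        resid = y - mu

        g_parts = []
        if include_beta:
            g_beta = X.T @ resid
            g_parts.append(g_beta)
        if use_p:
            g_theta = np.bincount(pj, weights=resid, minlength=J) - theta / s2p
            g_parts.append(g_theta)
        if use_i:
            g_b = np.bincount(ii, weights=resid, minlength=I) - b / s2i
            g_parts.append(g_b)
        gnorm = max((np.max(np.abs(g)) for g in g_parts), default=0.0)
        if gnorm < tol:
            converged = True
            break

        # Hessian blocks
        if use_p:
            Dth = np.bincount(pj, weights=w, minlength=J) + 1.0 / s2p
        if use_i:
            Dbb = np.bincount(ii, weights=w, minlength=I) + 1.0 / s2i
        if include_beta:
            Hbb_beta = (X * w[:, None]).T @ X
            if use_p:
                Hbeta_th = np.vstack(
                    [np.bincount(pj, weights=w * X[:, k], minlength=J)
                     for k in range(p)]
                )  # p x J
            if use_i:
                Hbeta_i = np.vstack(
                    [np.bincount(ii, weights=w * X[:, k], minlength=I)
                     for k in range(p)]
                )  # p x I

        if use_p and use_i:
            C = sp.csr_matrix((w, (pj, ii)), shape=(J, I))
            CtDinv = C.multiply(1.0 / Dth[:, None]).T.tocsr()  # I x J (scaled)
            S_ii = np.diag(Dbb) - (CtDinv @ C).toarray()
        elif use_i:
            S_ii = np.diag(Dbb)

        # assemble the reduced (item + beta) system after eliminating theta
        rhs = []
        if use_i:
            gb_t = g_b - (CtDinv @ g_theta) if use_p else g_b
            rhs.append(gb_t)
        if include_beta:
            gbeta_t = g_beta - Hbeta_th @ (g_theta / Dth) if use_p else g_beta
            rhs.append(gbeta_t)

        blocks = []
        if use_i and include_beta:
            S_ib = (Hbeta_i.T - (CtDinv @ Hbeta_th.T)) if use_p else Hbeta_i.T
            S_bb = Hbb_beta - (Hbeta_th / Dth) @ Hbeta_th.T if use_p else Hbb_beta
            top = np.hstack([S_ii, S_ib])
            bot = np.hstack([S_ib.T, S_bb])
            K = np.vstack([top, bot])
        elif use_i:
            K = S_ii
        elif include_beta:
            K = Hbb_beta - (Hbeta_th / Dth) @ Hbeta_th.T if use_p else Hbb_beta
        else:
            K = None

        if K is not None:
            try:
                sol = np.linalg.solve(K, np.concatenate(rhs))
            except np.linalg.LinAlgError:
                # near-singular under saturated weights: retry with a ridge
                K = K + 1e-8 * np.eye(K.shape[0])
                sol = np.linalg.solve(K, np.concatenate(rhs))
            off = 0
            if use_i:
                d_b = sol[:I]
                off = I
            if include_beta:
                d_beta = sol[off:off + p]
        if use_p:
            back = g_theta.copy()
            if use_i:
                back -= C @ d_b
            if include_beta:
                back -= Hbeta_th.T @ d_beta
            d_theta = back / Dth

        # damped update
        step = 1.0
        for _ in range(40):
            nb = beta + step * d_beta if include_beta else beta
            nt = theta + step * d_theta if use_p else theta
            ni = b + step * d_b if use_i else b
            fn = _penalized_loglik(ws, nb, nt if use_p else None,
                                   ni if use_i else None, s2p, s2i)
            if np.isfinite(fn) and fn >= f - 1e-12:
                break
            step *= 0.5
        else:
            # no ascent possible at machine precision: stationary point
            break
        beta, theta, b = nb, nt, ni
        if abs(fn - f) < 1e-13 * max(1.0, abs(f)) and gnorm < 1e-4:
            f = fn
            converged = True
            break
        f = fn

    # log-determinant of the random-effects Hessian at the mode
    eta = ws.eta(beta, theta if use_p else None, b if use_i else None)
    mu = np.clip(_expit(eta), _MU_EPS, 1 - _MU_EPS)
    w = mu * (1 - mu)
    logdet = 0.0
    if use_p:
        Dth = np.bincount(pj, weights=w, minlength=J) + 1.0 / s2p
        logdet += float(np.sum(np.log(Dth)))
    if use_i:
        Dbb = np.bincount(ii, weights=w, minlength=I) + 1.0 / s2i
        if use_p:
            C = sp.csr_matrix((w, (pj, ii)), shape=(J, I))
            S_ii = np.diag(Dbb) - (C.multiply(1.0 / Dth[:, None]).T @ C).toarray()
        else:
            S_ii = np.diag(Dbb)
        sign, ld = np.linalg.slogdet(S_ii)
        if sign <= 0:
            raise ConvergenceError("random-effects Hessian not positive definite")
        logdet += float(ld)

    return beta, theta, b, f, logdet, converged, n_iter, mu, w


def _laplace_loglik(ws, s2p, s2i, beta, theta, b, f_pen, logdet):
    val = f_pen - 0.5 * logdet
    if s2p is not None:
        val -= 0.5 * ws.J * math.log(s2p)
    if s2i is not None:
        val -= 0.5 * ws.I * math.log(s2i)
    return val


def _beta_covariance(ws, beta, theta, b, s2p, s2i):
    """Wald covariance of beta from the Laplace (joint) Hessian."""
    use_p = s2p is not None
    use_i = s2i is not None
    X, pj, ii = ws.X, ws.pj, ws.ii
    p, J, I = ws.p, ws.J, ws.I
    eta = ws.eta(beta, theta if use_p else None, b if use_i else None)
    mu = np.clip(_expit(eta), _MU_EPS, 1 - _MU_EPS)
    w = mu * (1 - mu)
    Hbb = (X * w[:, None]).T @ X
    if use_p:
        Dth = np.bincount(pj, weights=w, minlength=J) + 1.0 / s2p
        Hbt = np.vstack([np.bincount(pj, weights=w * X[:, k], minlength=J)
                         for k in range(p)])
        Hbb = Hbb - (Hbt / Dth) @ Hbt.T
    if use_i:
        Dbb = np.bincount(ii, weights=w, minlength=I) + 1.0 / s2i
        Hbi = np.vstack([np.bincount(ii, weights=w * X[:, k], minlength=I)
                         for k in range(p)])
        if use_p:
            C = sp.csr_matrix((w, (pj, ii)), shape=(J, I))
            S_ii = np.diag(Dbb) - (C.multiply(1.0 / Dth[:, None]).T @ C).toarray()
            Hbi_t = Hbi - (Hbt / Dth) @ (C.toarray())
        else:
            S_ii = np.diag(Dbb)
            Hbi_t = Hbi
        Hbb = Hbb - Hbi_t @ np.linalg.solve(S_ii, Hbi_t.T)
    try:
        cov = np.linalg.inv(Hbb)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return cov


def fit_crossed_logit(
    y,
    X,
    person_index,
    item_index,
    fix_variances=None,
    tol: float = 1e-6,
    inner_tol: float = 1e-8,
    max_outer: int = 100,
    max_inner: int = 200,
    start_sigma2: float = 0.5,
    refine_beta: bool = True,
    on_divergence: str = "raise",
    beta_names=None,
) -> GlmmFit:
    """Fit the crossed random-intercept logistic model by Laplace approximation.

    Parameters
    ----------
    y, X : binary response vector and full-column-rank fixed design.
    person_index, item_index : integer cluster codes (0-based, dense).
    fix_variances : optional pair fixing (sigma2_person, sigma2_item); a value
        of 0 removes that random term entirely (at (0, 0) the fit is ordinary
        logistic regression).
    refine_beta : run the joint (beta, log sigma) outer optimization of the
        Laplace objective after the fast profile stage.
    on_divergence : under (quasi-)complete separation the slope estimates are
        unbounded; ``"raise"`` raises :class:`ConvergenceError`, ``"flag"``
        returns the stalled fit with ``converged=False`` (used by the hybrid,
        where a memorizing forest can separate the pseudo-response).
    """
    ws = _Workspace(y, X, person_index, item_index)
    if np.all(ws.y == ws.y[0]):
        raise ConvergenceError("degenerate outcome: response is constant (separation)")

    fixed = fix_variances is not None
    if fixed:
        s2p0, s2i0 = fix_variances
        if s2p0 < 0 or s2i0 < 0:
            raise ValueError("variances must be nonnegative")
    else:
        s2p0 = s2i0 = start_sigma2

    state = {"beta": np.zeros(ws.p), "theta": None, "b": None, "inner": 0}
    trace = []

    def profile_obj(log_s2):
        s2p = math.exp(log_s2[0]) if log_s2[0] is not None else None
        s2i = math.exp(log_s2[1]) if log_s2[1] is not None else None
        return _profile_eval(s2p, s2i)

    def _profile_eval(s2p, s2i):
        res = _newton_joint(ws, s2p, s2i, state["beta"], state["theta"],
                            state["b"], include_beta=True,
                            tol=inner_tol, max_iter=max_inner)
        beta, theta, b, f_pen, logdet, conv, n_it, mu, w = res
        state.update(beta=beta, theta=theta, b=b)
        state["inner"] += n_it
        ll = _laplace_loglik(ws, s2p, s2i, beta, theta, b, f_pen, logdet)
        trace.append(ll)
        return ll

    n_outer = 0
    if fixed:
        s2p = s2p0 if s2p0 > _BOUNDARY_TOL else None
        s2i = s2i0 if s2i0 > _BOUNDARY_TOL else None
        ll = _profile_eval(s2p, s2i)
        converged = True
    else:
        def nm_obj(x):
            xs = np.clip(x, math.log(_VAR_FLOOR), math.log(100.0))
            return -_profile_eval(math.exp(xs[0]), math.exp(xs[1]))

        x0 = np.array([math.log(s2p0), math.log(s2i0)])
        res = sopt.minimize(nm_obj, x0, method="Nelder-Mead",
                            options={"xatol": 1e-4, "fatol": tol,
                                     "maxiter": max_outer * 4})
        n_outer = int(res.nit)
        xs = np.clip(res.x, math.log(_VAR_FLOOR), math.log(100.0))
        s2p, s2i = math.exp(xs[0]), math.exp(xs[1])
        ll = -float(res.fun)
        converged = bool(res.success)
        # collapse components at the boundary and re-profile
        drop_p = s2p < _BOUNDARY_TOL
        drop_i = s2i < _BOUNDARY_TOL
        if drop_p or drop_i:
            s2p = None if drop_p else s2p
            s2i = None if drop_i else s2i
            state.update(theta=None, b=None)
            ll = _profile_eval(s2p, s2i)

    if refine_beta and (s2p is not None or s2i is not None):
        ll, s2p, s2i, extra_outer, converged_r = _joint_refine(
            ws, state, s2p, s2i, fixed, tol, inner_tol, max_inner, max_outer)
        n_outer += extra_outer
        converged = converged and converged_r
        trace.append(ll)

    beta, theta, b = state["beta"], state["theta"], state["b"]
    # separation check: unbounded estimates under (near) perfect prediction
    eta = ws.eta(beta, theta, b)
    if np.max(np.abs(beta)) > 100 or np.max(np.abs(eta)) > 150:
        if on_divergence != "flag":
            raise ConvergenceError(
                "estimates diverged (quasi-complete separation)", trace=trace)
        converged = False

    cov = _beta_covariance(ws, beta, theta, b, s2p, s2i)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    s2p_out = float(s2p) if s2p is not None else 0.0
    s2i_out = float(s2i) if s2i is not None else 0.0
    boundary = (s2p_out < _BOUNDARY_TOL) or (s2i_out < _BOUNDARY_TOL)
    return GlmmFit(
        beta=beta,
        beta_cov=cov,
        se=se,
        sigma2_person=s2p_out,
        sigma2_item=s2i_out,
        person_modes=theta if theta is not None else np.zeros(ws.J),
        item_modes=b if b is not None else np.zeros(ws.I),
        laplace_loglik=float(ll),
        converged=bool(converged),
        boundary=boundary,
        n_inner_iters=int(state["inner"]),
        n_outer_iters=int(n_outer),
        beta_names=list(beta_names) if beta_names is not None
        else [f"x{k}" for k in range(ws.p)],
        trace=trace,
    )


def _joint_refine(ws, state, s2p, s2i, var_fixed, tol, inner_tol, max_inner,
                  max_outer):
    """Outer optimization of the Laplace objective over (beta, log sigma2).

    The random-effect modes are re-found by an inner Newton (over the random
    effects only) at each objective evaluation, warm-started from the previous
    mode.
    """
    use_p = s2p is not None
    use_i = s2i is not None
    p = ws.p

    def unpack(params):
        beta = params[:p]
        k = p
        sp_ = s2p
        si_ = s2i
        if not var_fixed:
            if use_p:
                sp_ = math.exp(np.clip(params[k], math.log(_VAR_FLOOR),
                                       math.log(100.0)))
                k += 1
            if use_i:
                si_ = math.exp(np.clip(params[k], math.log(_VAR_FLOOR),
                                       math.log(100.0)))
        return beta, sp_, si_

    def neg_obj(params):
        beta, sp_, si_ = unpack(params)
        res = _newton_joint(ws, sp_ if use_p else None, si_ if use_i else None,
                            beta, state["theta"], state["b"],
                            include_beta=False, tol=inner_tol,
                            max_iter=max_inner)
        _, theta, b, f_pen, logdet, _, n_it, _, _ = res
        state.update(theta=theta, b=b)
        state["inner"] += n_it
        ll = _laplace_loglik(ws, sp_ if use_p else None, si_ if use_i else None,
                             beta, theta, b, f_pen, logdet)
        return -ll

    x0 = list(state["beta"])
    if not var_fixed:
        if use_p:
            x0.append(math.log(s2p))
        if use_i:
            x0.append(math.log(s2i))
    res = sopt.minimize(neg_obj, np.asarray(x0), method="L-BFGS-B",
                        options={"maxiter": max_outer, "ftol": min(tol * 1e-2, 1e-11),
                                 "gtol": 1e-7})
    beta, sp_, si_ = unpack(res.x)
    state["beta"] = np.asarray(beta)
    neg = neg_obj(res.x)  # leave modes consistent with the optimum
    return -neg, sp_, si_, int(res.nit), bool(res.success)


def predict_prob(fit: GlmmFit, X, person_index=None, item_index=None,
                 include_random: bool = True) -> np.ndarray:
    """Predicted response probabilities from a fitted model.

    ``person_index``/``item_index`` are cluster codes into the fit's mode
    vectors; a code of -1 (or ``None`` arrays) marks an unseen cluster, which
    contributes 0 on the logit scale (population-average prediction).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(fit.beta):
        raise DesignError(
            f"design has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"expected {len(fit.beta)}"
        )
    eta = X @ fit.beta
    if include_random:
        if person_index is not None:
            pidx = np.asarray(person_index, dtype=int)
            ok = (pidx >= 0) & (pidx < len(fit.person_modes))
            eta = eta + np.where(ok, fit.person_modes[np.clip(pidx, 0, None)], 0.0)
        if item_index is not None:
            iidx = np.asarray(item_index, dtype=int)
            ok = (iidx >= 0) & (iidx < len(fit.item_modes))
            eta = eta + np.where(ok, fit.item_modes[np.clip(iidx, 0, None)], 0.0)
    return _expit(eta)
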