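"""Average-information REML for reaction-norm mixed models.

The model for one phenotype record per animal is

    y = X beta + g + e,      g_i = z(w_i)' b_i,
    {b} ~ N(0, A (x) K),     e_i ~ N(0, exp(eta' z_r(w_i))),

so the phenotypic covariance among the n recorded animals is

    V = (W K W') o A22 + diag(exp(Zr eta)),

where W stacks the genetic basis rows z(w_i)', A22 is the relationship
block among recorded animals, and "o" is the Hadamard product.  REML is
maximised directly in this marginal form: non-recorded relatives are exact
marginalised out and their coefficient solutions are recovered afterwards
by kriging through the pedigree.

Two interchangeable backends evaluate the likelihood and its
average-information (AI) updates:

* ``DenseCore`` forms V explicitly - exact for any relationship block,
  intended for datasets up to a few thousand records.
* ``FactoredCore`` uses A22 = diag(d0) + F F' (available when recorded
  animals are progeny of founder parents, the standard AI-sire half-sib
  design) and evaluates everything through the Woodbury identity in
  O(n (qm)^2) per iteration, never forming an n x n matrix.

K is optimised through its Cholesky factor (always psd); damped AI-Newton
steps alternate with an L-BFGS polish until a scale-invariant
stationarity measure (the expected gain of a damped Newton step) is met.
Eigenvalue bending only repairs indefinite starting values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as la
import scipy.sparse as sp

__all__ = ["REMLOptions", "REMLResult", "DenseCore", "FactoredCore", "ai_reml"]

LOG2PI = np.log(2.0 * np.pi)


@dataclass
class REMLOptions:
    max_iter: int = 60
    tol_logL: float = 1e-6
    tol_param: float = 1e-8
    max_halvings: int = 12
    bend_rel: float = 1e-6  # eigenvalue floor relative to largest
    polish_maxfun: int = 100  # L-BFGS evaluation budget for the polish stage
    verbose: bool = False


@dataclass
class REMLResult:
    K: np.ndarray
    eta: np.ndarray
    logL: float
    converged: bool
    n_iter: int
    history: list = field(default_factory=list)
    beta: np.ndarray | None = None
    Py: np.ndarray | None = None
    bent: bool = False


class ConvergenceError(RuntimeError):
    def __init__(self, msg, history):
        super().__init__(msg)
        self.history = history


def _bend(K: np.ndarray, floor_abs: float, rel: float) -> tuple[np.ndarray, bool]:
    """Clip negative/tiny eigenvalues so K stays invertible psd."""
    K = 0.5 * (K + K.T)
    ev, V = np.linalg.eigh(K)
    floor = max(rel * max(ev.max(), 0.0), floor_abs)
    if ev.min() >= floor:
        return K, False
    return (V * np.maximum(ev, floor)) @ V.T, True


# ---------------------------------------------------------------------------
class _CoreBase:
    """Shared parameter packing and AI-update plumbing."""

    def __init__(self, y, X, W, Zr):
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        self.W = np.asarray(W, float)
        self.Zr = np.asarray(Zr, float)
        self.n = len(self.y)
        self.p = self.X.shape[1]
        self.q = self.W.shape[1]
        self.c = self.Zr.shape[1]
        self.k_pairs = [(r, s) for r in range(self.q) for s in range(r, self.q)]
        self.n_par = len(self.k_pairs) + self.c

    # packing -----------------------------------------------------------
    def pack(self, K, eta):
        return np.concatenate([[K[r, s] for r, s in self.k_pairs], eta])

    def unpack(self, theta):
        K = np.zeros((self.q, self.q))
        for v, (r, s) in zip(theta, self.k_pairs):
            K[r, s] = K[s, r] = v
        return K, np.asarray(theta[len(self.k_pairs):], float)

    def resid_var(self, eta):
        return np.exp(np.clip(self.Zr @ eta, -40.0, 40.0))


# ---------------------------------------------------------------------------
class DenseCore(_CoreBase):
    """Reference backend with an explicit V (and P) matrix."""

    def __init__(self, y, X, W, Zr, A22):
        super().__init__(y, X, W, Zr)
        self.A22 = np.asarray(A22, float)
        if self.A22.shape != (self.n, self.n):
            raise ValueError("A22 shape does not match the record count")

    def set_params(self, K, eta) -> float:
        self.K, self.eta = K, eta
        self.r = self.resid_var(eta)
        V = (self.W @ K @ self.W.T) * self.A22
        V[np.diag_indices_from(V)] += self.r
        cho = la.cho_factor(V, lower=True)
        self.Vi = la.cho_solve(cho, np.eye(self.n))
        logdetV = 2.0 * np.sum(np.log(np.diag(cho[0])))
        self.U = self.Vi @ self.X
        XtViX = self.X.T @ self.U
        sign, logdetX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            raise np.linalg.LinAlgError("X'V^-1X not positive definite")
        self.Cx = np.linalg.inv(XtViX)
        Viy = self.Vi @ self.y
        self.beta = self.Cx @ (self.X.T @ Viy)
        self.Py = Viy - self.U @ self.beta
        self.yPy = float(self.y @ self.Py)
        self.P = self.Vi - self.U @ self.Cx @ self.U.T
        self.logL = -0.5 * (
            (self.n - self.p) * LOG2PI + logdetV + logdetX + self.yPy
        )
        return self.logL

    def _dV(self, i):
        if i < len(self.k_pairs):
            r, s = self.k_pairs[i]
            M = np.outer(self.W[:, r], self.W[:, s]) * self.A22
            return M + M.T if r != s else M
        m = i - len(self.k_pairs)
        return np.diag(self.r * self.Zr[:, m])

    def derivatives(self, want_ai: bool = True):
        T = np.empty((self.n, self.n_par))
        grad = np.empty(self.n_par)
        for i in range(self.n_par):
            dV = self._dV(i)
            t = dV @ self.Py
            T[:, i] = t
            grad[i] = -0.5 * (np.sum(self.P * dV) - float(self.Py @ t))
        if not want_ai:
            return grad, None
        PT = self.P @ T
        AI = 0.5 * T.T @ PT
        return grad, AI

    def vinv_apply(self, M):
        return self.Vi @ M

    def relationship_matvec(self, v):
        return self.A22 @ v


# ---------------------------------------------------------------------------
class FactoredCore(_CoreBase):
    """Woodbury backend for A22 = diag(d0) + F F' (half-sib designs)."""

    def __init__(self, y, X, W, Zr, d0, F):
        super().__init__(y, X, W, Zr)
        self.d0 = np.asarray(d0, float)
        self.F = sp.csr_matrix(F)
        self.m = self.F.shape[1]
        self._DF = [self.F.multiply(self.W[:, r][:, None]).tocsr() for r in range(self.q)]
        # the low-rank factor B = [D_1 F ... D_q F] is parameter-free
        self.B0 = sp.hstack(self._DF, format="csr") if self.m else None
        self.Xs = sp.csr_matrix(self.X)  # fixed effects are mostly CG dummies

    def set_params(self, K, eta) -> float:
        # a tiny relative ridge keeps K invertible (the Woodbury form needs
        # K^-1) while leaving the likelihood smooth as the optimiser walks
        # onto the psd boundary; the perturbation is O(1e-10) relative
        K = np.asarray(K, float)
        K = K + (1e-10 * max(np.trace(K) / self.q, 1e-30)) * np.eye(self.q)
        self.K, self.eta = K, eta
        self.r = self.resid_var(eta)
        u = np.einsum("ij,jk,ik->i", self.W, K, self.W)
        self.Rt = self.r + self.d0 * u
        self.Ri = 1.0 / self.Rt
        m = self.m
        if m:
            self.Q = self.B0.multiply(self.Ri[:, None]).tocsr()
            Kinv = np.linalg.inv(K)
            Minner = np.kron(Kinv, np.eye(m)) + (self.B0.T @ self.Q).toarray()
            self.cho_M = la.cho_factor(Minner, lower=True)
            sign, logdetK = np.linalg.slogdet(K)
            if sign <= 0:
                raise np.linalg.LinAlgError("K not positive definite")
            logdetV = (
                float(np.sum(np.log(self.Rt)))
                + m * logdetK
                + 2.0 * np.sum(np.log(np.diag(self.cho_M[0])))
            )
        else:
            self.Q = None
            logdetV = float(np.sum(np.log(self.Rt)))
        # U = V^-1 X through the sparse X path
        RiX = self.Xs.multiply(self.Ri[:, None]).tocsr()
        if m:
            t = (self.Q.T @ self.Xs).toarray()
            self.U = RiX.toarray() - self.Q @ la.cho_solve(self.cho_M, t)
        else:
            self.U = RiX.toarray()
        XtViX = (self.Xs.T @ self.U)
        sign, logdetX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            raise np.linalg.LinAlgError("X'V^-1X not positive definite")
        self.Cx = np.linalg.inv(XtViX)
        Viy = self.vinv_apply(self.y)
        self.beta = self.Cx @ (self.Xs.T @ Viy)
        self.Py = Viy - self.U @ self.beta
        self.yPy = float(self.y @ self.Py)
        self.logL = -0.5 * (
            (self.n - self.p) * LOG2PI + logdetV + logdetX + self.yPy
        )
        return self.logL

    # ----------------------------------------------------------------- ops
    def vinv_apply(self, M):
        one_d = np.ndim(M) == 1
        Md = M[:, None] if one_d else np.asarray(M, float)
        out = self.Ri[:, None] * Md
        if self.Q is not None:
            out = out - self.Q @ la.cho_solve(self.cho_M, self.Q.T @ Md)
        return out[:, 0] if one_d else out

    def relationship_matvec(self, v):
        out = self.d0[:, None] * (v[:, None] if v.ndim == 1 else v)
        if self.m:
            out = out + self.F @ (self.F.T @ (v[:, None] if v.ndim == 1 else v))
        return out[:, 0] if v.ndim == 1 else out

    def derivatives(self, want_ai: bool = True):
        nk = len(self.k_pairs)
        W, d0 = self.W, self.d0
        # diagonal of V^-1 and of the projector P
        diagVi = self.Ri.copy()
        if self.m:
            Minv = la.cho_solve(self.cho_M, np.eye(self.q * self.m))
            QM = self.Q @ Minv
            diagVi = diagVi - np.asarray(self.Q.multiply(QM).sum(axis=1)).ravel()
        UC = self.U @ self.Cx
        h = np.einsum("ij,ij->i", self.U, UC)
        diagP = diagVi - h

        # per-coefficient worker matrices
        Ys, Es = [], []
        for r in range(self.q):
            DF = self._DF[r]
            if self.m:
                Ys.append(self.vinv_apply(DF.toarray()))
                Es.append((DF.T @ self.U))  # m x p
            else:
                Ys.append(None)
                Es.append(None)

        grad = np.empty(self.n_par)
        T = np.empty((self.n, self.n_par))
        dv = diagVi * d0
        hp = h * d0
        for i, (r, s) in enumerate(self.k_pairs):
            t1 = float(np.sum(dv * W[:, r] * W[:, s]))
            c1 = float(np.sum(hp * W[:, r] * W[:, s]))
            t2 = c2 = 0.0
            if self.m:
                t2 = float(self._DF[s].multiply(Ys[r]).sum())
                c2 = float(np.sum((np.asarray(Es[r]) @ self.Cx) * np.asarray(Es[s])))
            trP = (t1 + t2) - (c1 + c2)
            tvec = W[:, r] * self.relationship_matvec(W[:, s] * self.Py)
            if r != s:
                trP *= 2.0
                tvec = tvec + W[:, s] * self.relationship_matvec(W[:, r] * self.Py)
            T[:, i] = tvec
            grad[i] = -0.5 * (trP - float(self.Py @ tvec))
        for m_i in range(self.c):
            dvec = self.r * self.Zr[:, m_i]
            trP = float(np.sum(diagP * dvec))
            tvec = dvec * self.Py
            T[:, nk + m_i] = tvec
            grad[nk + m_i] = -0.5 * (trP - float(self.Py @ tvec))
        if not want_ai:
            return grad, None
        PT = self.vinv_apply(T) - UC @ (self.U.T @ T)
        AI = 0.5 * T.T @ PT
        return grad, AI


# ---------------------------------------------------------------------------
def ai_reml(core, K0, eta0, options: REMLOptions | None = None) -> REMLResult:
    """Maximise the restricted likelihood: AI-Newton / quasi-Newton cycles.

    K is optimised through its Cholesky factor (K = L L'), which keeps it
    positive semi-definite without projecting steps; bending only repairs an
    indefinite starting value.  Newton steps use the average-information
    matrix mapped through the Jacobian of K = L L', Levenberg-damped,
    trust-region capped and halved until the likelihood does not decrease.
    When Newton progress stalls (curved valleys near the psd boundary), an
    L-BFGS polish takes over; the two alternate until the expected gain of
    a damped Newton step - a scale-invariant stationarity measure - drops
    below tolerance.
    """
    opt = options or REMLOptions()
    q = core.q
    scale = max(np.trace(np.asarray(K0, float)) / q, 1e-6)
    floor_abs = 1e-10 * scale
    K_start, bent_any = _bend(np.asarray(K0, float), floor_abs, opt.bend_rel)
    L = np.linalg.cholesky(K_start)
    eta = np.asarray(eta0, float).copy()
    l_pairs = [(r, s) for r in range(q) for s in range(r + 1)]  # lower triangle
    nl, nk, nc = len(l_pairs), len(core.k_pairs), core.c

    def theta_of(L, eta):
        return np.concatenate([[L[r, s] for r, s in l_pairs], eta])

    def split(theta):
        Lm = np.zeros((q, q))
        for v, (r, s) in zip(theta, l_pairs):
            Lm[r, s] = v
        return Lm, np.asarray(theta[nl:], float)


    def jacobian(L):
        """J[k_pair, l_param] = d K_rs / d L_ab for K = L L'."""
        J = np.zeros((nk, nl))
        for jcol, (a, b) in enumerate(l_pairs):
            for irow, (r, s) in enumerate(core.k_pairs):
                v = 0.0
                if r == a:
                    v += L[s, b]
                if s == a:
                    v += L[r, b]
                J[irow, jcol] = v
        return J

    state = {"L": L, "eta": eta}
    state["logL"] = core.set_params(
        state["L"] @ state["L"].T, state["eta"]
    )
    history = [state["logL"]]
    n_newton = 0

    def newton_gain():
        """Expected logL gain of a damped Newton step at the current point."""
        gK, AIK = core.derivatives()
        J = jacobian(state["L"])
        g = np.concatenate([J.T @ gK[:nk], gK[nk:]])
        A = np.zeros((nl + nc, nl + nc))
        A[:nl, :nl] = J.T @ AIK[:nk, :nk] @ J
        A[:nl, nl:] = J.T @ AIK[:nk, nk:]
        A[nl:, :nl] = A[:nl, nl:].T
        A[nl:, nl:] = AIK[nk:, nk:]
        A[np.diag_indices_from(A)] += 1e-8 * max(np.trace(A), 1.0)
        try:
            step = la.solve(A, g, assume_a="pos")
            return float(0.5 * g @ step)
        except np.linalg.LinAlgError:
            return float(np.sum(g * g) / max(np.trace(A), 1.0))

    def newton_phase(budget):
        nonlocal n_newton
        flat = slow = 0
        for _ in range(budget):
            n_newton += 1
            L_cur, eta_cur, logL = state["L"], state["eta"], state["logL"]
            K_cur = L_cur @ L_cur.T
            grad_K, AI_K = core.derivatives()
            J = jacobian(L_cur)
            Jfull = np.zeros((nk + nc, nl + nc))
            Jfull[:nk, :nl] = J
            Jfull[nk:, nl:] = np.eye(nc)
            grad = Jfull.T @ grad_K
            AI = Jfull.T @ AI_K @ Jfull
            theta = theta_of(L_cur, eta_cur)
            s = np.ones_like(theta)
            rms = max(np.sqrt(np.trace(K_cur) / q), 1e-3 * np.sqrt(scale))
            s[:nl] = np.maximum(np.abs(theta[:nl]), 0.1 * rms)
            lam = 1e-8 * max(np.trace(AI), 1.0) / len(theta)
            step = None
            for _i in range(10):
                try:
                    step = la.cho_solve(
                        la.cho_factor(AI + lam * np.eye(len(theta))), grad
                    )
                    if np.all(np.isfinite(step)):
                        break
                except np.linalg.LinAlgError:
                    pass
                lam *= 100.0
                step = None
            if step is None:
                step = grad * s * s / max(np.abs(grad * s).max(), 1.0)
            over = np.max(np.abs(step) / (5.0 * s))
            if over > 1.0:  # cap wild early moves
                step = step / over

            def try_direction(direction):
                frac = 1.0
                for _h in range(opt.max_halvings):
                    L_try, eta_try = split(theta + frac * direction)
                    try:
                        cand = core.set_params(L_try @ L_try.T, eta_try)
                    except np.linalg.LinAlgError:
                        frac *= 0.5
                        continue
                    if np.isfinite(cand) and cand >= logL - 1e-10:
                        return L_try, eta_try, cand
                    frac *= 0.5
                return None

            hit = try_direction(step)
            if hit is None:
                diag = np.maximum(np.diag(AI), 1e-12)
                hit = try_direction(grad / diag)
            if hit is None:
                core.set_params(K_cur, eta_cur)
                return "stuck"
            L_new, eta_new, new_logL = hit
            d_logL = new_logL - logL
            K_new = L_new @ L_new.T
            d_par = max(
                np.max(np.abs(K_new - K_cur)) / max(np.max(np.abs(K_new)), 1e-3 * scale),
                np.max(np.abs(eta_new - eta_cur)) if nc else 0.0,
            )
            state.update(L=L_new, eta=eta_new, logL=new_logL)
            history.append(new_logL)
            if opt.verbose:
                print(
                    f"newton {n_newton}: logL={new_logL:.6f} "
                    f"dlogL={d_logL:.3g} dpar={d_par:.3g}"
                )
            flat = flat + 1 if d_logL < opt.tol_logL else 0
            if d_logL < opt.tol_logL and (d_par < opt.tol_param or flat >= 2):
                return "converged"
            slow = slow + 1 if d_logL < 0.02 else 0
            if slow >= 3:
                return "slow"
        return "budget"

    def polish_phase():
        from scipy.optimize import minimize

        def negfg(th):
            Lm, et = split(th)
            try:
                ll = core.set_params(Lm @ Lm.T, et)
            except np.linalg.LinAlgError:
                return 1e12, np.zeros_like(th)
            gK, _ = core.derivatives(want_ai=False)
            Jm = jacobian(Lm)
            g = np.concatenate([Jm.T @ gK[:nk], gK[nk:]])
            return -ll, -g

        budget = opt.polish_maxfun * (1 + nl // 8)
        total_gain = 0.0
        th = theta_of(state["L"], state["eta"])
        # restart L-BFGS while it keeps improving: its curvature memory is
        # poor in these valleys and a fresh start often unlocks progress
        for _restart in range(6):
            resopt = minimize(
                negfg, th, jac=True, method="L-BFGS-B",
                options=dict(maxfun=budget, maxiter=budget, ftol=1e-12, gtol=1e-8),
            )
            L2, eta2 = split(np.asarray(resopt.x, float))
            try:
                ll2 = core.set_params(L2 @ L2.T, eta2)
            except np.linalg.LinAlgError:
                ll2 = -np.inf
            if np.isfinite(ll2) and ll2 >= state["logL"] - 1e-8:
                gain = ll2 - state["logL"]
                total_gain += gain
                state.update(L=L2, eta=eta2, logL=ll2)
                history.append(ll2)
                th = np.asarray(resopt.x, float)
                if gain < 1e-7:
                    break
            else:
                core.set_params(state["L"] @ state["L"].T, state["eta"])
                break
        return total_gain

    # Alternate Newton and polish until stationary.  The AI matrix is the
    # *average* information: near the psd boundary it can grossly
    # overestimate the achievable gain, so actual achieved improvements -
    # not the AI forecast - decide convergence.
    converged = False
    gain = np.inf
    for cycle in range(8):
        status = newton_phase(opt.max_iter)
        crit = newton_gain()
        if opt.verbose:
            print(f"cycle {cycle}: newton status={status} crit={crit:.3g}")
        if status == "converged" or crit <= 0.02:
            converged = True
            break
        gain = polish_phase()
        crit = newton_gain()
        if opt.verbose:
            print(f"cycle {cycle}: polish gain={gain:.3g} crit={crit:.3g}")
        if crit <= 0.02:
            converged = True
            break
        if gain < 1e-6 and status == "stuck":
            # neither a damped Newton line search nor quasi-Newton descent
            # can improve: stationary (typically a boundary optimum)
            converged = True
            break
    else:
        converged = gain < 0.05
    logL = state["logL"]
    if not np.isfinite(logL) or not converged:
        raise ConvergenceError(
            f"REML did not converge ({n_newton} Newton iterations, last "
            f"polish still gaining {gain:.3g} logL units)", history
        )
    K = state["L"] @ state["L"].T
    return REMLResult(
        K=K, eta=state["eta"], logL=logL, converged=converged, n_iter=n_newton,
        history=history, beta=core.beta.copy(), Py=core.Py.copy(), bent=bent_any,
    )
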