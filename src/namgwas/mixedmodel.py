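"""Linear mixed models with heteroscedastic residual groups, fit by REML.

The model is ``y = X b + sum_j Z_j u_j + e`` with ``u_j ~ N(0, s2_j I)``
independent across blocks and ``e ~ N(0, diag(t2_g(i)))`` where ``g(i)``
assigns each observation to one of a small number of residual-variance
groups (Smarthouse-by-treatment in the phenomics application).

The REML log-likelihood is evaluated through the Woodbury identity and
the matrix determinant lemma so only a q x q system (q = total random
effects) and a p x p system (p = fixed-effect rank) are factorised per
evaluation. Optimisation is bounded quasi-Newton on log-variances with
several starts around a method-of-moments initialisation.

BLUPs, their prediction-error variances and estimable-function
predictions come from the mixed-model-equation coefficient matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import f as f_dist

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class RandomBlock:
    """One iid random-effect block: ``u ~ N(0, s2 I_m)`` with design ``Z``."""

    name: str
    Z: np.ndarray
    level_names: list | None = None


def reduce_to_full_rank(X: np.ndarray, tol: float = 1e-9):
    """Column indices of a full-rank subset of ``X`` (pivoted QR)."""
    if X.shape[1] == 0:
        return np.array([], dtype=int)
    from scipy.linalg import qr
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    if diag.size == 0:
        return np.array([], dtype=int)
    rank = int(np.sum(diag > tol * diag[0])) if diag[0] > 0 else 0
    return np.sort(piv[:rank])


class MixedModel:
    """REML fitting for one response vector.

    Parameters
    ----------
    y, X
        Response and fixed-effect design; ``X`` is reduced internally to
        full column rank (estimable functions are unaffected).
    blocks
        Random-effect blocks, each with a single variance component.
    resid_groups
        Integer array assigning each observation to a residual-variance
        group; ``None`` means one homoscedastic group.
    column_names
        Optional labels for the columns of ``X`` (pre-reduction).
    """

    def __init__(self, y, X, blocks=None, resid_groups=None, column_names=None):
        self.y = np.asarray(y, dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = len(self.y)
        if X.shape[0] != n:
            raise ValueError("X and y lengths differ")
        self.column_names = list(column_names) if column_names is not None else [
            f"x{j}" for j in range(X.shape[1])]
        self._X_full = X
        self.kept = reduce_to_full_rank(X)
        self.X = X[:, self.kept]
        self.blocks = list(blocks or [])
        for b in self.blocks:
            if b.Z.shape[0] != n:
                raise ValueError(f"block {b.name} has wrong row count")
        if resid_groups is None:
            resid_groups = np.zeros(n, dtype=int)
        self.groups = np.asarray(resid_groups)
        self.group_levels, self.group_idx = np.unique(self.groups, return_inverse=True)
        self.n, self.p = n, self.X.shape[1]
        if self.n <= self.p:
            raise ValueError("need more observations than fixed-effect rank")
        self._q_sizes = [b.Z.shape[1] for b in self.blocks]
        self._Z = (np.concatenate([b.Z for b in self.blocks], axis=1)
                   if self.blocks else np.zeros((n, 0)))
        self.fitted_: bool = False

    # -- likelihood ----------------------------------------------------

    def _variance_vectors(self, theta):
        nb = len(self.blocks)
        block_vars = np.exp(theta[:nb])
        resid_vars = np.exp(theta[nb:])
        g_rep = np.repeat(block_vars, self._q_sizes) if nb else np.zeros(0)
        r_obs = resid_vars[self.group_idx]
        return block_vars, resid_vars, g_rep, r_obs

    def _solve_core(self, theta):
        """Factorised quantities for one parameter vector."""
        _, _, g_rep, r_obs = self._variance_vectors(theta)
        rinv = 1.0 / r_obs
        X, Z, y = self.X, self._Z, self.y
        q = Z.shape[1]
        if q:
            RZ = Z * rinv[:, None]
            A = np.diag(1.0 / g_rep) + Z.T @ RZ
            cA = cho_factor(A, lower=True)
            logdetA = 2.0 * np.sum(np.log(np.diag(cA[0])))
            logdetV = logdetA + np.sum(np.log(g_rep)) + np.sum(np.log(r_obs))

            def vinv(M):
                RM = M * rinv[:, None] if M.ndim == 2 else M * rinv
                t = Z.T @ RM
                s = cho_solve(cA, t)
                return RM - (RZ @ s)
        else:
            cA = None
            logdetV = np.sum(np.log(r_obs))

            def vinv(M):
                return M * rinv[:, None] if M.ndim == 2 else M * rinv

        ViX = vinv(X)
        XtViX = X.T @ ViX
        XtViy = ViX.T @ y
        try:
            cX = cho_factor(XtViX, lower=True)
            beta = cho_solve(cX, XtViy)
            logdetXtViX = 2.0 * np.sum(np.log(np.diag(cX[0])))
        except np.linalg.LinAlgError:
            beta = np.linalg.pinv(XtViX) @ XtViy
            sign, logdetXtViX = np.linalg.slogdet(XtViX)
            if sign <= 0:
                logdetXtViX = np.inf
        resid = y - X @ beta
        quad = float(resid @ vinv(resid))
        ll = -0.5 * ((self.n - self.p) * _LOG2PI + logdetV + logdetXtViX + quad)
        return {"ll": ll, "beta": beta, "vinv": vinv, "XtViX": XtViX,
                "resid": resid, "cA": cA, "rinv": rinv, "g_rep": g_rep}

    def reml_loglik(self, block_vars, resid_vars) -> float:
        """REML log-likelihood at the given variance components."""
        theta = np.log(np.concatenate([np.atleast_1d(block_vars),
                                       np.atleast_1d(resid_vars)])
                       if len(self.blocks) else np.atleast_1d(resid_vars))
        return self._solve_core(theta)["ll"]

    # -- fitting -------------------------------------------------------

    def fit(self, start_multipliers=(0.1, 1.0, 10.0), tol: float = 1e-8,
            maxiter: int = 500) -> "MixedModel":
        nb, ng = len(self.blocks), len(self.group_levels)
        # method-of-moments base scale from OLS
        beta0, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        rss = float(np.sum((self.y - self.X @ beta0) ** 2))
        s0 = max(rss / max(self.n - self.p, 1), 1e-12)
        best = None
        for mult in start_multipliers:
            theta0 = np.log(np.concatenate([
                np.full(nb, 0.5 * s0 * mult), np.full(ng, s0)]))
            lo = np.log(s0) - 25.0
            hi = np.log(s0) + 25.0
            res = optimize.minimize(
                lambda t: -self._solve_core(t)["ll"], theta0,
                method="L-BFGS-B", bounds=[(lo, hi)] * (nb + ng),
                options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-8},
            )
            if best is None or res.fun < best.fun - 1e-10:
                best = res
        self.theta_ = best.x
        self.converged_ = bool(best.success)
        core = self._solve_core(self.theta_)
        self.loglik_ = core["ll"]
        bv, rv, _, _ = self._variance_vectors(self.theta_)
        self.block_variances_ = {b.name: float(v) for b, v in zip(self.blocks, bv)}
        self.resid_variances_ = {lvl: float(v) for lvl, v in zip(self.group_levels, rv)}
        self.beta_ = core["beta"]
        self.beta_cov_ = np.linalg.inv(core["XtViX"])
        # BLUPs: u = G Z' Vinv resid = A^{-1} Z' R^{-1} resid
        if self.blocks:
            rhs = self._Z.T @ (core["resid"] * core["rinv"])
            u = cho_solve(core["cA"], rhs)
            self.u_ = {}
            off = 0
            for b, m in zip(self.blocks, self._q_sizes):
                self.u_[b.name] = u[off:off + m]
                off += m
        else:
            self.u_ = {}
        self.fitted_ = True
        return self

    # -- inference helpers --------------------------------------------

    def _require_fit(self):
        if not self.fitted_:
            raise RuntimeError("call fit() first")

    def is_estimable(self, L: np.ndarray, tol: float = 1e-6) -> bool:
        L = np.asarray(L, dtype=float)
        a, *_ = np.linalg.lstsq(self._X_full.T, L, rcond=None)
        err = np.linalg.norm(self._X_full.T @ a - L)
        return err <= tol * max(np.linalg.norm(L), 1.0)

    def predict(self, L_full: np.ndarray):
        """Estimate and s.e. of the estimable function ``L b`` (full space)."""
        self._require_fit()
        L = np.atleast_2d(np.asarray(L_full, dtype=float))[:, self.kept]
        est = L @ self.beta_
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", L, self.beta_cov_, L), 0.0))
        return est, se

    def wald_f(self, columns) -> tuple[float, float, float, float]:
        """Wald F test that the named fixed-effect columns are zero.

        Returns ``(F, df1, df2, p)``; df2 is the residual degrees of
        freedom ``n - p`` (containment-style approximation).
        """
        self._require_fit()
        name_to_reduced = {self.column_names[j]: i for i, j in enumerate(self.kept)}
        idx = [name_to_reduced[c] for c in columns if c in name_to_reduced]
        if not idx:
            return 0.0, 0.0, float(self.n - self.p), 1.0
        b = self.beta_[idx]
        C = self.beta_cov_[np.ix_(idx, idx)]
        stat = float(b @ np.linalg.solve(C, b)) / len(idx)
        df1, df2 = float(len(idx)), float(self.n - self.p)
        return stat, df1, df2, float(f_dist.sf(stat, df1, df2))

    def pev(self, block_name: str) -> np.ndarray:
        """Prediction-error variance matrix of one block's BLUPs."""
        self._require_fit()
        core = self._solve_core(self.theta_)
        rinv = core["rinv"]
        W = np.concatenate([self.X, self._Z], axis=1)
        C = W.T @ (W * rinv[:, None])
        ginv = np.concatenate([np.zeros(self.p), 1.0 / core["g_rep"]])
        C[np.arange(len(ginv)), np.arange(len(ginv))] += ginv
        Cinv = np.linalg.inv(C)
        off = self.p
        for b, m in zip(self.blocks, self._q_sizes):
            if b.name == block_name:
                return Cinv[off:off + m, off:off + m]
            off += m
        raise KeyError(block_name)

    def drop_block(self, name: str) -> "MixedModel":
        """A new unfitted model without the named random block."""
        blocks = [b for b in self.blocks if b.name != name]
        return MixedModel(self.y, self._X_full, blocks, self.groups,
                          self.column_names)

    def with_groups(self, groups) -> "MixedModel":
        return MixedModel(self.y, self._X_full, self.blocks, groups,
                          self.column_names)


def reml_lrt_boundary(ll_full: float, ll_reduced: float) -> float:
    """p-value of a REML ratio test for one variance component on the
    boundary: 0.5 chi2_0 + 0.5 chi2_1 mixture."""
    from scipy.stats import chi2
    stat = max(2.0 * (ll_full - ll_reduced), 0.0)
    if stat == 0.0:
        return 1.0
    return 0.5 * float(chi2.sf(stat, 1))


def reml_lrt(ll_full: float, ll_reduced: float, df: int) -> float:
    """Standard REML ratio test p-value on ``df`` degrees of freedom."""
    from scipy.stats import chi2
    stat = max(2.0 * (ll_full - ll_reduced), 0.0)
    return float(chi2.sf(stat, df))
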