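"""Maximum-likelihood logistic regression with a per-subject random intercept.

The model for event j of subject i is

    logit P(y_ij = 1) = beta0 + x_ij' beta + b_i + delta_ij,
    b_i ~ Normal(0, sigma_b^2) i.i.d.,

with an optional fixed offset delta. The marginal likelihood integrates the
random intercept out of each subject's Bernoulli product; the integral is
evaluated by *adaptive* Gauss–Hermite quadrature: for each subject the
integrand is re-centered at its mode (found by a safeguarded 1-D Newton
iteration, vectorized over subjects) and re-scaled by its curvature before
applying the Hermite rule, which keeps a modest node count (default 15)
accurate even for large clusters.

Standard errors come from the inverse observed information (numerical
Hessian of the negative marginal log-likelihood at the optimum); Wald
z = beta/se with two-sided normal p-values. BIC = k ln(n) - 2 lnL with
k = #fixed effects + 1 variance parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

__all__ = ["MixedLogitFit", "fit_mixed_logit", "SeparationError", "ConvergenceWarning"]


class SeparationError(RuntimeError):
    """The outcome is (quasi-)completely separated by the linear predictor."""


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class MixedLogitFit:
    """Fitted random-intercept logit. ``beta[0]`` is the intercept."""

    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    sigma_b: float
    loglik: float
    bic: float
    n_used: int
    n_groups: int
    converged: bool
    feature_names: list[str] = field(default_factory=list)
    #: deviance residuals of the subject-mode-conditional fit
    deviance_residuals: np.ndarray | None = None

    def summary_row(self, j: int) -> dict:
        return {
            "beta": float(self.beta[j]),
            "se": float(self.se[j]),
            "z": float(self.z[j]),
            "p": float(self.p[j]),
        }


def _expit(x: np.ndarray) -> np.ndarray:
    return special.expit(x)


def _log1pexp(x: np.ndarray) -> np.ndarray:
    # log(1 + e^x), overflow-safe
    out = np.empty_like(x)
    small = x < 33
    out[small] = np.log1p(np.exp(x[small]))
    out[~small] = x[~small]
    return out


class _AGQ:
    """Adaptive Gauss–Hermite marginal log-likelihood for one design."""

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                 offset: np.ndarray, n_nodes: int) -> None:
        uniq, idx = np.unique(groups, return_inverse=True)
        self.gidx_orig = idx  # original row order -> group index
        order = np.argsort(idx, kind="stable")  # group-sorted rows: group
        self.order = order                       # sums become reduceat calls
        self.X = X[order]  # includes intercept column
        self.y = y[order].astype(float)
        self.gidx = idx[order]
        self.q = len(uniq)
        self.starts = np.searchsorted(self.gidx, np.arange(self.q))
        self.offset = offset[order]
        z, w = np.polynomial.hermite.hermgauss(n_nodes)
        self.nodes = z  # physicists' rule: int e^{-z^2} f(z) dz ~ sum w f(z)
        self.logw = np.log(w) + z**2  # fold the e^{z^2} correction in
        self.modes = np.zeros(self.q)

    def _eta_fixed(self, beta: np.ndarray) -> np.ndarray:
        return self.X @ beta + self.offset

    def _group_sum(self, values: np.ndarray) -> np.ndarray:
        return np.add.reduceat(values, self.starts, axis=0)

    def _find_modes(self, eta: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
        """Per-subject mode b_i and curvature scale s_i of the integrand
        log f_i(b) = sum_j [y eta_b - log(1+e^{eta_b})] - b^2/(2 sigma^2)."""
        b = self.modes.copy()
        for _ in range(50):
            mu = _expit(eta + b[self.gidx])
            grad = self._group_sum(self.y - mu) - b / sigma**2
            hess = -self._group_sum(mu * (1 - mu)) - 1.0 / sigma**2
            step = grad / hess
            # safeguard: damp huge Newton steps
            step = np.clip(step, -5.0, 5.0)
            b = b - step
            if np.max(np.abs(step)) < 1e-10:
                break
        self.modes = b
        mu = _expit(eta + b[self.gidx])
        curv = self._group_sum(mu * (1 - mu)) + 1.0 / sigma**2
        return b, 1.0 / np.sqrt(curv)

    def _parts(self, theta: np.ndarray):
        beta, log_sigma = theta[:-1], theta[-1]
        sigma = np.exp(log_sigma)
        eta = self._eta_fixed(beta)
        b, s = self._find_modes(eta, sigma)
        # evaluate integrand at shifted/scaled nodes: b_ik = b_i + sqrt2 s_i z_k
        bk = b[:, None] + np.sqrt(2.0) * s[:, None] * self.nodes[None, :]  # q x K
        eta_k = eta[:, None] + bk[self.gidx, :]  # n x K
        ll_obs = self.y[:, None] * eta_k - _log1pexp(eta_k)
        ll_grp = self._group_sum(ll_obs)
        ll_grp += -0.5 * bk**2 / sigma**2 + self.logw[None, :]
        li = special.logsumexp(ll_grp, axis=1)
        post = np.exp(ll_grp - li[:, None])  # q x K posterior node weights
        li = li + 0.5 * np.log(2.0) + np.log(s) - np.log(sigma) - 0.5 * np.log(2.0 * np.pi)
        return li, post, eta_k, bk, sigma

    def negloglik(self, theta: np.ndarray) -> float:
        return -float(np.sum(self._parts(theta)[0]))

    def negloglik_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Objective and its gradient. The gradient differentiates the
        quadrature sum with the per-subject centering (modes/scales) held
        fixed; their contribution is of the order of the quadrature error
        (an exact quadrature is centering-invariant) and is negligible at
        the node counts used here."""
        li, post, eta_k, bk, sigma = self._parts(theta)
        mu_k = _expit(eta_k)  # n x K
        # d/dbeta: sum_i sum_k post_ik sum_j x_ij (y_ij - mu_ijk)
        resid = (self.y[:, None] - mu_k) * post[self.gidx, :]
        g_beta = self.X.T @ resid.sum(axis=1)
        # d/dlogsigma: sum_i [ sum_k post_ik b_ik^2 / sigma^2 - 1 ]
        g_ls = float(np.sum(post * bk**2) / sigma**2 - self.q)
        grad = -np.append(g_beta, g_ls)
        return -float(np.sum(li)), grad


def _plain_logistic_start(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Newton/IRLS warm start for the fixed effects (few damped steps)."""
    p = X.shape[1]
    beta = np.zeros(p)
    beta[0] = np.log((y.mean() + 1e-6) / (1 - y.mean() + 1e-6))
    for _ in range(25):
        mu = _expit(X @ beta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X + 1e-8 * np.eye(p)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(step)) > 10:
            step *= 10 / np.max(np.abs(step))
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    return beta


def _numerical_hessian(f, theta: np.ndarray, h: float = 1e-4) -> np.ndarray:
    p = len(theta)
    H = np.empty((p, p))
    hs = h * (1.0 + np.abs(theta))
    f0 = f(theta)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = hs[i]
            ej = np.zeros(p); ej[j] = hs[j]
            if i == j:
                H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / hs[i] ** 2
            else:
                fpp = f(theta + ei + ej)
                fpm = f(theta + ei - ej)
                fmp = f(theta - ei + ej)
                fmm = f(theta - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * hs[i] * hs[j])
    return H


def fit_mixed_logit(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    offset: np.ndarray | None = None,
    n_nodes: int = 15,
    feature_names: list[str] | None = None,
    compute_se: bool = True,
    max_iter: int = 2000,
    fix_sigma: float | None = None,
) -> MixedLogitFit:
    """Fit the random-intercept logit by maximizing the AGQ marginal
    likelihood over (beta, log sigma_b).

    ``X`` is the n-by-f design *without* an intercept column (one is added);
    ``y`` is binary; ``groups`` holds the subject id of each row. Rows with
    any non-finite entry must be removed by the caller (complete-case).

    Raises ``ValueError`` for degenerate inputs and :class:`SeparationError`
    when the fitted model perfectly separates the outcome. A fit that hits
    the iteration limit is returned with ``converged=False`` and a
    :class:`ConvergenceWarning` (never silent).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    groups = np.asarray(groups).ravel()
    n, f = X.shape
    if len(y) != n or len(groups) != n:
        raise ValueError("X, y and groups must be row-aligned")
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValueError("design or outcome contains non-finite values; "
                         "drop incomplete rows before fitting")
    if n < f + 2:
        raise ValueError(f"need at least f+2={f + 2} rows, got {n}")
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least 2 groups for a random intercept")
    if y.min() == y.max():
        raise ValueError("outcome is constant; the model is not identifiable")

    # internal change of variables: optimize on unit-SD columns (the raw
    # design may mix scales by orders of magnitude); map estimates back so
    # reported coefficients stay per-unit-of-predictor
    col_sd = X.std(axis=0)
    col_sd = np.where(col_sd > 0, col_sd, 1.0)
    Xd = np.column_stack([np.ones(n), X / col_sd])
    delta = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    agq = _AGQ(Xd, y, groups, delta, n_nodes)

    beta0 = _plain_logistic_start(Xd, y)
    if fix_sigma is not None:
        # pin the variance parameter (e.g. 0 -> plain logistic regression);
        # start from zero coefficients so the quadrature path, not the warm
        # start, determines the optimum
        ls = float(np.log(max(fix_sigma, 1e-6)))
        theta0 = np.append(np.zeros(f + 1), ls)
        bounds = [(None, None)] * (f + 1) + [(ls, ls)]
    else:
        theta0 = np.append(beta0, np.log(0.5))
        bounds = [(None, None)] * (f + 1) + [(-8.0, 3.0)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.minimize(
            agq.negloglik_grad,
            theta0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={
                "maxiter": max_iter,
                "maxfun": 10**6,
                # wide designs: the last objective digits are numerically
                # meaningless under quadrature error; stop earlier
                "ftol": 1e-12 if f <= 10 else 2.2e-9,
                "gtol": 1e-7 if f <= 10 else 1e-5,
            },
        )
    theta = res.x
    scale = np.concatenate([[1.0], col_sd])  # scaled beta -> per-unit beta
    beta, sigma = theta[:-1] / scale, float(np.exp(theta[-1]))
    loglik = -float(res.fun)
    converged = bool(res.success) or res.status == 0
    if not converged:
        # line-search failures ("ABNORMAL") usually happen at the optimum
        # where the quadrature-level gradient inconsistency dominates; accept
        # the point if it is stationary to well beyond statistical precision
        _, g = agq.negloglik_grad(theta)
        converged = float(np.max(np.abs(g))) < 1e-2 * (1.0 + abs(res.fun))

    # separation check on the mode-conditional fit
    eta = Xd @ theta[:-1] + delta + agq.modes[agq.gidx_orig]
    mu = _expit(eta)
    if np.max(np.abs(beta[1:]), initial=0.0) > 30 and (
        np.all(mu[y == 1] > 1 - 1e-6) and np.all(mu[y == 0] < 1e-6)
    ):
        raise SeparationError("complete separation detected: coefficients diverge")
    if not converged:
        warnings.warn(
            f"mixed logit did not converge: {res.message}", ConvergenceWarning
        )

    k = f + 2  # fixed effects incl. intercept, plus sigma_b
    bic = k * np.log(n) - 2.0 * loglik

    se = np.full(f + 1, np.nan)
    if compute_se:
        H = _numerical_hessian(agq.negloglik, theta)
        Hb = H[: f + 1, : f + 1]
        # use the full-parameter information when it is invertible, else the
        # beta block (log sigma at its boundary makes the full H singular)
        cov = None
        try:
            full = np.linalg.inv(H)
            d = np.diag(full)[: f + 1]
            if np.all(d > 0):
                cov = full[: f + 1, : f + 1]
        except np.linalg.LinAlgError:
            pass
        if cov is None:
            try:
                cov = np.linalg.inv(Hb)
            except np.linalg.LinAlgError:
                cov = np.linalg.pinv(Hb)
        se = np.sqrt(np.clip(np.diag(cov), 0, None)) / scale

    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))

    sign = np.where(y > 0.5, 1.0, -1.0)
    dev = sign * np.sqrt(np.clip(-2.0 * (y * np.log(np.clip(mu, 1e-12, None))
                                         + (1 - y) * np.log(np.clip(1 - mu, 1e-12, None))), 0, None))

    return MixedLogitFit(
        beta=beta,
        se=se,
        z=z,
        p=p,
        sigma_b=sigma,
        loglik=loglik,
        bic=float(bic),
        n_used=n,
        n_groups=agq.q,
        converged=converged,
        feature_names=["(intercept)"] + list(feature_names or [f"x{i}" for i in range(f)]),
        deviance_residuals=dev,
    )
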