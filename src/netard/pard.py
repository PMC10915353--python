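"""p-node automatic relevance determination (pARD).

Each gene k is regressed on all remaining genes under a Gaussian likelihood
with shared noise precision beta and an independent zero-mean Gaussian prior
on each coefficient with its own precision alpha_{k'}^{(k)}. A second prior
level places Gamma(s, r) distributions on every alpha and on beta. The p
coupled evidence problems are maximized jointly over
(alpha^(1), ..., alpha^(p), beta): the objective is the sum over nodes of the
log marginal likelihood (Gaussian evidence) plus the log Gamma prior terms.

The mode is located by fixed-point iteration in the MacKay/Tipping style,
extended for the Gamma hyperpriors. With the posterior covariance
Sigma^(k) = (beta * X_k'X_k + D_alpha)^{-1} and the "well-determinedness"
gamma_{k'} = 1 - alpha_{k'} Sigma^(k)_{k'k'}:

    alpha_{k'}^{(k)} <- (gamma_{k'} + 2(s_{k'}^{(k)} - 1))
                        / (b_{k'}^{(k)2} + 2 r_{k'}^{(k)})
    beta <- (N p - sum_k sum_{k'} gamma_{k'}^{(k)} + 2 p (s_beta - 1))
            / (sum_k ||X^(k) - X_{\\k} b^(k)||^2 + 2 p r_beta)

both clamped to [1e-6, 1e12] (the clamp covers shapes below 1, which the
Gamma prior permits down to s > 1/2). These are the stationarity conditions
of the joint objective for exactly this prior family; the beta prior enters
once per node, hence the p-fold terms. Updates are swept jointly over all
nodes until the relative change of every hyperparameter falls below
tolerance.

Coefficient estimates are the conditional posterior means

    b^(k) = (X_{\\k}' X_{\\k} + D_alpha / beta)^{-1} X_{\\k}' X^(k),

i.e. weighted ridge estimates with per-coefficient weights alpha / beta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import gammaln

__all__ = [
    "HyperParams",
    "ARDState",
    "standardize",
    "ridge_posterior",
    "log_marginal_likelihood",
    "pard_objective",
    "fit_pard",
]

ALPHA_MIN, ALPHA_MAX = 1e-6, 1e12
BETA_MIN, BETA_MAX = 1e-6, 1e12


@dataclass
class HyperParams:
    """Gamma hyperpriors of the pARD.

    s, r : (p, p) arrays; entry [k', k] is the shape/rate of the Gamma prior
        on alpha_{k'}^{(k)} (the precision of gene k''s coefficient in gene
        k's regression). The diagonal is ignored.
    s_beta, r_beta : Gamma prior of the shared noise precision beta.
    """

    s: np.ndarray
    r: np.ndarray
    s_beta: float = 1e-2
    r_beta: float = 1e-2

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.s.shape != self.r.shape or self.s.ndim != 2:
            raise ValueError("s and r must be square matrices of equal shape")
        off = ~np.eye(self.s.shape[0], dtype=bool)
        if np.any(self.s[off] <= 0) or np.any(self.r[off] <= 0):
            raise ValueError("Gamma shapes and rates must be strictly positive")
        if self.s_beta <= 0 or self.r_beta <= 0:
            raise ValueError("noise-precision prior parameters must be positive")

    @classmethod
    def uniform(cls, p: int, s: float, r: float,
                s_beta: float = 1e-2, r_beta: float = 1e-2) -> "HyperParams":
        return cls(np.full((p, p), s), np.full((p, p), r), s_beta, r_beta)


@dataclass
class ARDState:
    """Converged (or in-progress) pARD solution.

    alpha : (p, p) array; [k', k] is the coefficient precision of gene k' in
        node k's regression (diagonal unused, held at 0).
    beta : shared noise precision.
    b : (p, p) array of posterior-mean coefficients, [k', k] layout as alpha.
    post_cov : list of p arrays (p-1, p-1), the conditional posterior
        covariance of each node's coefficient vector.
    """

    alpha: np.ndarray
    beta: float
    b: np.ndarray
    post_cov: list = field(default_factory=list)
    objective_value: float = np.nan
    n_iter: int = 0
    converged: bool = False


def standardize(x: np.ndarray, gene_ids=None) -> np.ndarray:
    """Center each column to mean 0 and scale to standard deviation 1 (ddof=1)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("expression matrix contains non-finite values")
    sd = x.std(axis=0, ddof=1)
    bad = np.where(sd == 0)[0]
    if bad.size:
        names = ([str(gene_ids[j]) for j in bad] if gene_ids is not None
                 else [str(j) for j in bad])
        raise ValueError(f"constant expression column(s): {', '.join(names)}")
    return (x - x.mean(axis=0)) / sd


def _node_system(gram: np.ndarray, xty: np.ndarray, k: int,
                 alpha_k: np.ndarray, beta: float):
    """Cholesky pieces for node k: solves of (G_\\k + D/beta) and (beta G_\\k + D)."""
    idx = np.arange(gram.shape[0]) != k
    g_sub = gram[np.ix_(idx, idx)]
    rhs = xty[idx, k]
    m = beta * g_sub + np.diag(alpha_k)
    c, low = cho_factor(m, lower=True, check_finite=False)
    b = cho_solve((c, low), beta * rhs, check_finite=False)
    return idx, b, (c, low)


def ridge_posterior(x: np.ndarray, k: int, alpha_k: np.ndarray, beta: float):
    """Posterior mean and covariance of node k's coefficient vector.

    Returns ``(b, cov)`` where ``b`` solves
    (X_\\k' X_\\k + D_alpha / beta) b = X_\\k' X^(k) and
    ``cov = (beta X_\\k' X_\\k + D_alpha)^{-1}``.
    """
    x = np.asarray(x, dtype=float)
    alpha_k = np.asarray(alpha_k, dtype=float)
    if np.any(alpha_k <= 0) or beta <= 0:
        raise ValueError("alpha and beta must be strictly positive")
    gram = x.T @ x
    idx, b, chol = _node_system(gram, gram, k, alpha_k, beta)
    cov = cho_solve(chol, np.eye(alpha_k.size), check_finite=False)
    return b, cov


def log_marginal_likelihood(x: np.ndarray, k: int, alpha_k: np.ndarray,
                            beta: float) -> float:
    """Log Gaussian evidence of node k's regression model.

    ln N(X^(k) | 0, beta^{-1} I + X_\\k D_alpha^{-1} X_\\k'), evaluated via
    the Woodbury identity in the (p-1)-dimensional space so only
    (p-1)x(p-1) factorizations are needed.
    """
    x = np.asarray(x, dtype=float)
    alpha_k = np.asarray(alpha_k, dtype=float)
    if np.any(alpha_k <= 0) or beta <= 0:
        raise ValueError("alpha and beta must be strictly positive")
    n = x.shape[0]
    idx = np.arange(x.shape[1]) != k
    xk = x[:, k]
    xs = x[:, idx]
    m = beta * (xs.T @ xs) + np.diag(alpha_k)
    c, low = cho_factor(m, lower=True, check_finite=False)
    b = cho_solve((c, low), beta * (xs.T @ xk), check_finite=False)
    # ln|C| = -N ln beta - sum ln alpha + ln|beta X'X + D_alpha|
    logdet_m = 2.0 * np.sum(np.log(np.diag(c)))
    logdet_c = -n * np.log(beta) - np.sum(np.log(alpha_k)) + logdet_m
    # x' C^{-1} x = beta x'x - beta x'X b
    quad = beta * (xk @ xk) - beta * (xk @ (xs @ b))
    return float(-0.5 * (n * np.log(2 * np.pi) + logdet_c + quad))


def _log_gamma_pdf(t, s, r):
    return s * np.log(r) - gammaln(s) + (s - 1) * np.log(t) - r * t


def pard_objective(x: np.ndarray, state: ARDState, theta: HyperParams) -> float:
    """Joint objective: sum over nodes of evidence + Gamma log-priors.

    The beta prior term is counted once per node, matching the per-node sum
    that defines the objective.
    """
    x = np.asarray(x, dtype=float)
    p = x.shape[1]
    if state.beta <= 0:
        raise ValueError("beta must be positive")
    off = ~np.eye(p, dtype=bool)
    if np.any(state.alpha[off] <= 0):
        raise ValueError("alpha must be positive")
    total = 0.0
    for k in range(p):
        idx = np.arange(p) != k
        a = state.alpha[idx, k]
        total += log_marginal_likelihood(x, k, a, state.beta)
        total += float(np.sum(_log_gamma_pdf(a, theta.s[idx, k], theta.r[idx, k])))
        total += float(_log_gamma_pdf(state.beta, theta.s_beta, theta.r_beta))
    return total


def fit_pard(x: np.ndarray, theta: HyperParams, init: ARDState | None = None,
             tol: float = 1e-3, max_iter: int = 200,
             compute_objective: bool = False) -> ARDState:
    """Run the joint fixed-point iteration to a mode of the pARD posterior.

    ``x`` must be standardized. The returned state satisfies the ridge
    equation for its own (alpha, beta) exactly (the final sweep re-solves all
    p systems after the last hyperparameter update).
    """
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    gram = x.T @ x

    if init is not None:
        alpha = init.alpha.copy()
        beta = float(init.beta)
    else:
        alpha = np.ones((p, p))
        beta = 1.0
    np.fill_diagonal(alpha, 0.0)

    # stacked leave-one-out systems: sub[k] = gram with row/column k removed
    loo = np.array([[j for j in range(p) if j != k] for k in range(p)])
    gram_sub = gram[loo[:, :, None], loo[:, None, :]]      # (p, p-1, p-1)
    rhs_sub = gram[np.arange(p)[:, None], loo]             # (p, p-1)
    alpha_sub = alpha[loo, np.arange(p)[:, None]]          # (p, p-1)
    s_sub = theta.s[loo, np.arange(p)[:, None]]
    r_sub = theta.r[loo, np.arange(p)[:, None]]
    diag_ix = np.arange(p - 1)
    eye_sub = np.broadcast_to(np.eye(p - 1), (p, p - 1, p - 1))

    off_mask = ~np.eye(p, dtype=bool)
    b_sub = np.zeros((p, p - 1))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        m = beta * gram_sub.copy()
        m[:, diag_ix, diag_ix] += alpha_sub
        try:
            b_sub = np.linalg.solve(m, beta * rhs_sub[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError as err:
            raise FloatingPointError(f"pARD diverged (sweep {it}): {err}") from err
        if not np.all(np.isfinite(b_sub)):
            bad = int(np.where(~np.isfinite(b_sub).all(axis=1))[0][0])
            raise FloatingPointError(
                f"pARD diverged at node index {bad} (non-finite coefficients)")
        inv_m = np.linalg.solve(m, np.ascontiguousarray(eye_sub))
        sigma_diag = inv_m[:, diag_ix, diag_ix]            # (p, p-1)
        g = 1.0 - alpha_sub * sigma_diag
        gamma_sum = float(np.sum(g))
        # ||X^(k) - X_\k b||^2 via the Gram matrix, all nodes at once
        quad = np.einsum("ki,kij,kj->k", b_sub, gram_sub, b_sub)
        rss = np.diag(gram) - 2.0 * np.sum(b_sub * rhs_sub, axis=1) + quad
        rss_sum = float(np.sum(np.maximum(rss, 0.0)))
        alpha_new_sub = np.clip((g + 2.0 * (s_sub - 1.0))
                                / (b_sub ** 2 + 2.0 * r_sub),
                                ALPHA_MIN, ALPHA_MAX)
        beta_new = (n * p - gamma_sum + 2.0 * p * (theta.s_beta - 1.0)) / (
            rss_sum + 2.0 * p * theta.r_beta)
        beta_new = float(np.clip(beta_new, BETA_MIN, BETA_MAX))

        rel_a = float(np.max(np.abs(alpha_new_sub - alpha_sub)
                             / np.maximum(np.abs(alpha_sub), 1e-12)))
        rel_b = abs(beta_new - beta) / max(abs(beta), 1e-12)
        alpha_sub, beta = alpha_new_sub, beta_new
        if max(rel_a, rel_b) < tol:
            converged = True
            break

    # final coefficient solve so b is exactly self-consistent with (alpha, beta)
    m = beta * gram_sub.copy()
    m[:, diag_ix, diag_ix] += alpha_sub
    b_sub = np.linalg.solve(m, beta * rhs_sub[:, :, None])[:, :, 0]
    inv_m = np.linalg.solve(m, np.ascontiguousarray(eye_sub))
    post_cov = [inv_m[k] for k in range(p)]

    alpha = np.zeros((p, p))
    alpha[loo, np.arange(p)[:, None]] = alpha_sub
    b = np.zeros((p, p))
    b[loo, np.arange(p)[:, None]] = b_sub

    state = ARDState(alpha=alpha, beta=beta, b=b, post_cov=post_cov,
                     n_iter=it, converged=converged)
    if compute_objective:
        state.objective_value = pard_objective(x, state, theta)
    return state
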