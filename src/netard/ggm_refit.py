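"""Graph-constrained maximum likelihood for the precision matrix, and EBIC.

Given a sample covariance S = (1/N) X'X and an undirected graph G, the
covariance-selection MLE maximizes

    l(Omega) = ln det(Omega) - trace(S Omega)

over symmetric positive-definite Omega whose off-diagonal support is
restricted to the edges of G. At the optimum the implied covariance
W = Omega^{-1} matches S on every edge and on the diagonal (stationarity),
while Omega is exactly zero on non-edges.

The solver is the classical regression algorithm for covariance selection:
cycle over nodes; for node j with neighbor set ne(j), solve the reduced
system W_11[ne, ne] beta* = s_12[ne] and write W_11[:, ne] beta* into W's
j-th column; at convergence recover Omega column-wise from the final
regressions. Models are compared by an extended BIC on the same 1/N scale
as l(Omega):

    EBIC_gamma(Omega) = -l(Omega) + kappa * (ln N + 4 gamma ln p) / N

with kappa the number of edges (strict upper-triangle support of Omega).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_model import check_spd, partial_corr_from_precision, symmetrize

__all__ = [
    "ModelScore",
    "sample_cov",
    "gaussian_loglik",
    "fit_precision_given_graph",
    "ebic_score",
    "reestimate_weights",
]


@dataclass
class ModelScore:
    loglik: float
    kappa: int
    ebic: float
    gamma: float


def sample_cov(x: np.ndarray) -> np.ndarray:
    """S = (1/N) X'X — divisor N (the model assumes mean zero)."""
    x = np.asarray(x, dtype=float)
    return (x.T @ x) / x.shape[0]


def gaussian_loglik(omega: np.ndarray, s: np.ndarray) -> float:
    """l(Omega) = ln det(Omega) - trace(S Omega); Omega must be SPD."""
    omega = check_spd(omega)
    s = symmetrize(s)
    sign, logdet = np.linalg.slogdet(omega)
    if sign <= 0:
        raise ValueError("precision matrix is not positive definite")
    return float(logdet - np.sum(s * omega))


def fit_precision_given_graph(s: np.ndarray, edges, p: int | None = None,
                              tol: float = 1e-8, max_sweeps: int = 500
                              ) -> np.ndarray:
    """Covariance-selection MLE of Omega with support restricted to ``edges``.

    ``edges`` is an iterable of index pairs (k', k). Stationarity at the
    solution: (Omega^{-1})_{k'k} = S_{k'k} on every edge and on the diagonal.
    Emits a warning and returns the final iterate if the sweep budget is
    exhausted (possible when S is singular and the graph dense).
    """
    s = symmetrize(s)
    if p is None:
        p = s.shape[0]
    neighbors = [[] for _ in range(p)]
    for a, b in edges:
        a, b = int(a), int(b)
        if a == b:
            continue
        neighbors[a].append(b)
        neighbors[b].append(a)
    neighbors = [sorted(set(ne)) for ne in neighbors]

    w = s.copy()
    # start from a diagonal-consistent PD matrix; zero non-edge entries of W
    # are irrelevant, the sweeps overwrite columns
    betas = [np.zeros(len(ne)) for ne in neighbors]
    scale = float(np.mean(np.abs(np.diag(s)))) or 1.0
    converged = False
    for _ in range(max_sweeps):
        max_delta = 0.0
        for j in range(p):
            ne = neighbors[j]
            if not ne:
                new_col = np.zeros(p)
            else:
                idx = [i for i in range(p) if i != j]
                w11 = w[np.ix_(idx, idx)]
                # positions of ne within idx
                pos = [i if i < j else i - 1 for i in ne]
                sub = w11[np.ix_(pos, pos)]
                rhs = s[ne, j]
                try:
                    beta_star = np.linalg.solve(sub, rhs)
                except np.linalg.LinAlgError:
                    beta_star = np.linalg.lstsq(sub, rhs, rcond=None)[0]
                betas[j] = beta_star
                full = np.zeros(p - 1)
                full[pos] = beta_star
                new_col = np.zeros(p)
                new_col[idx] = w11 @ full
            delta = np.max(np.abs(new_col[np.arange(p) != j]
                                  - w[np.arange(p) != j, j]))
            max_delta = max(max_delta, float(delta))
            w[np.arange(p) != j, j] = new_col[np.arange(p) != j]
            w[j, np.arange(p) != j] = new_col[np.arange(p) != j]
        if max_delta < tol * scale:
            converged = True
            break
    if not converged:
        warnings.warn(
            "graph-constrained ML refit did not converge within the sweep "
            "budget; returning the final iterate", RuntimeWarning)

    # recover Omega from the final regressions
    omega = np.zeros((p, p))
    for j in range(p):
        ne = neighbors[j]
        if ne:
            w12 = w[ne, j]
            ojj = 1.0 / (s[j, j] - float(w12 @ betas[j]))
            omega[j, j] = ojj
            omega[ne, j] = -betas[j] * ojj
        else:
            omega[j, j] = 1.0 / s[j, j]
    return symmetrize(omega)


def ebic_score(omega: np.ndarray, s: np.ndarray, n: int, gamma: float
               ) -> ModelScore:
    """Extended BIC of a fitted precision matrix on the l(Omega) scale."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    omega = symmetrize(omega)
    p = omega.shape[0]
    ll = gaussian_loglik(omega, s)
    iu = np.triu_indices(p, k=1)
    kappa = int(np.count_nonzero(omega[iu]))
    ebic = -ll + kappa * (np.log(n) + 4.0 * gamma * np.log(p)) / n
    return ModelScore(loglik=ll, kappa=kappa, ebic=float(ebic), gamma=gamma)


def reestimate_weights(omega_hat: np.ndarray) -> np.ndarray:
    """Edge weights |pi| from the refit precision; zero exactly off-support."""
    pi = partial_corr_from_precision(omega_hat)
    w = np.abs(pi)
    w[omega_hat == 0] = 0.0
    np.fill_diagonal(w, 0.0)
    return w
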