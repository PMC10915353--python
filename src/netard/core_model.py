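"""Partial-correlation algebra for Gaussian graphical models.

Links the precision matrix Omega = Sigma^{-1} of a zero-mean Gaussian gene
expression vector to (i) partial correlations pi_{k'k}, (ii) the node-wise
optimal linear regression coefficients b_{k'}^{(k)}, and (iii) the weighted
adjacency matrix w_{k'k} = |pi_{k'k}| of the gene network.

The three are tied together by

    pi_{k'k} = -omega_{k'k} / sqrt(omega_{k'k'} * omega_{kk})
    b_{k'}^{(k)} = -omega_{k'k} / omega_{kk}
    pi_{k'k} = sign(b_{k'}^{(k)}) * sqrt(b_{k'}^{(k)} * b_{k}^{(k')})

so partial correlations can be recovered either exactly from Omega or as a
plug-in from estimated regression coefficients (with a sign/clipping rule for
estimates whose coefficient product falls outside [0, 1]).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "symmetrize",
    "check_spd",
    "partial_corr_from_precision",
    "regression_coefs_from_precision",
    "pi_from_coef_pair",
    "pi_from_coef_matrix",
    "weights_from_partial_corr",
]

#: relative eigenvalue threshold for the SPD check
SPD_RTOL = 1e-10


def symmetrize(m: np.ndarray) -> np.ndarray:
    """Return (M + M.T) / 2, tolerating I/O round-trip asymmetry."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    return (m + m.T) / 2.0


def check_spd(omega: np.ndarray, name: str = "omega") -> np.ndarray:
    """Symmetrize and validate that a matrix is symmetric positive definite.

    Positive definiteness is judged by the smallest eigenvalue exceeding
    ``SPD_RTOL`` times the largest; the diagonal must be strictly positive.
    Returns the symmetrized matrix.
    """
    omega = symmetrize(omega)
    if not np.all(np.isfinite(omega)):
        raise ValueError(f"{name} contains non-finite entries")
    if np.any(np.diag(omega) <= 0):
        raise ValueError(f"{name} has a non-positive diagonal entry")
    evals = np.linalg.eigvalsh(omega)
    if evals[0] <= SPD_RTOL * max(evals[-1], 0.0):
        raise ValueError(
            f"{name} is not positive definite (min eigenvalue {evals[0]:.3e})"
        )
    return omega


def partial_corr_from_precision(omega: np.ndarray) -> np.ndarray:
    """Partial correlation matrix from an SPD precision matrix.

    pi_{k'k} = -omega_{k'k} / sqrt(omega_{k'k'} omega_{kk}) off the diagonal,
    zero on the diagonal. Equals the correlation between the residuals of the
    two optimal linear regressions of X_{k'} and X_k on the remaining genes.
    """
    omega = check_spd(omega)
    d = np.sqrt(np.diag(omega))
    pi = -omega / np.outer(d, d)
    np.fill_diagonal(pi, 0.0)
    return pi


def regression_coefs_from_precision(omega: np.ndarray) -> np.ndarray:
    """Matrix B with B[k', k] = b_{k'}^{(k)} = -omega_{k'k} / omega_{kk}.

    Column k holds the coefficients of the optimal linear regression of gene k
    on all other genes; the diagonal is set to zero (a gene does not regress
    on itself).
    """
    omega = symmetrize(omega)
    diag = np.diag(omega)
    if np.any(diag <= 0):
        raise ValueError("precision matrix has a non-positive diagonal entry")
    b = -omega / diag[np.newaxis, :]
    np.fill_diagonal(b, 0.0)
    return b


def pi_from_coef_pair(b_kp_k: float, b_k_kp: float) -> float:
    """Plug-in partial correlation from a pair of regression coefficients.

    rho = sign(b_{k'}^{(k)}) * sqrt(b_{k'}^{(k)} * b_{k}^{(k')}) when the
    product is positive, 0 otherwise; the result is clipped to [-1, 1].
    Estimated coefficients need not satisfy 0 <= b b' <= 1, hence the rule.
    """
    if not (np.isfinite(b_kp_k) and np.isfinite(b_k_kp)):
        raise ValueError("coefficients must be finite")
    prod = b_kp_k * b_k_kp
    if prod <= 0:
        return 0.0
    rho = np.sign(b_kp_k) * np.sqrt(prod)
    return float(np.clip(rho, -1.0, 1.0))


def pi_from_coef_matrix(b: np.ndarray) -> np.ndarray:
    """Vectorized plug-in partial correlations from a coefficient matrix.

    ``b[k', k]`` is the coefficient of gene k' in gene k's regression. Entries
    whose symmetric product ``b[k',k] * b[k,k']`` is non-positive map to 0;
    the rest map to the signed square root, clipped to [-1, 1].
    """
    b = np.asarray(b, dtype=float)
    if not np.all(np.isfinite(b)):
        raise ValueError("coefficient matrix contains non-finite entries")
    prod = b * b.T
    with np.errstate(invalid="ignore"):
        pi = np.sign(b) * np.sqrt(np.where(prod > 0, prod, 0.0))
    pi = np.clip(pi, -1.0, 1.0)
    np.fill_diagonal(pi, 0.0)
    return pi


def weights_from_partial_corr(pi: np.ndarray) -> np.ndarray:
    """Weighted adjacency: element-wise |pi| off-diagonal, zero diagonal."""
    pi = symmetrize(pi)
    w = np.abs(pi)
    np.fill_diagonal(w, 0.0)
    return w
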