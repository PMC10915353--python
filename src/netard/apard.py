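"""Adaptive pARD (apARD): data-driven regularization of the edge weights.

The loop alternates (i) a pARD fit, (ii) plug-in edge weights
w_{k'k} = |pi_{k'k}| from the coefficient pairs, (iii) optional shrinkage of
weights outside a prior edge set E0, and (iv) an update of the Gamma
hyper-rates from the current weights and node connectivities:

    r_new[k', k] = lam / ((1 - xi) * phi(w_{k'k}) + xi * phi(v_{k'})) + 1/2
    s_new = r_new * r_new   (element-wise)

where v_k = (1/p) sum_j w_{jk} is node k's connectivity and phi is a strictly
increasing map from [0, 1] into (0, inf) (default phi(t) = t + 0.01). The
prior mean of alpha_{k'}^{(k)} is s/r = r_new, so a weak edge (small w) earns
a large prior precision and is shrunk harder in the next pARD fit, while a
strong edge earns a small one — the "strong get stronger, weak get weaker"
dynamic. xi interpolates between purely edge-wise regularization (xi = 0)
and purely connectivity-driven regularization (xi = 1), which concentrates
surviving edges on high-connectivity (hub) nodes. The additive 1/2 floor
keeps every shape s = r^2 above 1/4 (and above 1/2 whenever r > 1/sqrt(2)).

By default the rate update sees the weight matrix scaled by its maximum
entry and the connectivities scaled by their own maximum: as lam grows, all
weights shrink together, and without rescaling the floor of phi would swamp
the weak/strong contrast that drives the adaptation (and the connectivity
term, an average of weights, would be swamped relative to the edge term).
The default phi is quadratic with an additive floor,
phi(t) = t^2 + 0.01, which sharpens that contrast while capping the largest
rate at lam/0.01; the plain linear map t + 0.01 is available as
``phi_linear``.

When a prior edge set is supplied, weights of pairs outside it are scaled by
the shrinkage constant c in [0, 1) at the end of every outer iteration,
before the rate update; with c = 0 the non-prior block is exactly zero from
the first iteration on. The final weight matrix is sparsified by zeroing
entries below 1e-3, and the inferred graph has an edge wherever the
sparsified weight is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np

from . import core_model, pard

__all__ = [
    "AdaptiveConfig",
    "phi_linear",
    "phi_quadratic",
    "connectivity",
    "update_hyperrates",
    "apply_prior_graph_shrinkage",
    "hub_prior_edges",
    "prior_edge_mask",
    "fit_apard",
]


def phi_linear(t):
    """phi(t) = t + 0.01: strictly increasing, [0, 1] -> (0, inf)."""
    return t + 0.01


def phi_quadratic(t):
    """phi(t) = t^2 + 0.01 (default).

    The quadratic sharpens the contrast between weak and strong edges while
    the additive floor bounds the largest attainable rate at lam / 0.01, so
    the weak-get-weaker feedback prunes without a global death spiral.
    """
    return t ** 2 + 0.01


@dataclass
class AdaptiveConfig:
    """Tuning constants of the adaptive estimation loop.

    lam : overall regularization scale (larger -> sparser network).
    xi : in [0, 1]; weight on connectivity-driven (hub-seeking) relative to
        edge-wise regularization.
    phi : strictly increasing map [0, 1] -> (0, inf) applied to weights and
        connectivities before forming the rates.
    c_shrink : in [0, 1); multiplier applied each iteration to weights of
        pairs outside ``prior_edges`` (0 removes them outright).
    prior_edges : optional iterable of index or id pairs forming E0.
    normalize_rates : if True (default), the rate update sees the weight
        matrix scaled by its maximum entry and the connectivity vector scaled
        by its own maximum, so both phi arguments span [0, 1] and the
        relative weak/strong contrast drives the adaptation at every overall
        shrinkage level.
    reciprocal_rates : if True (default) use the reciprocal reading of the
        rate update, r = lam / (...) + 1/2; if False, the direct product
        reading r = lam * (...) + 1/2.
    sparsify_threshold : final weights below this are reset to zero.
    """

    lam: float = 1.0
    xi: float = 0.0
    phi: Callable[[np.ndarray], np.ndarray] = phi_quadratic
    c_shrink: float = 0.0
    prior_edges: Iterable | None = None
    normalize_rates: bool = True
    max_outer_iters: int = 20
    weight_tol: float = 1e-4
    sparsify_threshold: float = 1e-3
    reciprocal_rates: bool = True
    s_beta: float = 1e-2
    r_beta: float = 1e-2
    pard_tol: float = 1e-3
    pard_max_iter: int = 200

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if not 0.0 <= self.xi <= 1.0:
            raise ValueError("xi must lie in [0, 1]")
        if not 0.0 <= self.c_shrink < 1.0:
            raise ValueError("c_shrink must lie in [0, 1)")


def connectivity(w: np.ndarray) -> np.ndarray:
    """Node connectivities v_k = (1/p) * sum_j w_{jk}, each in [0, 1]."""
    w = np.asarray(w, dtype=float)
    return w.sum(axis=0) / w.shape[0]


def update_hyperrates(w: np.ndarray, v: np.ndarray, cfg: AdaptiveConfig):
    """New Gamma rates and shapes from current weights and connectivities.

    Returns ``(r_new, s_new)`` as (p, p) matrices with [k', k] indexing the
    prior on gene k''s coefficient in node k's regression (diagonal zeroed).
    """
    w = np.asarray(w, dtype=float)
    v = np.asarray(v, dtype=float)
    phi_w = cfg.phi(w)
    phi_v = cfg.phi(v)
    mix = (1.0 - cfg.xi) * phi_w + cfg.xi * phi_v[:, np.newaxis]
    if cfg.reciprocal_rates:
        r_new = cfg.lam / mix + 0.5
    else:
        r_new = cfg.lam * mix + 0.5
    s_new = r_new * r_new
    np.fill_diagonal(r_new, 0.0)
    np.fill_diagonal(s_new, 0.0)
    return r_new, s_new


def prior_edge_mask(p: int, prior_edges, gene_ids=None) -> np.ndarray:
    """Boolean (p, p) mask: True where the pair belongs to E0 (both orientations)."""
    mask = np.zeros((p, p), dtype=bool)
    if gene_ids is not None:
        pos = {g: i for i, g in enumerate(gene_ids)}
    for a, b in prior_edges:
        if gene_ids is not None and not isinstance(a, (int, np.integer)):
            if a not in pos or b not in pos:
                missing = a if a not in pos else b
                raise ValueError(f"prior edge references unknown gene: {missing}")
            a, b = pos[a], pos[b]
        if not (0 <= a < p and 0 <= b < p):
            raise ValueError(f"prior edge index out of range: ({a}, {b})")
        if a != b:
            mask[a, b] = mask[b, a] = True
    return mask


def apply_prior_graph_shrinkage(w: np.ndarray, prior_edges, c_shrink: float,
                                gene_ids=None) -> np.ndarray:
    """Scale weights of pairs outside the prior edge set E0 by c_shrink."""
    if not 0.0 <= c_shrink < 1.0:
        raise ValueError("c_shrink must lie in [0, 1)")
    w = np.asarray(w, dtype=float).copy()
    mask = prior_edge_mask(w.shape[0], prior_edges, gene_ids)
    off = ~np.eye(w.shape[0], dtype=bool)
    scale_here = off & ~mask
    w[scale_here] *= c_shrink
    return w


def hub_prior_edges(genes, hubs):
    """E0 for given hub genes: every pair touching at least one hub."""
    genes = list(genes)
    gene_set = set(genes)
    hubs = list(hubs)
    for h in hubs:
        if h not in gene_set:
            raise ValueError(f"hub gene not in gene list: {h}")
    uniq = set()
    for h in hubs:
        for g in genes:
            if g != h:
                uniq.add((h, g) if str(h) <= str(g) else (g, h))
    return sorted(uniq, key=lambda e: (str(e[0]), str(e[1])))


def fit_apard(x: np.ndarray, cfg: AdaptiveConfig, gene_ids=None,
              return_history: bool = False):
    """Run the adaptive estimation loop on a standardized expression matrix.

    Returns ``(w, edges)`` — the sparsified weighted adjacency and the edge
    list (index pairs, k' < k) of the inferred graph — or, with
    ``return_history``, ``(w, edges, history)`` where history holds the
    per-iteration maximum weight change.
    """
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    prior_mask = None
    if cfg.prior_edges is not None:
        prior_mask = prior_edge_mask(p, cfg.prior_edges, gene_ids)

    # neutral start: rates as if every weight were 0.5
    phi_half = float(cfg.phi(np.array(0.5)))
    if cfg.reciprocal_rates:
        r0 = cfg.lam / phi_half + 0.5
    else:
        r0 = cfg.lam * phi_half + 0.5
    r_mat = np.full((p, p), r0)
    s_mat = r_mat * r_mat
    np.fill_diagonal(r_mat, 0.0)
    np.fill_diagonal(s_mat, 0.0)

    w_prev = None
    state = None
    history = []
    for outer in range(cfg.max_outer_iters):
        # rebuild theta with strictly positive placeholders on the diagonal
        s_use = s_mat + np.eye(p)
        r_use = r_mat + np.eye(p)
        theta = pard.HyperParams(s_use, r_use, cfg.s_beta, cfg.r_beta)
        try:
            state = pard.fit_pard(x, theta, init=state, tol=cfg.pard_tol,
                                  max_iter=cfg.pard_max_iter)
        except FloatingPointError as err:
            raise FloatingPointError(
                f"outer iteration {outer + 1}: {err}") from err
        pi = core_model.pi_from_coef_matrix(state.b)
        w = core_model.weights_from_partial_corr(pi)
        if prior_mask is not None:
            off = ~np.eye(p, dtype=bool)
            w[off & ~prior_mask] *= cfg.c_shrink
        delta = np.inf if w_prev is None else float(np.max(np.abs(w - w_prev)))
        history.append(delta)
        w_prev = w
        if delta < cfg.weight_tol:
            break
        w_for_rates = w
        v = connectivity(w)
        if cfg.normalize_rates:
            if w.max() > 0:
                w_for_rates = w / w.max()
            if v.max() > 0:
                v = v / v.max()
        r_mat, s_mat = update_hyperrates(w_for_rates, v, cfg)

    w_final = w_prev.copy()
    w_final[w_final < cfg.sparsify_threshold] = 0.0
    iu = np.triu_indices(p, k=1)
    edges = [(int(i), int(j)) for i, j in zip(*iu) if w_final[i, j] > 0]
    if return_history:
        return w_final, edges, history
    return w_final, edges
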