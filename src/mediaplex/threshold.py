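"""Epidemic threshold from the epidemic-free awareness profile.

Linearising the MMCA around the disease-free state gives an eigenvalue
condition: infection invades once βU exceeds μ divided by the spectral
radius of the awareness-weighted adjacency

    H = diag(pU + γ·pA) · B,

where B is the epidemic-layer adjacency and (pU, pA) is the stationary
awareness profile of the information dynamics (UAU + selective media) with
no disease present.  H is entrywise nonnegative, so its spectral radius is
a real (Perron) eigenvalue; with w = pU + γ·pA it shares its nonzero
spectrum with the symmetric matrix diag(√w)·B·diag(√w), which is what we
diagonalise.

:func:`threshold_by_scan` provides an independent numerical onset estimate
by scanning and bisecting the stationary infected density of the full MMCA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .dynamics import DynamicsParams, MMCAState, iterate_to_stationary
from .network import LayerGraph, MediaMask, MultiplexNetwork

__all__ = [
    "AwarenessFixedPoint",
    "ThresholdResult",
    "ScanRangeError",
    "epidemic_free_awareness",
    "awareness_fixed_point_direct",
    "build_H",
    "spectral_radius",
    "epidemic_threshold",
    "threshold_by_scan",
]

_DENSE_LIMIT = 2000


class ScanRangeError(RuntimeError):
    """The β grid does not bracket the epidemic onset."""


@dataclass
class AwarenessFixedPoint:
    p_u: np.ndarray
    p_a: np.ndarray
    iterations: int
    converged: bool


@dataclass
class ThresholdResult:
    p_u: np.ndarray
    p_a: np.ndarray
    lambda_max: float
    beta_c: float
    degenerate: bool


def epidemic_free_awareness(
    params: DynamicsParams,
    net: MultiplexNetwork,
    mask: MediaMask,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> AwarenessFixedPoint:
    """Stationary awareness of the information dynamics with no disease.

    Solved by iterating the full MMCA with βU = 0: infection drains away
    (μ > 0) and the awareness marginals converge to the fixed point of the
    awareness-only system.  With κ = 0 the awareness marginal evolves
    autonomously, so this equals the direct awareness-only iteration
    (:func:`awareness_fixed_point_direct`) exactly.
    """
    result = iterate_to_stationary(
        MMCAState.homogeneous(net.n_nodes, params.rho0),
        params.replace(beta_u=0.0),
        net,
        mask,
        tol=tol,
        max_iter=max_iter,
    )
    return AwarenessFixedPoint(
        p_u=result.state.p_u,
        p_a=result.state.p_a,
        iterations=result.iterations,
        converged=result.converged,
    )


def awareness_fixed_point_direct(
    params: DynamicsParams,
    net: MultiplexNetwork,
    mask: MediaMask,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    p_a0: np.ndarray | None = None,
) -> AwarenessFixedPoint:
    """Awareness fixed point by iterating the awareness-only equations.

    pU' = pU·r·(1−m_i) + pA·δ·(1−m_i),  pA' = 1 − pU',
    with r recomputed from pA each sweep.  Kept as an independent route to
    the same fixed point as :func:`epidemic_free_awareness`.
    """
    n = net.n_nodes
    adj_info = net.info_layer.adjacency()
    m_i = mask.m_i
    p_a = np.zeros(n) if p_a0 is None else np.asarray(p_a0, dtype=float).copy()
    converged = False
    iterations = 0
    from .dynamics import _neighbor_products  # shared exact product kernel

    for iterations in range(1, max_iter + 1):
        r = _neighbor_products(adj_info, 1.0 - params.lambda_ * p_a)
        p_u_new = (1.0 - p_a) * r * (1.0 - m_i) + p_a * params.delta * (1.0 - m_i)
        p_a_new = 1.0 - p_u_new
        change = float(np.abs(p_a_new - p_a).max())
        p_a = p_a_new
        if change < tol:
            converged = True
            break
    return AwarenessFixedPoint(p_u=1.0 - p_a, p_a=p_a, iterations=iterations, converged=converged)


def build_H(
    p_u: np.ndarray, p_a: np.ndarray, gamma: float, epi: LayerGraph
) -> sp.csr_matrix:
    """Awareness-weighted adjacency H with entries (pU_i + γ·pA_i)·b_ij.

    The epidemic layer is undirected (b_ij = b_ji), so H is a row scaling of
    the symmetric adjacency; its spectrum is unchanged under transposition.
    """
    w = np.asarray(p_u, dtype=float) + gamma * np.asarray(p_a, dtype=float)
    if w.shape != (epi.n_nodes,):
        raise ValueError("awareness vectors must have one entry per node")
    return sp.diags(w) @ epi.adjacency()


def spectral_radius(adj: sp.csr_matrix, weights: np.ndarray | None = None) -> float:
    """Spectral radius of diag(weights)·adj for a symmetric nonnegative adj.

    Uses the symmetric similarity diag(√w)·adj·diag(√w): dense eigvalsh up
    to 2000 nodes, Lanczos (eigsh) above.
    """
    n = adj.shape[0]
    if weights is None:
        sym = adj
    else:
        s = sp.diags(np.sqrt(np.clip(np.asarray(weights, dtype=float), 0.0, None)))
        sym = s @ adj @ s
    if sym.nnz == 0:
        return 0.0
    if n <= _DENSE_LIMIT:
        vals = np.linalg.eigvalsh(sym.toarray())
        return float(vals[-1])
    vals = spla.eigsh(sym.tocsc().astype(float), k=1, which="LA", return_eigenvectors=False)
    return float(vals[0])


def epidemic_threshold(
    params: DynamicsParams,
    net: MultiplexNetwork,
    mask: MediaMask,
    tol: float = 1e-10,
) -> ThresholdResult:
    """Spectral epidemic threshold βc = μ / Λmax(H).

    Computes the epidemic-free awareness profile, forms the weights
    pU + γ·pA, and divides μ by the spectral radius of H.  When Λmax = 0
    (e.g. γ = 0 with everyone aware) the threshold is degenerate and
    reported as +inf.
    """
    if params.mu <= 0:
        raise ValueError("mu must be positive for a finite threshold")
    awareness = epidemic_free_awareness(params, net, mask, tol=tol)
    w = awareness.p_u + params.gamma * awareness.p_a
    lam = spectral_radius(net.epi_layer.adjacency(), w)
    degenerate = lam <= 1e-12
    beta_c = float("inf") if degenerate else params.mu / lam
    return ThresholdResult(
        p_u=awareness.p_u,
        p_a=awareness.p_a,
        lambda_max=lam,
        beta_c=beta_c,
        degenerate=degenerate,
    )


def threshold_by_scan(
    params: DynamicsParams,
    net: MultiplexNetwork,
    mask: MediaMask,
    beta_grid: np.ndarray,
    cutoff: float = 1e-4,
    refine_tol: float = 1e-3,
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> float:
    """Empirical epidemic onset from the stationary MMCA infected density.

    Finds the first grid β whose stationary ρI exceeds ``cutoff`` and
    bisects between it and its subcritical predecessor down to
    ``refine_tol``.  Raises :class:`ScanRangeError` when the grid does not
    bracket the onset (entirely sub- or supercritical).
    """
    beta_grid = np.asarray(beta_grid, dtype=float)
    if beta_grid.ndim != 1 or beta_grid.size < 2 or np.any(np.diff(beta_grid) <= 0):
        raise ValueError("beta_grid must be ascending with at least two values")

    def stationary_rho(beta: float) -> float:
        res = iterate_to_stationary(
            MMCAState.homogeneous(net.n_nodes, params.rho0),
            params.replace(beta_u=beta),
            net,
            mask,
            tol=tol,
            max_iter=max_iter,
        )
        return res.rho_i

    rho = [stationary_rho(b) for b in beta_grid]
    above = [i for i, v in enumerate(rho) if v > cutoff]
    if not above:
        raise ScanRangeError("no supercritical beta on the grid")
    first = above[0]
    if first == 0:
        raise ScanRangeError("grid starts supercritical; extend it downward")
    lo, hi = float(beta_grid[first - 1]), float(beta_grid[first])
    while hi - lo > refine_tol:
        mid = 0.5 * (lo + hi)
        if stationary_rho(mid) > cutoff:
            hi = mid
        else:
            lo = mid
    return hi
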