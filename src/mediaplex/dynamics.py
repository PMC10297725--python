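"""Microscopic Markov chain (MMCA) solver for the coupled UAU-SIS process.

Each individual occupies one of four joint states — unaware-susceptible
(US), unaware-infected (UI), aware-susceptible (AS), aware-infected (AI) —
and the MMCA tracks the per-node probabilities of those states under a
synchronous discrete-time update.  A time step has four phases:

  I.   awareness diffusion (UAU): an unaware node learns from each aware
       information-layer neighbour with probability λ; an aware node
       forgets with probability δ;
  II.  mass-media broadcast: a still-unaware targeted node becomes aware
       with probability m;
  III. epidemic transmission (SIS): a susceptible node is infected by each
       infected epidemic-layer neighbour with probability βA = γ·βU if it
       is aware after phase II, βU otherwise; an infected node recovers
       with probability μ;
  IV.  self-awakening: a node infected at the end of phase III and still
       unaware becomes aware with probability κ.

The per-node closure treats neighbours as independent, giving the escape
products r (not informed), qU and qA (not infected while unaware/aware) and
the composed awareness factors f.  Iterating the update to a fixed point
yields the stationary infected density ρI and aware density ρA.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
import scipy.sparse as sp

from .network import MediaMask, MultiplexNetwork

__all__ = [
    "DynamicsParams",
    "MMCAState",
    "TransitionFactors",
    "MMCAResult",
    "compute_factors",
    "mmca_step",
    "iterate_to_stationary",
    "infected_density",
    "aware_density",
]

_UNIT_FIELDS = ("beta_u", "gamma", "mu", "lambda_", "delta", "m", "eta", "kappa", "rho0")


@dataclass(frozen=True)
class DynamicsParams:
    """All rate/probability parameters of the coupled process.

    beta_u : infection probability per infected contact for unaware nodes
    gamma  : infection attenuation for aware nodes (βA = γ·βU; 0 = immune)
    mu     : recovery probability
    lambda_: awareness transmission probability per aware contact
    delta  : forgetting probability
    m      : media broadcast success probability for targeted nodes
    eta    : media broadcast proportion (top-η fraction by info degree)
    kappa  : self-awakening probability of unaware infected nodes
    rho0   : initially infected fraction
    """

    beta_u: float
    gamma: float = 0.4
    mu: float = 0.5
    lambda_: float = 0.15
    delta: float = 0.6
    m: float = 0.5
    eta: float = 0.0
    kappa: float = 0.0
    rho0: float = 0.2

    def __post_init__(self) -> None:
        for name in _UNIT_FIELDS:
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"{name}={val} outside [0, 1]")

    @property
    def beta_a(self) -> float:
        """Infection probability for aware nodes, βA = γ·βU."""
        return self.gamma * self.beta_u

    def replace(self, **changes) -> "DynamicsParams":
        return replace(self, **changes)


@dataclass
class MMCAState:
    """Per-node probabilities of the four joint states."""

    p_us: np.ndarray
    p_ui: np.ndarray
    p_as: np.ndarray
    p_ai: np.ndarray

    @classmethod
    def homogeneous(cls, n: int, rho0: float) -> "MMCAState":
        """Mean-field start: every node has pUI = rho0, pUS = 1 - rho0, unaware-only."""
        return cls(
            p_us=np.full(n, 1.0 - rho0),
            p_ui=np.full(n, rho0),
            p_as=np.zeros(n),
            p_ai=np.zeros(n),
        )

    @property
    def n(self) -> int:
        return self.p_us.shape[0]

    @property
    def p_u(self) -> np.ndarray:
        return self.p_us + self.p_ui

    @property
    def p_a(self) -> np.ndarray:
        return self.p_as + self.p_ai

    @property
    def p_i(self) -> np.ndarray:
        return self.p_ui + self.p_ai

    @property
    def p_s(self) -> np.ndarray:
        return self.p_us + self.p_as

    def conservation_error(self) -> float:
        """Max deviation of per-node probability mass from 1."""
        total = self.p_us + self.p_ui + self.p_as + self.p_ai
        return float(np.abs(total - 1.0).max())

    def arrays(self) -> Iterator[np.ndarray]:
        yield from (self.p_us, self.p_ui, self.p_as, self.p_ai)


@dataclass
class TransitionFactors:
    """Escape products and awareness transition factors for one step."""

    r: np.ndarray     # P(not informed by neighbours)
    q_u: np.ndarray   # P(not infected | unaware)
    q_a: np.ndarray   # P(not infected | aware)
    f_uu: np.ndarray  # P(U -> U after phases I-II)
    f_ua: np.ndarray  # P(U -> A after phases I-II)
    f_au: np.ndarray  # P(A -> U after phases I-II)
    f_aa: np.ndarray  # P(A -> A after phases I-II)


@dataclass
class MMCAResult:
    """Outcome of fixed-point iteration."""

    state: MMCAState
    rho_i: float
    rho_a: float
    iterations: int
    converged: bool
    residual: float
    max_conservation_error: float


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def _neighbor_products(adj: sp.csr_matrix, factors: np.ndarray) -> np.ndarray:
    """Exact per-node product of ``factors[j]`` over neighbours j.

    Segmented product over the CSR structure; rows without neighbours give
    the empty product 1.
    """
    vals = np.append(factors[adj.indices], 1.0)
    starts = np.minimum(adj.indptr[:-1], vals.size - 1)
    out = np.multiply.reduceat(vals, starts)
    out[np.diff(adj.indptr) == 0] = 1.0
    return out


def compute_factors(
    state: MMCAState,
    params: DynamicsParams,
    net: MultiplexNetwork,
    mask: MediaMask,
    adj_info: sp.csr_matrix | None = None,
    adj_epi: sp.csr_matrix | None = None,
) -> TransitionFactors:
    """Escape products and awareness factors from the current state.

    r_i  = Π_j over info neighbours (1 − λ·pA_j)
    qU_i = Π_j over epi neighbours (1 − βU·pI_j)
    qA_i = Π_j over epi neighbours (1 − βA·pI_j)
    and, with m_i the media probability for node i,
    fU→U = r·(1−m_i), fU→A = 1−fU→U, fA→U = δ·(1−m_i), fA→A = 1−fA→U.
    """
    if adj_info is None:
        adj_info = net.info_layer.adjacency()
    if adj_epi is None:
        adj_epi = net.epi_layer.adjacency()
    p_a = state.p_a
    p_i = state.p_i
    r = _neighbor_products(adj_info, 1.0 - params.lambda_ * p_a)
    q_u = _neighbor_products(adj_epi, 1.0 - params.beta_u * p_i)
    q_a = _neighbor_products(adj_epi, 1.0 - params.beta_a * p_i)
    m_i = mask.m_i
    f_uu = r * (1.0 - m_i)
    f_au = params.delta * (1.0 - m_i)
    return TransitionFactors(
        r=r, q_u=q_u, q_a=q_a,
        f_uu=f_uu, f_ua=1.0 - f_uu, f_au=f_au, f_aa=1.0 - f_au,
    )


def mmca_step(
    state: MMCAState, factors: TransitionFactors, params: DynamicsParams
) -> MMCAState:
    """One synchronous MMCA update (factors must come from ``state``)."""
    mu, kappa = params.mu, params.kappa
    f_uu, f_ua, f_au, f_aa = factors.f_uu, factors.f_ua, factors.f_au, factors.f_aa
    q_u, q_a = factors.q_u, factors.q_a
    us, ui, as_, ai = state.p_us, state.p_ui, state.p_as, state.p_ai

    p_us = ui * f_uu * mu + ai * f_au * mu + us * f_uu * q_u + as_ * f_au * q_u
    p_ui = (
        ui * f_uu * (1 - mu) + ai * f_au * (1 - mu)
        + us * f_uu * (1 - q_u) + as_ * f_au * (1 - q_u)
    ) * (1 - kappa)
    p_as = ui * f_ua * mu + ai * f_aa * mu + us * f_ua * q_a + as_ * f_aa * q_a
    p_ai = (
        ui * (f_ua * (1 - mu) + f_uu * (1 - mu) * kappa)
        + ai * (f_aa * (1 - mu) + f_au * (1 - mu) * kappa)
        + us * (f_ua * (1 - q_a) + f_uu * (1 - q_u) * kappa)
        + as_ * (f_aa * (1 - q_a) + f_au * (1 - q_u) * kappa)
    )
    return MMCAState(p_us=p_us, p_ui=p_ui, p_as=p_as, p_ai=p_ai)


def iterate_to_stationary(
    state0: MMCAState,
    params: DynamicsParams,
    net: MultiplexNetwork,
    mask: MediaMask,
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> MMCAResult:
    """Iterate factor computation + update until the state stops moving.

    Stops when the max-abs per-node change over all four probabilities drops
    below ``tol``; non-convergence within ``max_iter`` is reported via
    ``converged=False``, never raised.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    adj_info = net.info_layer.adjacency()
    adj_epi = net.epi_layer.adjacency()
    state = state0
    residual = np.inf
    max_cons = state.conservation_error()
    iterations = 0
    for iterations in range(1, max_iter + 1):
        factors = compute_factors(state, params, net, mask, adj_info, adj_epi)
        new = mmca_step(state, factors, params)
        residual = max(
            float(np.abs(b - a).max()) for a, b in zip(state.arrays(), new.arrays())
        )
        max_cons = max(max_cons, new.conservation_error())
        state = new
        if residual < tol:
            break
    return MMCAResult(
        state=state,
        rho_i=infected_density(state),
        rho_a=aware_density(state),
        iterations=iterations,
        converged=residual < tol,
        residual=residual,
        max_conservation_error=max_cons,
    )


def infected_density(state: MMCAState) -> float:
    """ρI: mean over nodes of pUI + pAI."""
    return float(state.p_i.mean())


def aware_density(state: MMCAState) -> float:
    """ρA: mean over nodes of pAS + pAI."""
    return float(state.p_a.mean())
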