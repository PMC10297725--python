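"""Stochastic simulation of the coupled awareness-epidemic process.

Discrete-time, synchronous, four phases per step (awareness diffusion,
media broadcast, epidemic transmission, self-awakening), matching the
per-node transition trees that the MMCA closure averages over.  Also
provides an exact joint-distribution propagator over the full 4^N state
space for tiny systems, used as an unbiasedness oracle for the simulator,
and a plain single-layer SIS simulator sharing the same per-step RNG layout
so that matched-seed trajectory comparisons are possible in the decoupled
limit (γ=1, κ=0).

Every step draws exactly five uniform (runs × nodes) arrays, in a fixed
order, regardless of parameter values; this keeps random streams aligned
across parameterisations with the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import scipy.sparse as sp

from .dynamics import DynamicsParams
from .network import LayerGraph, MediaMask, MultiplexNetwork

__all__ = [
    "NodeStates",
    "SimulationResult",
    "init_states",
    "mc_step",
    "run_ensemble",
    "simulate_sis",
    "exact_small_chain",
]


@dataclass
class NodeStates:
    """Joint discrete state of every individual: (aware, infected) flags."""

    aware: np.ndarray
    infected: np.ndarray

    @property
    def n(self) -> int:
        return self.aware.shape[0]

    def labels(self) -> np.ndarray:
        """Per-node labels in {US, UI, AS, AI}."""
        lab = np.array(["US", "UI", "AS", "AI"])
        return lab[2 * self.aware.astype(int) + self.infected.astype(int)]


@dataclass
class SimulationResult:
    """Ensemble summary: density trajectories and stationary tail averages."""

    rho_i_t: np.ndarray      # mean over runs of per-run infected density, len t_max+1
    rho_a_t: np.ndarray
    rho_i_t_se: np.ndarray   # standard error over runs, per time point
    rho_i: float             # tail-averaged stationary infected density
    rho_a: float
    rho_i_se: float          # SE over runs of the per-run tail average
    rho_a_se: float
    n_steps: int
    transient: int
    tail: int
    n_runs: int
    seed: int


def init_states(net: MultiplexNetwork, rho0: float, seed: int) -> NodeStates:
    """round(rho0·N) uniformly chosen individuals start UI; everyone unaware."""
    if not (0 <= rho0 <= 1):
        raise ValueError("rho0 must be in [0, 1]")
    n = net.n_nodes
    k = int(round(rho0 * n))
    rng = np.random.default_rng(seed)
    infected = np.zeros(n, dtype=bool)
    infected[rng.choice(n, size=k, replace=False)] = True
    return NodeStates(aware=np.zeros(n, dtype=bool), infected=infected)


def _step_batch(
    aware: np.ndarray,
    infected: np.ndarray,
    params: DynamicsParams,
    adj_info: sp.csr_matrix,
    adj_epi: sp.csr_matrix,
    targeted: np.ndarray,
    m: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance a (runs, nodes) batch of joint states by one four-phase step."""
    shape = aware.shape
    u_info = rng.random(shape)
    u_media = rng.random(shape)
    u_inf = rng.random(shape)
    u_rec = rng.random(shape)
    u_wake = rng.random(shape)

    # phase I: UAU, synchronous within phase
    n_aware_nb = aware.astype(np.float64) @ adj_info
    p_gain = 1.0 - (1.0 - params.lambda_) ** n_aware_nb
    gained = ~aware & (u_info < p_gain)
    forgot = aware & (u_info < params.delta)
    aware = (aware & ~forgot) | gained

    # phase II: selective mass media
    aware = aware | (~aware & targeted & (u_media < m))

    # phase III: SIS with awareness-dependent infectivity, synchronous
    n_inf_nb = infected.astype(np.float64) @ adj_epi
    beta_i = np.where(aware, params.beta_a, params.beta_u)
    p_inf = 1.0 - (1.0 - beta_i) ** n_inf_nb
    newly = ~infected & (u_inf < p_inf)
    recovered = infected & (u_rec < params.mu)
    infected = (infected & ~recovered) | newly

    # phase IV: self-awakening of unaware infected
    aware = aware | (infected & ~aware & (u_wake < params.kappa))
    return aware, infected


def mc_step(
    states: NodeStates,
    params: DynamicsParams,
    net: MultiplexNetwork,
    mask: MediaMask,
    rng: np.random.Generator,
) -> NodeStates:
    """One stochastic step for a single configuration."""
    aware, infected = _step_batch(
        states.aware[None, :],
        states.infected[None, :],
        params,
        net.info_layer.adjacency(),
        net.epi_layer.adjacency(),
        mask.targeted[None, :],
        mask.m,
        rng,
    )
    return NodeStates(aware=aware[0], infected=infected[0])


def _init_batch(n: int, k: int, n_runs: int, rng: np.random.Generator) -> np.ndarray:
    """Each run independently infects k uniformly chosen individuals."""
    scores = rng.random((n_runs, n))
    order = np.argsort(scores, axis=1)
    infected = np.zeros((n_runs, n), dtype=bool)
    rows = np.repeat(np.arange(n_runs), k)
    infected[rows, order[:, :k].ravel()] = True
    return infected


def run_ensemble(
    params: DynamicsParams,
    net: MultiplexNetwork,
    mask: MediaMask,
    n_runs: int = 1000,
    t_max: int = 200,
    tail: int = 50,
    seed: int = 0,
    chunk_size: int | None = None,
) -> SimulationResult:
    """Average the stochastic process over independent runs.

    Runs are processed in chunks; chunk c uses its own generator seeded from
    (seed, c), so results are deterministic given (seed, n_runs, chunk_size).
    Stationary densities are the per-run average over the final ``tail``
    steps, then averaged over runs; the SE is across runs.
    """
    if t_max <= tail:
        raise ValueError("t_max must exceed tail")
    n = net.n_nodes
    k = int(round(params.rho0 * n))
    adj_info = net.info_layer.adjacency()
    adj_epi = net.epi_layer.adjacency()
    if chunk_size is None:
        chunk_size = max(1, min(n_runs, 20_000_000 // max(n, 1)))

    dens_i = np.empty((n_runs, t_max + 1))
    dens_a = np.empty((n_runs, t_max + 1))
    done = 0
    chunk_index = 0
    while done < n_runs:
        r = min(chunk_size, n_runs - done)
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), chunk_index]))
        infected = _init_batch(n, k, r, rng)
        aware = np.zeros((r, n), dtype=bool)
        dens_i[done : done + r, 0] = infected.mean(axis=1)
        dens_a[done : done + r, 0] = 0.0
        targeted = np.broadcast_to(mask.targeted, (r, n))
        for t in range(1, t_max + 1):
            aware, infected = _step_batch(
                aware, infected, params, adj_info, adj_epi, targeted, mask.m, rng
            )
            dens_i[done : done + r, t] = infected.mean(axis=1)
            dens_a[done : done + r, t] = aware.mean(axis=1)
        done += r
        chunk_index += 1

    tail_i = dens_i[:, -tail:].mean(axis=1)
    tail_a = dens_a[:, -tail:].mean(axis=1)
    sqrt_r = np.sqrt(n_runs)
    return SimulationResult(
        rho_i_t=dens_i.mean(axis=0),
        rho_a_t=dens_a.mean(axis=0),
        rho_i_t_se=dens_i.std(axis=0, ddof=1) / sqrt_r if n_runs > 1 else np.zeros(t_max + 1),
        rho_i=float(tail_i.mean()),
        rho_a=float(tail_a.mean()),
        rho_i_se=float(tail_i.std(ddof=1) / sqrt_r) if n_runs > 1 else 0.0,
        rho_a_se=float(tail_a.std(ddof=1) / sqrt_r) if n_runs > 1 else 0.0,
        n_steps=t_max,
        transient=t_max - tail,
        tail=tail,
        n_runs=n_runs,
        seed=seed,
    )


def simulate_sis(
    epi: LayerGraph,
    beta: float,
    mu: float,
    rho0: float,
    n_runs: int,
    t_max: int,
    seed: int = 0,
    chunk_size: int | None = None,
) -> np.ndarray:
    """Plain single-layer SIS reference simulator.

    Returns per-run infected-density trajectories, shape (n_runs, t_max+1).
    Draws the same five uniform arrays per step as the coupled kernel (using
    only the infection and recovery ones), so with the same seed and
    chunking its trajectories coincide exactly with the coupled process when
    γ = 1 and κ = 0, where awareness cannot influence infection.
    """
    n = epi.n_nodes
    k = int(round(rho0 * n))
    adj = epi.adjacency()
    if chunk_size is None:
        chunk_size = max(1, min(n_runs, 20_000_000 // max(n, 1)))
    dens = np.empty((n_runs, t_max + 1))
    done = 0
    chunk_index = 0
    while done < n_runs:
        r = min(chunk_size, n_runs - done)
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), chunk_index]))
        infected = _init_batch(n, k, r, rng)
        dens[done : done + r, 0] = infected.mean(axis=1)
        for t in range(1, t_max + 1):
            rng.random((r, n))                # phase I draw (unused)
            rng.random((r, n))                # phase II draw (unused)
            u_inf = rng.random((r, n))
            u_rec = rng.random((r, n))
            rng.random((r, n))                # phase IV draw (unused)
            n_inf_nb = infected.astype(np.float64) @ adj
            p_inf = 1.0 - (1.0 - beta) ** n_inf_nb
            newly = ~infected & (u_inf < p_inf)
            recovered = infected & (u_rec < mu)
            infected = (infected & ~recovered) | newly
            dens[done : done + r, t] = infected.mean(axis=1)
        done += r
        chunk_index += 1
    return dens


# ---------------------------------------------------------------------------
# exact small-system chain
# ---------------------------------------------------------------------------

def exact_small_chain(
    params: DynamicsParams,
    net: MultiplexNetwork,
    mask: MediaMask,
    t: int,
) -> np.ndarray:
    """Exact expected infected density ρI(0..t) over the 4^N joint chain.

    Propagates the full joint distribution over all 4^N configurations with
    the same four-phase kernel as :func:`mc_step`; the initial distribution
    is uniform over the C(N, k) ways of placing k = round(rho0·N) UI
    individuals among otherwise-US unaware nodes, matching
    :func:`init_states`.  Only feasible for N ≤ 8.
    """
    n = net.n_nodes
    if n > 8:
        raise ValueError("exact chain limited to 8 nodes (4^N states)")
    n_states = 4**n
    a_info = net.info_layer.adjacency().toarray()
    a_epi = net.epi_layer.adjacency().toarray()
    m_i = mask.m_i

    # digit i of a configuration: 0=US, 1=UI, 2=AS, 3=AI; node 0 most significant
    digits = np.array(np.unravel_index(np.arange(n_states), (4,) * n)).T  # (S, n)
    aware = digits >= 2
    infected = digits % 2 == 1
    infected_frac = infected.mean(axis=1)

    # per-config, per-node probability of being aware after phases I-II
    n_aware_nb = aware @ a_info.T
    r = (1.0 - params.lambda_) ** n_aware_nb
    p_aware2 = np.where(aware, 1.0 - params.delta * (1.0 - m_i), 1.0 - r * (1.0 - m_i))

    # per-config, per-node infection probability after phase III, by own awareness
    n_inf_nb = infected @ a_epi.T
    p_inf_u = np.where(infected, 1.0 - params.mu, 1.0 - (1.0 - params.beta_u) ** n_inf_nb)
    p_inf_a = np.where(infected, 1.0 - params.mu, 1.0 - (1.0 - params.beta_a) ** n_inf_nb)

    # per-config per-node next-state distribution over (US, UI, AS, AI)
    kern = np.empty((n_states, n, 4))
    kern[:, :, 0] = (1.0 - p_aware2) * (1.0 - p_inf_u)
    kern[:, :, 1] = (1.0 - p_aware2) * p_inf_u * (1.0 - params.kappa)
    kern[:, :, 2] = p_aware2 * (1.0 - p_inf_a)
    kern[:, :, 3] = p_aware2 * p_inf_a + (1.0 - p_aware2) * p_inf_u * params.kappa

    # initial distribution: uniform over size-k infected subsets, all unaware
    k = int(round(params.rho0 * n))
    p = np.zeros(n_states)
    weights = 4 ** np.arange(n - 1, -1, -1)
    for subset in combinations(range(n), k):
        idx = sum(weights[i] for i in subset)  # digit 1 (UI) at subset, 0 elsewhere
        p[idx] += 1.0
    p /= p.sum()

    rho = np.empty(t + 1)
    rho[0] = float(p @ infected_frac)
    for step in range(1, t + 1):
        p_next = np.zeros(n_states)
        for c in np.nonzero(p > 1e-18)[0]:
            v = kern[c, 0]
            for i in range(1, n):
                v = np.kron(v, kern[c, i])
            p_next += p[c] * v
        p = p_next
        rho[step] = float(p @ infected_frac)
    return rho
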