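"""Independent reference implementations used as test oracles.

Everything here is deliberately written with plain Python loops and explicit
path enumeration, sharing no code with the package's vectorised kernels.
"""

from __future__ import annotations

import numpy as np


def neighbor_lists(n, edges):
    nbrs = [[] for _ in range(n)]
    for u, v in edges:
        nbrs[u].append(v)
        nbrs[v].append(u)
    return nbrs


def factors_elementwise(p_a, p_i, lambda_, beta_u, beta_a, delta, m_i, info_edges, epi_edges):
    """Escape products and awareness factors, one node at a time."""
    n = len(p_a)
    info_nbrs = neighbor_lists(n, info_edges)
    epi_nbrs = neighbor_lists(n, epi_edges)
    r = np.ones(n)
    q_u = np.ones(n)
    q_a = np.ones(n)
    for i in range(n):
        for j in info_nbrs[i]:
            r[i] *= 1.0 - p_a[j] * lambda_
        for j in epi_nbrs[i]:
            q_u[i] *= 1.0 - p_i[j] * beta_u
            q_a[i] *= 1.0 - p_i[j] * beta_a
    f_uu = np.array([r[i] * (1.0 - m_i[i]) for i in range(n)])
    f_au = np.array([delta * (1.0 - m_i[i]) for i in range(n)])
    return r, q_u, q_a, f_uu, 1.0 - f_uu, f_au, 1.0 - f_au


def tree_step_node(p4, r, q_u, q_a, m_i, delta, mu, kappa):
    """Next 4-state distribution of one node by transition-tree enumeration.

    ``p4`` = (pUS, pUI, pAS, pAI).  Paths: awareness through the UAU phase
    then media, infection through the SIS phase (probability depends on
    awareness after media), then self-awakening of unaware infected.
    """
    out = [0.0, 0.0, 0.0, 0.0]  # US, UI, AS, AI
    for start, p_start in enumerate(p4):
        if p_start == 0.0:
            continue
        aware0 = start >= 2
        infected0 = start % 2 == 1
        # awareness after phases I-II: enumerate (UAU outcome, media outcome)
        if aware0:
            branches = [(True, 1.0 - delta), (False, delta * (1.0 - m_i)),
                        (True, delta * m_i)]
        else:
            branches = [(False, r * (1.0 - m_i)), (True, r * m_i), (True, 1.0 - r)]
        for aware2, p_aw in branches:
            if p_aw == 0.0:
                continue
            # SIS phase
            if infected0:
                inf_branches = [(False, mu), (True, 1.0 - mu)]
            else:
                q = q_a if aware2 else q_u
                inf_branches = [(False, q), (True, 1.0 - q)]
            for infected3, p_inf in inf_branches:
                if p_inf == 0.0:
                    continue
                # self-awakening
                if infected3 and not aware2:
                    out[1] += p_start * p_aw * p_inf * (1.0 - kappa)
                    out[3] += p_start * p_aw * p_inf * kappa
                else:
                    idx = 2 * aware2 + infected3
                    out[idx] += p_start * p_aw * p_inf
    return np.array(out)


def sis_mmca_stationary(n, edges, beta, mu, rho0=0.2, tol=1e-12, max_iter=200_000):
    """Independent single-layer SIS microscopic Markov chain fixed point."""
    nbrs = neighbor_lists(n, edges)
    p = np.full(n, float(rho0))
    for _ in range(max_iter):
        q = np.ones(n)
        for i in range(n):
            for j in nbrs[i]:
                q[i] *= 1.0 - beta * p[j]
        p_new = (1.0 - p) * (1.0 - q) + p * (1.0 - mu)
        if np.abs(p_new - p).max() < tol:
            p = p_new
            break
        p = p_new
    return p
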