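# mediaplex

Coupled information–epidemic spreading on two-layer multiplex networks with a
**selective mass-media broadcaster**.

During an outbreak, information about the disease spreads through virtual
contacts while the disease itself spreads through physical contacts, and the
two processes feed back on each other: informed (aware) individuals protect
themselves and are harder to infect. Mass media accelerate the information
side — but broadcasting to an entire population is expensive, so a realistic
broadcaster targets only a fraction of the population, and the natural choice
is the best-connected individuals. `mediaplex` is a toolkit for studying this
setting: how much does targeted broadcasting suppress the epidemic, how does
it shift the epidemic threshold, and how does the answer depend on whether
the social hubs of the information network are also hubs of the
physical-contact network?

It is aimed at researchers in network epidemiology and spreading dynamics who
want a reproducible implementation of the model, its mean-field theory, and
its stochastic simulation in one place.

## The model

Two undirected graph layers share one population of N individuals:

* **Information layer** (adjacency A): Unaware–Aware–Unaware (UAU) dynamics.
  An unaware node becomes aware via each aware neighbour with probability λ
  per step; an aware node forgets with probability δ.
* **Epidemic layer** (adjacency B): Susceptible–Infected–Susceptible (SIS)
  dynamics. A susceptible node is infected via each infected neighbour with
  probability β^U if unaware, β^A = γ·β^U if aware (γ ∈ [0,1] is the
  infection attenuation; γ = 0 means aware nodes are immune); an infected
  node recovers with probability μ.
* **Selective mass media**: a global broadcaster reaches only the top-η
  fraction of individuals ranked by information-layer degree, making each
  targeted unaware individual aware with probability m per step.
* **Self-awakening**: an infected, still-unaware individual notices its own
  infection with probability κ (κ = 0 by default).

Each joint node state is one of {US, UI, AS, AI}. A time step applies four
phases in order: (I) UAU diffusion, (II) media broadcast, (III) SIS
transmission using each node's awareness after phase II, (IV) self-awakening.

**Microscopic Markov chain (MMCA).** Per node i the escape probabilities

    r_i  = Π_j (1 − λ A_ji p_j^A)          (not informed)
    q_i^U = Π_j (1 − β^U B_ji p_j^I),  q_i^A = Π_j (1 − β^A B_ji p_j^I)

combine with the media probability m_i into awareness factors
f_i^{U→U} = r_i(1−m_i), f_i^{A→U} = δ(1−m_i) (and complements), which drive a
synchronous update of the four per-node state probabilities. Iterating to a
fixed point gives the stationary infected density ρ_I = N⁻¹ Σ_i p_i^I and
aware density ρ_A.

**Epidemic threshold.** Linearising around the disease-free state, infection
invades once β^U exceeds

    β_c^U = μ / Λ_max(H),   H = diag(p^U + γ p^A) · B,

where (p^U, p^A) is the stationary awareness profile of the disease-free
information dynamics and Λ_max is the spectral radius (real, by
Perron–Frobenius). The package computes this and, independently, locates the
onset by scanning/bisecting the stationary MMCA density.

**Interlayer degree correlation r_s.** Layers are generated as scale-free
graphs (configuration-model realisation of a power-law degree sequence with
an exact edge budget) and coupled so that an individual's degrees in the two
layers are rank-matched (r_s = +1), rank-anti-matched (r_s = −1), or paired
at random (r_s = 0).

## Worked example

```python
from mediaplex import *

info = generate_layer(1000, 2.5, 10, seed=0)   # information layer, <k> = 10
epi = generate_layer(1000, 2.5, 5, seed=1)     # epidemic layer, <k> = 5
net = couple_layers(info, epi, "positive")     # hubs aligned across layers
print(f"info edges: {info.n_edges}, epi edges: {epi.n_edges}, "
      f"interlayer rank correlation: {interlayer_rank_correlation(net):.3f}")

params = DynamicsParams(beta_u=0.4, gamma=0.4, mu=0.5, lambda_=0.15,
                        delta=0.6, m=0.5, eta=0.5)
mask = media_mask(net, params.eta, params.m)   # broadcast to top 50% by info degree

res = iterate_to_stationary(MMCAState.homogeneous(net.n_nodes, params.rho0),
                            params, net, mask)
print(f"MMCA stationary rho_I = {res.rho_i:.4f}, rho_A = {res.rho_a:.4f} "
      f"({res.iterations} iterations)")

sim = run_ensemble(params, net, mask, n_runs=200, t_max=200, tail=50, seed=42)
print(f"Monte Carlo rho_I = {sim.rho_i:.4f} +/- {sim.rho_i_se:.4f} (200 runs)")

th = epidemic_threshold(params, net, mask)
print(f"epidemic threshold beta_c = {th.beta_c:.4f} (Lambda_max = {th.lambda_max:.2f})")
```

Output:

```
info edges: 5000, epi edges: 2500, interlayer rank correlation: 0.973
MMCA stationary rho_I = 0.4167, rho_A = 0.5655 (88 iterations)
Monte Carlo rho_I = 0.4143 +/- 0.0003 (200 runs)
epidemic threshold beta_c = 0.0464 (Lambda_max = 10.78)
```

At β^U = 0.4 the mean-field theory and the stochastic ensemble agree to
~0.002 on the stationary prevalence; broadcasting to the top half of the
information layer raises the invasion threshold from 0.0257 (η = 0, same
network) to 0.0464.

The same experiments are available from the shell via the `mediaplex` CLI
(`generate`, `sweep-beta`, `threshold-curve`, `fragment-curve`, `mmca`,
`simulate`), all writing CSVs with provenance headers; see
`mediaplex --help`.

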