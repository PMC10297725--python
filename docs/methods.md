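# Methods

## Model

A population of N individuals lives on two undirected simple graphs: an
information layer (adjacency A, UAU awareness dynamics) and an epidemic layer
(adjacency B, SIS disease dynamics). A global media node broadcasts to the
top-η fraction of individuals ranked by information-layer degree. Discrete
time, synchronous updates, four phases per step, in this order:

1. **UAU diffusion** — unaware i stays uninformed with probability
   r_i = Π_j (1 − λ A_ji p_j^A); aware i forgets with probability δ.
2. **Media broadcast** — a targeted, still-unaware i becomes aware with
   probability m.
3. **SIS transmission** — susceptible i escapes infection with probability
   q_i^U = Π_j (1 − β^U B_ji p_j^I) if unaware *after phase II*, q_i^A with
   β^A = γβ^U if aware; infected i recovers with probability μ.
4. **Self-awakening** — an individual infected at the end of phase III and
   still unaware becomes aware with probability κ.

Assumptions: both layers are static, unweighted and undirected; the media
node has no in-links (it is never influenced); infection affects awareness
only through phase IV; awareness affects infection only through the
attenuated β^A. With γ = 1 and κ = 0 both couplings vanish and the infection
marginal is exactly a single-layer SIS process on B — the package asserts
this limit against an independently coded single-layer SIS MMCA and against
matched-seed stochastic trajectories.

The MMCA is the standard per-node mean-field closure: neighbours are treated
as independent, giving a 4N-dimensional synchronous map over the per-node
state probabilities (US, UI, AS, AI). Probability conservation per node is
algebraically exact under the update and is tracked (not re-normalised) at
every sweep; the suite requires it to hold to 1e−12 at N = 1000.

## Parameters

| name | meaning | default | rationale |
|------|---------|---------|-----------|
| β^U | infection probability, unaware | (swept) | principal control parameter |
| γ | attenuation, β^A = γβ^U | 0.4 | mid-range coupling; 0 = immunity of aware nodes |
| μ | recovery probability | 0.5 | reference default |
| λ | awareness transmission | 0.15 | reference default |
| δ | forgetting probability | 0.6 | reference default |
| m | media success probability | 0.5 | moderate broadcast efficacy; no canonical value exists, chosen once and held fixed |
| η | broadcast proportion | 0 | swept in experiments |
| κ | self-awakening | 0 | default off; fully implemented and tested |
| ρ0 | initial infected fraction | 0.2 | reference default |

Network defaults: N = 1000, degree exponent 2.5, mean degree 10
(information) and 5 (epidemic), i.e. 5000 and 2500 edges exactly.

## Network generation and coupling

The generator samples a degree sequence by flooring continuous Pareto
variates with exponent `exponent` and minimum
x_min = (⟨k⟩ + ½)(α−2)/(α−1), so the floored mean matches the target; the
sequence is realised with a configuration model, collapsed to a simple graph
(self-loops and multi-edges dropped), and then uniformly random edges are
added or removed to hit the exact budget round(N·⟨k⟩/2). This honours the
three quantities the design fixes — node count, edge count, tail exponent —
with the simplest construction; the suite verifies a maximum-likelihood
(Hill) tail fit of a 10 000-node layer lands in [2.2, 2.8].

Interlayer coupling identifies the k-th largest-degree information node with
the k-th largest (positive), k-th smallest (negative), or a random
(seeded) epidemic node. Degree ties are broken by ascending node ID, making
couplings and media masks fully deterministic; at N = 1000 the tie-break
choice is immaterial. Because power-law degree vectors contain heavy ties,
the realised Spearman correlation of rank-matched layers is ≈ ±0.97 rather
than exactly ±1; random coupling gives |r_s| < 0.1.

**Media eligibility.** The targeting rule is R_i ≤ ⌈ηN⌉ on descending
information-degree ranks, so η = 0 targets nobody and η = 1 targets
everybody. A strict-inequality variant (η > R_i/N, under which η = 1
excludes the last rank) is kept behind `media_mask(..., strict=True)` for
comparison. ⌈ηN⌉ is computed after rounding ηN to 9 decimals to keep float
representation fuzz (0.35·1000 = 350.00000000000006) from off-by-one
targeting.

## Numerical choices

* **Escape products** r, q^U, q^A are computed exactly per node with a
  segmented product over the CSR adjacency (`np.multiply.reduceat`) — no
  log-space approximation; underflow of an exact product returns 0, the
  correct limit.
* **Fixed point**: synchronous iteration from the homogeneous start
  (p^UI = ρ0, p^US = 1−ρ0, nobody aware), stopping when the max-abs per-node
  change over all four probabilities falls below 1e−9, cap 10⁴ sweeps.
  Non-convergence is reported in the result, never raised. The homogeneous
  all-unaware start makes the η = 0 "no information ever" property exact.
  Supercritical fixed points are initialisation-independent (checked from
  ρ0 = 0.2 and 0.9 to 1e−6).
* **Epidemic-free awareness** is obtained by iterating the full MMCA with
  β^U = 0 (infection drains, awareness marginal closes on itself); an
  independent direct iteration of the awareness-only fixed-point equations
  is kept and the two are asserted equal in tests.
* **Threshold**: H = diag(w)·B with w = p^U + γp^A shares its nonzero
  spectrum with the symmetric diag(√w)·B·diag(√w), so Λ_max comes from a
  symmetric eigensolver (dense up to N = 2000, Lanczos above). w ≡ 0 (e.g.
  γ = 0 with full, unforgetting awareness) is flagged degenerate with
  β_c = +∞.
* **Onset scan**: the smallest β whose stationary MMCA density exceeds
  1e−4, refined by bisection to below 1e−3 (5e−4 in the suite); a grid that
  is entirely sub- or supercritical raises an out-of-range error. Spectral
  and scanned thresholds agree to ≤ 1e−3 across five parameter sets at
  N = 300 in the suite.
* **Monte Carlo**: each step draws exactly five uniform (runs × nodes)
  arrays in fixed order, regardless of parameters, so random streams stay
  aligned across parameterisations; the single-layer SIS reference simulator
  draws the same layout, enabling matched-seed trajectory identity in the
  γ = 1, κ = 0 limit. Runs are vectorised in chunks; chunk c is seeded from
  (master_seed, c), so ensembles are deterministic given (seed, n_runs,
  chunk_size). Stationary densities average the final 50 of 200 steps per
  run, then across runs (standard errors across runs). Production default is
  1000 runs; the suite uses 200–300 for speed and 100 000 for the
  small-fixture unbiasedness checks.
* **Exact small-system chain**: for N ≤ 8 the full joint distribution over
  4^N configurations is propagated with the same four-phase kernel, which
  factorises per node given the current configuration; the initial
  distribution is uniform over the C(N, k) placements of k = round(ρ0·N)
  infected individuals. This is the unbiasedness oracle for the simulator
  (agreement within 3 standard errors at 10⁵ runs on all fixtures).

## Open design points, resolved

* **Phase order of κ**: self-awakening is applied after the SIS phase, as
  phase IV of the step; with κ = 0 (all default experiments) any alternative
  placement coincides.
* **r_s as modes, not targets**: only the three regimes {−1, 0, +1} are
  implemented (rank match / anti-match / random); continuous interpolation
  of interlayer correlation is out of scope.
* **Awareness route for the threshold**: the epidemic-free profile comes
  from the full solver rather than the reduced equations, with the reduced
  route retained as a cross-check.

## A note on the interlayer-correlation orderings

The suite measures, over seeded ensembles: the fragment count N_c of the
epidemic layer after deleting all edges of the targeted (top-η information
degree) individuals, the epidemic threshold β_c, and the stationary
prevalence ρ_I, under each coupling mode. In these computations **positive**
coupling — information hubs sitting on epidemic hubs — consistently produces
the largest N_c, the largest β_c, and the smallest ρ_I (e.g. at η = 0.3,
N = 1000, 20 seeds: N_c ≈ 650 positive vs ≈ 300 negative). This is coherent
with classical targeted-immunisation results: media-protected information
hubs are epidemic hubs precisely under positive coupling, and unplugging
hubs fragments a scale-free network fastest. Two acceptance checks that
encode the opposite ordering are therefore expected to fail and are left
failing rather than adjusted; all three measured quantities reverse
*together*, which is the signature of a consistent labelling of the coupling
modes.

## What the generator emulates — and what it does not

Synthetic layers are independent scale-free graphs with prescribed exponent
and edge budget, coupled only through the degree-rank identification. Real
contact networks additionally exhibit clustering, degree–degree
assortativity within layers, community structure, edge overlap between
layers, and temporal turnover — none of which are modelled. Conclusions
validated here (mean-field accuracy, threshold formulas, suppression
monotonicity in η) are statements about this ensemble; on real networks the
MMCA's neighbour-independence closure is known to degrade with clustering
and the quantitative thresholds will shift.

## Known limitations

* The MMCA overestimates prevalence near the threshold (worst observed gap
  ≈ 0.04 against 200-run ensembles at N = 500); the 0.05 agreement band in
  the suite reflects that.
* The stochastic process on a finite network has an absorbing state; the
  200-step/50-tail protocol measures the quasi-stationary plateau and is
  unreliable extremely close to the threshold, where extinction within the
  window is common.
* `exact_small_chain` scales as 4^N per step and is capped at N = 8.
* Layers must be undirected and unweighted; more than two layers, weighted
  broadcasts, and degree-preserving rewiring to intermediate r_s values are
  out of scope.
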