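# Methods

## Model

`nncrn` samples ensembles of simple undirected networks whose
degree–degree correlations are controlled up to a chosen shortest-path
distance and maximally random beyond it.  The observable is the Pearson
correlation of degrees over node pairs at exact distance *l*:

r_l = ( ⟨k k′⟩_l − ⟨k⟩_l² ) / ( ⟨k²⟩_l − ⟨k⟩_l² ),

where ⟨·⟩_l averages over all ordered pairs (i, j) with dist(i, j) = l.
For l = 1 this is the classical assortativity coefficient; for l = 2 it
measures second-neighbor (long-range) correlation.  Two conventions are
fixed deliberately:

* **Pairs, not walks.** Each unordered pair at distance l contributes
  exactly once (twice as ordered pairs), no matter how many distinct
  shortest paths realize the distance.  A pair that is adjacent is at
  distance 1 and never counts toward l = 2.
* **Finite distances only.** Pairs in different components have no
  distance and are excluded; r_l is a statistic of the connected
  structure that exists, not of a completed metric.

### Sampling ensembles

Both chains are Metropolis–Hastings walks over degree-preserving
double-edge swaps, (u1,u2),(v1,v2) → (u1,v2),(v1,u2), with a lazy step
(probability 1/2, for aperiodicity), structural rejection of proposals
creating loops or parallel edges, and acceptance

P(accept) = min(1, exp(J · (r_next − r_prev))).

* **Distance-1 chain**: both ordered edges drawn uniformly.  Hard
  constraint: the degree sequence.  Equilibrium: Π(G) ∝ exp(J·r1(G)).
* **Distance-2 chain**: the second edge is drawn uniformly among ordered
  edges whose *source degree equals the first edge's source degree*.
  Swaps then exchange partners between equal-degree sources, so every
  adjacent degree pair count — the joint profile P(k,k′|l=1), and hence
  r1 — is an exact integer invariant.  Equilibrium: Π(G) ∝ exp(J·r2(G))
  over the profile-constrained class.

The degree-matched draw is implemented without any mutable index:
because swaps never change a degree, a node of degree d always carries
exactly d ordered edges, so drawing a uniform node among those of degree
d and then a uniform neighbor is exactly uniform over the qualifying
ordered edges (including, possibly, the first edge itself — which then
falls to the degenerate-proposal rejection).

**Sign convention.** Positive J drives the targeted r positive.  The
opposite convention (positive J favoring negative r, i.e. acceptance
min(1, exp(−J·Δr))) is available via `paper_sign=True` / `--paper-sign`;
the two are related by J → −J.

**Degenerate proposals** (the same unordered edge drawn twice, or a
replacement identical to the current edge set) are automatic rejections
that still consume a time step, keeping step accounting uniform and
reversibility intact.

**Extrinsic baseline r2_ext.** Nearest-neighbor correlations propagate:
|r1| large pushes r2 positive even with no intrinsic two-hop structure
(like degrees chain at even distances under assortative mixing, and
alternate under disassortative mixing — both raise r2).  The baseline is
estimated by running the distance-2 chain at J = 0 and averaging r2 over
spaced samples after a burn-in (default: the second half of the budget).
A network is intrinsically correlated at l = 2 when its r2 departs from
this baseline.

### Incremental statistics

r_l is maintained through exact integer sufficient statistics over
ordered pairs at distance l: the count n, S1 = Σk, S2 = Σk², and
S11 = Σkk′.  For l = 1 a swap changes only S11 (degrees are preserved
and the four endpoints merely exchange partners).  For l = 2 the four
rewired edges all join members of the swap quartet {u1,u2,v1,v2}, so the
adjacency — and therefore the common-neighbor set — of any pair avoiding
the quartet is untouched; only pairs with an endpoint in the quartet can
change distance-2 status.  The update therefore re-enumerates the
distance-2 partner sets of the four endpoints before and after the swap,
at cost O(⟨k²⟩²/⟨k⟩²) per proposal in expectation.  Because the sums are
integers, incremental maintenance cannot drift; the periodic full
recomputation (`full_recompute_interval`, default every 10⁵ accepted
moves) is a corruption *check* — any disagreement raises an error rather
than being silently patched.

The production chains are numba-compiled kernels over CSR adjacency
arrays (~1–2 µs per distance-2 proposal at ⟨k⟩ = 5).  An independent
pure-python path (`mh_step`, `delta_r_for_swap`) implements the same
chain step-by-step; the test suite cross-checks the two against full
from-scratch recomputation.

## Robustness analysis

Networks are dismantled by random edge failure, random node failure, or
a targeted attack removing nodes by decreasing degree.  The Newman–Ziff
construction adds elements in the reverse order under incremental
union-find, yielding the largest-component size N_LCC at every
occupation number n in near-linear time.

* **Grid.** All curves and summary measures live on the microcanonical
  grid (exact n, p = n/M or n/N).  The canonical fixed-probability
  ensemble differs by O(1/√M); the microcanonical grid is used because
  it is what the incremental construction measures directly.
* **Targeted order** is static (initial degrees), with ties broken
  uniformly at random per run so ensembles average over tie orders.  An
  adaptive attack recomputing degrees after each removal is a different
  (and not Newman–Ziff-compatible) protocol, out of scope.
* **f_x%** (default x = 1%): p_x% is the largest grid p with
  ⟨N_LCC⟩ < x·N, and f_x% = 1 − p_x%.  If the condition holds nowhere
  (possible under edge removal on tiny graphs, where a lone node keeps
  ⟨N_LCC⟩ ≥ 1) the convention is p_x% = 0, f_x% = 1.
* **R** is the uniform average of S(n) = ⟨N_LCC(n)⟩/N over the grid,
  which equals ∫₀¹E[S(p)]dp exactly under binomial occupancy.  S is
  normalized by the full node count N in all modes.
* **Susceptibility** χ = (⟨N_LCC²⟩ − ⟨N_LCC⟩²)/⟨N_LCC⟩ is reported as 0
  where ⟨N_LCC⟩ = 0 (keeps arrays dense; such points cannot be peaks).
  Peak extraction takes all local maxima, optionally after a centered
  moving average (`smooth_window`, default 1 = none) and above a
  prominence floor expressed as a fraction of max χ
  (`min_prominence_frac`, default 0 = all maxima).  Finite ensembles put
  shot noise on χ; the prominence floor is how physically meaningful
  transitions are separated from that noise.  Core–periphery networks
  genuinely show two prominent peaks (the low-p core transition and the
  higher-p periphery transition); f* = 1 − p* is attached to each.
* **Efficiency** E is the mean of 1/dist over *connected* ordered pairs
  — disconnected pairs are excluded, not counted as 0; `all_pairs=True`
  restores the common global-efficiency convention.  E(p) under removal
  is direct Monte-Carlo (it has no union-find incremental form): at each
  retained fraction p, remove, then measure among survivors; p denotes
  the retained fraction uniformly across this package.  The diameter
  l_max is the largest finite distance scanned.
* **Molloy–Reed threshold** p_c = ⟨k⟩/(⟨k²⟩ − ⟨k⟩), from analytic pmf
  moments or sample moments; undefined (an error) when ⟨k²⟩ ≤ ⟨k⟩.

## Initial networks (synthetic data)

* **Erdős–Rényi**: G(N, M) with M = round(N⟨k⟩/2) distinct uniform
  edges.  Fixing M (rather than an independent edge probability) pins
  ⟨k⟩ exactly, which is the quantity the chains condition on; degrees
  are asymptotically Poisson(⟨k⟩).  Default study condition: N = 20000,
  ⟨k⟩ = 5.0 (reduced-scale profiles below).
* **Power-law configuration model**: degrees i.i.d. from
  P(k) ∝ k^(−γ) on k ∈ [k_min, k_c] by inverse CDF (γ = 2.5, k_min = 2
  by default), one uniformly chosen degree redrawn until the sum is
  even, uniform stub matching, then self-loops and parallel edges are
  removed by degree-preserving double-edge swaps against uniformly
  chosen edges — the realized degree sequence equals the drawn one
  exactly.  The cutoff defaults to the structural cutoff k_c = ⌊√N⌋, the
  largest degree at which a simple uncorrelated graph avoids
  cutoff-induced correlations; it is also the choice under which the
  distribution's Molloy–Reed threshold is 0.07 at N = 20000.
* **Fixtures**: deterministic paths, stars, cycles, cliques for tests
  and worked examples.

These generators emulate the two canonical degree-distribution classes
(homogeneous and heavy-tailed) with *no* structure beyond the degree
sequence: no clustering, no communities, no spatial embedding, no
degree correlations beyond those the chains impose.  Results on them
isolate the effect of r1 and r2; they do not establish how those effects
interact with the additional structure of real networks.

## Problem sizes and reproducibility

Chains equilibrate well within 10⁴·M proposals (the default budget); at
J = 0 or reduced N, far less suffices.  The CI test profile uses
N = 300–2000, 50–200·M proposals, 5–12 realizations and 50–100
percolation runs per ensemble — sizes chosen so the full suite runs in
minutes while every directional claim (r1 ordered with J1, r2_ext shift,
f1% rising and R falling with r2, the double-peak susceptibility of
assortative power-law networks) is resolved by several standard errors.
The shipped `configs/reduced_scale.yaml` and `configs/paper_scale.yaml`
hold the laptop-scale and full study profiles.

All randomness flows from explicit seeds: generators and chains take
numpy `Generator`s or integer seeds, and the experiment grid derives
per-(cell, realization, stage) seeds from its master seed through
`SeedSequence`, so grids are exactly reproducible and every output row
logs its seed.

## Known limitations

* No chain is provided for l ≥ 3: no irreducible degree-profile-
  preserving pair move set is known beyond l = 2, and two-hop update
  locality (the basis of the incremental cost) is lost.
* The equilibrium normalizing constants of the exponential ensembles are
  never evaluated — Metropolis sampling makes them implicit.
* r2 ranges are constrained by the degree distribution and r1; extreme
  couplings saturate at distribution-dependent bounds (at reduced N the
  attainable |r1|, |r2| for power-law networks differ from full scale).
* Targeted attack is static-order; adaptive recalculation is out of
  scope.  Cascading failures and local-information attacks are likewise
  out of scope.
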