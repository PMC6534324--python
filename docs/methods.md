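# Methods

## Model summary and assumptions

A population consists of independently growing groups of two cell
phenotypes, A and B.  Growth is density independent, so in the long run
the population grows exponentially at a rate λ set by the life cycle
(the integer partition of the critical size M into offspring sizes), the
2×2 game, the phenotype-switching probability m, the selection strength
w, and the division-time profile T_n.  Assumptions baked into the
implementation:

* groups are well mixed (no geometry); payoff averages exclude
  self-interaction, and solitary cells play no game;
* selection is weak: payoffs enter the divider choice and the waiting
  time only through factors 1 + O(w);
* fragmentation is instantaneous, costless, and assigns cells to
  offspring groups uniformly at random (multivariate hypergeometric);
* no cell death and no interactions between groups.

There are exactly 37 life cycles with M ≤ 7, the default search space.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| m | per-daughter switching probability | required | boundary values 0, 1 accepted with a reducibility warning |
| w | selection strength (dimensionless) | 1e-3 (CLI) | guard: w·max\|payoff\| < 0.5, overridable |
| T_n | division-time component at size n (time units) | ln((n+1)/n) | "neutral": every life cycle has λ = 1 at w = 0 |
| max_M | largest critical size scanned | 7 | trajectory enumeration guarded at M ≤ 7; the DP scales further |

## Growth-rate computation

Q(λ) is built by a forward dynamic program over compositions; its
entries are sums of positive terms e^{−λT}, so ρ(Q(λ)) is strictly
decreasing and the growth rate is the unique root of ρ(Q(λ)) = 1.  The
root objective uses the spectral radius rather than det(Q − I): same
root, but monotone and sign-stable (the determinant alternates sign with
the matrix size).  Brent's method on an initial bracket (0.5, 1.5)
(expanded geometrically to [1e-3, 16] before giving up) with
xtol = 1e-12; the residual |ρ − 1| is reported.  The DP is validated
entrywise (1e-12) against literal trajectory enumeration for all life
cycles with M ≤ 5, and trajectory semantics are pinned by closed forms
(the 1+1 projection matrix, 20 composition paths for 1+1+1).

The weak-selection derivative λ′ = dλ/dw at w = 0 uses Richardson-
extrapolated one-sided differences with steps w₁ = 1e-3, w₂ = 5e-4
(λ(0) = 1 exactly under the neutral profile, so no third solve is
needed).  The extrapolation cancels the λ″ term, leaving ~1e-7
truncation on top of ~1e-9 solver noise.  A second, fully independent
route — an exact symbolic linearization of the secular condition in
rational arithmetic (tests/symbolic_oracle.py) — agrees with the finite
differences to the truncation level and supplies frozen reference
values.

## Optimality scans

Life cycles are ranked by λ′.  Ties are reported, never broken: the
co-optimal set collects every life cycle within a relative tolerance of
the maximum, default 1e-6.  The tolerance sits above the ~1e-7
finite-difference truncation (so genuinely degenerate games — see below
— are reported as ties) and below real gaps between distinct optima.

Because the payoffs always enter multiplied by w, λ′ is linear in
(a, b, c, d), and the A↔B relabelling symmetry gives a and d (and b and
c) equal weights.  Phase maps over (ϕ, m) at ψ = ±1 therefore evaluate,
per life cycle and m, only the two basis responses F = λ′(a=d=1/2,
b=c=0) and G = λ′(a=d=0, b=c=1/2) and form λ′ = ±F + ϕG; a direct
per-cell route through the canonical representative matrix
(a = d = ψ/2, b = c = ϕ·|ψ|/2) is kept for cross-validation and the two
agree in the tests.

Default grids: ϕ from −8 to 3 in steps of 0.05, refined to 0.01 on
[0.8, 1.2]; m with 25 logarithmic points on [1e-3, 0.1], then steps of
0.02 to 0.98, refined to 0.01 on [0.5, 0.99].  The strongly negative ϕ
reach is deliberate: the transitional optima occupy small windows
between the multiple-fission region and the 2+2 region (measured here:
2+1 around ϕ ∈ [−3, −1], m ≈ 0.05–0.66; 2+1+1 around ϕ ∈ [−7.5, −5],
m ≈ 0.017–0.03), and a scan stopping at ϕ = −3 misses 2+1+1 entirely.
The census counts *strict* optima (singleton co-optimal sets); tie
cells, such as the entire ϕ = 1 line, are reported but excluded, since
they are measure-zero boundaries.

## Degeneracies worth knowing about

* **ϕ = 1 (equal gains from switching).**  When a + d = b + c there is
  no benefit difference between homogeneous and heterogeneous groups,
  and every life cycle whose parts are all ≥ 2 has identical λ′ (the
  donation game is the canonical case).  The 2+2/4+3 phase boundary sits
  exactly on this line for every m ≠ 1/2.
* **m = 1/2.**  Every daughter's phenotype is then an independent fair
  coin flip, so stationary group compositions are binomial at every size
  regardless of the life cycle; at first order in w *all*
  multicellular-offspring life cycles become degenerate for every ϕ
  (verified symbolically: λ′ = 1/4 exactly for 2+2, 3+2 and 4+3 under
  (1, −3, 3, 0)).  Consequently the 2+2 → 4+3 threshold of the
  prisoner's-dilemma sweep is evaluated as the m → 1/2 limit of the λ′
  crossing — computed at m = 0.45 and 0.55 and required to agree — which
  lands on c = 4 (the ϕ = 1 line), while at exactly m = 1/2 the package
  truthfully reports the tie.  The 1+1 → 2+2 threshold at c = 2 is
  strict even at m = 1/2 (λ′(2+2) = (1+ϕ)/4 crosses λ′(1+1) = 0).

## Self-interaction variant

The optional variant keeps the focal cell's own type in the payoff
average for groups of two or more (α = (ia+jb)/(i+j), β = (ic+jd)/(i+j))
while solitary cells still play no game.  Of the two readings of
"dropping the self-interaction exclusion", the alternative — letting a
solitary cell collect its diagonal payoff — reshapes the optimality
landscape drastically (only 1+1 and 4+3 survive); the implemented
reading perturbs the landscape only mildly, which is the regime the
variant is meant to probe, and leaves exactly five strictly optimal life
cycles across all games: 1+1, 1+1+1, 2+1, 2+2, 4+3.

## Monte-Carlo cross-validation

The agent-based simulator samples every random choice the analytic
machinery averages over — divider identity, daughter phenotypes,
fragmentation assignment — but keeps the inter-division waiting times
deterministic, exactly as the model defines them.  Two consequences
shape the estimator:

* a population started synchronized can *stay* synchronized (with
  deterministic lifetimes the process is lattice: every 1+1 lineage
  divides at exact multiples of ln 2), making log N(t) a staircase whose
  straight-line fit is biased.  Runs therefore start from a
  stationary-like ensemble: 20 groups per newborn type by default, each
  with its first division drawn at a uniform random fraction of its
  waiting time;
* unbounded exponential growth is capped (default 1e5 cells; tests use
  4000) by uniform group downsampling with doubling bookkeeping weights,
  which leaves the growth-rate estimate unbiased.

λ̂ is the regression slope of log weighted cell count over the second
half of the run.  The test battery (10 life cycle/game combinations,
w = 0.005, 8 seeds each) requires agreement with the spectral-radius
result within 3 standard errors of the seed-to-seed spread.

What the simulator does *not* emulate: cell death, group interactions,
spatial structure, or fluctuating division times — so agreement validates
the bookkeeping of the analytic calculation, not the realism of those
assumptions.

## Problem sizes and runtimes

The acceptance script solves 37 + ~80 root problems and finishes in
seconds.  A full phase map (two basis responses for 37 life cycles over
~120 m values, then ~30k grid cells by arithmetic) takes about half a
minute on one core; the Monte-Carlo battery about the same.  Trajectory
enumeration is exponential in M and guarded at M ≤ 7 (at M = 7 a single
start state can have ~10^4 composition paths); the dynamic program has
no such limit in practice.

## Known limitations

* λ′ is a first-order criterion; where it ties (ϕ = 1, or m = 1/2),
  second-order effects decide finite-w competitions, and the package
  reports ties rather than guessing.
* The finite-difference λ′ carries ~1e-7 truncation error; boundaries
  located by bisection inherit the xtol of the scan, not that error.
* Phase-map censuses depend on the scan grids; the defaults were chosen
  to cover all optimality regions found for M ≤ 7, but a life cycle
  optimal only outside ϕ ∈ [−8, 3] or m ∈ [1e-3, 0.99] would be missed.
* m = 0 and m = 1 make Q reducible; the spectral radius is still well
  defined and the solver proceeds with a warning.
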