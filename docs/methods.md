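# Methods

## Model

A linear dynamic network is a pair (A, drivers): a real `n × n` state
matrix whose entry `a_ij` is the weight of the edge *j → i*, and an ordered
set of `n_c` driver nodes.  The input matrix `B` has one canonical basis
column per driver, so when the drivers are the first `n_c` nodes
`B = [I 0]ᵀ`.  Continuous-time networks evolve as `ẋ = Ax + Bu`,
discrete-time ones as `x⁺ = Ax + Bu`; stability means all eigenvalues in
the open left half-plane (respectively, open unit disk).

## Fragility: the stability radius

`r(A)` is the **complex, unstructured** stability radius: the perturbation
Δ ranges over all complex matrices, and `r(A) = min_ω σ_min(A − iωI)` for a
stable continuous-time matrix (minimum over the unit circle `A − e^{iθ}I`
in discrete time).  An unstable matrix has `r = 0` by convention — the
empty perturbation already destabilizes it — and this is a result, not an
error.  Structured radii (perturbations confined to existing edges) are out
of scope.

Two independent algorithms are provided:

* **Bisection** (`stability_radius`, the production path).  The level test
  is spectral: ε exceeds the radius iff the Hamiltonian matrix
  `[[A, −εI], [εI, −Aᵀ]]` has a purely imaginary eigenvalue; in discrete
  time, iff the symplectic pencil `([[A, −εI], [0, I]], [[I, 0], [−εI,
  Aᵀ]])` has a generalized eigenvalue on the unit circle.  The initial
  bracket is `[0, s(A)]`, valid because `r ≤ s`, and bisection stops when
  the bracket is narrower than `tol` (default 1e−6; the result is within
  `tol` of the true radius).  Boundary eigenvalues are detected with an
  absolute threshold `1e−7 · max(1, ‖A‖)`; because the eigenvalues collide
  on the boundary with square-root sensitivity, this misclassifies ε only
  within ~1e−14 of the radius, far below `tol`.
* **Dense grid with refinement** (`stability_radius_grid`, the oracle).
  `σ_min(A − iωI)` is scanned over `|ω| ≤ 3‖A‖` on 2001 points (the
  minimizer cannot lie beyond `‖A‖`; the margin guards the refinement),
  then the best bracket is polished with a bounded scalar minimizer.  The
  two paths agree to 1e−4 on randomized ensembles in both time modes; the
  oracle never calls the bisection code.

## Responsiveness: the controllability Gramian

`G` solves `AG + GAᵀ + BBᵀ = 0` (continuous; SciPy's Bartels–Stewart
solver) or `AGAᵀ − G + BBᵀ = 0` (discrete), is symmetrized, and is reported
with the Frobenius residual of its defining equation.  Responsiveness is
the average singular value `σ̄(G)`; since G is PSD this equals
`trace(G)/n`, which is how it is computed.  Useful exact facts used
throughout the tests: `trace(G)` is additive over driver columns (so
`σ̄` is additive over disjoint driver sets and linear in `n_c` on average);
`σ̄(G) ≥ n/trace(G⁻¹)` for invertible G; and for the normal family below,
`trace(G) = n_c/(2α)`.  Minimum control energy `x_fᵀG⁻¹x_f` is computed by
a positive-definite solve, never an explicit inverse, and requires
`min_eig(G)` above `1e−10 · max(1, trace G)`.

Residual caveat: the raw residual is reported unscaled.  For extreme
similarity-conjugated matrices (β near 2 at n = 40, `‖A‖ ~ 1e12`,
`‖G‖ ~ 1e23`) the absolute residual necessarily inflates to
`~eps·‖A‖‖G‖`; validation there must be relative to `‖A‖‖G‖ + ‖BBᵀ‖`.

## Tradeoff bounds

`evaluate_bounds` computes the right-hand sides listed in the README and
the ratios `σ̄/rhs`.  Applicability flags: *symmetric* when
`‖A − Aᵀ‖_F ≤ 1e−8 max(1, ‖A‖_F)`; *normal* when `‖AAᵀ − AᵀA‖_F ≤ 1e−8
max(1, ‖A‖_F²)`; *diagonalizable* when the eigenvector condition number is
defined.  These thresholds are package choices — no canonical tolerance
exists for "numerically normal".  κ(V) uses unit-Euclidean-norm eigenvector
columns (the bounds hold for any diagonalizing V; unit columns are the
canonical scaling) and is computed as `σ_max(V)/σ_min(V)` from an SVD; a
condition estimate above `1/eps` marks the matrix defective and κ
undefined, and the κ-dependent checks are skipped rather than fed a
meaningless huge number.

The bounds are continuous-time theorems.  They provably fail in discrete
time (A = 0 has `σ̄ = 1 > 1/(2r) = 1/2`), so `evaluate_bounds` rejects
discrete-time networks; discrete families (the wave discretization) are
characterized by `r`, `s` and `σ̄` only.

## Synthetic families: what they state and what they do not

All generators are seeded and bitwise reproducible.  Defaults are the
conditions of the experiments they emulate; a green trend test establishes
the qualitative tradeoff direction in these stylized families, not any
quantitative property of real ecological, neuronal or traffic systems.

* **Bounded-degree digraphs** — exact d-regular in/out degrees via
  configuration-model stub pairing with conservative 2-swap repair
  (bounded retries, then failure).  Weights i.i.d. U[0, 1]; the diagonal is
  shifted so the margin equals a draw from U[0.1, 1.0] — a spread, rather
  than a fixed value, so the ensemble traces out the bound envelope.
* **Normal family** `A_skew − αI` — skew part from i.i.d. standard-normal
  upper triangle, antisymmetrized.  Exactly normal, `r = s = α`,
  `σ̄ = n_c/(2αn)`; attains the normal-case bound with equality and pins
  the equality case of the test suite.
* **Non-normal family** `D_β⁻¹ A_sym D_β` — symmetric core stabilized to a
  margin drawn from U[0.5, 1.5]; the conjugation leaves the spectrum (and
  s) fixed while κ(V) and `‖A − Aᵀ‖` grow with β.  Beyond β ≈ 1.6 at
  n = 40 the true radius falls below what double-precision bisection can
  resolve (`r ~ s/κ ~ 1e−8`); sweeps that need ranked radii stop there.
* **LQR family** — random symmetric plant, `K_γ = −R⁻¹BᵀP` from the
  continuous algebraic Riccati equation with Q = I, R = γI, B = I; the
  closed loop `A + BK_γ` is stable for every γ ≥ 1, and larger control
  cost yields a more robust, less responsive loop.
* **Mutualistic GLV** — `ẋᵢ = xᵢ(rᵢ − sᵢxᵢ + Σ γᵢⱼxⱼ)` on a Watts–Strogatz
  support (k = 4, p = 0.3), `rᵢ ~ U[0.5, 1]`, `sᵢ ~ U[1, 2]`,
  `γᵢⱼ ~ U[0, 0.7]`.  The interaction cap 0.7 makes a species' expected
  mutualistic input (≈ k·γ̄ = 1.4) comparable to its self-limitation,
  which is the boundary regime in which the probability of a feasible,
  stable coexistence equilibrium decays toward zero with richness.  A fact
  worth knowing when interpreting those curves: with positive growth rates
  a feasible mutualistic GLV equilibrium is automatically stable
  (M-matrix semipositivity plus D-stability), so "loses stability" here
  means "loses feasibility"; genuinely unstable interior equilibria
  require obligate mutualists (negative growth), which is how the
  perturbation-collapse behaviors are produced.  This generic GLV is a
  stand-in for the original saturating mutualistic model, which is not
  reproduced; conclusions are qualitative only.
* **Platoon** — optimal-velocity car-following `v̇ᵢ = a(V(hᵢ) − vᵢ)`,
  `ḣᵢ = vᵢ₋₁ − vᵢ`, `V(h) = v_max(tanh(h − h_c) + tanh h_c)/(1 + tanh
  h_c)`, defaults a = 1, v_max = 2, h_c = 2.  States are (headway,
  velocity) deviations of the followers; the leader speed α fixes the
  equilibrium headway via `V(h*) = α` and is valid on (0, v_max).  While
  the block eigenvalues are complex the margin is pinned at a/2; fragility
  and responsiveness co-move along the α sweep (they fall together at
  moderate speeds and rise together approaching free flow), which is the
  asserted trend.  The car-following law and parameters are a canonical
  stand-in, not a reproduction of any specific published platoon.
* **Wave discretization** — first-order upwind `uᵢ⁺ = (1−δ)uᵢ + δuᵢ₊₁`
  with zero inflow, spectral radius `1 − δ`, nilpotent at δ = 1; CFL
  requires δ ≤ 1.  A Lax–Wendroff stencil and periodic boundaries are
  selectable because the "right" stencil for the reference experiment is
  not determinate: note that for the upwind matrix the singular-value
  condition number σ_max/σ_min *decreases* as δ decreases, the opposite of
  the reference's reported trend, so that trend is deliberately not
  asserted anywhere.  Both σ_max/σ_min and κ(V) are reported.

## Case studies

Both are **simplified surrogates** that preserve the objective direction of
the procedures they stand in for; per-iteration values are meaningful only
as trends.

* *Ecological*: greedy ±step perturbation of one existing interaction,
  accepted iff the equilibrium stays feasible and total abundance rises.
  Metrics are recorded for the community matrix `Γ − diag(s)` — the
  network the algorithm edits.  Abundance maximization drives this matrix
  toward singularity, so fragility and responsiveness rise together.  (On
  the Jacobian `diag(x*)(Γ − diag(s))` the equilibrium-scale factor
  dominates and reverses the responsiveness trend; the community matrix is
  D-stability-equivalent for stability purposes and is the right object
  for the tradeoff.)
* *Neuronal*: an unstable excitatory/inhibitory matrix (half-normal
  columns, positive then negative, scale `2/√n`, leak 1) is stabilized by
  line-search descent on the softmax-smoothed spectral abscissa
  (temperature 0.1), whose exact gradient blends the first-order
  eigenvalue sensitivities `Re(uvᵀ/uᵀv)` of all near-rightmost
  eigenvalues; only inhibitory columns are updated.  Plain steepest
  descent on the rightmost eigenvalue alone stalls when eigenvalues crowd
  the front, which is why the smoothed objective is used; with a large
  spectral gap the two directions coincide.  A non-simple rightmost
  eigenvalue has no derivative; the step falls back to a random rescaling
  of the inhibitory columns that is kept only if it does not hurt the
  margin.  The trace records each time the true margin improves, so
  recorded margins increase monotonically, and the run stops at the target
  margin (default 0.1).

## Numerical choices and degenerate inputs

* Radius bisection tolerance 1e−6 by default (1e−9 where closed forms are
  checked to 1e−8); all tolerances are absolute, appropriate for the
  n ≤ a few hundred, O(1)-margin matrices this package targets.
* Driver sets are 0-based in the library, 1-based in files and CLI.
* Dense linear algebra throughout; no sparse path (n ≤ a few hundred in
  every stock experiment).
* The GLV simulator clips abundances at zero within solver tolerance and
  flags (rather than raises) trajectories whose norm exceeds 1e6 —
  divergence is an expected outcome for unstable equilibria.
* Degenerate-input conventions: unstable matrix → `r = 0` (not an error);
  infeasible GLV equilibrium → flagged model (not an error); Gramian of an
  unstable network → `StabilityError` naming the margin; singular Gramian
  in the energy computation → `ControllabilityError`.

## Known limitations

* The radius is unstructured and complex; real or structured radii can be
  substantially larger and are not computed.
* κ(V)-based quantities degrade for κ approaching 1/eps; such matrices are
  reported as defective rather than trusted.
* The β family beyond β ≈ 1.6 (n = 40) exceeds double-precision radius
  resolution, as noted above.
* Trend assertions use Spearman rank correlation on seeded medians; they
  certify direction, not effect size.
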