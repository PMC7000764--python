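# fragnet

Fragility and responsiveness are competing properties of networked dynamical
systems.  `fragnet` measures both for linear dynamic networks

```
dx/dt = A x + B u        (continuous time)
x[k+1] = A x[k] + B u[k] (discrete time)
```

where `A` is the weighted adjacency matrix (`a_ij` = influence of node *j*
on node *i*) and `B` selects the *driver* nodes that receive independent
external inputs — and certifies the tradeoff bounds that tie the two
together.  It is aimed at researchers in network science, systems biology,
neuroscience and control who want to ask, for a given interaction matrix:
*how close is this system to instability, how cheaply can it be steered,
and is the combination of both even achievable?*

## Metrics

* **Fragility** `1/r(A)`, where `r(A) = min { ‖Δ‖ : A + Δ unstable }` is
  the (complex, unstructured) **stability radius** — the spectral norm of
  the smallest edge-weight perturbation that destabilizes the network.
  Computed by bisection on ε with the purely-imaginary-eigenvalue test of
  the Hamiltonian matrix `[[A, −εI], [εI, −Aᵀ]]` (continuous time) or the
  unit-circle test of the analogous symplectic pencil (discrete time), and
  cross-checked against a dense frequency-grid oracle.
* **Responsiveness** `σ̄(G)`, the average singular value of the
  controllability Gramian `G = ∫₀^∞ e^{At} B Bᵀ e^{Aᵀt} dt`, obtained from
  the Lyapunov equation `AG + GAᵀ + BBᵀ = 0` (Stein equation in discrete
  time).  Large `σ̄(G)` means external stimuli are strongly amplified and
  control is cheap; the minimum energy to reach a state `x_f` is
  `x_fᵀ G⁻¹ x_f`.
* **Supporting quantities**: the spectral stability margin
  `s(A) = −max Re λ_i(A)`, the eigenvector condition number `κ(V)`, and
  the non-normality degree `‖A − Aᵀ‖`.

For every stable continuous-time network the package evaluates the bounds

```
σ̄(G) ≤ (n_c/n) (1 + 4‖A−Aᵀ‖/(3π r)) (1/r)      (general)
σ̄(G) ≤ (n_c/n) / r                              (symmetric A)
σ̄(G) ≤ (n_c/n) κ²(V) / (2 s)                    (diagonalizable A)
σ̄(G) ≤ (n_c/n) / (2 r)                          (normal A)
```

together with the sandwich `s/κ(V) ≤ r ≤ s`.  A responsive network is
therefore necessarily fragile, and the bounds quantify how the driver
fraction `n_c/n`, the spectrum, and the non-normal geometry each enter the
tradeoff.

## Generators

Seeded factories for the network families used to probe the tradeoff:
bounded-degree random digraphs with uniform weights and diagonal
stabilization; the normal family `A_skew − αI`; the non-normal family
`D_β⁻¹ A_sym D_β` with `D_β = diag(1, β, …, β^{n−1})`; LQR closed loops
(`Q = I`, `R = γI`); mutualistic Lotka–Volterra communities on small-world
topologies (with an ODE simulator); optimal-velocity vehicle platoons
linearized at uniform flow; and discrete-time upwind discretizations of the
one-way wave equation.  `fragnet.experiments` orchestrates the standard
sweeps (drivers, size, family parameter, stability-probability curve) into
tidy DataFrames, and `fragnet.case_studies` provides two iterative
surrogates (ecological abundance maximization, neuronal stabilization) that
trace the tradeoff along an optimization path.

## Worked example

```
$ fragnet generate --family skew_normal --n 40 --alpha 1.5 --seed 1 \
      --out skew40.tsv --drivers 10
$ fragnet metrics skew40.tsv --drivers 10
{
  "r": 1.4999996423721291,
  "s": 1.4999999999999976,
  "kappa_V": 1.0000000000000022,
  "non_normality": 21.998826504113836,
  "sigma_bar": 0.08333333333333333,
  ...
}
```

The generated matrix is normal (`kappa_V = 1`), so its stability radius
coincides with its margin, `r = s = α = 1.5`: the smallest destabilizing
perturbation is exactly as large as the distance of the spectrum from the
imaginary axis.  The responsiveness is `σ̄(G) = 0.0833… = n_c/(2αn) =
10/120`, the closed form for this family — which meets the normal-case
bound `(n_c/n)/(2r)` with equality (the reported `ratio_normal` is
0.99999976): this family sits exactly on the tradeoff frontier, so making
it more robust (larger α) must make it proportionally less responsive.

The same analysis is available as a library:

```python
from fragnet import skew_normal_family, fragility_report, controllability_gramian

net = skew_normal_family(40, alpha=1.5, seed=1).with_drivers(range(10))
frag = fragility_report(net.A)            # r, s, kappa_V, ||A - A^T||
gram = controllability_gramian(net)       # G, sigma_bar = trace(G)/n
```

## Acceptance script

`scripts/acceptance.py` regenerates the headline certification quantities
from scratch — eigenvector conditioning of the normal family, the extremal
bound ratios over symmetric, bounded-degree and non-normal ensembles, and
the equality case of the normal-family bound — by running the package's own
generators and metrics, and writes them as JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All randomness derives from `--seed`.  See `docs/methods.md` for the
numerical choices and the limits of what the synthetic families establish.
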