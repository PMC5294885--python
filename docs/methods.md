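# Methods

## Scope

`grnmsm` coarse-grains the stochastic dynamics of small gene-regulatory-network
(GRN) motifs into Markov State Models (MSMs). The pipeline is: define a motif
as a mass-action reaction system with explicit promoter binding configurations;
enumerate the truncated Chemical Master Equation (CME) state space and assemble
the sparse generator `Q`; form the row-stochastic lagtime transition matrix
`T(tau) = expm(tau Q)`; extract its dominant spectrum; cluster microstates into
`C` metastable macrostates with PCCA+; project `T` onto the macrostates; and
analyze the reduced model with transition path theory and Chapman–Kolmogorov /
projection error diagnostics. Exact stochastic simulation (Gillespie's direct
method) provides an independent route to stationary distributions, relaxation
curves, and autocorrelation functions.

## Models

All motifs treat transcription factors as acting through homodimers (except
the monomeric toggle variant), with dimerization lumped into the DNA-binding
event. A microstate is `(n_A, n_B, promoter configuration(s))` counting *free*
protein copies.

* **MISA** (mutual inhibition / self-activation): genes A and B; each protein
  dimer activates its own promoter and represses the other's. Each promoter
  has 4 configurations (activator x repressor occupancy), so 16 joint
  configurations; with copy numbers capped at 30 the space has
  31 x 31 x 4 x 4 = 15,376 microstates. Protein is produced at `g1` only in
  the activator-bound / repressor-free configuration, at `g0` otherwise.
* **Exclusive toggle switch (ETS)**: two genes share one promoter that is
  unbound or bound by either repressor (3 configurations, mutually
  exclusive); dimeric and monomeric repressor variants.
* **Self-regulating gene**: one gene, two promoter states, self-activating.

Conventions (both exposed as config switches):

* dimer binding propensity `h n (n-1)` (ordered pairs); the alternative
  `h n (n-1)/2` only rescales `h`;
* sequestration: binding removes the bound copies (2 for a dimer, 1 for a
  monomer) from the free pool; unbinding returns them.

## Rate parameters

The degradation rate `k = 1` defines the time unit; all other rates are
relative to it. The shipped presets are the package's reference conditions,
chosen from promoter-occupancy arguments so that each motif genuinely shows
the dynamical structure it is meant to study; they are defaults, not fits,
and every preset value can be overridden in the config.

* **MISA baseline** (`g0=2, g1=14, h_a=0.1, f_a=1, h_r=1e-4, f_r=1e-2`):
  self-activation is near-adiabatic (an unrepressed gene switches on within
  a few protein lifetimes, occupancy ratio `h_a n(n-1)/f_a ~ 13` at high
  expression) while repressor exchange is slow (`1/f_r = 100`), giving four
  metastable phenotypes (Lo/Lo, Hi/Lo, Lo/Hi, Hi/Hi) governed by repressor
  occupancy. `g1/k = 14` keeps the stationary mass outside the 30-copy box
  at the 1e-5–1e-4 scale. The repressor-unbinding sweep varies `f_r` over
  {1e-3 … 1} at fixed `h_r`, which weakens repression and monotonically
  populates the Hi/Hi phenotype.
* **MISA slow (non-adiabatic)** (`h_a=1e-3, f_a=1e-2, h_r=1e-6, f_r=1e-4`):
  *all* binding events are slow relative to protein dynamics, so every one
  of the 16 promoter configurations becomes metastable; activator exchange
  is ~100x faster than repressor exchange, which organizes the 16 states
  into 4 subnetworks (grouped by repressor occupancy) — a two-level
  dynamical hierarchy.
* **ETS dimer** (`g0=1, g1=20`, binding equilibrium `X_eq = f/h = 100` held
  fixed while `f` sweeps 1e-4 … 1e4): with `g1(g1-1) >> X_eq` the switch is
  bistable even in the adiabatic limit; at slow binding a third (Hi/Hi,
  unbound-promoter) basin appears. The slowest lifetime `t_2` is
  non-monotonic in `f` with its minimum near `f = 1`.
* **ETS monomer** (`g0=2, g1=30, h=1e-4, f=1e-2`, cap 50, N = 7,803): the
  small-number regime in which the stochastic model is tristable although
  the corresponding ODE model (no cooperativity) has a single fixed point.

## Numerical methods

* **Generator**: assembled reaction-by-reaction with vectorized propensities;
  rows sum to zero by construction. Production events that would leave the
  copy-number box are dropped (reflecting truncation); their rates are kept
  per state to support a Finite-State-Projection-style estimate, where an
  absorbing sink collects the dropped flux and its mass at a horizon bounds
  the transient truncation error. The stationary leak estimate solves the
  stationary distribution on a box enlarged by a user factor (default 2) and
  reports the mass outside the original box.
* **Stationary distribution**: shift-invert Arnoldi on `Q^T` around the zero
  eigenvalue (sparse LU); dense null space below 50 states. Ergodicity is
  verified by strong connectivity of the jump graph; reducible chains raise
  an error naming the component count.
* **`T(tau)` action**: `expm_multiply` (Al-Mohy–Higham) on vectors/columns;
  a dense exponential is materialized only below 3,000 states. The dominant
  spectrum uses Arnoldi iteration on that action with a deterministic start
  vector (all-ones), so repeated runs are bit-reproducible.
* **Implied timescales**: `t_i = -tau / ln |lambda_i|`, modulus for complex
  eigenvalues, `t_1 = inf` for the Perron root.
* **PCCA+**: the dominant right invariant subspace is made real by replacing
  each complex-conjugate eigenvector pair with its (Re, Im) columns — an
  invariant-subspace (real-Schur-equivalent) basis that reduces to plain
  eigenvectors for reversible chains. Memberships `chi = psi B` are
  optimized for metastability `trace(D~^{-1} chi^T D T chi)`; because
  `T psi = psi M` exactly for a small block matrix `M`, the objective is a
  `C x C` computation and the optimization never touches the full matrix.
  Initialization is the inner-simplex vertex search; refinement runs
  Nelder–Mead on the `(C-1)^2` free parameters of the feasibility-filled
  transform and is accepted only if it improves metastability without
  emptying a macrostate that the vertex solution kept populated. If a
  complex pair straddles the subspace boundary there is no C-dimensional
  real invariant subspace; the code warns and uses the pair's real part
  (this occurs only where the C-th process is spectrally degenerate noise).
* **Coarse model**: `T~ = D~^{-1} chi^T D T chi`, `pi~ = chi^T pi`. The
  validation and TPT workflow projects on the *crisp* partition (argmax of
  chi, lowest-index tie-break): with a numerically approximate fuzzy basis,
  the fuzzy projection acquires a spurious slow drift in deeply metastable
  regimes, while the crisp flux sum does not.
* **TPT**: committors are linear boundary-value solves on `T~` (backward on
  the `pi~`-reversed chain); the reactive flux is antisymmetrized to a net
  flux; paths are removed max-bottleneck-first (ties: fewer hops, then
  lexicographic), with a default residual tolerance of 1e-4 of the total
  flux. Paths are defined on macrostates of the coarse model.
* **SSA**: direct method, two uniforms per event from a PCG64 stream, inner
  loop JIT-compiled with numba (a pure-Python loop with the identical
  random stream is kept as a fallback and is tested for equality).
  Histograms are time-weighted. Simulations ignore the truncation, so
  occupancy outside the box independently estimates the truncation leak.
* **Projection error**: full dynamics `chi^T (T^T)^k p_0` versus coarse
  dynamics `(T~^T)^k (chi^T p_0)`, reported as total variation (half-L1)
  per step, with an L2 curve alongside; the global variant sums the curves
  over one stationary-restricted initialization per macrostate (K = 500 by
  default, reduced where a figure-level budget calls for it — the sweep in
  the acceptance script uses K = 250, which changes totals but none of the
  orderings). The Chapman–Kolmogorov test compares `diag(T~^k)` with the
  coarse-grained diagonal of the full k-step dynamics.

## What the presets do and do not emulate

The presets are synthetic study conditions, not calibrated fits to any
measured cell system: protein production is single-step (no mRNA), binding
is dimer-mediated without an explicit dimer species, and parameters are
round numbers chosen for the occupancy ratios above. Consequences verified
by the test suite: multistability and its parameter dependence, the spectral
gap structure, the promoter-configuration identity of slow-regime
macrostates, error orderings of reduced models, and agreement between
matrix and simulation routes. Passing tests demonstrate the correctness and
internal consistency of the machinery on these conditions — not quantitative
agreement with any particular experimental network, and published values
that depend on a specific unpublished rate table (e.g. an exact timescale
ladder) are reproduced in structure and order of magnitude rather than to
printed precision.

## Known limitations

* Full-space enumeration limits practical use to ~5e5 microstates; there is
  no adaptive state-space expansion or trajectory-based MSM estimation.
* PCCA+ refinement is derivative-free; for C = 16 the (C-1)^2 = 225-variable
  refinement is capped and typically only polishes the vertex solution.
* TPT runs on the coarse model only (macrostate resolution), matching the
  intended workflow; microstate-resolution TPT is out of scope.
* The autocorrelation observable defaults to a macrostate indicator; the
  fitted relaxation constant depends on that choice.
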