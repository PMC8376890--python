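# Methods

This note documents the models, algorithms, numerical choices and known
limitations behind `odeident`. It states how results are computed; every
number quoted here is produced by the test suite or `scripts/acceptance.py`.

## Model class and assumptions

A model is an affine-in-input ODE system
`dx/dt = f0(x, θ) + Σᵢ uᵢ(t) fᵢ(x, θ)`, `y = h(x, θ)`, with smooth (not
necessarily rational) vector fields, a stable ordering of states, parameters
and outputs, and initial conditions that may be numeric, zero, tied to
parameters (e.g. `x2(0) = p1/p3`) or unknown. Unknown initial conditions are
*promoted* to parameters; the unknown vector is ordered `[system parameters,
IC parameters in state order]`, and every downstream matrix (sensitivity
columns, Jacobi columns, singular-vector components) follows this ordering.
Initial-condition marker symbols may appear inside the dynamics (the
receptor-trafficking fixture has a synthesis term `k_t·EpoR(0)`), in which
case the promoted parameter enters both through the initial state and the
vector field; both routes are handled by the same chain rule.

Identifiability here is **local** (uniqueness in a neighbourhood of a
generic point), decided at a *scenario*: an initial-condition pattern plus a
nominal assignment. The pipeline deliberately runs the cheap numeric screen
first and the exact symbolic check only on the few flagged unknowns; the
numeric step also guards against the known failure mode of purely symbolic
approaches on models like `dx/dt = 1 + θx²`, `x(0) = 0`, which is
identifiable although naive series analyses suggest otherwise.

## Numeric screen

* **Forward sensitivities.** The variational system is assembled
  symbolically (Jacobians of the full right-hand side including the
  input-weighted fields), compiled with `sympy.lambdify`, and integrated
  with LSODA at `rtol = 1e-12`, `atol = 1e-14`. Initial state sensitivities
  are the Jacobian of the initial-condition expression vector with respect
  to the unknowns — an identity entry for a promoted initial value, a
  chain-rule row for a parameter-tied one, zero otherwise.
* **Grid and horizon.** Default grid: 101 points on `[0, 10]` model time
  units, overridable; verdicts are asserted over three grids in the tests.
  Several benchmark models have finite-time escape for generic positive
  draws (`dx/dt = p x²` reaches infinity at `t = 1/(p x0)`), so a cheap
  state-only pre-integration with a blow-up event (`|x|∞ > 1e6`) shrinks
  the grid to 80 % of the detected escape time. The grid must keep at least
  as many points as there are unknowns.
* **Input signals.** Constant, piecewise-constant and offset-sine inputs are
  supported. The controlled two-state benchmark needs a persistently
  exciting input: with constant `u`, its second state is frozen at the
  parameter-tied initial value and two parameters become genuinely
  inseparable, which is a property of that experiment rather than of the
  model; its default input is therefore `u = 1 + sin t + 0.5 sin 3t`.
* **Conditioning.** Before the SVD, columns whose norm is below `1e-9` of
  the largest column norm are clamped to exact zero — they are integration
  error, not signal, and normalising them would amplify noise to unit
  size — and the matrix is equilibrated by three rounds of row/column norm
  (Ruiz) scaling. Diagonal scaling preserves rank and the set of vanishing
  columns; on the bundled models it widens every spectral gap to ≥ 10
  decades at the default settings.
* **Gap rule and candidates.** Numerically zero singular values are those
  beyond the first gap of ≥ 10 decades in the descending log spectrum
  (first-from-the-top when several qualify, retaining the largest rank; the
  report flags multiple gaps). Candidate unidentifiable unknowns are those
  with `|component| > 1e-5` in any beyond-gap unit-norm right singular
  vector; supports are reported per vector and as a union, since distinct
  vectors name distinct totally correlated sets.
* **Genericity.** A classification repeats the signature over three fresh
  log-uniform draws from `[0.1, 10]` (positive, matching the nonnegative
  states of the bundled models) and requires a unanimous verdict; otherwise
  the pattern is "ambiguous" and goes to symbolic confirmation. This guards
  against the thin-set phenomenon — identifiability claims that hold only
  generically — and against unlucky draws in which a weak informative
  direction sinks within ~8 decades of the double-precision floor (observed
  on rare draws of the receptor and pharmacokinetics fixtures; the gap rule
  itself cannot distinguish such a direction from noise, which is precisely
  why the symbolic stage exists).

## Symbolic verification

* **Series rows.** For uncontrolled models the rows are `∂(L^r_f h)/∂θ^sel`
  evaluated at `x(0)`; for controlled models, Fliess words over the field
  indices ordered by length (drift power first, then input-containing words
  lexicographically). Inputs can instead be *bound* to a constant stimulus,
  folding `f0 + u·f1` into a single drift so the series describes exactly
  that experiment — this is how the JAK/STAT scenario (constant unit
  stimulus) is verified; its correlated sets sit five Lie orders deep, far
  beyond any practical word enumeration across eight outputs.
* **Evaluation order.** Scenario initial conditions are substituted *before*
  differentiation — that is how initial-condition-specific unidentifiability
  manifests. Numeric initial values are rationalised exactly (floats would
  put the linear algebra in an inexact field with unreliable zero tests).
* **Invariant-manifold reduction.** Zero-pinned states that are
  flow-invariant (checked by a symbolic fixed-point iteration, including
  every input field) are substituted into the dynamics; the series then
  lives on the invariant manifold. This both shrinks expressions and makes
  severed information flow explicit — e.g. `ka` cancels from the reduced
  pharmacokinetics equations, so its column vanishes identically. Selected
  unknowns absent from the reduced model contribute unit null vectors
  outright and are excluded from the staged computation.
* **Staged null-space.** Rows are added one word (one Lie order, all
  outputs) per stage, skipping rows whose restricted derivatives are all
  identically zero. After each contributing stage the generic null-space is
  recomputed over the fraction field `QQ(symbols)` (sympy `DomainMatrix`,
  with basis vectors normalised in-field so the last nonzero entry is 1;
  a generic-elimination fallback covers non-rational models). Termination:
  empty null-space → identifiable; basis unchanged for 2 consecutive
  contributing stages, or row cap `3·|θ^sel| + 4` / word supply exhausted →
  unidentifiable with the basis, explicitly a bounded-evidence verdict.
  Per-coefficient expression blow-ups (op-count cap 200 000) drop only that
  output's deeper words; if no stable answer is reached before the supply
  runs dry the verdict is "inconclusive", never silent.
* **Correlation PDE.** Each basis vector emits the PDE
  `Σⱼ cⱼ ∂φ/∂θⱼ = 0`. Solving it is out of scope; a user-supplied candidate
  first integral is verified by symbolic substitution (residual returned).

## Initial-condition searches

Patterns assign each state one of: zero, generic-nonzero (fresh positive
draw per evaluation), fixed value, unknown symbol, or parameter-tied
expression. `search_reinstating_sets` explores zero→nonzero change-sets
breadth-first (sizes 1, 2, …; supersets of found reinstating sets pruned, so
reported sets are minimal among tested ones); `search_problematic_sets`
enumerates zero-sets the same way and is by construction not exhaustive
beyond its size cap. Numeric positives (and non-unanimous "ambiguous"
patterns) are re-confirmed symbolically before entering the problematic
list; unconfirmed ones remain visible as "suspected" in the tested table.
Budget defaults: `max_changes = max_zeros = 3`, ≤ 200 classifications, all
seeded and reproducible at the verdict level.

## Influence graph

Edge `x_b → x_a` iff the Jacobian entry `∂(dx_a/dt)/∂x_b` of the full
right-hand side is not identically zero after substituting the
invariant-zero states — i.e. the coupling is evaluated on the invariant
manifold, so a frozen state keeps its linearised subsystem edges but loses
couplings proportional to its value. Strongly connected components
(networkx, cross-checked against pairwise reachability in the tests) are a
structural diagnostic of information flow, not a decision procedure.

## Bundled models and scenarios

Seven fixtures with their published equations, initial-condition patterns
and default unknown sets: the two-state benchmark and its identifiable
reparameterisation, the controlled two-state benchmark, the six-state
Epo-receptor trafficking model (10 unknowns), the fourteen-state JAK/STAT
model (23 unknowns; its two unprinted constants are set to 1 and its
stimulus to the constant 1, overridable — the verdicts are robust to generic
positive choices), the four-state mannose-receptor pharmacokinetics model
(11 unknowns), and the one-state cautionary toy. Free nominal values are
drawn log-uniform from `[0.1, 10]` with a recorded seed. The
pharmacokinetics fixture exposes both initial-condition readings (its
printed system sets `x4(0) = 0` while the search treats all four initial
values as unknown); the default scenario is the problematic
`x3(0) = x4(0) = 0` pattern with generic positive `x1(0)`, `x2(0)`.

## What the scenarios do and do not show

The fixtures are exact published equation sets, not data; passing tests
show that the two-step pipeline reproduces the known identifiability
structure of these models at generic nominal points and seeded draws. They
do not exercise measurement noise, model misspecification, or practical
identifiability (confidence intervals, profile likelihoods), all of which
are out of scope. Unidentifiable verdicts from the staged symbolic check are
bounded-evidence statements (a null-space that persisted up to the row cap),
not proofs; identifiable verdicts are exact rank statements about the
truncated series. Global identifiability is never claimed.

## Problem sizes

Default test and acceptance runs use the models as published (up to 14
states / 23 unknowns), 81–151 grid points, three draws per classification,
generating series to word length 3–4 for printed-matrix comparisons, and
search caps of 1–2 changes/zeros on the search examples — the regimes in
which all bundled results are reproduced.
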