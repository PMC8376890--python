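# odeident

Local structural identifiability analysis of nonlinear ODE models, with a
focus on the role of initial conditions.

Structural identifiability is a binary, a-priori property of a model: can
unique parameter values in principle be recovered from error-free
input–output data? For nonlinear models the answer can depend on the chosen
initial conditions — an otherwise identifiable model may lose
identifiability on a "thin" set of initial values (often, but not always,
zero values). `odeident` is a tool for systems biologists and modellers to

* decide local structural identifiability of a model at a given scenario,
* pinpoint *which* parameters and initial conditions are totally correlated,
* search initial-condition space for problematic sets that destroy
  identifiability, and for minimal changes that reinstate it.

## The method

Models are written in standard affine-in-input state-space form

```
dx/dt = f0(x, θ) + Σᵢ uᵢ(t) fᵢ(x, θ),    x(0) = x0,    y = h(x, θ),
```

with states `x ∈ Rⁿ`, unknown parameters `θ` (dimension `p`, extended up to
`p + n` when initial values are unknown and promoted to parameters), inputs
`u`, and measured outputs `y ∈ Rᵐ`. Two complementary analyses are combined:

1. **Numeric screen (sensitivity SVD).** The forward sensitivity system

   `d/dt (∂x/∂θ) = (∂F/∂x)(∂x/∂θ) + ∂F/∂θ`,
   `∂y/∂θ = (∂h/∂x)(∂x/∂θ) + ∂h/∂θ`

   is integrated at a generic (seeded random) nominal point and the output
   sensitivities on a time grid `t₀..t_N` are stacked into the
   `m(N+1) × (p+n)` sensitivity matrix `S`. Full column rank of `S` is
   sufficient for local structural identifiability. The numeric rank is read
   off the SVD `S = Σᵢ uᵢ σᵢ vᵢᵀ`: singular values that fall beyond a
   distinct gap (≥ 10 decades on the log scale) are numerically zero, and
   the above-threshold components of the corresponding right singular
   vectors name the candidate unidentifiable set `θ^unid`.

2. **Symbolic verification (Lie-derivative Jacobi matrix).** The output's
   generating-series coefficients — `h`, `L_f h`, `L²_f h`, … evaluated at
   `x(0)` (Fliess-series coefficients over words of vector-field indices for
   controlled models) — are differentiated **only with respect to
   `θ^unid`**. The resulting Jacobi matrix `∂G/∂θ^unid` grows one Lie order
   at a time; its generic null-space either is destroyed (identifiable) or
   persists (unidentifiable). A persisting basis vector `c` names a totally
   correlated set and encodes the first-order PDE
   `Σⱼ cⱼ ∂φ/∂θⱼ = 0`, whose solutions `φ` are the identifiable parameter
   combinations.

On top of the verdict machinery sit diagnostics and searches: invariant-zero
state detection (zero initial values that the flow keeps at zero forever),
the directed state-influence graph and its strongly connected components,
and breadth-first searches for problematic zero sets / minimal reinstating
nonzero sets.

## Worked example

Seven classic models ship as fixtures (`odeident fixtures list`). The
two-state benchmark `m1`,

```
dx1/dt = p1 x1² + p2 x1 x2,   x1(0) = x10 ≠ 0,
dx2/dt = p3 x1² + x1 x2,      x2(0) = 0,      y = x1,
```

loses identifiability of `p2` and `p3` precisely because `x2(0) = 0`:

```bash
$ odeident analyze --fixture m1 --out-dir out_m1
{"verdict": "unidentifiable", "theta_unid": ["p2", "p3"], "n_draws": 3, "symbolic": "unidentifiable"}
$ echo $?
2
```

The numeric screen finds one singular value beyond a > 10-decade gap with
nonzero components on `p2` and `p3`; the symbolic step confirms with the
null-space basis `(-p2/p3, 1)`, i.e. the correlation PDE
`-(p2/p3) ∂φ/∂p2 + ∂φ/∂p3 = 0`, solved e.g. by `φ = p2·p3` — only the
product of the two parameters is identifiable. The same library calls are

```python
import odeident as oi
res = oi.classify_pattern(oi.build_fixture("m1"),
                          oi.default_scenario("m1")[1])
print(res.verdict, res.candidates)     # unidentifiable ('p2', 'p3')
```

Identifiability is reinstated by a single initial-condition change:

```bash
$ odeident search-ics --fixture m1 --mode reinstate --max-changes 1 --out-dir out_m1
{"mode": "reinstate", "found": [["x2"]], "incomplete": false}
```

For the four-state pharmacokinetics fixture `m5_pk` (globally identifiable
for generic initial values), `search-ics --mode problematic` recovers the
two problematic zero-pairs `{x1(0), x2(0)}` and `{x3(0), x4(0)}`, and
`odeident graph --fixture m5_pk` shows the influence graph splitting into
two strongly connected components under `x3(0) = x4(0) = 0` — the
structural reason why `ka`, `beta1`, `beta2` become unidentifiable there.

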