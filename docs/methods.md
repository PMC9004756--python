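# Methods

## Models and coordinates

Both frameworks describe one host (resource) and one parasitoid
(consumer) population with an attack rate *f*(*h*, *p*) that is an
arbitrary, continuously differentiable, strictly positive function of
the two densities. All stability statements are local statements about
the nontrivial coexistence equilibrium, organised by the attack rate's
elasticities there:

- *f_h* = (h\*/f) ∂f/∂h — host sensitivity. Negative for a saturating
  (Type II) response; positive where the rate accelerates with host
  density (the rising flank of a Type III response).
- *f_p* = (p\*/f) ∂f/∂p — parasitoid sensitivity. Negative for mutual
  interference, positive for cooperation.

Both are constrained to ≥ −1 so that the net rates *f·h* (per
parasitoid) and *f·p* (per host) are non-decreasing in the respective
density; more negative values would mean that adding hosts lowers total
host capture, which we exclude as biologically pathological.

### Attack-rate families

| family | form | (f_h, f_p) |
|---|---|---|
| constant | c | (0, 0) |
| type2 | c₁/(1 + c₁T_h h) | (−c₁T_h h/(1+c₁T_h h), 0) |
| generalized_hill | c₁h^q/(1 + c₁T_h h^{q+1}) | (q − (q+1)x/(1+x) with x = c₁T_h h^{q+1}, 0) |
| parasitoid_power | c₁p^α, −1 < α < 1 | (0, α) |
| monomial | c·h^a·p^b | (a, b) |

The monomial family is the bridge to the (f_h, f_p) plane: its
elasticities are the exponents themselves, independent of density, so
atlas computations parameterise directly by (a, b) rather than by a
fitted mechanistic family. Families ignore the density they do not
depend on rather than erroring; host-only and parasitoid-only forms are
legitimate members of the same interface.

### Continuous framework

dh/dt = r h − f h p, dp/dt = f h p − γ p. The equilibrium solves
h·f(h, r h/γ) = γ. Closed forms exist for every built-in family except
`generalized_hill`, which is solved by bracketed Brent iteration on
log h; the host balance is monotone with a single crossing precisely
when the handling time is shorter than the mean parasitoid lifespan
(T_h < 1/γ), which the code enforces as a precondition. Equilibrium
residuals are verified below 1e−10 relative.

Linearisation at the equilibrium, written in the elasticities, gives

    A = [ −r·f_h        −γ(1+f_p) ]
        [  r(1+f_h)      γ·f_p    ]

with trace −r·f_h + γ·f_p and determinant rγ(1 + f_h + f_p) (both
reductions are verified against central-difference Jacobians of the
vector field in the test suite). Stability (negative trace, positive
determinant) is therefore

    f_p < r f_h/γ   and   1 + f_h + f_p > 0.

### Discrete framework (semi-discrete derivation)

Within a season of length T (T = 1 throughout; it can be absorbed into
the rate constant), larvae L (initial R·H_t), searching parasitoids P
(initial P_t) and parasitized larvae I evolve as

    dP/dτ = −γ_P P,   dL/dτ = −c(L)·P·L − γ_L L,   dI/dτ = c(L)·P·L − γ_I I

with c = L^{f_h}·P_t^{f_p}. With zero within-season mortality —
the setting of every headline result — L + I = R·H_t is conserved and
the system integrates in closed form, yielding the year-to-year map
stated in the README. Conventions worth recording:

- The parasitoid factor of the monomial uses the start-of-season
  density P_t (the density that sets the year's attack phenotype), so
  it stays fixed within a season even when γ_P > 0 in exploratory use.
- Near f_h = 0 the bracket form (1 + f_h x)^{−1/f_h} is evaluated as
  exp(−log1p(f_h x)/f_h) and switched to its limit exp(−x) below
  |f_h| = 1e−8; continuity across the switch is tested.
- For f_h < 0 the within-season larval density can reach zero in finite
  time; a non-positive bracket maps to H' = 0, P' = R·H (complete
  parasitism), a modeling convention validated against direct
  integration of the season dynamics.

The fixed point satisfies P\* = (R−1)H\* exactly (survivors plus
parasitized partition R·H), with

    H* = [(1 − R^{−f_h}) / (f_h (R−1)^{1+f_p})]^{1/(1+f_h+f_p)},

where (1 − R^{−f_h})/f_h → log R as f_h → 0 (evaluated via expm1). The
runtime equilibrium is a Brent solve on log H (positivity enforced)
seeded by this closed form, with the fixed-point residual checked below
1e−10; the closed form and solver cross-validate each other.

The Jacobian of the map at the equilibrium reduces to

    A = [ R^{−f_h}       −m ]         s = (1 − R^{−f_h})/f_h,
        [ R − R^{−f_h}    m ],        m = (1+f_p)·s/(R−1),

with Tr = R^{−f_h} + m and Det = R·m. The Jury conditions for a 2×2
map are 1 − Det > 0, 1 − Tr + Det > 0, 1 + Tr + Det > 0. Here
1 − Tr + Det = s(1 + f_h + f_p) identically — the shared necessary
condition — and 1 + Tr + Det is a sum of positive terms on the
admissible domain (asserted on scanned grids), so stability is
equivalent to the two-inequality criterion in the README, with the
boundary's removable singularity at f_h = 0 filled by the limit
−(R log R + 1 − R)/(R log R).

## Simulation cross-checks

The continuous model is integrated in log densities (DOP853, rtol
1e−10, atol 1e−12), which enforces positivity by construction and keeps
the classical first integral c(h+p) − γ log h − r log p below 1e−6
relative drift over 30 natural periods — the integrator-quality bar
that makes the neutral point classifiable. Orbits are sampled at 80
points per natural period 2π/√(rγ). Runs that leave a ±100 window in
log density terminate early; super-exponential orbits (cooperation-
driven blow-up, or host collapse under f_h < 0) can starve the step-size
control in finite time, and a solver stop that occurs after the orbit
has moved more than a factor 50 from its start is recorded as the
divergence it is.

Classification of a trajectory started at a relative perturbation of
1e−3 (inside the linearisation regime) compares the peak deviation over
the last third of the record with the first third: ratio < 0.9 damped,
> 1.1 diverging, else neutral — a band wide enough to absorb integrator
noise at the neutral point. Two refinements matter in practice: an
orbit whose late deviation exceeds 100× the initial perturbation is
diverging even if its envelope has flattened (growth onto a bounded
invariant loop after a Neimark–Sacker-type loss of stability saturates
the envelope ratio), and a discrete run ending in extinction (H = 0,
which is absorbing and reached exactly once the escape fraction
underflows) is diverging outright — instability of the map typically
manifests as oscillations that grow until the host crashes.

Horizons: ≥ 30 natural periods (continuous), a few hundred generations
(discrete; 800 near the discrete Type III threshold, where the
spectral radius is within ~2% of one and transients are long). Iterated
densities are capped at 1e12× the equilibrium host density.

## Stability atlas

Grids default to f_h ∈ [−1, 3] × f_p ∈ [−1.5, 1.5] at 301×301 — all
four quadrants of the stabilizing/destabilizing mechanisms at a
resolution that runs in well under a second. Cells are scored with the
full trace/determinant (continuous) and full three-Jury (discrete)
criteria rather than the reduced two-inequality forms, so the band
f_p < −1 — scanned only to render the shared necessary-condition line,
and biologically excluded — still receives mathematically correct
verdicts. Cells whose minimum slack is within 1e−9 of zero are recorded
marginal and excluded from subset/agreement assertions (the classical
models sit exactly on a boundary, so the marginal band cannot be
dropped). Cross-framework comparisons hard-code the matching
r = log R, γ = 1; standalone continuous scans accept any (r, γ).

Asymptotic limits are verified at R = 1 + 1e−6 and R = 1e6 (r = 1e−6
and 1e6 in continuous time) with tolerance 1e−2 on boundary positions,
with one exception: the discrete corner approaches its large-R limit
(0, −1) only at rate log 2/log R — its location is exactly
f_h = −log(2 − 1/R)/log R — so at R = 1e6 it still sits 0.050 away from
the limit, and its convergence is checked against the analytically
derived bound 1.2·log 2/log R instead. Reaching 1e−2 would require
R ≈ 2¹⁰⁰.

## Design notes and tolerances

- Marginal tolerance: |slack| ≤ 1e−9 for analytic criteria,
  max|Re λ| ≤ 1e−6 (continuous) / |ρ − 1| ≤ 1e−6 (discrete) for
  eigenvalue verdicts. The criteria are strict inequalities; the
  boundary is measure-zero but contains the classical baselines.
- Central differences for elasticities use a relative log-space step of
  1e−6 and must agree with analytic forms to 1e−6 relative.
- Closed-form map vs within-season integration agrees to 1e−8 relative
  (integration at rtol 1e−11); randomized sweeps use the fixed default
  seed 20220412, overridable on the command line.
- Randomized agreement sweeps pair every analytic verdict with its
  numerical counterpart at ≥ 200 draws; the ODE-simulation leg of the
  continuous comparison runs on a 10-draw seeded subsample (each
  high-accuracy 30-period integration costs far more than an
  eigenvalue solve, and the eigenvalue leg already covers the volume).

## What the generated data do and do not show

All inputs are parameter sets; no field data enter anywhere. The
within-season integrator doubles as the independent oracle for the
closed-form map, and simulations cross-validate linear (local) verdicts
with finite perturbations. Passing tests therefore demonstrate internal
consistency of the analytic criteria, their Jacobians and the nonlinear
dynamics — not that any real host–parasitoid system follows these
models. In particular: there is no host self-limitation (host growth is
unbounded without the parasitoid), the discrete derivation assumes all
within-season mortality is negligible, and instability is only
classified (damped/neutral/diverging), with no characterization of the
resulting limit cycles or invariant loops beyond their detection.

The phenomenological discrete variant (substituting f(H_t, P_t) into
the classical escape fraction) is provided for documentation contrast
only and is excluded from the atlas; it can disagree qualitatively with
the mechanistic semi-discrete map.
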