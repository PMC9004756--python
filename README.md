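# hpstab

Stability analysis of host–parasitoid (consumer–resource) population
models in continuous and discrete time, under arbitrary density-dependent
attack rates.

## The problem

A parasitoid attacks hosts at a per-host, per-parasitoid rate *f*(*h*, *p*)
that may depend on both densities: saturation through handling time
(Type II functional response), acceleration at low host density
(Type III), mutual interference between parasitoids, or cooperation.
Which of these processes — alone or combined — make the coexistence
equilibrium locally stable, and does the answer depend on whether the
populations are modeled in continuous time (overlapping generations,
Lotka–Volterra form) or in discrete yearly generations
(Nicholson–Bailey form)?

`hpstab` answers this by reducing each mechanism to the attack rate's
**log sensitivities** (elasticities) at equilibrium,

    f_h = (h*/f) ∂f/∂h,      f_p = (p*/f) ∂f/∂p,

and mapping stability over the (*f_h*, *f_p*) plane.

## The two models

**Continuous time** (generalized Lotka–Volterra):

    dh/dt = r h − f(h, p) h p
    dp/dt = f(h, p) h p − γ p

with host growth rate *r* and parasitoid mortality *γ*. The nontrivial
equilibrium satisfies *f*(*h*\*, *p*\*) = *r*/*p*\*, *p*\* = *r h*\*/*γ*,
and is asymptotically stable iff

    f_p < r f_h / γ   and   1 + f_h + f_p > 0.

**Discrete time** (generalized Nicholson–Bailey, derived semi-discretely):
within each season the vulnerable larval stage *L* (initial density
*R H_t*, with *R* > 1 viable eggs per adult host) is attacked at the
monomial rate *L*^*f_h* *P_t*^*f_p*; solving the within-season dynamics
over one season yields the map

    H_{t+1} = R H_t (1 + f_h (R H_t)^{f_h} P_t^{1+f_p})^{−1/f_h}
    P_{t+1} = R H_t − H_{t+1}

whose equilibrium (with *P*\* = (*R*−1)*H*\*) is stable iff

    f_p < [R + (f_h(R−1) − R) R^{f_h}] / (R (R^{f_h} − 1))   and   1 + f_h + f_p > 0.

Headline consequences, all recomputed by this package:

- a Type III response alone stabilizes for *f_h* > 0 in continuous time
  but needs *f_h* > 1 in discrete time (for **every** *R*);
- the classical models (*f_h* = *f_p* = 0) are neutrally stable
  (continuous, cycles of period 2π/√(rγ)) and unstable with diverging
  oscillations (discrete);
- as *R* → 1 both frameworks share the criterion *f_p* < 0 with
  1 + *f_h* + *f_p* > 0; as *R* → ∞ the discrete region's two boundary
  lines meet near (*f_h*, *f_p*) = (0, −1);
- the discrete stability region is contained in the continuous one at
  matched parameters (*r* = log *R*, *γ* = 1).

Every analytic verdict is cross-validated numerically: eigenvalues of
the equilibrium Jacobian (Hurwitz conditions in continuous time, Jury
conditions for the map), and simulation (adaptive ODE integration /
map iteration) with envelope classification of perturbed trajectories.

## Worked example

Verdict for a discrete-time model combining moderate attack-rate
acceleration (*f_h* = 0.5) with moderate parasitoid interference
(*f_p* = −0.3) at *R* = 2 — each mechanism is insufficient alone, but
together they stabilize:

```
$ hpstab stability --framework discrete --R 2 --fh 0.5 --fp -0.3
# discrete equilibrium at (fh=0.5, fp=-0.3): stable
status=stable
cond1_slack=0.1535533905932737
cond2_slack=1.2
spectral_radius=0.9055942870169107
...
```

`cond1_slack` is the margin to the interference/acceleration boundary
(positive = stable side), `cond2_slack` the margin of the shared
necessary condition 1 + *f_h* + *f_p* > 0, and the spectral radius of
the map Jacobian is below one, confirming the analytic verdict.

Stability-region summaries for two reproduction levels (grids are
written next to the given prefix):

```
$ hpstab atlas --R 2 --R 20 --nfh 81 --nfp 81 --out atlas
framework   R   r         corner_fh    corner_fp    fp_intercept  fh_intercept  stable_fraction
continuous  2   0.693147  -0.59061611  -0.40938389   0            0             0.62399
discrete    2   0.693147  -0.5849625   -0.4150375   -0.27865248   1             0.423868
continuous  20  2.99573   -0.25026702  -0.74973298   0            0             0.713916
discrete    20  2.99573   -0.22292692  -0.77707308  -0.68288221   1             0.480719
```

The discrete `fh_intercept` stays pinned at 1 (the Type III threshold),
the interference intercept `fp_intercept` deepens with *R*, and the
stable fraction of the scanned window is smaller in discrete time.

Simulating the classical continuous model confirms neutral cycling at
the predicted period 2π/√(rγ) ≈ 6.2832:

```
$ hpstab simulate --framework continuous --r 1 --gamma 1 --horizon 80 --out lv.tsv
classification=neutral
period_estimate=6.279692802286124
neutral_period=6.283185307179586
```

The same analyses are available as library calls
(`hpstab.nb_stability`, `hpstab.lv_simulate`, `hpstab.scan_region`, …);
see `docs/methods.md` for the model derivations and numerical choices.

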