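# Methods

## Model

The package implements a deterministic, well-mixed, stage-structured
predator–prey model. State variables are average counts: adult coffee
berry borers `A`, immature borers `I` (eggs through pupae, which live
inside the berry), and predatory ants `H` of a single species that feeds
on both stages. Generations overlap, space and migration are ignored, and
no sex structure is modelled.

    dA/dt = ω I − μ A − α A H
    dI/dt = ϕ A (1 − I/q) − ω I − θ I − δ I H
    dH/dt = (r + ε α A + ε δ I) H (1 − H/k)

Immature recruitment ϕA is damped by the logistic factor `1 − I/q` because
the berries can host at most `q` immatures; predation is mass action on
both stages; the ants persist without the borer (they have other food, so
their logistic growth rate `r` is positive) and gain extra growth
`ε(αA + δI)` from consumed prey. Adult mortality splits into predation
(αAH) and everything else (μA: natural death, traps, insecticide). μ is
the management parameter and must be positive — adult borers die of
natural causes regardless of intervention — while `α = δ = 0` is allowed
and decouples the ants into a plain logistic equation.

### Parameters

| name | meaning | unit | baseline |
|------|---------|------|----------|
| q | carrying capacity, immature borers | count | 700 |
| k | carrying capacity, ants | count | q/20 = 35 |
| r | intrinsic ant growth rate | 1/day | 0.01 |
| α | predation rate on adults | 1/(ant·day) | 0.01 |
| δ | predation rate on immatures | 1/(ant·day) | 0.01 |
| ε | biomass conversion efficiency | — | 0.2 |
| θ | immature natural death rate | 1/day | 0.23 |
| μ | adult non-predation death rate | 1/day | variable, reference 0.03 |
| ϕ | oviposition rate | eggs/(adult·day) | 2 |
| ω | immature→adult development rate | 1/day | 0.17 |

The baseline values are illustrative rather than field-calibrated (borer
life-history figures vary strongly with temperature across studies); k is
tied to q on the premise that ants are outnumbered by borers. Time is in
days throughout; this is documented, not enforced.

## Analysis

**Invariant region.** Ω = [0, ωq/μ] × [0, q] × [0, k] is positively
invariant: the planes H = 0 and H = k are invariant (dH/dt vanishes
identically on both), and on the remaining faces the field points inward
(e.g. on I = q, dI/dt = −(ω+θ+δH)q < 0). At the reference μ = 0.03 the
adult bound is ωq/μ = 3966.67; an alternative figure of 3967.66 circulates
in earlier quotations of this bound and appears to be a digit
transposition — the package always computes from the formula, which also
shifts the derived "approximately 3373" culling figure to 3372.

**Thresholds and equilibria.** B0 = ϕω/(μ(θ+ω)) and
Ψ0 = ϕω/((kα+μ)(kδ+θ+ω)) are net reproduction rates (adult daughters per
adult) without and with the predator at capacity. The four equilibria are
closed-form; E2 (borers, no ants) exists biologically iff B0 ≥ 1 and E4
(coexistence, ants at k) iff Ψ0 ≥ 1, with collisions E2→E1 at B0 = 1 and
E4→E3 at Ψ0 = 1. Collisions are flagged when |threshold − 1| ≤ 1e−9
(relative); the thresholds are closed-form, so the tolerance only absorbs
rounding noise. Biological sense uses non-strict ≥ 0 so collided
equilibria remain admissible. Closed-form coordinates are always guarded
by a residual check ‖f(E)‖ < 1e−8·(1+‖E‖). When kα exceeds
ϕω/(kδ+θ+ω), μ\* is negative; it is reported verbatim together with an
`eradication_for_all_mu` flag rather than clamped.

In the non-negative octant E1–E4 are provably the only equilibria
(dH/dt = 0 with A, I ≥ 0 forces H ∈ {0, k}, and each plane carries exactly
two planar equilibria). Off the octant a further equilibrium family exists
on the degeneracy line r + ε(αA + δI) = 0, necessarily with negative
components; Newton searches started inside Ω occasionally converge to it,
so the root-finding oracle in the tests asserts uniqueness of E1–E4 only
over the admissible octant and checks that any stray root lies on that
line.

**Eigenvalues.** At every equilibrium the Jacobian block-decouples into
the ant direction and a 2×2 borer block whose discriminant is positive, so
all eigenvalues are real and closed-form. The eigenvalue whose sign the
relevant threshold controls is stored last, making the collision cases
show their zero in a fixed slot. Numeric eigenvalues (dense solver) are
matched to the closed-form labelling by nearest value, not magnitude
sorting, and the two routes must agree to 1e−8 (scaled). The printed form
of E4's predator-direction eigenvalue is derived here as
λ₁ = −[qε(kδ+θ+ω)(αω+kαδ+δμ)(Ψ0−1)/(ϕω) + r], which the numeric oracle
confirms. Zero eigenvalues are declared at |λ| ≤ 1e−8·(1+‖J‖).

**Classification.** Five regimes in μ: below μ\* (E4 locally
asymptotically stable; E1, E2, E3 saddles), at μ\* (E3 = E4 nonhyperbolic
collision), between μ\* and μ\*\* (E3 stable, E4 senseless), at μ\*\* (E2
collides with E1, which stays unstable by the Liapunov argument below),
and beyond (E3 stable, E2 and E4 senseless). Regime membership is decided
with a 1e−9 relative tolerance on μ against the closed-form critical
values. Note that the commonly quoted μ\* = 0.1033 is a 4-dp rounding of
31/300 − 0.35 = 0.103333…; evaluated literally at μ = 0.1033 the system
still sits (barely) in the coexistence regime with Ψ0 = 1.00007, so the
collision analyses use the exact closed form.

**Bifurcation certificates.** Transcriticality at (E3, μ\*) and, for the
ant-free planar restriction, at (origin, μ\*\*) is certified with the three
Sotomayor scalars c1 = wᵀf_μ, c2 = wᵀDf_μ v, c3 = wᵀD²f(v,v), with null
eigenvectors normalised to second component 1 (so the scalars match their
closed forms, c2 = −(kδ+θ+ω)²/(ϕω) and c3 = −2(kδ+θ+ω)/q, with kδ dropped
in the planar case). Each scalar is recomputed by central finite
differences (μ-step 1e−6 scaled; state-step 1e−4 scaled, which is exact
here because the field is polynomial of degree ≤ 3) and the two routes
must agree to 1e−4 relative. The instability of the extinction state E1 in
the nonhyperbolic case B0 = 1 is demonstrated numerically with the
Liapunov function V = H on the half-ball of radius ρ/2,
ρ = min(r/(ε√(α²+δ²)), k): V̇ > 0 throughout, and every seeded start
(default seed 20230675) must exit the ball in finite time.

## Numerics

Integration uses `scipy.integrate.solve_ivp` with LSODA (analytic Jacobian
supplied), rtol 1e−8, atol 1e−10; LSODA's implicit fallback covers the
mild stiffness near I = q when ϕ is large. Non-negativity is never
clipped: a solver defect would surface as an invariance-check failure
(slack 1e−6) instead of being masked. Convergence to an equilibrium is
declared when the maximum distance over the trailing 10% of the time span
is below 1e−3 absolute (populations are O(10–10³)). The default horizon is
5000 days, several times the slowest eigenvalue time-scale (r = 0.01/day)
of the baseline regimes. The single exception is the collision regime
μ = μ\* exactly: the approach to E3 along the centre manifold is algebraic,
x(t) ≈ 1/(|c|t) with |c| ≈ 4.0e−4 for the baseline values, so the regime
study integrates that case to 2e7 days to pass the same 1e−3 criterion.

## Synthetic generator

Randomized tests draw all inputs from `cbb_ants.synthetic`. Rates (r, α,
δ, θ, μ, ϕ, ω) are log-uniform on [1e−3, 3] so both sides of each
threshold are exercised; q is uniform on [100, 5000], ε on [0.05, 1], and
k = q × U[0.02, 0.2] keeps ants scarcer than borers. A master seed is
fanned out through `SeedSequence.spawn`, one substream per draw, so
enlarging a batch preserves its prefix. Initial states are uniform in Ω,
optionally restricted to H > 0 (the interior-basin arguments require ants
present). What the generator emulates is the *structure* the analysis
assumes — positive rates, bounded capacities, admissible starts — not
field-realistic parameter distributions; green tests therefore validate
the mathematics of the model, not its fit to any plantation.

## Problem sizes

The randomized studies use 100 (parameters, start) pairs for invariance
(500-day horizon), 10 interior starts per mortality regime for attractor
checks, 200 parameter sets for eigenvalue cross-validation, 500 for
threshold orderings, and 20 × 50 Newton starts for the equilibrium-oracle
search; the whole suite and all analysis drivers complete in well under a
minute on a laptop-class core.

## Limitations

Deterministic and non-spatial; no seasonality, no delays, no stochastic
forcing; a single predator species with ant-to-borer interaction only
through mass action; no economic layer on the management sweep. The model
admits no limit cycles at its equilibria's linearisations (all eigenvalues
real) and none were sought globally. Published tabulations of the two
asymmetric predation scenarios (α, δ) = (0.011, 0.01) and (0.01, 0.011)
interchange their μ\* values relative to the closed form
μ\* = ϕω/(kδ+θ+ω) − kα; the sweep reproduces the formula and flags the
discrepancy in its report rather than matching those two rows.
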