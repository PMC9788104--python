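# Methods

## Model

`reefrescue` simulates a metacommunity of `n = 20` reef patches arranged on
a larval-dispersal ring across a 3 °C spatial temperature gradient. Each
patch `a` carries three state variables: fractional coral cover `C_a`,
fractional macroalgal cover `M_a`, and the coral subpopulation's mean
thermal optimum `z_a` (°C), which evolves. The coupled dynamics are

    dC_a/dt = g_C(T_a, z_a, C_a, M_a) C_a + l_a F_a + (V/2) (∂²g_C/∂z²) C_a
    dz_a/dt = (z_i,a − z_a) l_a F_a / max(C_a, C_min) + q_a V (∂g_C/∂z)
    dM_a/dt = g_M(C_a, M_a) M_a

- **Coral fitness** `g_C = r_C (1 − α_CM M − α_CC C) − m_C`, with a Gaussian
  thermal performance curve `r_C = r_C0/√(2πw²) · exp(−(T−z)²/(2w²))` and a
  bleaching-like mortality `m_C = 1 − exp(−(T−z)²/(2w²))` applied only when
  `T > z`. Both kernels share the width `w`; a config switch
  (`exponent_convention="plain"`) replaces the `2w²` divisor with `w²` in
  both, since the source formulation is typographically ambiguous between
  the two.
- **Selection and load.** Directional selection is `q V ∂g_C/∂z` with the
  analytic gradient (mortality branch included only for `T > z`; the kernel
  is C¹ at `T = z`). The genetic-load term uses the analytic curvature
  clamped at zero from above, keeping the load a pure cost. The attenuation
  `q = max(0, 1 − C_min/max(C_min², C))` switches selection off at
  vanishing cover (`C_min = 10⁻⁶`); this shut-off is what makes a
  sufficiently deep collapse evolutionarily absorbing.
- **Dispersal.** `l_a = β Σ_b D_ab C_b` and the immigrant trait
  `z_i,a = β Σ_b D_ab C_b z_b / l_a` (resident trait where `l_a = 0`).
  Settlement is gated by free space `F = max(0, 1 − C − M)`.
- **Macroalgae** have constant rates, do not evolve and do not disperse;
  they matter purely as a spatial competitor whose occupancy can close a
  patch to coral recolonization.

## Dispersal network

Each patch connects to itself and four neighbours, all links of strength
0.2 (reef-row sums are exactly 1). Patches are indexed by thermal rank and
placed on the ring in a **folded** layout: even ranks ascend one arm, odd
ranks descend the other, so temperature is unimodal around the ring — the
hottest patches cluster on one side, the coldest on the other, and every
link spans at most four thermal ranks (≈0.63 °C). At the thermal extremes
each patch's neighbours are exactly its four thermally closest. A monotone
`rank` layout (hottest joined directly to coldest at the wraparound) is
available as an option; with it, cold-adapted immigrants permanently
gene-swamp the hottest patches across that seam, which suppresses the
hot-strategy restoration benefit and artificially pre-adapts the coldest
patches. The folded layout is the default because it matches the intended
geometry (thermally similar neighbours) without that artifact.

## Climate forcing

Per-patch baselines are evenly spaced over 25.5–28.5 °C (network mean
27 °C). Warming adds a network-uniform saturating trend
`ΔT (1 − e^{−t/τ})` with `ΔT = 5 °C` and `τ = 200/3` yr, so ~95 % of the
27→32 °C rise occurs within 200 years. Each year carries one network-wide
anomaly drawn i.i.d. from N(0, 0.3²) °C. Temperatures are piecewise-constant
within a year. One anomaly stream per replicate seed covers burn-in plus
monitoring; replicate *r* of every scenario shares that stream (common
random numbers), so scenario contrasts are not confounded by forcing noise.

## Restoration

Each targeted reef is paired with a nursery patch whose cover and trait are
externally imposed: cover `C_s = rate/β` (so the maximum potential
supplementation rate is `β C_s = rate`, realized input `β C_s F`), trait
`z_s = z_target + ΔZ` re-imposed at every year boundary from the target's
current mean trait. After the plan's duration the nursery cover is zero.
Strategies target the 4 hottest (`hot`), 4 coldest (`cold`) or 4 random
patches (`random`; redrawn per replicate by default). Nurseries receive no
larvae and are excluded from network means.

## Protocol

Replicates start at `C = 0.25`, `z = local baseline`, `M = 0.1`; burn in
for 1000 years (stationary mean temperature, anomalies on), then run 500
monitored years of warming with the intervention active. Burn-in
equilibration is checked as <10⁻³ cover drift per decade between the means
of the last two 50-year windows. Metrics: per-year medians with central
50 % and 80 % quantile bands (linear-interpolation quantiles) of
network-mean coral cover across replicates; median year-500 cover; and the
median across replicates of each replicate's minimum cover.

## Numerical integration

Within each year the ODE system (60 states) is integrated with LSODA at
`rtol 10⁻⁸ / atol 10⁻¹⁰`; the gene-flow term is stiff when cover is near
`C_min` (relaxation rates up to `l F/C_min`), which LSODA handles
implicitly. A fixed-step RK4 integrator is available as a reference and
agrees with LSODA to <10⁻⁴ cover over decade-scale tests. Yearly events
apply at integer-year boundaries in a fixed order: temperature switch,
nursery trait re-definition, supplementation on/off. Solver overshoot
within 10⁻⁸ of the cover bounds is clipped; larger violations trigger
re-integration of that year at 100× tighter tolerances. Covers are not
floored: extinction is reported when network mean cover < 10⁻⁴.

## Calibrated parameters

The demographic scales and competition coefficients are **calibrated
in-repo**, not literature-sourced; the study's qualitative claims pin them
tightly. Defaults: `r_C0 = 0.95`, `w = 1.25 °C`, `β = 0.01 yr⁻¹`,
`r_M0 = 0.09 yr⁻¹`, `m_M0 = 0.027 yr⁻¹`; bistable matrix
`α_CC = 1.09, α_CM = 1.3, α_MC = 0.865, α_MM = 0.8`; coexistence matrix
`(1.2, 0.6, 0.5, 2.0)`. The bistable matrix is certified by
`verify_regime`: stable coral-dominated (`C* = 1/α_CC ≈ 0.92`) and stable
macroalgae-dominated (`M* ≈ 0.875`, which excludes even fully adapted coral
since `α_CM M* > 1`) states separated by an interior saddle near
`(C, M) ≈ (0.44, 0.40)`.

What the calibration had to reconcile, and why these values:

- **Tracking capacity.** The selection response can sustain at most
  `q V (e^{−1/2}/w)(amp·comp + 1)` °C/yr of warming (`amp = r_C0/√(2πw²)`
  ≈ 0.30). At `V = 0.1` this tracks the initial 0.075 °C/yr warming after a
  modest cover decline (minimum network cover ≈ 0.26, recovery to ≈ 0.91);
  at `V = 0.05` it cannot, and the thermal lag runs away.
- **Deep collapse.** Once the lag passes the survival threshold, mortality
  exceeds growth even at full competitive release, cover free-falls by many
  orders of magnitude, and `q → 0` freezes adaptation: the no-intervention
  `V = 0.05` and `V = 0` networks end the projection below 10⁻⁴ cover.
  Macroalgae, released from coral competition, then occupy the patches and
  make the collapse permanent.
- **Trait-injection rescue.** Outplanting matters almost entirely through
  gene flow, whose forcing scales as `l F/C`: the nursery can move a
  target's thermal optimum only when the patch is nearly empty. At `w =
  1.25` the Gaussian growth tail is wide enough that a rescued,
  trait-boosted population regrows while still ahead of the local
  temperature; at `w = 1`, the yearly re-definition of `z_s` relative to the
  target's current trait ratchets the optimum ~3 °C above ambient faster
  than the population can anchor it, and rescue fails at low rates.
- **Closure clock.** Macroalgal occupancy of emptied patches (from a
  burn-in level of ~10⁻⁴–10⁻³ at ~0.06 yr⁻¹) closes non-target patches
  roughly 60–120 years after the crash. Hot-strategy targets crash
  earliest, engage the nursery earliest, and their recolonized populations
  seed one to two further patches down-gradient before closure; cold
  targets crash and rescue latest, and their spillover window is already
  shut. This timing, not any per-strategy asymmetry in the mechanics,
  produces the hot > cold ordering.

The calibrated defaults reproduce: extinction at `V = 0` (every replicate),
median year-500 cover ≈ 0.91 at `V = 0.1`, interim minima ≈ 0.2–0.3 % of
habitat under even the strongest intervention, hot-strategy medians
0.36–0.92 across rates 10⁻⁶–10⁻⁴ yr⁻¹, and cold-strategy medians
0.17–0.18. The cold ceiling sits ~0.001–0.002 above the published 0.18
because two constraints pinch: recovery above 0.9 at `V = 0.1` requires
`C* > 0.9`, and rescued cold targets also equilibrate near `C*`, giving
`4 C*/20 ≈ 0.18` as a floor for the cold-strategy network mean.

## What the generator emulates — and does not

The synthetic climate captures a spatial mean gradient, a saturating
network-uniform warming trend, and white interannual noise shared across
patches. It does not represent emission-scenario trajectories, spatially
heterogeneous warming, autocorrelated variability or marine heatwave
events; passing tests therefore demonstrate the model's internal logic
under idealized forcing, not skill on any real reef system. Likewise absent
by design: symbiont dynamics, acclimatization, genetic tradeoffs,
non-thermal stressors, outplant translocation mortality, macroalgal climate
response, and patch-size heterogeneity.

## Problem sizes

Desk-scale runs use 10 replicates per scenario (the full design specifies
50) and the 20-patch network; one 1500-year replicate integrates in ~1-2 s,
so the acceptance evaluation (7 scenarios × 10 replicates) completes in a
few minutes. The complete 180-scenario × 50-replicate grid is supported by
`run_grid` (resumable, one trajectory file per scenario) but takes hours on
one CPU.

## Known limitations

- The calibration is a point in a tightly pinched parameter region; several
  published contrasts sit within ~1 % of their thresholds there
  (notably the cold-strategy ceiling), so small parameter changes flip them.
- The rank-layout ring option reproduces the letter of a monotone thermal
  ring but produces gene-swamping artifacts at the seam (see above).
- LSODA determinism is exact for a fixed platform/build; cross-platform
  bit-identity is not guaranteed, though summary metrics are robust.
- With `V = 0`, trait dynamics reduce to pure gene flow; the convex-hull
  invariant on traits then holds only in the absence of nursery enhancement.
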