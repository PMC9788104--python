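# reefrescue

An eco-evolutionary simulation of coral reef metacommunities under climate
warming, built to ask a conservation question: when does outplanting
propagated corals — plain **demographic restoration**, or **assisted
evolution** with thermally enhanced colonies — actually improve reef
outcomes, and when does natural adaptive capacity make it unnecessary?

It is aimed at reef ecologists and conservation modellers who want a
transparent, tested implementation of the coupled cover/trait dynamics to
run restoration scenario experiments against.

## Model in brief

Twenty reef patches on a larval-dispersal ring span a 3 °C temperature
gradient. Each patch holds coral cover `C`, macroalgal cover `M`, and the
coral's evolving thermal optimum `z`:

    dC/dt = g_C·C + l·F + (V/2)(∂²g_C/∂z²)·C        (growth + settlement + genetic load)
    dz/dt = (z_i − z)·l·F/max(C, C_min) + q·V·∂g_C/∂z   (gene flow + selection)
    dM/dt = g_M·M

Coral growth is a Gaussian function of `T − z` with width `w`, with an
extra mortality cost when `T > z` (thermal bleaching); macroalgae compete
for space with constant rates. Larval input `l = β Σ D_ab C_b` comes from a
patch's four thermally-nearest neighbours, itself, and — for restoration
scenarios — a nursery patch with imposed cover `C_s = rate/β` and trait
`z_target + ΔZ`. Climate forcing combines the spatial gradient, a
saturating 27→32 °C warming trend over ~200 years, and annual network-wide
N(0, 0.3²) anomalies. The default competition matrix is certified
*bistable* (coral- and macroalgae-dominated alternative stable states); a
*coexistence* preset is included. See `docs/methods.md` for the full model
description, parameter values and calibration rationale.

## Worked example

```python
from reefrescue.study import scenario, headline_metrics

for V in (0.0, 0.05, 0.1):
    m = headline_metrics(scenario(V=V), n_replicates=3, base_seed=0)
    print(f"V = {V:<4}: median final cover = {m['median_final_cover']:.3f}, "
          f"median minimum = {m['median_min_cover']:.2e}")

m = headline_metrics(scenario(V=0.05, strategy="hot", rate=1e-5, delta_Z=3.0),
                     n_replicates=3, base_seed=0)
print(f"hot +3degC @ 1e-5/yr: median final cover = {m['median_final_cover']:.3f}")
```

prints

```
V = 0.0 : median final cover = 0.000, median minimum = 6.68e-321
V = 0.05: median final cover = 0.000, median minimum = 1.59e-08
V = 0.1 : median final cover = 0.920, median minimum = 1.88e-01
hot +3degC @ 1e-5/yr: median final cover = 0.882
```

Read: without supplementation, corals with no additive genetic variance
(`V = 0`) or low variance (`V = 0.05`) collapse to extinction during the
5 °C warming trajectory, while moderate variance (`V = 0.1`) lets them
adapt and recover to 92 % cover after a transient dip to ~19 %. Targeting
the four hottest reefs with thermally enhanced outplants (+3 °C, input rate
10⁻⁵ of reef area per year) rescues the low-variance network to 88 % final
cover — though its interim crash below 1 % cover is not prevented.

## Analysis pipeline

Numbered drivers under `analysis/` reproduce the study's experiments and
write tables to `results/`:

1. `01_certify_regimes.py` — equilibria/stability of both competition presets
2. `02_biological_scenarios.py` — V × β grid, no intervention
3. `03_intervention_strategies.py` — hot/cold/random × rate × enhancement
4. `04_duration_effects.py` — how long supplementation must be sustained
5. `05_effort_cost.py` — hectares and US$ for real-world reef areas

Each takes `--seed` and `--replicates`. A thin CLI (`reefrescue run|grid|
summarize|calibrate|cost`) wraps the same library for shell use.

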