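# ideovine

Model-assisted ideotyping of grapevine drought tolerance: derive whole-plant
hydraulic traits from raw phenotyping data, simulate plant dehydration to
leaf hydraulic failure with a soil–plant resistance–capacitance network,
screen large random trait-combination libraries for drought-tolerant
"elite" trait syndromes, and project seasonal hydraulic-failure risk over
multi-year weather series.

The package is aimed at plant ecophysiologists and breeders who want to ask:
*which combinations of measurable hydraulic traits let a vine survive longest
without water, and how would such ideotypes fare under a drier future
climate?*

## The model in brief

**Trait derivation.** Transpiration from a weighed pot is
`E = Δw / A_L / MW_w` and canopy conductance `G_c = K_G(T)·E/D`, retained
only at saturating light (PPFD > 800 µmol m⁻² s⁻¹). Stomatal closure follows
the sigmoid

```
G_c(Ψ) = g_sm / (1 + exp(−slp·(Ψ − P_gs50)))
```

with `Ψ_gs90 = P_gs50 − ln(9)/slp` the 90%-closure threshold. Leaf embolism
follows the vulnerability sigmoid

```
PEP(Ψ) = 100 / (1 + exp((slp/25)·(Ψ − P50_leaf)))
```

with `P12 = 50/slp + P50` and `P88 = −50/slp + P50`, fitted from optical
difference imaging of dehydrating leaves (cumulative percentage of embolised
pixels, PEP). Pressure–volume analysis of `−1/Ψ` against water deficit
yields π₀ (osmotic potential at full turgor), ε (modulus of elasticity) and
Ψ_TLP = π₀·ε/(π₀+ε); detached-leaf mass loss yields the minimum conductance
`g_min = E·P/D`. Hydraulic safety margins are `HSM_Px = Ψ_gs90 − Px`.

**Simulation.** The plant is a chain of conductances and capacitances —
three Van Genuchten soil layers → root → stem → leaf apoplasm (scaled by
1 − PLC/100) → leaf symplasm — forced by day/night blocks of temperature,
humidity and light. Transpiration `E = g·D_leaf/P_atm` combines stomata,
cuticle (g_min) and two boundary layers; leaf temperature follows a
linearised energy balance; net CO₂ assimilation is a Farquhar-type model
coupled to stomatal supply; embolism is irreversible and returns its water
to the stream. A dry-down ends at "100 PLC" in leaves (99.5% threshold):
the **time to leaf hydraulic failure** is the performance measure.

**Screening.** Random libraries draw the eight measured traits (G_cmax,
G_c90, g_night, g_min, π₀, ε, P50_leaf, PLC_slope) uniformly within the
V. vinifera range of the genotype table; an extended mode also perturbs
architecture parameters ±50%. The top-k survivors ("Elites") are clustered
(z-scores, complete linkage, elbow criterion) and their trait means compared
against the Vitis means.

The packaged genotype table (`ideovine/data/vitis_traits_synthetic.csv`) is
a synthetic stand-in constructed to be internally consistent and
physiologically plausible for Vitis; no measured accessions are
distributed.

## Worked example

```bash
python examples/screen_ideotypes.py
```

prints (seed 1, 2,000 combinations, desk scale):

```
library mean time to leaf hydraulic failure:  105.6 d
elite mean (top 200):                         130.1 d
reference Grenache:                           143.7 d
combinations outperforming Grenache:           0.15 %
elite trait syndromes (elbow method):         2 clusters
```

and a per-trait shift table in which the Elites show lower maximum
stomatal conductance (−6.5%), lower minimum conductance (−18.5%), earlier
stomatal closure (Gc90 14.6% less negative), more negative P50 (−5.9%) and
a much larger HSM_P12 — the drought-tolerant trait syndrome: spend less
water before and after stomatal closure, and keep a wider margin between
closure and embolism. Only a small fraction of random combinations beats
the best genotype, a measure of how well historical selection has already
optimised it.

Other examples: `derive_traits_from_drydown.py` (balance record → stomatal
traits), `fit_vulnerability_from_scans.py` (image stack → P50),
`seasonal_projection.py` (multi-year PLC risk). A thin CLI mirrors the
stages: `ideo synth|traits|simulate|screen|cluster|project|run` (see
`ideo --help`).

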