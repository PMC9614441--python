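# Methods

This note documents the models, parameter choices and numerical decisions
behind `ideovine`, and what the synthetic-data tests do and do not show.

## Trait derivation

**Balance analysis.** The weight rate is a centred difference over a
configurable window (default 30 min) to suppress balance noise; transpiration
is `E = (−dW/dt)/A_L/MW_w` with MW_w = 18 g mol⁻¹. Canopy conductance uses
the conductance-coefficient form `G_c = K_G(T)·E/D`. K_G is implemented as
its ideal-gas expression `K_G = (R/M_w)·T_K` (kPa m³ kg⁻¹), which is exactly
linear in temperature; with these coefficients the mass-unit route is
identical to the molar Fickian form `G_c = E·P/D`, so forward-generated and
inverted conductances agree to rounding. Both coefficients are arguments for
users who prefer published empirical linearisations. G_c is kept only at
saturating light (PPFD > 800 µmol m⁻² s⁻¹); samples with RH = 0 are invalid.

**Stomatal closure sigmoid.** `G_c(Ψ) = g_sm/(1+exp(−slp·(Ψ−P_gs50)))` with
slp > 0, so G_c → g_sm as Ψ → 0⁻. The 90%-closure threshold follows in
closed form, `Ψ_gs90 = P_gs50 − ln(9)/slp`. The fitter accepts either
predawn or midday water potential as the driver and records which was used
(`psi_kind`): the two differ by the soil-to-leaf drawdown, and the choice is
a property of the dataset, not of the fitter.

Pairing G_c samples with the sparse predawn readings is done by default
through the predawn-Ψ-versus-pot-weight relation rather than by
interpolating in time: both quantities reflect the same soil water store,
so the mapping transfers predawn readings to any sampling time without the
systematic bias that intraday soil drying imposes on temporal
interpolation. Samples whose differencing window straddles the dawn/dusk
light transition are excluded (default window 09:00–17:00).

**Pressure–volume analysis.** `−1/Ψ` is regressed on water deficit
(100 − RWC). The post-turgor-loss linear region is found by exhaustive
breakpoint search minimising the residual sum of squares of the linear fit,
ties broken toward more post-TLP points (on noise-free data every split at
or beyond the true breakpoint has zero RSS, so the tie rule selects the
true one). π₀ = −1/intercept at RWC = 100. The turgor pressure
(Ψ minus the extrapolated osmotic line) is regressed on water deficit over
the turgid region: its slope gives ε (MPa per unit RWC fraction) and its
zero crossing the TLP — on the standard model this reproduces
Ψ_TLP = π₀·ε/(π₀+ε) exactly. Points with Ψ ≈ 0 are excluded (−1/Ψ
diverges). At least five points beyond zero turgor are required.

**Minimum conductance.** The steady state of a detached-leaf mass-loss
record is the longest terminal window whose mass–time regression is linear
(R² ≥ 0.99 by default; at zero noise a much tighter threshold, e.g. 0.9999,
pinpoints the window free of the stomatal transient). `g_min = E·P/D`,
normalised to projected (one-sided) lamina area by default; the two-sided
convention is available via `area_basis="total"`.

**Optical embolism.** Consecutive scans are differenced; salt-and-pepper
outliers removed by a 3×3 median filter; the remainder thresholded
(default: mean + 3 SD of the difference image, or an absolute threshold);
embolism area is the suprathreshold pixel count and PEP the cumulative area
normalised by the sequence total. Frames stream through the pipeline one at
a time, so multi-thousand-scan stacks process in bounded memory. Each frame
carries a stem water potential interpolated from the psychrometer trace.

**Leaf-area allometry.** Power law (log–log least squares) versus a
through-origin linear model, selected by leave-one-out cross-validated
RMSE; both force zero area at zero length and the choice is recorded on the
model object.

## The hydraulic network

Topology: three soil layers → stem → leaf apoplasm → leaf symplasm, the
minimal chain consistent with the measured traits. Stem embolism is not
modelled — the failure criterion is leaf PLC. Per-leaf-area basis
throughout; potentials in MPa, fluxes in mmol m⁻² s⁻¹.

- **Soil.** Van Genuchten retention and Mualem conductivity
  (α in MPa⁻¹). The soil-to-root conductance of each layer is referenced at
  the initial (field-capacity) content, `k = k_sat·k_rel(Se)/k_rel(Se_fc)`:
  a freshly watered profile is hydraulically non-limiting and the layer
  cuts off as its conductivity collapses — the mechanism that ultimately
  ends the dry-down. Defaults (θs = 0.43, θr = 0.06, α = 300 MPa⁻¹,
  n = 2.1, k at field capacity 5×10⁴ mmol m⁻² s⁻¹ MPa⁻¹) were chosen once
  so that the reference genotypes' times to failure fall in the
  ~75–145-day range with the conservative cultivars near 145 days; they are
  a scenario property, shipped in `data/default_simulation.yaml` and fully
  overridable. The 180 mm of total available water (between −0.033 and
  −1.5 MPa) is distributed over the three layers by thickness fraction.
- **Plant storage.** The leaf symplasm capacitance follows from the
  pressure–volume relations (C_FT above the TLP, the larger C_TLP below,
  both from π₀, ε and a saturated leaf water content of 8 mol m⁻²). The
  stem capacitance (default 5 mol m⁻² MPa⁻¹) stands for all woody storage.
  Cavitation releases water from a finite apoplasm reservoir
  (default 2 mol m⁻², drained in proportion to PLC) into the stream.
- **Stomata.** Daytime `g_s = max(G_cmax·σ(Ψ_leaf), g_min)`, nighttime
  `g_s = max(g_night·σ(Ψ_leaf), g_min)` with σ the closure sigmoid; whether
  nighttime conductance is down-regulated by water potential is not
  empirically settled, so regulation is the default and a config switch
  (`regulate_gnight`) turns it off. Vapour transport combines g_s with leaf
  and canopy boundary layers in series.
- **Leaf temperature.** Linearised isothermal-net-radiation balance:
  ΔT = (a_SW·SW − λE)/(c_p·g_bH + 4εσT³). With closed stomata the leaf
  warms several degrees above air, raising the leaf-to-air VPD and hence
  the cuticular water loss — an important accelerator of the endgame. A
  flag (`energy_balance=False`) pins the leaf at air temperature.
- **Assimilation.** Farquhar Rubisco/RuBP-limited minimum with Arrhenius
  temperature scaling of Vcmax, Jmax, Rd, Kc, Ko and Γ*, solved jointly
  with the stomatal CO₂ supply in closed form (quadratic per limitation).
  Grapevine-typical Vcmax25 = 60, Jmax25 = 120 µmol m⁻² s⁻¹.

**Integration.** Backward-Euler solve of the three plant nodes with
transpiration linearised in leaf water potential (the sigmoid's steepness
otherwise destabilises explicit stepping), explicit soil stocks updated
from the same discrete fluxes, and adaptive sub-stepping whenever a
sub-step would move any potential by more than 0.2 MPa. Because storage,
soil and transpiration updates come from one discrete balance, water mass
is conserved to machine precision; an audit tracks the worst per-step
residual and the cumulative budget closure. The default step is 60 s;
screening and projection use coarser steps (900–1,200 s), which shift times
to failure by well under 1% (the dt-halving test). Failure ("100 PLC") is
PLC ≥ 99.5%, since the sigmoid never attains 100 exactly; the crossing time
is interpolated within the step. Potentials are floored at −12 MPa, far
beyond any failure point, purely as a numerical guard.

## Screening, clustering, shifts

Traits are drawn independently and uniformly within the V. vinifera range
of the genotype table (correlated sampling is deliberately not the
default: the screen asks what unconstrained recombination could achieve).
G_c90 is varied through P_gs50 with the closure slope fixed at the table
mean. The extended screen perturbs nine architecture parameters and the
canopy leaf-area scale within ±50% of defaults. Elites are the top k = 200
by time to failure, ties broken by sample index; evaluation is chunked and
order-independent. Clustering: z-scored traits (G_cmax, Ψ_gs90, g_min,
PLC_slope, P50, HSM_P12), complete linkage on Euclidean distance, number of
clusters at the largest second difference of the within-cluster sum of
squares over k = 1..10. Constant columns are dropped with a warning. Trait
shifts are percent deviations of elite means from the V. vinifera means.

Library sizes default to 50,000 (standard) and 20,000 (extended) in the
pipeline configuration; the test suite, examples and the acceptance script
run 1,000–2,000-member screens, which leave the selection statistics
noisier but preserve every qualitative contrast (elite > library mean, the
syndrome directions, the rarity of combinations beating the best
genotype).

## Seasonal projection

Years are strictly independent: on DOY 1 the soil is reset to field
capacity and PLC to zero. ("Re-saturation" is implemented as field
capacity: water above it would drain below the root zone on the model's own
assumptions.) Canopy leaf area ramps linearly from budbreak (DOY 120) to
full canopy (DOY 140, LAI 1.5), declines linearly from senescence onset
(DOY 200) to defoliation (DOY 290) — the senescence trajectory is not
otherwise constrained — and scales the canopy vapour coupling and
assimilation. Rain (less an optional interception fraction, default 0)
fills the top layer to field capacity, cascades downward, and any surplus
runs off; direct soil evaporation is neglected. Daily weather is
disaggregated to hourly forcing: a piecewise cosine for air temperature
hitting Tmin at 05:00 and Tmax at 15:00 exactly, constant absolute
humidity (RH capped at 99%), and a half-sine PPFD whose integral matches
the daily radiation (PAR = 45% of shortwave, 4.57 µmol J⁻¹). All complete
years run as one vectorised batch.

## Synthetic data

Every generator embeds its ground truth (parameters, noise settings, seed)
and is deterministic per seed. Noise models are the simplest consistent
with the instruments: Gaussian balance noise (default SD 0.5 g) and
per-frame salt-and-pepper scan noise.

The dry-down generator emulates a mini-lysimeter pot experiment: a
~3.5 L plant-available store dried over 25–30 days, weights every 20 min,
predawn water potential every 2 days. It deliberately idealises the pot
plant as tightly coupled (peat-like substrate with wide water release and
high conductivity, large plant conductances, negligible boundary layers,
leaf at air temperature): these are the conditions under which a stomatal
fit against predawn water potential is unbiased, and they are what the
round-trip recovery tests certify. Real pots violate them to varying
degrees (midday drawdown, substrate conductance collapse), so passing
round-trips demonstrate the correctness of the analysis chain, not the
absence of measurement bias in the field.

The optical generator toggles non-overlapping 3×3 pixel blocks so that
cumulative embolised area tracks the target vulnerability curve exactly;
the weather generator superimposes sinusoidal seasonality, Bernoulli rain
with exponential amounts, and optional linear warming/drying trends.

## Known limitations

- Stem embolism, xylem refilling, frost/heat mortality and fruit growth
  are out of scope; the failure criterion is leaf PLC only.
- The packaged genotype table is synthetic (no accessions are
  distributed); absolute times to failure are scenario-calibrated and
  should be read comparatively, not as predictions for named cultivars.
- The one-big-leaf canopy ignores within-canopy light and VPD gradients;
  boundary-layer conductances are constants, not wind functions.
- Uniform independent trait sampling ignores genetic linkage between
  traits; the extended screen treats architecture parameters as freely
  adjustable.
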