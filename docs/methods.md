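# Methods

This note documents the models, the numerical choices, and the synthetic
study design behind `vpdtraits`. It is written for a reader who wants to
know exactly what each derivation computes and what the test suite does and
does not demonstrate.

## Scientific setting

The package implements a trait pipeline for tropical tree communities
sampled along a vapour-pressure-deficit (VPD) gradient: three sites
(wet → moist → periodically dry), seven one-hectare plots, with species
sampled up to a basal-area cutoff in each plot. Optimality and hydraulic
theory make directional predictions for how community-mean traits should
shift toward drier air — stomata held more closed (lower ci/ca), higher
photosynthetic capacity (Vcmax25, Jmax25) and respiration, more sapwood
per leaf area (Huber value AS/AL), more negative turgor-loss point (TLP),
shorter stature, and — under the xylem safety–efficiency trade-off — lower
potential conductivity (Kp), narrower vessels, denser vessels and denser
wood. The pipeline derives each trait from raw measurements, aggregates to
basal-area-weighted community means, classifies the plot-ordered trends,
and grades 14 hypotheses as consistent / weakly consistent / inconsistent.

## Trait derivations

### FvCB model and A-Ci fitting (`aci`)

Net assimilation is A = min(Ac, Aj) − Rd with

    Ac = Vcmax (ci − Γ*) / (ci + Kc(1 + O/Ko))
    Aj = J (ci − Γ*) / (4 ci + 8 Γ*)

Kinetics default to the Bernacchi-style set (Γ*25 = 42.75, Kc25 = 404.9
µmol mol⁻¹, Ko25 = 278.4 mmol mol⁻¹, O = 210 mmol mol⁻¹) with simple
Arrhenius temperature responses (Ea: Γ* 37.83, Kc 79.43, Ko 36.38
kJ mol⁻¹); all constants are overridable through `KineticConstants`.
Measurements were taken at saturating light (PPFD 2000 µmol m⁻² s⁻¹), so
the default light model is J = Jmax; a non-rectangular hyperbola
(θ = 0.9, apparent quantum yield 0.3) is available via
`AciConfig(light_model="nrh")`.

Fitting minimizes Σ(A_obs − A_model)² jointly over (Vcmax, Jmax, Rd) at
leaf temperature with the hard `min` operator — no pre-assignment of
limitation states, which avoids the instability of state-by-state fitting.
The optimizer is bounded trust-region least squares (Vcmax ∈ [1, 300],
Jmax ∈ [1, 500], Rd ∈ [0, 10]) with an analytic Jacobian, started from a
deterministic five-point grid; starts stop early once two of them agree to
1e-6 in the objective, which keeps the fit independent of point order and
fast. Per-point limitation states (C / J / tie at 1% closeness) are
recorded; a curve with no electron-transport-limited point flags
`jmax_unidentifiable` rather than returning a silent number, and fewer
than 5 valid points is refused. Capacities are normalized to 25 °C by

    X25 = X(T) · exp[(Ea/R)(1/T_K − 1/298.15)]

with Ea(Vcmax) = 65.33, Ea(Jmax) = 43.54, Ea(Rd) = 46.39 kJ mol⁻¹
(simple Arrhenius; measurements sit at 30 °C, close enough to 25 °C that
peaked deactivation would be overfitting). Asat400/Asat2000 are the mean
of replicate 400-ppm readings and the 2000-ppm reading; Rd enters the
trait table from the darkened readings of the same leaves, not from the
A-Ci fit, mirroring the measurement protocol (the fitted Rd stays
available in `photo_params`).

### Isotopes (`isotope`)

Δ13C = (δ_air − δ_leaf)/(1 + δ_leaf/1000), and χ = ci/ca inverts the
two-endpoint mixing model χ = (Δ − a)/(b − a) with a = 4.4 ‰ (diffusion)
and b = 27 ‰ (carboxylation), δ_air defaulting to −8 ‰ with a per-record
override column. The linear model is transparent and exactly invertible;
records with χ outside [0, 1] are flagged, never clipped. Mesophyll and
post-photosynthetic corrections are out of scope.

### Hydraulics (`hydraulics`)

Kp follows Hagen–Poiseuille:
Kp = (π ρ_w / 128 η) · VD · d⁴ (VD in m⁻², d in m, η = 1.002e-9 MPa s,
ρ_w = 998.2 kg m⁻³, i.e. 20 °C water). The representative diameter d
defaults to the hydraulic mean (mean of d⁴, fourth root), which makes Kp
exactly the per-vessel Poiseuille sum per section area; `arithmetic`
mode uses the plain mean diameter (≤ the hydraulic value by Jensen's
inequality) and matches datasets that only recorded an average diameter.
The Huber value is sapwood area / leaf area in cm² m⁻², assuming the
de-barked twig cross-section is all sapwood, petioles excluded upstream.
Twig density is oven-dry mass over soaked volume.

PV curves are reduced by regressing −1/ψ on water deficit (1 − RWC) over
the post-turgor-loss tail. Candidate tails drop 0, 1, 2, … of the wettest
points (min 4 kept); the selected tail is the longest within 1e-9 of the
best R² — a strict "drop while R² improves" greedy can stall on a local
dip when a barely-pre-loss point is nearly collinear with the tail, so
all candidates are scored. π_o = −1/intercept (at RWC = 1); TLP is the
fitted line evaluated at the wettest retained point, the operational
point of departure from linearity. Fits with tail R² < 0.9 are flagged
failures. TLP ≤ π_o holds for every successful fit.

The daytime water balance
E/AL = 1.6 VPD_la Aarea / ((ca − ci) Patm) = Ks ΔΨmax (AS/AL) / h
is implemented as separate demand/supply/Fick's-law operations plus the
inversion for Aarea; the closure identity holds to machine precision by
construction and is verified over random parameter sets. ΔΨmax is a free
input (it is not measured by this kind of campaign); P50 and embolism
dynamics are out of scope.

### Optimality layer (`optimality`)

The least-cost prediction is χ = ξ/(ξ + √D), ξ = √(β(K + Γ*)/(1.6 η*)),
with D the VPD in Pa, K and Γ* converted to Pa at standard pressure,
β = 146, η* = 1 (the gradient spans < 1.5 °C of mean temperature).
Coordination (Ac = Aj at growth conditions with J = φ0·Iabs, φ0 = 0.085)
gives Vcmax = φ0 Iabs (ci + K)/(ci + 2Γ*), normalized to 25 °C. These
quantitative predictions feed **direction checks only** — the hypothesis
grading never asserts predicted trait magnitudes, because the theory
commits to signs, not values, at this scale.

## Community statistics (`stats`)

* **Outliers** — IQR rule, k = 1.5, type-7 (linear interpolation)
  quartiles; the mask flags, removal is a separate logged step, matching
  a protocol where verified extreme values are retained.
* **CWM** — mean = Σwx/Σw with species basal areas as weights; the SE uses
  the Kish effective sample size n_eff = (Σw)²/Σw² with an
  n_eff/(n_eff − 1) small-sample correction, so equal weights reduce
  exactly to the ordinary mean and SE.
* **ANOVA + letters** — weighted one-way fit; pairwise Tukey–Kramer tests
  on weighted group means with pooled weighted MSE and per-group n_eff;
  compact letters by insert-and-absorb, so groups share a letter iff
  their pair is non-significant (verified minimal against an exhaustive
  clique-cover oracle for ≤ 5 groups). The exact studentized-range
  quantile is cached per (α, k, df); pairwise p-values are optional
  because each one costs a numerical integral.
* **Variance partitioning** — three dummy-coded linear fits give R²(plot),
  R²(species), R²(plot+species); unique components [a] = R²(both) −
  R²(species), [b] = R²(both) − R²(plot), shared and residual [d] follow;
  raw fractions sum to 1 identically; adjusted mode applies the Ezekiel
  correction (small negatives possible, flagged mode).
* **SMA** — slope = sign(r)·sd(y)/sd(x), p-value from the Pearson
  correlation test.
* **PCA** — covariance-matrix SVD on centered, log10-transformed
  (Asat400, Kp, AS/AL, Vcmax25) but *unstandardized* data, so arrow
  length encodes trait variance; signs fixed by making each axis's
  largest-magnitude loading positive.

ANOVA/CWM run on the measured scale by default (transforms are registered
per trait and overridable); species values are two-stage means (leaves →
tree means → species mean), and ANOVA weights are species-level basal
areas, the natural reading of "basal area as weights" for species-level
replicates.

## Trend classification and grading (`harness`)

Plots are ordered by VPD. A trend is recognized iff (i) some driest-site
plot shares no Tukey letter with some wettest-site plot, and (ii) every
mid-site community mean lies between the wet-site and dry-site means
(site means, not every plot — one anomalous plot should not erase a
site-scale pattern). The label is `increase`/`decrease` when the plot
sequence is monotone in the observed direction, `slight …` when removing
exactly one plot restores monotonicity, and `no trend` otherwise.
Grades: label matches the expected direction → consistent; the `slight`
variant → weakly consistent; anything else → inconsistent. Hmax carries
no inferential statistics (census data — every tree is measured), so it
is classified on ordering alone and flagged. Vcmax25 and Jmax25 are
classified on site-scale community means: the A-Ci campaign measures one
individual per species per plot and is typically incomplete at some
plots, so plot-scale letters would test noise. Hypothesis 14 (Kp vs
AS/AL) is graded from the sign and p < 0.05 of the species-scale SMA,
separate from the plot-trend machinery.

## Synthetic study design (`synthdata`)

The generator emulates the sampling design, not just the numbers: 7 plots
in 3 sites with VPD 0.28 → 0.72 kPa; plot positions clustered by site
(fractions 0, 0.08 | 0.42, 0.50 | 0.84, 0.92, 1.0 of the wet→dry axis)
because plots of a site are a few hundred metres apart and share a met
station — VPD separates sites, not plots within a site; 12 species per
site (disjoint pools across sites, shared within), lognormal basal areas
drawn at the site level (σ = 0.6) with mild per-plot jitter (σ = 0.15);
3 trees per species, 3 leaves per tree, and one A-Ci individual per
species per plot.

Plot-level true trait means interpolate linearly in VPD between wet- and
dry-end values taken from the study conditions: χ 0.85→0.71, Vcmax25
22→46, Jmax25 38→91, Rd 1.7→2.4, Asat400 4.6→7.7, Asat2000 15.9→22.9
(µmol m⁻² s⁻¹), AS/AL 360→902 cm² m⁻², TLP −1.3→−1.6 MPa, Kp 29→59
kg m⁻¹ MPa⁻¹ s⁻¹, vessel density 45→70 mm⁻², deciduous individuals
2%→65%. Endpoints without printed magnitudes carry realistic values with
the observed direction: wood density 0.55→0.67, twig density 0.50→0.62
g cm⁻³, Hmax 45→18 m. Note the Kp increase is the *observed* trend — it
deliberately contradicts the safety–efficiency hypothesis, so the harness
must grade Kp inconsistent on correctly generated data. Vessel diameter
is emergent (implied by Kp and vessel density through Poiseuille), rising
a few percent across the gradient — the same "Kp trend driven by lumen
diameter" structure the classification should call out against the
hypothesized decrease.

Hierarchy of variation: species effect ~ N(0, (0.12·span)²) constant for
a species across its site's plots; tree effect ~ N(0, (0.06·span)²); plus
per-measurement noise (A-Ci noise 0.5 µmol m⁻² s⁻¹, spot 0.4, dark 0.15,
δ13C 0.25 ‰, RWC 0.005, vessel-diameter lognormal σ 0.2). Making the
interspecific layer twice the intraspecific one reproduces the
variance-partitioning signature ([b] > [a], shared dominant). A global
`noise_scale` multiplies every sd; at zero the generator switches to
deterministic vessel counts with the section area adjusted so realized
vessel density is exact, and pipeline-recovered plot CWMs reproduce the
configured means to 1e-6 — the closure test of the whole derivation
chain. Raw measurements are produced by the *forward* models (FvCB at the
protocol CO2 sequence with realized ci = 0.7·setpoint + jitter — a
plumbing stand-in for stomatal dynamics, not physiology; PV curves from a
linear-turgor osmotic model whose analytic turgor-loss point
π_o·ε/(ε + π_o) is recorded as truth and always included as a sampling
point; anatomy sections whose diameters are rescaled so the hydraulic-mean
Kp hits the target exactly).

What the generator does **not** emulate: seasonality and deciduous leaf
phenology dynamics, plot microclimate beyond the VPD axis, non-Gaussian
trait distributions, missing-data patterns, co-variation between traits
within species beyond the shared gradient, and instrument drift.
Passing tests therefore show that the pipeline recovers known structure
under realistic noise — not that the field study's numbers are correct.

## Problem sizes and numerics

Default problem sizes (84 A-Ci fits, 756 PV fits, 252 anatomy sections
per study; 100-seed Monte-Carlo for the end-to-end checks; 200 curves for
fit-recovery; 1000 parameter sets for the balance closure) were chosen so
each property is measured with comfortable margin while a full suite run
stays in the minutes range on one core. Determinism: every random draw
flows from one `numpy` Generator seed; identical (config, seed) gives
byte-identical bundles, and all outputs print at 6 significant digits.

## Known limitations

* The χ inversion ignores mesophyll drawdown and ternary corrections; a
  Γ*-aware variant would shift absolute χ slightly (directions are
  unaffected).
* Kp is potential, not measured, conductivity; the hydraulic-mean mode is
  exact for the Poiseuille sum but real sapwood conducts through a
  fraction of vessels.
* The TLP operational definition (line evaluated at the tail's wettest
  point) is grid-dependent; with sparse post-loss sampling it biases
  slightly dry (≤ 2% at the default 14-point design).
* Tukey–Kramer with Kish effective n is a pragmatic generalization for
  weighted unbalanced groups, not an exact finite-sample theory.
* The harness's "any wet/dry plot pair separated" significance rule is one
  reading of a qualitative criterion; the alternative (pooled site groups)
  is stricter and would demote borderline trends.
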