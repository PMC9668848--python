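# Methods

## Isotope arithmetic

Delta values (‰) convert to heavy-isotope atom percent through the fixed
reference ratios R_VPDB = 0.0111802 (¹³C/¹²C) and R_AIR = 0.0036765
(¹⁵N/¹⁴N). Enrichment is always expressed as atom % *excess* over the mean
of the four unlabelled baseline cores of the same field, matched per pool
(per fatty acid for PLFA). Negative excesses — possible for weakly enriched
pools under instrument noise — are retained and flagged in the QC report
rather than clipped: clipping would bias budget sums of low-enrichment
pools upward.

The FAME derivatization correction removes exactly one methanol-derived
carbon (δ¹³C = −29.3‰ by default); it is the algebraic inverse of the
one-carbon mixing model, so forward dilution followed by correction is an
identity to round-off. Carbon weights for group pooling are nmol × (number
of carbon atoms in the PLFA), i.e. molar carbon per fatty acid.

## Tracer budget conventions

* Subplot area is that of the 40 cm collar (π·0.20² ≈ 0.1257 m²); soil is
  sampled to 7 cm; bulk density defaults to 0.8 g cm⁻³.
* Tracer pool size = pool element mass × excess/100, in g excess isotope
  per subplot. The tracer mass is treated as small against the pool mass.
* Relative ¹³C excess divides by the *same subplot's* day-0 shoot
  enrichment (the initial fixed ¹³C differs between subplots); subplots
  with non-positive initial enrichment get missing relative values.
* Recovery fractions use day 1 for plants and microbes and day 5 for
  fauna, where those groups' enrichments peak. The ¹³C denominator is the
  subplot's day-0 shoot ¹³C pool size; the ¹⁵N denominator is the injected
  ¹⁵N mass (20 kg N ha⁻¹ equivalent at 98 atom %, scaled to subplot area,
  ≈ 245 mg ¹⁵N excess).
* AMF, actinobacterial and methanotroph PLFA pools have no published
  PLFA→biomass factor; their enrichment is reported but their biomass stays
  in PLFA units and no tracer pool size or recovery is computed for them —
  we do not invent conversion factors.

## Gas fluxes

The headspace model is linear: four points over 30 minutes cannot
constrain curvature and accumulation in a 1.2 L chamber stays near-linear
on that horizon. Flux = OLS slope × (V/A) × P/(RT), flagged when R² < 0.9
with a non-near-zero slope. The ~1.25 % headspace dilution per 15 mL sample
draw is ignored (known small negative bias). The last-point isotope value
is a two-pool mixture of ambient air closed into the chamber and
soil-emitted gas; the emitted gas's atom % is recovered by a single mass
balance using the chamber's own t₀ and t₃₀ concentrations (no Keeling
regression — only one point carries isotope data), and unlabelled-control
chambers provide the natural-abundance source value to subtract.

## Mixed models

One REML core fits y = Xβ + Zb + ε with variance components on the log
scale (Nelder–Mead), in two presets:

* **enrichment** — random site intercept, separate residual variance per
  sampling time (tracer variability shrinks strongly as enrichment decays);
* **biomass** — crossed site and time random intercepts, common residual.

If a random variance collapses toward the boundary, the model is refit
without it (heteroscedastic GLS) and flagged; the reduced fit is kept only
when its REML criterion is no worse. Fixed-effect intervals are Wald. In
the single-time, site-balanced limit the management estimate coincides
exactly with the plain two-group mean difference (the management contrast
is orthogonal to the site blocks). Drought effects use the log response
ratio of paired plots, each plot first averaged over all sampling dates
(the response trends are roughly parallel in time, and averaging stabilises
the ratio); per-management means and 95 % Wald intervals of predicted means
come from the same REML core with site as random intercept; Wald rather
than profile intervals are the default. Pairs with non-positive means are
dropped with a record.

## Community analysis

Hellinger-transformed abundances (fauna counts plus the four PLFA group
biomasses) feed Bray–Curtis dissimilarities, PCoA via Gower double
centring, and one-way PERMANOVA/PERMDISP. Negative PCoA eigenvalues are
reported and their axes excluded from the returned configuration (no
Lingoes/Cailliez correction by default); PERMDISP handles them by
subtracting the imaginary-axis contribution from squared centroid
distances. PERMANOVA permutes rows freely (the design's sites are crossed
with management, and no stratified scheme is imposed by default); PERMDISP
permutes least-squares residuals. All permutation p-values use
(1 + #{perm ≥ obs})/(1 + N) with N = 999 by default. Vector fitting
projects variables onto the first two axes and keeps those with p ≤ 0.05 —
the conventional criterion for retaining fitted vectors.

## The simulator

Tracer dynamics are linear first-order: x′(t) = M x(t) from a pulse at
t = 0, solved exactly with the matrix exponential. Linearity is an
assumption of convenience — it gives closed forms, exact mass conservation
(matrix columns sum to zero by construction) and testability; no saturation
kinetics are represented. Carbon and nitrogen use separate rate matrices
over a shared compartment list because the tracers travel different routes:
¹³C enters the shoot and drains through CO₂ efflux; ¹⁵N enters a soil
mineral-N compartment, is taken up by roots, translocated to shoots (which
therefore plateau), immobilised by microbes and drained by N₂O. A model is
rejected when any matrix column creates mass or when a compartment
receiving tracer has no path to an efflux.

Default rates and pools are a *calibration*, not ground truth: noiseless
shoot ¹³C enrichment ≈ 0.50 atom % excess at day 0 falling to ≈ 0.12 by
day 1; shoot ¹⁵N rising over ~2 days to a ≈ 5.5 atom % excess plateau;
microbial ¹³C peaking near day 1 and mesofauna near day 5; below-ground
relative ¹³C excesses of order 2–40 %. The ¹³C pulse defaults to 80 mg
excess per subplot (the fraction of a 250 mL 99 atom % ¹³C-CO₂ injection a
subplot's vegetation plausibly fixes); the ¹⁵N pulse follows from the
20 kg N ha⁻¹ dose. Microbial pool carbon is derived from the default PLFA
profile through the published conversion factors, so the pipeline's
PLFA-based biomass reproduces the model's pools exactly. Management and
drought enter as named multipliers on rate-matrix edges and pulse sizes;
the defaults make intensive management fix less ¹³C (×0.71) and allocate
less to AMF, and drought reduce plant-to-microbe transfer
(shoot→bacteria ×0.7, shoot→fungi ×0.85, shoot→AMF ×0.8) and the fixed
pulse (×0.9).

Observation noise is multiplicative lognormal on amounts, masses, counts
and flux magnitudes (CV 10 %), additive Gaussian on δ values (0.3‰,
IRMS-like), and lognormal on the per-plot ¹³C pulse (CV 15 %, photosynthetic
differences between subplots). The day-0 soil sample taken a few hours
after the ¹⁵N injection is represented as day 0 on the shared sampling
grid; sub-day sampling is supported but not the default.

What the generator does *not* emulate: spatial heterogeneity within plots,
plant growth and phenology over the chase, drought physiology (treatments
are phenomenological multipliers), chromatographic peak errors, and any
nonlinearity of uptake. Passing round-trip tests therefore demonstrates
the *accounting* is exact and the statistics calibrated — not that the
linear model captures real soil kinetics.

## Problem sizes used in validation

The validation suite uses the full 36-plot factorial at 6 sampling days;
rate re-estimation uses 50 simulated datasets; mixed-model coverage 200
datasets; PERMANOVA type-I calibration 500 null datasets at 199
permutations; effect-size detection 200 replications. These sizes give
Monte-Carlo standard errors comfortably inside the asserted calibration
bands.

## Known limitations

* Rate re-estimation is demonstrated for the two shoot outflow rates with
  the remaining rates held at their configured values; joint estimation of
  the full matrix is not identifiable from pool means alone.
* The chamber inversion assumes the emitted gas composition is constant
  over the 30-minute deployment.
* Fauna body length is a per-field mean, so within-field size variation
  collapses into the allometric coefficients; the shipped coefficients are
  documented placeholders of realistic magnitude, editable as CSV.
* Bulk soil organic matter is not tracked as a pool; recovery fractions sum
  below 1 partly because unmeasured pools (mineral N, dissolved C) hold
  tracer.
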