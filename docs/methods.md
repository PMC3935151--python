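# Methods

This note records the models, conventions, and numerical choices behind
`dielmat`, and what the synthetic generators do and do not emulate.

## Flux recovery from concentration series

A microcosm is an 11 mm mat core (area 9.503×10⁻⁵ m²) sealed in a 14 mL
vial with 4 mL site water (10 mL N₂ headspace); a flux chamber is a
1.5 L water volume over an open mat surface whose enclosed area is
site-specific and must be configured (`Geometry.chamber_area_m2` has no
default — an error tells the user to set it).

Amounts are recovered per compartment: headspace gases by the ideal gas
law n = x·PV/RT at the configured temperature and pressure (defaults
298.15 K, 1 atm — headspace sampling conditions are rarely reported, so
they are explicit configuration); liquid and chamber analytes as
concentration × volume. Net flux over a window is **endpoint
differencing** — amount at window end minus amount at window start,
divided by mat area — not a regression slope, because the quantity of
interest is accumulation between stated time points. Window edges are
linearly interpolated between samples, which makes flux exactly
additive over adjacent windows and antisymmetric under window reversal.

Sign convention throughout: positive = accumulation in the overlying
compartment (release from the mat), negative = uptake. Daytime DIC
fluxes are therefore negative.

Known bias: H₂ dissolved in the 4 mL liquid phase is neglected in the
headspace flux. At these volumes and H₂'s low solubility the error is
small, but it is a bias, not noise.

Replicate aggregation uses the sample SD (n−1); with one replicate the
SD is reported as 0 with n = 1 recorded. Treatment comparisons use the
unpaired two-tailed Student's t-test with a pooled variance,
significance at α = 0.05.

## The electron balance

Electron coefficients are configuration with two presets. The default
(`paper`) follows total-charge-state bookkeeping: acetate 8, formate 1,
propionate 13, H₂ 2, glycogen 24 per glucosyl, 4 e⁻ per fixed carbon.
Strict redox half-reaction bookkeeping would give formate 2 and
propionate 14; that alternative ships as the `redox` preset. Results
are therefore explicit about which currency they use.

The diel average of a day/night flux pair is (|day| + |night|)/2 — the
average magnitude of carbon moved per phase. Its SD defaults to the
arithmetic mean of the two phase SDs (`mean_sd`); quadrature
√(sd_d²+sd_n²)/2 is available and is the better choice when the phase
errors are independent, but the arithmetic mean is the more conservative
default for small-n flux data whose errors share systematic components
(same chambers, same analyzer).

Fermentation products accumulate at night only, so their diel value is
the night flux magnitude. The two summary statistics divide total (and
total − net) product electron flux by the **DIC-derived** fixed-carbon
electron flux. The glycogen storage row is reported for context but
enters neither percentage: glycogen-derived storage and DIC-derived
fixation estimate the same quantity, and the DIC measurement is far
better constrained (the glycogen phase differences carry replicate SDs
larger than their means). The glycogen-based denominator can be read
directly off the table by any user who wants it.

Uncertainty propagation offers three methods. `mean_sd` scales each
row's averaged SD by its electron coefficient and combines relative
errors of ratio statistics linearly (worst-case, correlated errors);
`quadrature` assumes independence throughout; `monte_carlo` resamples
every phase flux as an independent normal and recomputes the whole
table per draw (vectorized, deterministic given a seed, n ≥ 1000
draws). No standard propagation reproduces every published
percentage-row SD from published row SDs, which is why all three are
exposed and reported rather than one being declared canonical.

Report rounding is half-away-from-zero to 1 decimal, applied only at
the presentation layer; all computation is full precision. When 1-dp
inputs are fed in, derived cells are only trustworthy to the precision
those inputs support (e.g. 28.0 × 8 = 224.0, whereas an unrounded
28.03 would print 224.2); tests compare at input-supported precision.

## NanoSIMS isotope enrichment

Carbon arrives as C₂⁻ dimers. With atom fraction f and independent
pairing, P(¹²C¹²C) = (1−f)² and P(¹³C¹²C) = 2f(1−f), so the measured
count ratio m = ¹³C¹²C/¹²C¹²C equals 2f/(1−f) = 2r exactly, where
r = ¹³C/¹²C. The dimer correction r = m/2 is therefore exact for this
pair of ion species — the ¹³C₂ dimer affects neither numerator nor
denominator — and f = r/(1+r) recovers the atom fraction without
approximation. δ¹³C = (r/R_VPDB − 1)×1000 with R_VPDB = 0.0112372.
Detector dead-time and QSA corrections are out of scope; counts are
assumed already corrected upstream, and one input row is one spot's
total counts.

Significance testing is normality-gated: Shapiro–Wilk on each group,
and if either rejects at α = 0.05 the two-sided Wilcoxon rank-sum
(Mann–Whitney U, asymptotic with tie correction, so ties-heavy integer
data cannot error) replaces the t-test. The result records which path
was taken. A constant group is treated as failing normality. Outliers
are flagged by Tukey fences (1.5×IQR beyond the quartiles, quartiles by
linear interpolation — Tukey hinges would differ slightly on small n)
and always retained; below n = 4 nothing is flagged and a warning is
issued.

## Community profiles

Rarefaction is a multivariate-hypergeometric subsample (without
replacement) to a common depth, repeated (default 100×) to give
mean ± SD of observed richness, Chao1, and ACE per sample. Chao1 uses
the classic form S_obs + F1²/(2F2) and switches to the bias-corrected
form only when F2 = 0 (legacy-pipeline behavior); ACE uses the standard
abundance-coverage form with rare threshold 10 (configurable), γ²
clamped at 0, and falls back to Chao1 with a warning when every rare
individual is a singleton. Both implementations are cross-checked in
the test suite against scikit-bio's, which is used only as an oracle.

Expression ratios are (cDNA relative abundance)/(DNA relative
abundance) per taxon at a chosen level (default genus), computed on
full unrarefied libraries — the ratio is scale-free — and restricted to
taxa above 1 % DNA relative abundance; excluded taxa (including
cDNA-only taxa, which fail the DNA filter by construction) are returned
with reasons rather than silently dropped. Taxonomy strings are opaque
ordered labels; truncated levels pool into "unclassified".

## Synthetic generators

`ScenarioConfig` defaults are the study conditions themselves: net
(total) nighttime fluxes acetate 14.9 (28.0), formate 8.3 (10.0),
propionate 2.4 (6.6), H₂ 0.83 (1.77) mmol m⁻²; DIC −121.4 day /
+77.5 night mmol m⁻²; glycogen +21.2 day / −31.6 night mmol glucosyl
m⁻²; 6 replicates; 12 h/12 h photoperiod (hours since dawn; day =
[0, 12), night = [12, 24)). Treatments act as multiplicative factors on
the net fluxes: `disruption` uses the per-species total/net ratios so a
noise-free run expresses both table halves exactly; molybdate with
sulfate-free medium doubles H₂; DCMU multiplies H₂ by 0.2 and daytime
DIC uptake by 0.05; NH₄Cl is a factor of 1. These factors reproduce the
qualitative treatment responses of such experiments, chosen once; the
generator is a measurement emulator, not a mat model (no light field,
diffusion, or reaction network — an explicit non-goal).

Replicate noise is multiplicative log-normal on the per-replicate
production rate, parameterized by a CV with mean exactly 1
(σ² = ln(1+cv²), μ = −σ²/2), so fluxes stay positive and cv = 0 is
exactly noise-free. Product accumulation is linear over the night
window; the chamber DIC series is piecewise linear from a baseline of
6 mmol L⁻¹ (clamped at 0, relevant only for extreme configurations).
OTU tables draw a log-normal (σ = 1.5) abundance profile, multiply the
n_dominant most abundant OTUs' cDNA weight by the dominance factor, and
sample both libraries multinomially so column sums equal the requested
depths exactly. Spot counts are Poisson: λ₁₂ = mean_counts and
λ₁₃ = mean_counts·2r with r set by the group's target δ.

What passing tests therefore show: the analysis stages recover known
fluxes, percentages, δ values, and community structure from data with
the right noise families and exact conservation relations. What they do
not show: robustness to drift, nonlinear accumulation, solubility
partitioning, detector artifacts, chimeric or mis-clustered OTUs, or
any feature of real instrument output beyond these families.

## Problem sizes and determinism

Default test problem sizes — 10⁷-ion spot simulations pooled over 10³
spots, 10⁴ rarefaction draws, 10⁵ Monte-Carlo draws, 100-seed recovery
sweeps — were chosen so the estimators' own sampling error is well
below the tolerances being checked. Every stochastic operation takes an
explicit seed (numpy `default_rng`); identical seeds give bit-identical
outputs end to end, including written reports.
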