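# Methods

This note documents the models and numerical conventions behind `altidiv`,
the choices made where several defensible options existed, and what the
synthetic-data generator does and does not emulate.

## Census model and units

A census row is one measured stem with DBH (diameter at 1.3 m) ≥ 10 cm.
Rows below the threshold are filtered out (count logged); each row is
treated as one individual — multi-stemmed trees are **not** merged, because
stem-to-individual mapping is field-protocol specific and silently merging
would change every density-based quantity. Basal area is `π·(DBH/200)²` m²
from DBH in cm. All per-area quantities divide by the plot's surveyed
`area_ha`, never by the nominal 1 ha: PSP areas routinely deviate a few
percent from nominal, and the distinction matters once densities are
compared across plots.

Stems whose species id is missing from the attribute table are pooled into
an `unidentified` pseudo-species: they count toward abundance, diversity
and basal area, but are excluded from endemism and conservation
denominators (they cannot carry either attribute).

## Diversity and evenness

Shannon–Wiener uses natural logarithms throughout. Simpson's diversity is
computed in both common forms; the finite-sample ("unbiased")
`1 − Σnᵢ(nᵢ−1)/[N(N−1)]` is the headline `D1` because it pairs with the
concentration SI used by the Simpson evenness. Zero-count species never
enter sums, and accumulation runs over counts sorted descending so results
are independent of input order at float precision.

Simpson evenness divides by the diversity of the *most even integer
allocation* of the observed N individuals among the observed S species.
The naive alternative — dividing by the maximum of SI — is degenerate
(division by zero for a monoculture reference), and the continuous maximum
(all pᵢ = 1/S) is unattainable for integer counts when S ∤ N; the integer
allocation makes E_D = 1 exactly achievable and keeps E_D ∈ (0, 1].
Evenness is undefined (NaN) for S < 2.

## Dominance and the Importance Value Index

Relative density is area-normalised by default (counts/`area_ha` summed
within the group); a `pooled` mode using raw counts is available since both
conventions appear in the literature. Relative frequency is the species'
plot-occupancy normalised over **all species' occupancies** — this is the
component that makes each column sum to 100 and ΣIVI = 300; the raw
occupancy percentage (plots occupied / plots in group) is reported
alongside, as field papers quote both and the two differ by an order of
magnitude in species-rich communities. Within an altitude class, the
plots of that class are the frequency universe.

Altitude classes default to half-open 400/600-m bins
(0–400, 400–800, 800–1200, 1200–1800, >1800 m) with explicit per-plot
overrides, because field studies sometimes group a ridge-top plot with the
class below its nominal altitude.

## Conservation pooling

Red-List categories pool as CR(PE)/CR/EN → `≥END`, VU → `VU`,
NT/LC → `NT+LC`, everything else (DD, NE, EX, EW, unknown) → residual.
Percentages are reported against two denominators with explicit labels:
*evaluated* species (the three assessed pools) and all *identified*
species. Occupancy bins default to {1, 2–3, 4–5, 6+} plots and
total-abundance classes to {1, 2–10, 11–50, 51–200, >200} individuals;
both are configurable and validated (bins must partition, breaks must be
ascending).

## Climate

Saturation vapour pressure uses the FAO-56 curve
`0.6108·exp(17.27·t/(t+237.3))` kPa. Monthly VPD is the mean of SVP at
T_max and T_mean minus the actual vapour pressure, floored at zero — note
this T_max/T_mean averaging (not the FAO T_max/T_min convention) follows
the convention of the PSP climate tables this package cross-checks
against. Annual means are computed monthly → annual → long-term; annual
rainfall is the long-term mean of yearly totals.

The soil-water-deficit model is the Malhi–Wright monthly bookkeeping:
`SWD_t = max(0, ET_t − rain_t)` and the running cumulation
`CSWD_t = max(0, CSWD_{t−1} + ET_t − rain_t)`, reset toward zero by wet
months and never negative. ET defaults to the model's canonical fixed
100 mm month⁻¹; a per-month `et` column overrides it (no Penman–Monteith
implementation is attempted — ET estimation is out of scope). A signed-SWD
variant (keeping negative balances) is available behind a flag for
sensitivity checks. Drought indices take per-calendar-month means across
the reference years (default 1990–2018) and then the maximum month:
`SWD_max` and `CSWD_max`. `CSWD_max ≥ SWD_max` always.

A calendar month is 'dry' iff **both** (1) rain < ET in strictly more than
half the years, and (2) its mean SWD strictly exceeds 20 mm month⁻¹. Both
thresholds are strict: ties at exactly half the years or exactly 20 mm
fail, so the classification cannot flip on representation noise at the
boundary.

## Altitudinal trends

Ordinary least squares on altitude (degree 1 or 2) via statsmodels.
Confidence bands are pointwise 95% intervals for the *mean response* — the
interpretation matching dotted confidence curves on published trend
figures. The quadratic vertex is `x* = −b/(2c)`, classified min/max by the
sign of the curvature; both the curvature coefficient's p-value and the
overall model F-test p are reported, since "the quadratic is significant"
can mean either. Outlier exclusion is never automatic: callers pass
explicit indices, which are recorded on the fit, mirroring the practice of
declaring excluded plots in print. Fits on fewer than 12 points carry a
small-sample warning (a ten-plot gradient leaves 7 df for a quadratic).

## Constrained ordination

CCA follows the classical algorithm: proportions `P = Y/y₊₊`, chi-square
residuals `Q̄ᵢⱼ = (Pᵢⱼ − rᵢcⱼ)/√(rᵢcⱼ)` (total inertia = ΣQ̄², identically
the χ² statistic over the grand total), projection of Q̄ onto the row-mass-
weighted, weighted-centred constraint space via an orthonormal basis (SVD
with a relative 1e-10 rank cutoff, so collinear constraints reduce the
effective rank instead of blowing up), then SVD of the fitted matrix.
Squared singular values are the constrained eigenvalues.

Score convention, stated in the result metadata: species scores are the
column-standardised right singular vectors scaled by singular values
(scaling-2 style); site scores are weighted averages of the unit species
axes (LC scores also provided); biplot scores are weighted correlations of
each constraint with the LC axes. Disturbance enters as 0/1 indicators
with one level dropped (recorded) to avoid exact collinearity.

The permutation test permutes rows of X and uses the pseudo-F
`(CI/q)/((TI−CI)/(n−q−1))` with q the effective constraint rank;
`p = (1 + #{F* ≥ F})/(1 + n_perm)`, minimum 99 permutations, seed
mandatory. Forward selection greedily adds the candidate with the largest
conditional constrained-inertia gain, admitting it while a conditional
permutation p (candidate column permuted, selected columns held fixed,
statistic = the gain) is ≤ α; candidates adding no rank are skipped as
collinear.

Applying chi-square weighting to a response matrix of derived indices and
percentages is hard to justify, so a matrix of floristic metrics is
ordinated by the RDA variant by default: metrics range-scaled to [0, 1]
(so units are commensurable), covariance inertia, uniform row weights.
The raw-composition chi-square path remains available, and both modes are
labelled in the output.

## Synthetic data

The generator's defaults describe a ten-plot gradient at the altitudes
117–2132 m with nominal 1-ha plots (area 1.085 ha): per-plot richness
`E[S] = 130 − 0.045·alt` (SD 6), species drawn from a regional pool of 700
species whose altitudinal optima are uniform on −400..2600 m with a
±350 m occurrence window (optima extend past the physical gradient so the
candidate pool does not thin out and cap richness at the ends), log-series
abundances with shape 0.96 (≈5–8 thousand stems per census, roughly half
the species at ≤10 individuals, ~90% of species in ≤3 plots), lognormal
DBH (meanlog 3.0, sdlog 0.5, truncated at 10 cm), endemic probability
`0.70 − 1.2×10⁻⁴·alt` with a 4% exotic fraction below 400 m, and a convex
endangered-probability quadratic `0.20 − 2.4×10⁻⁴·alt + 1.6×10⁻⁷·alt²`.

Climate: sinusoidal monthly temperature seasonality (amplitude 0.9 °C)
around a sea-level mean of 27.2 °C with a 5.8 °C km⁻¹ lapse; DTR widening
with altitude (5.9 + 5×10⁻⁴·alt °C); annual rainfall 3900 − 0.9·alt mm
distributed over months with a pronounced February–March low, so plots
above roughly 1400 m satisfy both dry-month criteria in February (above
~1800 m also March) while low plots never do; Gaussian noise (0.3 °C,
20% of monthly rainfall). All draws come from one
`numpy.random.default_rng(seed)`, so output is byte-identical per seed.

What the generator does **not** emulate: real species identities or
phylogenetic structure, spatial autocorrelation within plots, temporal
census dynamics, interannual climate modes (ENSO-like persistence),
cloud-immersion effects, or soil gradients. Passing tests therefore
demonstrate correctness of the arithmetic and recoverability of planted
gradient structure under idealised sampling — not that real censuses meet
these assumptions.

## Problem sizes and determinism

Simulation-based checks use sizes chosen to make Monte-Carlo error small
relative to their tolerances: 1000 random count vectors for the diversity
oracle, 100 random 29-year series for the water-deficit oracle, 500 null
datasets at 99 permutations for permutation-test calibration (rejection
rate 0.05 ± 0.02), 999 permutations for planted-association detection, and
80 replicate gradients for slope recovery (the SD of the endemism-slope
mean over 80 replicates is ≈4% of the planted value, well inside the 10%
check). Every stochastic test and the acceptance script derive all
randomness from explicit seeds.
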