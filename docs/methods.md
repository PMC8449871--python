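# Methods

This note documents the models, parameter choices and numerical
conventions behind `emulstab`, and what the synthetic-data tests do and do
not demonstrate about real data.

## Droplet sizing

Micrographs are segmented by a global Otsu threshold; the droplet side of
the threshold is inclusive (`<=` for dark droplets), so a noise-free
two-level image — where Otsu returns the droplet intensity itself — still
segments correctly. Connected components (8-connectivity) are filtered by
equivalent-circle diameter `2·sqrt(area/π) ≥ 3 px` and circularity
`4πA/P² ≥ 0.6`; digitized disks can score slightly above 1, so the filter
is a lower bound only. Objects touching the image border are excluded
because their diameters are censored. These operators are deliberately
minimal: no watershed splitting of fused droplets, so the pipeline assumes
dilute, non-overlapping fields; heavily flocculated images would need a
different front end.

Pixel diameters convert to microns by the full-image-width calibration
(µm spanned ÷ pixels across). Size statistics are the arithmetic mean and
the Sauter mean d₃₂ = Σd³/Σd² (≥ the mean for every population, with
equality only when monodisperse — a property test). An optional seeded
subsample of 50 droplets mirrors the counting protocol of 50 droplets per
image; the default uses every detection. Published mean sizes are treated
as generic mean droplet sizes; both statistics are always reported since
the convention behind the printed values is not stated.

## Synthetic micrographs

Droplet diameters are drawn log-normal — the conventional family for
homogenized emulsions; the real distribution family of the study emulsions
is unknown, so this is a modeling assumption, not a measured fact.
Defaults: 1000 px spanning 250 µm (0.25 µm/px), 50 droplets per image,
ln-mean ln(12 µm) and ln-SD 0.25 (median 12 µm, spanning roughly 7–20 µm —
the range of the screened emulsions' average sizes), dark droplets
(intensity 60) on a light background (200), additive Gaussian intensity
noise of SD 8 clipped to the 8-bit range. Placement rejects overlaps with
a 1 px clearance (so rendered disks stay separate connected components)
and fails loudly after 100 retries per droplet; droplets are kept ≥ 2 px
off the border so ground truth is never censored. Disks are hard-edged
(pixel centers inside the radius), which keeps the flood-fill oracle and
the area-equivalent diameter exact to discretization (< 0.5 % for
diameters ≥ 20 px).

What passing tests show: the measurement chain (threshold → components →
circularity → scale → d₃₂) is unbiased to within 2 % on clean,
non-overlapping fields and 5 % at the default noise. What they do not
show: robustness to uneven illumination, out-of-focus droplets,
flocculated clusters, or polydispersity beyond the log-normal family.

## Flow curves and the yield value

The continuous phases behave as plastic (yield-stress) fluids. The
synthetic generator uses the Herschel–Bulkley law σ(f) = τ₀ + K·f^n
(τ₀ ≥ 0 Pa, K ≥ 0 Pa·s^n, 0 < n ≤ 1 shear-thinning), sampled on a 30-point
log grid over the oscillatory sweep range 0.05–500 Hz, with additive
Gaussian stress noise (default 0.05 Pa) clipped at zero.

The yield value τy is defined operationally as the stress at the minimum
sweep frequency — the direct curve reading this analysis uses — with two
alternatives: a plateau estimate (median stress over the lowest frequency
decade, ≥ 3 points) and the τ₀ of a bounded Herschel–Bulkley fit
(τ₀, K ≥ 0, 0 < n ≤ 2; initial values from the curve's endpoints). For a
true HB fluid the point reading overshoots τ₀ by exactly K·f_min^n, which
is asserted in tests; at the default parameters this is ≈ 2 % of τ₀.
Frequencies stay in Hz as swept; no rad/s conversion is applied, so τy is
literally "stress at the lowest sweep frequency". Yield-value units are
Pa (the study table prints "Pa s", presumed a typo for a stress).

## The coded-factor models

Factors are coded 2·(x − midpoint)/range so lows map to −1, highs to +1,
midpoints to 0; coding and decoding are exact inverses (property test).
The bundled 24-run design (21 vertices + 3 center points in 3 blocks) is
shipped verbatim; no design-construction algorithm is included. Blocks
enter every model as sum-to-zero fixed-effect contrasts, which makes the
intercept the grand mean and lets predictions at a coded point omit the
block terms; R² is also reported for a refit without blocks since the
convention behind published R² values is not stated (the with-blocks
value is what matches them).

Responses: size at T0 and T5 (µm), the recomputed variation rate (%), and
the ordinal creaming class 1–5. The class is modeled by OLS after its
power transform like the others — statistically crude for an ordinal
scale, but it is the procedure this analysis defines.

Default term sets per response follow the published model summaries. The
source table's interaction rows are typographically corrupted (a
duplicated row, values that match no refitted coefficient under any term
set), so the sets are configurable; the defaults were fixed by refitting:
the size-at-T0 set {A–E, AB, AE, BC, CE, DE} reproduces every published
coefficient to printed precision, the variation-rate set
{A–E, AE, BC, BD, CE, DE} best matches its published column, and the
creaming-class set {B, D, E, BE} follows the screening narrative (D
dominant, then E, then the starch×time interaction, with B retained for
hierarchy). When an interaction is included its parent main effects are
added automatically.

**Box-Cox scan.** λ runs over [−2, 2] in 0.01 steps on the normalized
scale y^(λ) = (y^λ − 1)/(λ·ġ^(λ−1)) (ġ·ln y at λ = 0, ġ the geometric
mean), minimizing the residual SS of the response's own model matrix
(chosen terms + blocks) — the same matrix the model is fit on, which is
how DoE software presents the diagnostic. The named transform is the
canonical member ({1: identity, 0.5: sqrt, 0: log10, −0.5: inverse-sqrt})
nearest the optimum when within ±0.25 of it. With only ~10 residual
degrees of freedom the SSE profile is flat near its optimum, so
`lambda_best` should always be read alongside the name: on the bundled
data the T0 response's optimum is λ = 0.27 with both the log and
square-root families inside the 95 % likelihood-ratio interval — the
naming rule reports sqrt while the log transform (used by the default
fit) is statistically indistinguishable from it.

**Fit statistics.** OLS via statsmodels; R²_adjusted with model degrees of
freedom; R²_predicted = 1 − PRESS/SST with PRESS from the closed-form
leave-one-out identity eᵢ/(1 − hᵢᵢ), verified in tests against explicit
refit-without-row-i predictions. Rank-deficient term sets raise an
aliasing error naming the collinear columns.

**Effect screening.** Effects (never the intercept or block contrasts) are
ranked by |t|; the plain limit is the two-sided t critical value at α
(default 0.05) and the Bonferroni limit the one at α/m with m the number
of screened effects. Effects at or above the Bonferroni limit are
"highly significant", between the limits "significant". Under a pure-noise
response the familywise rate of Bonferroni exceedances stays below α
(500-simulation check).

## Micro-stress and the creaming index

The droplet micro-stress is taken linear in diameter, σ = k·d. The ten
bundled (diameter, stress) pairs are consistent with a single slope to
within 0.8 % relative residual, which is the empirical justification; the
default k★ ≈ 32.5 Pa/m is the least-squares slope through the origin of
those pairs, recomputed at call time. Physically k lumps the buoyancy
contrast Δρ·g with a geometric prefactor; the pairs cannot separate the
two, so k is exposed as a single parameter. The creaming index
CI = τy/σ(d) is kept real-valued and rounded only for display (the
published table mixes integer and thousands-scaled presentations). ADS is
the Sauter mean of a droplet set, LDS its maximum observed diameter (no
percentile definition exists for "largest"); CI_ads ≥ CI_lds always, and
their ratio equals LDS/ADS exactly.

The stability screen keeps emulsions with size variation strictly below
12 % and creaming class ≥ 3; the boundary semantics (12.0 % excluded,
class 3 included) follow the rule's wording.

## Degenerate inputs and numerical choices

Featureless images yield an empty detection list, not an error. Empty
droplet sets, non-positive diameters, empty flow curves, non-positive
responses under log/root transforms, and out-of-range coded points raise
typed input errors. The Box-Cox objective's λ = 0 limit is implemented
explicitly and is continuous to ~1e−6 relative (tested at λ = ±1e−6).
Herschel–Bulkley fits are bounded (τ₀, K ≥ 0, n ≤ 2) so τ₀ estimates sit
at 0 rather than going negative for yield-free fluids. All generators are
deterministic under a fixed seed, and the pipeline writes byte-identical
reports for identical config + seed (the report records version, seed and
a config hash).

## Problem sizes

The test suite and acceptance script use 1000² px micrographs with 50
droplets (10 seeds per noise level), 100 noisy flow curves for the τ₀
recovery study, and 500 null simulations for the screening-rate check —
sizes at which the Monte-Carlo margins in the assertions are comfortably
resolved while a full run stays in the tens of seconds.
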