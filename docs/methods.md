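# Methods

## Data model

All statistics run off an `AbundanceTable`: a taxon × group matrix with three
measures per group — N (total items), V (summed item volume, mm³) and Freq
(number of predators whose stomach contained the taxon). Groups are strata
labelled `species|site[|size_class]`, plus one pooled `environment|site`
group per site, mirroring a design in which benthos cores, nekton sweeps and
zooplankton filter samples are pooled per site into a single availability
sample. Records carry a closed habitat-class vocabulary (benthos, nekton,
zooplankton, terrestrial), a digestion flag and a non-prey flag.

Non-prey items (sloughed skin, plant matter, stones) are retained as records
but never enter abundance tables or proportions. Items of trap-attracted taxa
(anurans) that show no signs of digestion can optionally be dropped
(`drop_trap_suspect`, default off) to guard against in-trap ingestion in
baited-funnel-trap studies.

### Denominator convention

Items too digested to identify are kept under the taxon `Unidentified` but
excluded from proportion denominators by default (a flag includes them).
Published per-taxon percentages in this kind of table are often inconsistent
about whether unidentified material is in the denominator; excluding it is
the reproducible, documented choice here, and every statistic in the package
(including the acceptance numbers) uses identified-prey denominators.

## Prey volume

Item volume is estimated from linear calliper measures as an ellipsoid,
V = (4/3)π(L/2)(W/2)(H/2). When only length and width are measured, height
defaults to width (prolate spheroid) — a documented convention, since the
number of axes actually measured per item varies between datasets. Volume
profiles are available, but all selection statistics default to the count
basis, matching how diet tables of this kind are reported.

## Diversity

Simpson's index of diversity is `1 − Σp²` (default), with the inverse form
`1/Σp²` also exposed because the two are routinely conflated in the
ecological literature (the inverse form is sometimes printed where a [0, 1]
index is described). Shannon diversity is `−Σ p ln p` (base e default; 2 and
10 switchable). Zero-proportion taxa contribute nothing to either index, so
padding a profile with absent taxa never changes a value.

## Electivity and selection inference

E* = (r − p)/(r + p − 2rp). Endpoints are exact: +1 for a taxon eaten but
absent from the environment, −1 for one available but never eaten; E* is NaN
when r = p = 0, and the result is clamped to [−1, 1] against float round-off
at the endpoints. E* is not computed for taxa whose total dietary count,
summed across both predator species at the site, is below 10 (configurable;
the basis can be switched from item counts to stomach frequencies — counts
are the default because frequency-based thresholds contradict which taxa
carry reported E* values in tables of this kind).

Significance follows the classical resource-selection recipe: a chi-square
goodness-of-fit test of observed diet counts against expected counts
`n·p_i`, with the availability proportions renormalized over the tested taxa
so expectations sum to n; taxa with zero availability are dropped from the
test (their selection is already read from E* = +1). Pearson residuals
(O−E)/√E are reported per taxon, and the statistic equals the sum of their
squares. Simultaneous 95% Bonferroni (Neu-method) intervals
`p̂ ± z_{1−α/(2k)}·√(p̂(1−p̂)/n)` on the usage proportions, clipped to
[0, 1], give per-taxon verdicts: preferred when the (renormalized)
availability falls below the interval, avoided when above, proportional
otherwise; a never-observed taxon has the degenerate interval [0, 0].

## Niche overlap and null models

Pianka's symmetric overlap `O_jk = Σp_ij p_ik / √(Σp_ij² Σp_ik²)` is computed
on count-basis diet profiles over the union of taxa in the site table;
taxa present only in the environment contribute zero to every term and so
do not affect the value. Significance uses randomization null models in the
RA1–RA4 family: each iteration randomizes both species' utilization vectors
and recomputes the overlap. RA3 (permute the observed proportions among all
categories; retains niche breadth, destroys zero structure) is the default
with 1,000 iterations, matching the long-standing convention of null-model
software for this index. RA1 redraws all entries uniformly; RA2 redraws only
non-zero entries; RA4 permutes non-zero entries among non-zero positions.
The reported 95% interval is the 2.5th–97.5th percentile band of the null
distribution — it describes the null model, not the sampling error of the
observed index — and both tail probabilities use the add-one permutation
convention p = (#{null ≥ obs} + 1)/(n + 1), which is a valid, conservative
p-value and can never be exactly zero.

## Size classes and anurophagy

The default size-class scheme is small 30–52, medium 52–72, large ≥72 mm
SVL, with half-open intervals assigned upward (52.0 mm is medium) — a fixed
convention where a printed range like "30–52" is ambiguous. Per-size-class
overlap compares like classes across species (small vs small, …). SVLs below
the scheme are labelled `unclassified` with a warning rather than silently
binned. Anurophagy is the ratio of anuran items (taxon `Anura`, or
`Anura:<subtype>`) to all identified prey in a group, with an optional
record-level breakdown by anuran category (non-congeneric tadpoles, eggs and
adults vs congeners, i.e. potential cannibalism).

## Synthetic data

The generator emulates the study design: per site a multinomial
environmental sample from a true availability distribution (default totals
matching the packaged tables, 2,873 and 1,723 items); per predator an SVL
from a truncated normal (means 62/45 mm for the larger/smaller species), a
negative-binomial stomach total (dispersion k = 0.8 by default — strongly
overdispersed, because in real tables a few stomachs dominate the counts of
swarming prey such as cladocerans and tadpoles), taxa multinomial from the
group's true utilization, 5% empty stomachs, and non-prey contamination at
roughly the rates seen in real samples (skin 15%, plant 14%, stones 1%).
`paper_like_config()` sets availability, utilization, predator numbers and
items-per-stomach means to the packaged tables' observed values, so the
synthetic world statistically resembles the study.

What the generator does not emulate: digestion-driven detectability
differences between taxa, within-stomach taxon clumping beyond the
negative-binomial total, seasonal or pond-level heterogeneity, and
measurement error in linear measures. Passing recovery tests therefore shows
the estimators are consistent under multinomial sampling, not that field
data meet those assumptions.

## Problem sizes and numerical choices

Null-model runs default to 1,000 iterations; calibration tests use 2,000
multinomial replicates (chi-square type-I error) and a ~500-replicate
uniformity check of null-model p-values — sizes at which the binomial noise
on a 5% rate is well inside the asserted bands. Report tables round half
away from zero at 2 decimals. All randomness flows through
`numpy.random.Generator` seeds; identical config + seed reproduces report
bundles byte for byte.

## Known limitations / unrecoverable published values

Recomputing from the printed count tables reproduces the electivity worked
examples exactly and the two site overlaps to within 0.01 (0.496 vs 0.491,
0.966 vs 0.965 — the residual gap is consistent with the authors having used
a slightly different category resolution, e.g. subdividing anurans). The
printed Shannon (2.31/2.55/2.58/1.64) and Simpson (0.68/0.28) values, the
χ² residual columns, the anuran-row E* values and the size-class overlaps
are **not** recoverable from the printed counts under any standard variant
tried; the package implements the standard formulas and treats those printed
numbers as artefacts of unstated conventions or inputs that were never
published. Sex-stratified and per-pond analyses are out of scope.
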