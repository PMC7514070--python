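# Methods

This note documents the statistical model behind `dendrosim`, the choices
made where the design was genuinely open, and what the synthetic fixtures
do and do not demonstrate about real data.

## Prewhitening and the parameter panel

Dendro-provenancing relies on year-to-year (high-frequency) growth
variability; medium- and low-frequency trends are removed by
autoregressive prewhitening. For each raw series of length *n*, candidate
AR orders *p* = 0..min(⌊10·log₁₀(n)⌋, n−1) are fit by Yule–Walker on the
demeaned series with divisor-*n* autocovariances (statsmodels
`yule_walker(method="mle")`), and the order minimizing
AIC(p) = n·log(σ̂²_p) + 2p is kept. The residuals are the one-step-ahead
innovations, defined from index *p* onward — each residual series
therefore starts `ar_order` years after its raw series — and are
re-centered so their mean equals the raw-series mean, the residual
chronology convention that keeps series on comparable levels. Only the
yearly cross-sectional means and SDs are consumed downstream, which are
translation-consistent under either centering convention; the choice is
recorded here so both variants are reproducible by adjusting the returned
residuals.

The parameter panel aligns all residual series of all sites by calendar
year. The common period is the maximal consecutive range in which *every*
site has at least `min_replication` (default 15) residual values per year;
holes inside a site's qualifying range raise an error rather than being
imputed, because the pipeline assumes gap-free measured series. Yearly
SDs use the n−1 denominator. Note that AR trimming can shorten the common
period below the raw overlap: a 64-calendar-year overlap with a maximal
selected order of 1 yields a 63-year panel. The panel length is always
derived from the data, never hard-coded.

## Covariance-preserving signal generation

The joint matrix `M = [rmv | ln(rsd)]` is modelled as multivariate normal
(SDs are log-transformed first, since yearly residual SDs are
right-skewed and a log-normal law fits them better). With `μ` the column
means and `Σ` the sample covariance of `M`, the pseudo panel is

```
X = μ + Z (E Λ^{1/2})ᵀ ,   Σ = E Λ Eᵀ,
```

where `Z` is an `n_years × 2S` standard-normal draw matrix that is
**empirically standardized** before colouring: columns are centered,
orthogonalized by an SVD rotation and scaled to unit sample variance.
After this step the *sample* covariance of `X` equals `Σ` exactly (up to
floating-point rounding), not merely in expectation — so all simulation
repetitions realize the same set of site signals and the correlation-matrix
delta Δ{pmv−rmv} sits at the 10⁻¹⁵ level in every repetition. The
standardization requires `n_years > 2S`; a plain (non-standardized)
sampler is available via `empirical=False` and in that mode the sample
covariance converges at the usual 1/√n rate. Eigenvalues below
−10⁻⁸·λ_max are rejected as non-PSD; tiny negative eigenvalues above that
tolerance are clamped to zero, which also admits rank-deficient Σ. The
eigendecomposition square root is used rather than Cholesky precisely to
tolerate semi-definite input.

Yearly draws are independent across years: the signals emulate AR
*residual* chronologies, whose residual autocorrelation is negligible by
construction. Any true year-to-year dependence left after prewhitening is
not modelled; neither is temporal variability of the between-site
correlation structure (one Σ governs all 1000 pseudo years).

## Pseudo series, partitions, object chronologies

A pseudo series (ps) samples `N(pmv_t, psd_t)` over the full timeline
(default 1000 years). Partitioning into pseudo historical series (phs)
draws lengths from the empirical pool with replacement until they sum to
≥ the timeline, cuts forward from year 1, truncates the final partition
to the remaining years and discards it when shorter than 50 years. Kept
partitions plus the discarded tail tile the timeline disjointly. The
cutting direction (forward from year 1) is a convention; only the
tail-discard rule interacts with it: the discarded years sit at the
recent end of the timeline, which is why late years accumulate coverage
more slowly during dataset generation.

Pseudo object chronologies (poc) average 6 ps yearwise before
partitioning, emulating building chronologies that are themselves means
of several series. At on-site ratio osr < 1, the off-site donors are
drawn uniformly and independently from the other S−1 signals; at
osr = 4/6 the two off-site ps may come from the same donor. Both choices
are the maximally non-informative reading of "off-site admixture" and are
kept in one place (`_object_mean_values`) for sensitivity variants. Each
poc's nominal label is the on-site signal regardless of osr — a
classification is "correct" when the nominal label matches the pref's
initializing signal, since contamination is defined by origin of the
nominal signal.

Generation repeats whole draw-and-partition rounds per site until every
year is covered by `target_replication` (default 30) records, keeping the
overshoot — totals therefore vary between repetitions. Years near the end
of the timeline accumulate coverage more slowly (they are covered only
when the final partition survives the tail discard), which the coverage
loop handles automatically; a guard aborts with a diagnostic if a
degenerate constant pool can never tile the tail.

## The constructor

Initial prefs are per-site means of 30 fresh ps restricted to the most
recent 150 years of the timeline, mimicking living-tree chronologies that
are extended backward. The placement is a modelling choice recorded in
`ConstructorConfig`. The initial chronology counts as **one** contributor
(weight 1) in the pref mean and replication, not as 30 series — per-run
mean replications near 2 for sparsely growing prefs are only possible
under this convention.

Matching is one-nearest-neighbour on the t statistic of the Pearson
correlation at the candidate's fixed calendar position (cross-dating is
assumed correct; no offset search). Overlap must reach 50 years;
zero-variance overlaps are skipped; `t` at |r| = 1 is capped at 10⁶ to
preserve ordering without infinities; exact ties (probability zero in
continuous data) break to the lowest pref index for determinism. Runs are
batch-synchronous — all candidates are scored against the prefs as frozen
at the run's start, and all acceptances are applied together — and
classifications are final: members are never re-scored against the grown
prefs. Pref values are defined for any year with ≥ 1 contributor; no
minimum replication is imposed on the pseudo references themselves.
Termination is guaranteed because every continuing run classifies at
least one candidate from a finite pool. Runs that classify nothing are
not logged; the "number of runs executed" is the number of productive
runs, so a repetition in which the first scan finds no match reports 0.

## Evaluation conventions

* Pref *length* is the count of covered years (identical to the span
  under contiguous growth).
* *Mean replication* is the mean per-year contributor count over covered
  years.
* *Contamination* of a pref is the percentage of members whose site (or
  contrast group: elevation band, coarse elevation with medium+low
  merged, watershed) differs from the initializing signal's group.
  Empty prefs report 0% with an `empty` flag so per-run tables stay
  rectangular.
* Per-run trajectories are cumulative (all members classified up to that
  run), which makes them monotone in membership.
* Multi-repetition per-run statistics (95th-percentile contamination,
  median length, median mean replication) are computed only over the runs
  executed in **every** repetition. The 95th percentile uses linear
  interpolation between order statistics (`numpy.quantile` default).
* Length categories: a pref that attracted zero members falls in category
  "0" even though its initial chronology is 150 years long; otherwise
  categories are 1–333, 334–667, 668–999, and full length. Attractor
  categories bin the member count (0–100, 101–500, 501–1000, >1000).
* Classified and correct percentages use the denominators
  classified/generated and correct/classified; with nothing classified
  the correct percentage is reported as 0.

## Synthetic fixtures

The fixture module emulates the real inputs: S sites in elevation-band
blocks whose standard-normal signals follow a block correlation design
(defaults r ≈ 0.6 within, 0.25 between blocks — chosen as a realistic
level of between-site similarity for a temperate conifer network); trees
mix the site signal with idiosyncratic noise at a within-site correlation
of 0.5; an AR(1) filter (coefficient 0.5) injects the persistence that
prewhitening removes; widths are `base·exp(scale·value)`, the standard
lognormal positivity assumption. Watershed labels cut across elevation
blocks so the two contrasts are not confounded. The length pool is a
truncated lognormal (minimum 50, median ≈ 70 years, matching the typical
range of historical series).

What passing tests on these fixtures show: the covariance transfer, the
partition algebra, the constructor mechanics and the evaluation
conventions are correct, and classification behaves as theory predicts at
the extremes (perfect separation for orthogonal signals, collapse at
between-site correlation 0.95). What they do not show: quantitative
contamination levels for any real region. The fixture's block-structured
signals are cleaner than real site networks — classification rates on the
fixture are substantially higher than a real dataset would yield — so the
acceptance report's Table-style numbers characterize the fixture, not any
real study area. Real analyses should feed measured RWL data through the
same pipeline.

## Problem sizes and numerical choices

The shipped test-suite and acceptance scales were chosen as the smallest
sizes at which each property is cleanly observable: covariance fidelity
over 1000 repetitions of a 1000-year, 15-site panel; separability over 50
repetitions of a 5-site, 200-year, replication-5 setting; partition checks
over 10,000 random pools; 10,000 objects for the variance law; and 5
repetitions at full scale (1000 years, replication 30) for the Table-style
settings. The full experiment runner supports the complete 1000-repetition
design via configuration; repetitions are embarrassingly parallel and
their seeds are spawned deterministically from one root seed
(`numpy.random.SeedSequence`), so results are independent of execution
order and resumable from per-repetition JSON artifacts.

Floating-point conventions worth knowing: panel CSVs are written with
`%.17g` and read with round-trip float parsing, so serialization is
bit-exact; the RWL writer refuses widths that collide with the
end-of-series sentinel of the chosen dialect (9.99 mm at 0.01 mm
precision); correlations are clipped to [−1, 1] before the t transform.

## Known limitations

* High-frequency only: no growth-trend, missing-ring or measurement-error
  model; poc members always share the calendar alignment of their ps.
* One covariance for the whole timeline; no temporal drift in between-site
  similarity.
* Single proxy (ring width); multivariate extensions (density, isotopes)
  are out of scope.
* The constructor implements a single classifier (thresholded 1-NN on
  correlation t-values at fixed dating); alternative similarity measures
  or continuous thresholds are not provided.
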