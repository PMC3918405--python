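# Methods

## The observation model and the synthetic trial

Observed trait values follow the standard multi-environment model

    Y_hk(ij) = μ + E_h + R_i(h) + C_j(h) + G_k + GE_hk + ε_hk(ij)

with μ the per-trait population mean, E_h the fixed effect of year h,
R_i(h) and C_j(h) fixed row and column effects nested within the year,
G_k ~ N(0, σ²_G) the random genotypic effect, GE_hk ~ N(0, σ²_GE) the
genotype-by-year interaction, and ε ~ N(0, σ²_ε) the residual. Normality
of G, GE and ε is an assumption of this package (the model itself only
requires mean-zero variance components); it is the conventional
quantitative-genetics choice and is what the downstream ANOVA-based
statistics expect.

The generator (`corescale.synthetic`) realizes this model directly. Its
defaults emulate a genebank field trial of 168 accessions × 20 quantitative
traits over 2 years × 2 replications, each planting on a 6-row × 80-column
field (168 of 480 cells occupied, random placement, fresh randomization per
replication by default). Per-trait means span 10–150 in heterogeneous
units; default component magnitudes, as fractions of the trait mean, are
σ_G = 12%, σ_GE = 5%, σ_ε = 8%, year effects 5%, row/column gradients 2% —
values a field agronomist would call an ordinary, moderately heritable
trial. Genotypic effects are correlated across traits (AR(1)-style
correlation, ρ = 0.3 between adjacent traits) because real trait panels
are never independent. A `redundancy_fraction` (default 0.30) of the
accessions are copies of randomly chosen donors' genotypic vectors plus
jitter (default 0, i.e. exact duplicates): redundancy is the condition the
stepwise sampler exists to exploit, so the study fixture must contain it.

Two deliberate simplifications: fixed effects are drawn and then exactly
centered within their scope, making the additive decomposition exactly
identified (so noise-free recovery tests can demand equality rather than
equality-up-to-offset); and replication within a year is encoded as its
own environment label ("Y1R2") while sharing the year's E, R, C and GE
draws, which keeps the long-format record to the six fields
environment/row/column/accession/trait/value.

What the generator does *not* emulate: incomplete-block or alpha designs,
spatially autocorrelated (rather than additive row/column) field trends,
missing plots, measurement-scale artifacts, or qualitative traits. Tests
passing on this fixture therefore show that the algorithms behave as
specified under the stated model — not that any particular real collection
will yield the same numbers.

## Genotypic-value adjustment

`adjust()` fits, per trait, the fixed-effects model
μ + environment + row(environment) + column(environment) + genotype by
ordinary least squares with sum-to-zero constraints (rows and columns get
one constraint per environment, i.e. proper nesting), and reports
genotypic values as μ̂ + genotype effect. This is an intentionally plain
stand-in for a mixed-model analysis (variance-component estimation with
random-genotype prediction): it removes the same nuisance effects and
preserves the pipeline contract, but it does not shrink. Consequences
worth knowing:

- With ~2 plants per column level, the 80 column effects are estimated
  very noisily. When true spatial gradients are weak (the generator's 2%
  default) this added estimation noise outweighs the bias it removes and
  raw per-accession means correlate *better* with the truth; with strong
  gradients (≈10% of the mean) the adjustment wins clearly. The test
  suite demonstrates the second regime; users with nearly gradient-free
  fields should prefer plain means or a shrinkage fit from specialist
  software, which can be passed in as a ready-made genotypic matrix.
- GE is not a model term; averaging over environments removes its
  expectation and leaves σ²_GE/H in the genotypic values' error.
- Any data-estimated intercept absorbs 1/H of a constant added to one
  environment, so genotypic values are invariant to such shifts only up
  to a common offset (differences between accessions are exactly
  invariant). Single-planting data leave genotype confounded with field
  cells; the fit refuses with an error naming the factor.

## Distances, standardization and LDSS

Subcores are constructed on the standardized collection (z-scores against
the initial collection's per-trait mean and n−1 sd) and evaluated on the
unstandardized one. Six pairwise distances are supported: Euclidean,
standardized Euclidean (variances from a reference collection),
Mahalanobis (reference covariance; pseudo-inverse with a flag when
singular), city block, cosine and correlation distance. Reference
parameters (sds, covariance) are computed once on the initial collection
and held fixed during stepwise deletion, which makes "recompute distances
after each removal" a pure submatrix operation; a `reestimate` switch
recomputes them on the survivors at every step for users who prefer the
stricter reading.

LDSS removes one member of the globally closest pair (which is exactly the
first UPGMA merge, hence the method's indifference to the clustering
algorithm) until the target size is reached:
`max(2, round(N·p/100))`, rounding half away from zero. The kept member is
chosen by a fair coin from a single per-run RNG stream, so a run is fully
reproducible from its seed; ties in the closest pair break toward the
lexicographically smallest index pair. The removal trace (removed id, kept
id, distance) is retained for auditing and oracle tests.

## Evaluation statistics

MD and VD use, per trait, a pooled-variance two-sample t-test and a
two-sided variance-ratio F-test of the subset against the *full* initial
collection at α = 0.05 — the conventional choices where the source
framework says only "significant difference". CR, VR, CR_max, CR_mea are
mean percent ratios subset/initial; CR_min inverts its ratio
(initial min / subset min) so that a subset whose minimum drifts upward
scores below 100. Ratio terms with a zero denominator, opposite-sign
numerator and denominator, or an undefined CV (zero mean) are excluded
from that statistic's average and listed in the report rather than
producing meaningless negative percentages.

## Homogeneous-population counting

For each evaluation parameter, values at each sampling percentage (with
replication) are compared by one-way ANOVA and Tukey–Kramer all-pairs
tests (exact Tukey HSD at equal n). The compact letter display assigns
letters to the maximal cliques of the non-significance graph — the fixed
point of the classic insert-and-absorb construction — ordered by
descending group mean, so two percentages share a letter exactly when they
do not differ significantly. The number of distinct letters (equivalently
the alphabetical index of the largest letter) is the homogeneous-population
count; a parameter that earns more letters separates more percentage
levels and is the more valid threshold candidate. For significance graphs
induced by a single threshold on ordered means this clique construction is
provably minimal; the test suite verifies minimality by exhaustive cover
search for up to six groups.

## The Monte Carlo surface

One replication draws one random trait order; the trait set for count k is
that order's first k traits, so subsets are nested in k within a
replication (halving the variance of adjacent-k contrasts) while trait
identity is randomized across replications. Every (k, p) cell runs LDSS
and evaluates the chosen parameter; cell seeds derive from the base seed
via `SeedSequence(base, spawn_key=(rep, k, p_index))`, so cells can be
computed in any order with identical results and the whole surface is a
pure function of the base seed. The reference design is percentages
10–30% in 1% steps × trait counts 1–20 × 20 replications (8 400 LDSS
runs, a few minutes at 168 accessions); tests and the bundled pipeline
default to smaller grids that exercise the same code paths.

## Formula families, selection, inversion

Twelve candidate families f(x, y) — x the sampling percentage in percent,
y the trait count — span constants-plus-products up to
log-and-rational-composite forms; the working family is
`f = a + b·log(xy − cy − d)` (natural log throughout; the constants'
magnitudes force percent-scale x). Each family is refit by multi-start
Levenberg–Marquardt least squares, initialized at its reference constants
± 10% and seeded random perturbations; log arguments are guarded by a
steep linear penalty below the domain boundary, and solutions violating
the domain on the data are discarded. A family whose every start fails is
reported as non-converged, not fatal. Reported `error` is mean absolute
error (RMSE alongside); `size` is each family's fixed expression
complexity, carried as selection metadata.

Selection drops fits with R² < 0.70, then takes the smallest-size family
whose error is within 20% (configurable) of the best error — a
reproducible form of the qualitative rule "reject the simple families for
error, the big ones for size". On the reference (size, error, R²) triples
this rule selects the size-15 logarithmic family.

Inversion at a threshold CR* solves f(x, y) = CR* for x per trait count:
closed form `x = (e^((CR*−a)/b) + cy + d)/y` for the working family,
otherwise a bracketed Brent solve (xtol 1e−12) after a 4096-point domain
scan on (0, 500]. Roots are verified to reproduce CR* to 1e−9; cells with
no in-domain root are flagged undefined, and roots outside the fitted
percentage grid carry an extrapolation note (the optimal percentage at
y = 20 lies below the simulated 10% floor — using it is itself an
extrapolation, and the note says so).

## Validation

`compare_treat_ck` evaluates LDSS (treat) and completely random (CK)
subsets over a common set of seeds and reports per-percentage means and
sds of the five ratio parameters. `project_pca` performs correlation-scale
PCA (traits z-scored, since units are heterogeneous) of the initial
collection and projects all accessions onto the first two components;
component signs are fixed by making each loading vector's
largest-magnitude entry positive, so the projection is deterministic, and
the explained-variance percentages of the two components are reported.
Plots are intentionally out of scope: the exported projection and
comparison tables are the module contract, and any plotting layer is a
trivial consumer of them.

## Numerical and design notes

- Sample (n−1) standard deviations everywhere.
- Distances clamp tiny negative round-off (cosine/pseudo-inverse
  Mahalanobis) to zero; zero-variance traits, zero-norm rows and
  constant rows raise errors naming the offender.
- Target sizes below 2 are floored at 2; a percentage of 100 is an exact
  no-op with an empty trace.
- All randomness in a pipeline run flows from one seed; per-stage seeds
  derive from it through named `SeedSequence` spawn keys, and a rerun with
  an identical config is byte-identical, manifest included.
- The flat key=value run config round-trips losslessly and is hashed into
  the manifest.

## Known limitations

- The fixed-effects adjustment does not shrink and can underperform raw
  means on weakly gradiented fields (see above); it is a documented
  stand-in, not a mixed-model replacement.
- Closest-pair ties are broken deterministically but the least-distance
  "subgroup" is always treated as a pair; simultaneous multi-way ties are
  resolved one removal at a time.
- The candidate-family list is a fixed hypothesis space; no free-form
  symbolic-regression search is performed.
- Homogeneous-population minimality is guaranteed for threshold-type
  significance structures (equal replication); with very unbalanced
  groups the Tukey–Kramer graph can in principle lose the interval
  property, where the clique display remains valid but may not be the
  absolute minimum letter count.
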