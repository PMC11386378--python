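# Methods

This note documents the models implemented in `granulecology`, the choices
made where the methodology was genuinely open, and the limits of what the
synthetic-data validation can show.

## Study design and data model

The unit of observation is a single methanogenic granule treated as a whole
microbial community. The default design has 16 untreated replicate granules
("ORIGINAL") plus nine micro-batch-reactor conditions with three replicate
granules each (43 samples): C1 baseline plate incubation (pH 7, 37 °C, VFA
mixture, cobalt supplied), C2/C3 pH 4/10, C4 23 °C, C5/C6/C7 cellulose /
glucose / acetate substrate, C8 acetate without cobalt, C9 VFA mixture
without cobalt. Counts are ASV × sample non-negative integers; analyses run
at ASV level (core/neutral) or after genus collation, where ASVs without a
genus assignment pool into a single `unknowns` row. All tables are
tab-separated UTF-8 with a `taxon_id` first column; rankings break ties by
total abundance and then lexicographic id so results are reproducible
across platforms.

## Synthetic community generator

`simulate_experiment` draws, per sample, a Dirichlet-multinomial count
vector: expected composition π, composition noise Dirichlet(θ·π), depth
lognormal(mean 20 000, σ = 0.1). Base log-abundances are Normal(0, 2),
giving the strongly uneven abundance distribution typical of amplicon
surveys. θ = 2000 reproduces the tight replicate-to-replicate similarity
that motivates treating granules as replicate ecosystems; smaller θ
describes looser biological replication than single-granule data show.

Planted structure (all sets pairwise disjoint, defaults in parentheses):

* **Resilient / susceptible genera** (8 + 8): log-fold effect ±1.0 in all
  nine conditions. Effects are planted directly on the relative-abundance
  scale — a planted taxon's expected proportion in condition c is exactly
  π_i·e^δ, with only the unplanted block renormalising. This makes the
  planted δ the exact estimand of the response model; realising effects
  through a global softmax instead would let the condition-specific
  normaliser leak into every coefficient and make the planted truth
  unrecoverable by any compositional method.
* **Stable-ensemble genera** (10, abundant): per-condition effects drawn
  Normal(0, 0.5) then shifted so the subset's expected summed proportion is
  identical in every condition — the property the ensemble search detects.
* **Core ASVs** (10): mean base log-abundance 3.0, hence detected in every
  sample (occupancy 1).
* **Neutral-block ASVs** (30): per-sample abundance multipliers from the
  gamma construction of Dirichlet(N·m·p) with m = 0.1, the idiosyncratic
  drift the Sloan model describes.
* **Specialist genera** (6): home-condition boost e⁴ on rare single-ASV
  genera (k ≤ 2 home conditions), concentrating their abundance in few
  design states without distorting the rest of the simplex.
* Background genera receive independent Normal(0, 0.5) condition effects.

One global seed fans out to fixed per-stage child seeds, so identical seeds
give byte-identical tables. The generator does not emulate sequence-level
artefacts (chimeras, taxonomy mis-assignment), phylogenetic correlation of
responses, granule spatial structure, or time series; recovery rates
measured on it say nothing about those failure modes.

`simulate_neutral_community` realises the Sloan sampling assumptions
directly (composition Dirichlet(N·m·p), multinomial counts at depth N) and
is the ground truth for the neutral-fit validation. `simulate_vfa_series`
produces a seeded exponential decay over the 12 sampling hours of a 48-h
incubation cycle for the consumption-fraction arithmetic.

## Replicate-consistency screening

Counts + 0.5 pseudocount are CLR-transformed per sample
(x_ij = ln((c_ij+½)/g_j), g_j the geometric mean over taxa, columns sum to
0). Sample j's contribution is SS_j/ΣSS with
SS_j = Σ_i (x_ij − x̄_i·)²; samples contributing strictly more than
median + 2·IQR (linear-interpolation quantiles) are outliers.

A structural property of this rule deserves emphasis: for 16 exchangeable
samples with any continuous noise — even exactly Gaussian contributions —
at least one sample exceeds median + 2·IQR in roughly one run in five,
because the empirical IQR of 16 values is itself highly variable. A "no
outliers" outcome on a single real dataset is therefore consistent with
homogeneity, but *zero* flags cannot be expected in much more than ~80% of
repeated homogeneous experiments, and a single injected outlier is flagged
*alone* at a similarly capped rate (chance flags among the remaining 15).
The acceptance suite asserts the stricter rates and documents the failure;
the screen itself is implemented exactly as defined.

## Diversity and ordination

Rarefaction subsamples without replacement (multivariate hypergeometric),
dropping and warning on samples shallower than the requested depth (default
"auto" = minimum column sum). Chao1 uses the bias-corrected estimator;
Shannon entropy uses natural log (nats). Group comparisons: omnibus one-way
ANOVA, then pairwise Welch t-tests with Benjamini–Hochberg adjustment and
the star convention * p<0.05, ** p<0.01, *** p<0.001 — the pairwise family
is a documented choice; only the omnibus test is prescribed by the
original analysis. Bray–Curtis distances come from total-sum-scaled
proportions; PCoA is classical scaling (Gower centring of −½d², axes with
negative eigenvalues reported but dropped); PERMANOVA uses Anderson's
pseudo-F with seeded label permutations and
p = (#{F* ≥ F} + 1)/(n_perm + 1) — with the default 999 permutations the
attainable floor is exactly 0.001. Note Bray–Curtis is a semimetric; no
triangle inequality is claimed, and the PCoA of such distances can have
negative eigenvalues, which is why they are reported.

## Condition-response model

Per genus (top-100 by summed relative abundance), counts follow a
negative-binomial regression with log sample total as offset, an intercept,
and nine condition coefficients against the ORIGINAL reference; dispersion
is estimated by maximum likelihood (floored at 1e-8), with a
Poisson-then-moment-estimate GLM fallback when the ML optimiser fails
(flagged, not fatal). With latent rank d > 0, u_iᵀλ_j terms are estimated
by alternating conditional maximisation — taxon-wise NB GLMs with
dispersions held at their rank-0 estimates, then one Fisher-scoring update
per sample score, iterated to a 1e-6 log-likelihood tolerance (max 500
rounds, seeded score initialisation, centred scores for identification).
Rank 0 is the default: the classification uses only coefficient signs, and
latent factors are a variance-absorbing refinement. Classification:
resilient ⇔ all nine β̂ > 0, susceptible ⇔ all < 0, otherwise mixed; with
`require_ci` a condition counts only when its 95% Wald interval excludes
zero. Wald rather than profile intervals is a documented cost/accuracy
trade-off. All-zero genera get NA coefficients and a mixed label.

## Stable-ensemble search

The objective is the coefficient of variation (sample SD, n−1, over mean)
of a genus subset's summed relative abundance across all samples; the full
community has CV 0 by closure, which is why the subset size is capped
(default 20, enforced by repair: members beyond the cap are dropped
lowest-mean-abundance first). The genetic algorithm follows the uniform
phenotypic mode: population 200, tournament selection (k = 3), uniform
crossover (p = 0.5), per-gene mutation 1/n_genera, elitism 5, stop after 50
stall generations or 1000 total. The initial population seeds every
singleton (best CV first), which guarantees the result never exceeds the
best single genus, and elitism makes the best-so-far trajectory
non-increasing — both asserted at run time. One implementation detail
matters for global optimality: after each generation, duplicate genotypes
beyond their first occurrence are replaced with fresh random individuals.
Without this the population collapses onto one basin within a few
generations and deterministic repair then locks low-abundance genera out of
full-size subsets. `exhaustive_stable_ensemble` enumerates all subsets up
to the cap (budget 2×10⁶) and serves as the oracle the GA is validated
against. The original ensemble-quotient formulation optimises a normalised
quotient whose exact scaling can differ from plain CV; CV is used here as
the figure the method reports.

## Core ranking and neutral assembly

The occupancy index is ½·(fraction of all samples detecting the ASV) +
½·(mean within-group detection fraction); equal weights are configurable
since the method names both ingredients without weighting. Walking down the
ranking, the cumulative share of total Bray–Curtis similarity
(Σ_{i∈K} min(r_ij, r_ik) summed over sample pairs, as a percentage of the
full-community similarity) gives a non-decreasing curve ending at exactly
100%; the core is the shortest prefix after which every marginal gain is
below 2 percentage points — read as the only monotone interpretation of
"include until no more than a 2% gain remains".

The Sloan fit estimates one parameter Nm by least squares of observed
against predicted occupancy over taxa, with p_i the observed mean relative
abundance and detection limit d = 1/(mean depth). Two occupancy models are
provided. The classical threshold form predicts
1 − BetaCDF(d; Nm·p, Nm(1−p)) — the probability the latent proportion
exceeds d. The default "exact" form predicts the probability of observing
at least one read in a sample of N = 1/d reads whose composition is
Beta-distributed: 1 − B(a, b+N)/B(a, b), a closed form via log-beta
functions. When detection is defined by counts (count > 0, as in practice),
the threshold form is systematically biased — it maps "proportion below d"
to "undetected", although a proportion near d is still detected with
substantial probability — and under count-level simulation its fitted Nm
lands roughly a factor of two low; the exact form removes this bias while
agreeing with the threshold form in the limit where sampling noise is
negligible. The 95% band is a Wilson binomial interval around the predicted
occupancy at n = number of samples; observed occupancy above / within /
below the band classifies an ASV as selected / neutral /
dispersal-limited.

A calibration caveat parallels the screening rule: the Wilson band covers
only binomial occupancy noise, but the prediction is evaluated at an
abundance estimated from the same 50-odd samples. In the occupancy
transition zone the abundance estimate of a rare taxon carries relative
error comparable to the band width, so even data simulated exactly under
the neutral model place noticeably fewer than 95% of taxa inside the
nominal 95% band. The migration parameter and fit R² are unaffected; the
band should be read as a classification device, not a calibrated
confidence statement — consistent with how such fits behave on real
communities, where well-fitting datasets routinely leave 15–40% of taxa
outside the band.

## Niche breadth and overlap

Condition states are the ten design groups (ORIGINAL + C1…C9); R = 10, so
B_N has floor 1/10 — the value observed for a genus confined to a single
state. For each genus, q_j is its share of summed group-mean relative
abundance in state j; B = 1/Σ q_j², B_N = B/R. The permutation null
shuffles sample-to-state assignments (n_perm seeded draws), preserving each
genus's abundance multiset while breaking condition association;
specialist-tail p = (#{B_N* ≤ B_N} + 1)/(n_perm + 1), generalist-tail
analogous, BH-adjusted across genera per tail. Classification combines an
empirical-quantile threshold (5th/95th percentile of all recovered B_N)
with tail significance at α = 0.05. Adding a design state where a genus is
absent leaves B unchanged but increments R, lowering B_N — an intended
property of the normalisation. Levins overlap LO₁,₂ = Σ q₁q₂ / Σ q₂² is
deliberately asymmetric (denominator from the second genus): LO₁,₂ = 1
means genus 1 is present wherever genus 2 concentrates its use.

## Cross-analysis summary and VFA arithmetic

The membership matrix collects the taxon sets returned by each stage
(top-25, resilient, susceptible, stable, core, specialist) as booleans over
their union, rows sorted by category count; a taxon in both response
classes is rejected as a sign-rule violation. VFA consumption is
(C_first − C_last)/C_first per 48-h cycle, negative values reported as net
production; group comparisons use a seeded two-sided permutation test on
the difference of means — permutation rather than an unnamed parametric
family, because it is assumption-light and reproducible.

## Validation scale and runtime

The test and acceptance runs use the study-design sizes throughout (300
taxa, 43 samples, depth 2×10⁴; 50 samples for neutral-model recovery; 100
generator seeds for screening rates; 500 simulations at 199 permutations
for null calibration; 20 twelve-genus instances for GA-vs-exhaustive
checks). These sizes keep the full suite in the minutes range on one CPU
while leaving Monte-Carlo error well below the asserted margins.

## Known limitations

* The package ingests count tables; it does not perform primer trimming,
  ASV inference, taxonomy assignment, or chromatography processing.
* The response model is fitted independently per genus; latent factors
  capture shared sample-level structure but no phylogenetic or trait
  covariates.
* The GA is stochastic; optimality is guaranteed only against the
  exhaustive oracle on small pools, and validated statistically elsewhere.
* Levins breadth treats the ten design states as equally distinct niches;
  it does not model graded environmental distance between conditions.
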