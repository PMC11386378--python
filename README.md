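# granulecology

Whole-ecosystem microbiome analysis of replicate methanogenic granules.

Methanogenic granules — the self-immobilised biofilm aggregates of anaerobic
sludge-bed bioreactors — contain the complete trophic chain of anaerobic
digestion, from hydrolysers and fermenters through syntrophs to methanogens.
Because a single granule is a whole community, a plate of single-granule
micro-batch reactors (μBRs) turns one bioreactor into a highly replicated
ecology experiment: many identical communities, each exposed to a controlled
environmental cue (pH, temperature, substrate, trace-metal deprivation).

`granulecology` implements the analysis chain such an experiment needs, for
microbial ecologists working from 16S amplicon count tables:

* **Replicate-consistency screening** — centred log-ratio (CLR) transform of
  each sample, per-sample share of the group's total variance, and outlier
  flagging above `median + 2·IQR` of those shares.
* **Diversity** — rarefaction, Chao1 (`S_obs + F₁(F₁−1)/(2(F₂+1))`), Shannon
  entropy (nats), pairwise group tests with significance stars, Bray–Curtis
  distances `d(j,k) = 1 − Σᵢ min(r_ij, r_ik)`, principal-coordinates analysis,
  and a seeded permutation PERMANOVA.
* **Condition response** — per-genus negative-binomial regression
  `log μ_ij = log s_i + α_j + β_{j,c(i)}` against the untreated reference
  (optional latent factors, rank d ≥ 0); genera with all nine condition
  coefficients positive are *resilient*, all negative *susceptible*.
* **Stable ensemble** — genetic-algorithm search (ensemble quotient
  optimisation, uniform mode) for the genus subset whose summed relative
  abundance has minimal coefficient of variation across samples, with an
  exhaustive enumerator as oracle on small pools.
* **Core and assembly** — occupancy/replicate-consistency ranking, cumulative
  percent contribution to Bray–Curtis similarity, the "last 2% gain" core
  rule, and a Sloan neutral-model fit
  (occupancy predicted from mean abundance and one migration parameter Nm)
  partitioning taxa into neutral, selected (above the 95% band) and
  dispersal-limited (below).
* **Niche** — Levins breadth `B = 1/Σ q_j²` over the R = 10 design states,
  normalised `B_N = B/R ∈ [1/R, 1]`, permutation null with BH adjustment,
  specialist/generalist calls, and the asymmetric Levins overlap
  `LO₁,₂ = Σ q₁q₂ / Σ q₂²`.
* **Synthetic communities** — a Dirichlet-multinomial generator reproducing
  the study layout (16 untreated replicates + 9 conditions × 3 granules,
  n = 43) with planted resilient/susceptible/stable/core/neutral/specialist
  taxa, so every stage can be validated against known truth.

## Worked example

```python
import granulecology as g

counts, frame, taxonomy, truth = g.simulate_experiment(g.SimConfig(seed=2))
genus = g.collapse_to_genus(counts, taxonomy)

report = g.screen_group(counts.select_samples(frame.samples_in(g.ORIGINAL)))
print(f"outlier cutoff {report.cutoff:.4f}; flagged: {report.outliers or 'none'}")

res = g.beta_diversity(genus, frame.groups_of(genus.sample_ids),
                       n_perm=999, seed=7)
print(f"PERMANOVA pseudo-F {res.permanova_f:.2f}, p = {res.permanova_p}")

model = g.fit_response_model(
    genus.select_taxa(g.top_n_taxa(genus, 100)), frame)
print("response labels:", model.labels.value_counts().to_dict())

sol = g.search_stable_ensemble(g.to_relative(genus), 20, seed=11)
print(f"stable ensemble: {len(sol.members)} genera, CV = {sol.cv:.4f}")

fit = g.fit_neutral_model(counts)
print(f"Sloan fit: Nm = {fit.Nm:.0f} (m = {fit.m:.3f}), "
      f"R^2 = {fit.r_squared:.3f}")
print("assembly classes:",
      g.classify_neutrality(fit).value_counts().to_dict())
```

prints

```
outlier cutoff 0.0784; flagged: none
PERMANOVA pseudo-F 13.87, p = 0.001
response labels: {'mixed': 86, 'resilient': 8, 'susceptible': 6}
stable ensemble: 20 genera, CV = 0.0251
Sloan fit: Nm = 1617 (m = 0.079), R^2 = 0.948
assembly classes: {'neutral': 193, 'above': 84, 'below': 18}
```

Reading the output: none of the 16 untreated replicate granules contributes
an outlying share of the group's CLR variance, so the replicates form one
homogeneous community. The nine imposed conditions separate cleanly in
Bray–Curtis space (p = 0.001 is the floor of 999 permutations). Among the
top-100 genera, 8 respond positively to every condition and 6 negatively —
the generator planted 8 of each, with |log-fold effect| = 1. The 20-genus
stable ensemble holds its summed abundance to a 2.5% coefficient of
variation across all 43 samples, and the neutral fit recovers a migration
parameter near the generator's m = 0.1 while flagging the
occupancy-manipulated taxa as non-neutral.

The same stages are available as a CLI for table-based workflows:
`granulecology simulate|outliers|diversity|respond|eqo|core|neutral|niche|integrate|vfa`
(see `granulecology --help`).

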