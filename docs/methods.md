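# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of the `microstab` pipeline, in the order the method runs.

## Data model

All artifacts are UTF-8 TSV with `#`-prefixed comment headers carrying
units and seeds; missing values are written `NA` and are never silently
zero. Count tables are accepted taxa-as-rows or samples-as-rows and
normalized internally to samples × taxa; counts must be non-negative
integers, identifiers unique, and every taxon observed anywhere must have
a taxonomy entry (unassigned ranks allowed). Validation failures name the
file, row, and column. Each downstream stage declares its own NA policy
(e.g., random-forest assembly drops incomplete rows; resistance cells
lacking a group emit NA rows with a warning).

## Synthetic experiments

The generator emulates a sterilization–dilution–reinoculation design: two
source communities ("cultivated" and "prairie") with partially overlapping
taxon pools (default 700 taxa each, 30% shared), lognormal species
abundances, three inoculum sizes (D0 ≫ D1 > D2), six weeks of regrowth,
and an antibiotic-style stress crossed over the design.

Mechanism per sample:

1. **Inoculum** — a multinomial draw of the level's cell count from the
   land use's pool; dilution removes rare taxa.
2. **Regrowth** — survivor relative abundances are multiplied by
   lognormal(0, 0.5) noise and renormalized: biomass recovers, lost
   richness does not. This is the simplest mechanism consistent with
   dilution experiments in which respiration re-equilibrates across levels
   while richness stays depressed.
3. **Stress** — multiplicative effects on tagged guilds
   (stress-sensitive ×0.1, stress-tolerant ×3, nitrifier ×0.75), applied
   *only* in stressed samples of the lowest-diversity level. This encodes
   the qualitative observation that compositional and functional stress
   responses are confined to diversity-depleted communities; higher-
   diversity treatments are exchangeable between control and stressed.
4. **Sequencing** — a multinomial read draw at a negative-binomial depth
   (mean 20,000, dispersion 20).

**Calibration of dilution defaults.** The dilution cell counts and pool
parameters were calibrated once, jointly, so the default gradient shows
the ~46% and ~45% stepwise mean-richness losses characteristic of strong
dilution-to-extinction gradients (observed means ≈ 650/350/195). A 100-cell
lowest level cannot produce that second step — richness is capped by the
inoculum size at ~85 taxa while a 45% loss from D1 requires ~195 — so the
defaults are pool_size = 700, abund_sdlog = 1.4, cells = (10⁶, 1200, 380).
These are calibration defaults, not fitted values, and were not revisited.

**Processes from planted drivers.** Covariates (biomass, DNA yield, 16S
abundance, AOA/AOB, tetW/tetM, community-mean operon number) are generated
with land-use- and treatment-dependent structure: biomass is inflated
×1.69 in stressed lowest-dilution samples, ITS abundance is near zero in
diluted treatments (no fungal establishment; no fungal community is
simulated), and ARG abundances decay with dilution. Each function is a
stated linear combination of named drivers plus Gaussian noise —
respiration ∝ biomass, SIR ∝ sensitive-genus relative abundance,
total enzyme ∝ biomass, net N mineralization ∝ biomass + membership
gradient, nitrification ∝ (AOA + AOB) — with noise SDs chosen once so each
planted driver explains roughly 70–90% of its function's variance. The β
vector, noise SDs, guild labels, copy numbers, and seed are emitted as
`truth.tsv`. Inorganic-N pools are constructed backwards from the planted
rates over a 7-day interval with baselines (40, 5 mg N kg⁻¹) large enough
that pools stay non-negative.

What the generator does **not** emulate: fungal/protist communities,
temporal antibiotic degradation, spatial structure, sequencing error or
chimeras, compositional count correlation beyond the multinomial. Passing
recovery tests therefore show the *statistical machinery* works when its
assumptions hold, not that real soil data satisfy those assumptions.

## Repeated rarefaction

Rarefaction draws are multivariate hypergeometric (without replacement),
repeated (default 1000×) and averaged per sample; per-iteration streams
are seeded from (seed, sample id, iteration) so results are independent of
sample order and processing schedule. Shannon is computed in natural log
by default (recorded in output metadata; a base-2 switch is provided).
The default depth is the smallest retained sample total; samples below
depth are excluded with a warning and the exclusion list propagates.
Metrics are averaged over iterations (not computed on an averaged table).

## Raup–Crick (RC_Bray) null model

The regional pool is, by default, all samples in the table (restrictable
to a subset). Null communities preserve each sample's observed richness S
and total N: S distinct taxa are drawn without replacement with
probability proportional to occurrence frequency, one individual is
placed in each, and the remaining N − S individuals are distributed
multinomially by pooled relative abundance. The weighted
without-replacement draw uses the Gumbel-top-k construction (take the S
largest of log wᵢ + Gumbel(0,1)), which is exactly the sequential
renormalized scheme and vectorizes across iterations; equivalence is
verified against brute-force enumeration in the tests.

With obs the observed Bray–Curtis value,
α = [#(BC_null < obs − 10⁻¹⁰) + ½·#(|BC_null − obs| ≤ 10⁻¹⁰)]/n_null and
RC = 2α − 1. The tie tolerance exists because exact floating-point
equality is meaningless; 10⁻¹⁰ is far below the 1/(N_x+N_y) resolution of
Bray–Curtis on integer counts. Each unordered pair runs on a substream
keyed by its sorted sample ids, so the matrix is invariant to row order
and to any parallel schedule, and the diagonal is −1 by definition (a
sample is more similar to itself than any null pair). RC matrices tend to
saturate near ±1 when assembly is strongly deterministic; that is a
property of the statistic, not an error.

## Ordination and PERMANOVA

PCoA double-centers −½·J·D²·J and eigendecomposes. RC input carries −1 on
the diagonal and signed entries, so it is first shifted by its minimum
off-diagonal value with the diagonal zeroed — a monotone, rank-preserving
transform recorded on the result. Negative eigenvalues are reported as a
mass (no Lingoes/Cailliez correction), coordinates exist only for positive
eigenvalues, and the first k axes (default 3, configurable) are exported
as predictors PCoA1..k.

PERMANOVA uses sequential (type-I) sums of squares from the
Gower-centered matrix via projection hat matrices, free row permutation,
and the one-sided smoothed p-value (1 + #(F\* ≥ F))/(1 + n_perm), which is
never exactly zero. Residual sums of squares within 10⁻¹⁰ of zero
(relative) are treated as a perfect fit, giving an infinite F rather than
a round-off-sign artifact. Factors with fewer than two levels, or with one
sample per level, are rejected.

## Processes, multifunctionality, resistance

qCO₂ is respiration/biomass (NA with a warning when biomass ≤ 0); net N
rates are pool differences over the interval and may legitimately be
negative (immobilization, denitrification) — they are flagged, never
clamped. Total enzyme activity is the sum of the four rates and NA
propagates. Multifunctionality is the unweighted mean of z-scaled
functions using the sample (n−1) standard deviation (population-SD
switch available); it errors, naming the column, on any zero-variance
function, and is invariant to affine rescaling of inputs.

The resistance index uses the control-minus-stressed difference
D₀ = C₀ − P₀: RS = 1 − 2|D₀|/(|C₀| + |D₀|), 1 = no change, bounded below
by −1. |C₀| keeps the index defined for functions with negative control
means; its use is logged. Group means (not medians) define C₀ and P₀.
Two pairings are offered: one RS per land-use × diversity cell
(cell means), or one RS per stressed replicate against the control mean
(bootstrap- and error-bar-friendly). The companion resilience
(recovery-over-time) index is out of scope: the design has a single
post-stress time point.

## Random-forest importance

Model error is always out-of-bag: each sample is predicted only by trees
whose bootstrap excluded it. In-bag evaluation would reward overfitting
and inflate every predictor. OOB membership is reconstructed from each
tree's bootstrap stream and matches the learner's own OOB predictions
bit-for-bit (asserted in tests against an independent bookkeeping route).

The forest is tuned over candidates-per-split 1..P at fixed seed,
selecting the OOB-MSE argmin (ties to the smallest value); the trace is
emitted. Importance is the mean increase in OOB MSE over the unshuffled
baseline across n_shuffles (default 30) independent whole-column
permutations, others fixed. Raw (possibly negative) means are retained;
the ranked report clamps at zero. Defaults are 10,000 trees for analysis
runs; the test and recovery suites run at 200–500 trees, where rankings
are stable because tree count only affects Monte-Carlo noise.

Predictor sets are response-specific: AOA/AOB are offered only to
nitrification models, and responder-genus relative abundances only in the
"alternative" variant. Zero-variance columns are dropped with a warning;
fewer than 10 complete rows is an error.

## Problem sizes used by the checks

The test suite runs the full design (60 samples, ~1200-taxon pool) for
driver-recovery checks at 500 trees with 5 shuffle repetitions over 20
seeds, and the end-to-end reproducibility check at 30 rarefaction
iterations, 30 null iterations, 200 trees, and 99 permutations. Module
tests use a down-scaled scenario (120-taxon pool, 36 samples). These sizes
were chosen so the whole suite runs comfortably on a laptop; all
statistical tolerances are stated per test (3-SE Monte-Carlo bands,
exact enumeration on tiny instances).

## Known limitations

- The null-model pool definition (whole experiment vs. per group) changes
  RC values; the default pools across all samples and is configurable.
- PCoA on shifted RC matrices is a pragmatic embedding of a signed,
  non-Euclidean statistic; negative-eigenvalue mass should be inspected.
- The responder screen is a fold-change + rank-test filter with BH
  correction, not a count-model differential-abundance method; with real
  overdispersed counts it is conservative for rare taxa.
- Sequential PERMANOVA sums of squares depend on term order, as in any
  type-I decomposition; terms are tested in the order given.
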