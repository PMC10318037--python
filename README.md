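# microstab

Analysis pipeline linking soil **bacterial community structure** to
**ecosystem-function stability under stress**, built for
dilution-to-extinction microcosm experiments (two land uses × three
diversity levels D0 > D1 > D2 × control/stressed × replicates).

It is aimed at microbial ecologists who have an ASV count table, sample
metadata, and per-sample biogeochemical measurements, and who want to ask:
*which characteristics of the bacterial community — α diversity, membership,
biomass, functional-group abundances — best predict ecosystem process rates
and their stability?*

## What it computes

- **α diversity by repeated rarefaction**: per sample, Shannon
  H′ = −Σ pᵢ ln pᵢ and observed richness S, averaged over many independent
  without-replacement subsamples at a fixed depth.
- **Raup–Crick null-model dissimilarity (RC_Bray)**: the observed
  Bray–Curtis dissimilarity BC = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ) of each sample pair is
  ranked within a null distribution of dissimilarities between
  probabilistically assembled communities with matched richness and total
  abundance (taxa drawn by occurrence frequency, individuals placed by
  pooled relative abundance), then rescaled to RC = 2α − 1 ∈ [−1, 1]. This
  removes the confounding of dissimilarity with α diversity, which matters
  when richness varies several-fold across treatments.
- **Ordination and inference**: principal-coordinates analysis (PCoA) of any
  dissimilarity matrix, and a sequential-sum-of-squares PERMANOVA with free
  row permutation.
- **Ecosystem processes**: C mineralization, substrate-induced respiration
  (SIR), metabolic quotient qCO₂ = respiration/biomass, total hydrolytic
  enzyme activity (BG + LAP + NAG + AP), net N mineralization and net
  nitrification from inorganic-N accumulation, and **multifunctionality**
  (mean z-scaled rate per sample).
- **Stability**: the Orwin–Wardle resistance index
  RS = 1 − 2|D₀|/(|C₀| + |D₀|), with D₀ = C₀ − P₀ the control-minus-stressed
  difference; RS = 1 means no change, RS → −1 extreme change.
- **Predictor importance**: tuned random-forest regression of each function
  on candidate microbial predictors (richness, Shannon, PCoA axis scores,
  biomass, DNA yield, 16S abundance, mean 16S operon number, tetW/tetM,
  Proteobacteria:Actinobacteria ratio; AOA/AOB for nitrification), with
  importance measured as the increase in out-of-bag MSE after shuffling
  each predictor across the data set.
- **Synthetic experiments**: a generator that emulates the full design with
  *planted drivers* (biomass, a membership gradient, a designated genus,
  nitrifier abundance) and emits the generating coefficients as ground
  truth, so the whole chain can be exercised and driver recovery scored.

## Worked example

```python
import microstab as ms

scn = ms.SimulationScenario(seed=1)          # 2 x 3 x 2 x 5 = 60 samples
counts, meta = ms.simulate_communities(scn)
proc, truth = ms.simulate_processes(counts, meta, scn)

div = ms.repeated_rarefaction(counts, n_iter=100, seed=1)
funcs = ms.derive_functions(proc)
res = ms.resistance_table(funcs, meta)
```

Mean rarefied richness falls stepwise across the dilution gradient
(~43%, then ~45%), while Shannon diversity declines more gently:

```
diversity_level  mean_richness  mean_shannon
D0                       610.9           5.4
D1                       349.1           5.1
D2                       191.6           4.7
```

Resistance of substrate-induced respiration collapses only in the
lowest-diversity (D2) soils — the planted stress effect:

```
  land_use diversity_level     C0     P0    RS
cultivated              D0  9.848 11.968 0.646
cultivated              D1 10.065 11.699 0.721
cultivated              D2 11.887  1.381 0.062
   prairie              D0 12.396 12.343 0.991
   prairie              D1 10.922 11.269 0.938
   prairie              D2 11.969  1.463 0.065
```

And the tuned random forest recovers the planted driver of nitrification —
nitrifier (AOA/AOB) abundance ranks far above every other predictor, with
α-diversity metrics nowhere near the top:

```
predictor  raw_importance  importance  rank
aoa               0.52237     0.52237     1
aob               0.17383     0.17383     2
biomass           0.00460     0.00460     3
abund_16s         0.00450     0.00450     4
PCoA2             0.00353     0.00353     5
tetw              0.00239     0.00239     6
```

(tuned candidates-per-split 13, out-of-bag MSE 0.051 — produced by the
snippet above followed by `tune_and_fit` / `permutation_importance`; see
`docs/methods.md`.)

A command-line interface mirrors the library:

```bash
microstab simulate --out sim/
microstab run --config cfg.yaml --indir sim/
microstab diversity --indir sim/ --iters 1000 --seed 1 --out diversity.tsv
```

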