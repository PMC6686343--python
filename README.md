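# selfmeth

Analysis pipeline for studies that relate **genetic diversity**, **genome-wide
DNA methylation** and **parasite loads** in mixed-mating (predominantly
self-fertilizing) animal populations — the study design used for the mangrove
killifish, where populations consist of a few highly homozygous selfing
lineages connected by rare outcrossing.

It is aimed at population geneticists and molecular ecologists working with:

- codominant **microsatellite** genotype tables,
- dual-digest **MS-AFLP** (methylation-sensitive AFLP) band matrices from the
  EcoRI/HpaII and EcoRI/MspI isoschizomer pair,
- per-individual **parasite counts** by morphotype, and
- Bayesian-clustering **membership (q-value) matrices**.

## What it computes

**MS-AFLP scoring.** Band patterns map to methylation states — HPA+/MSP+
unmethylated, HPA+/MSP− hemimethylated, HPA−/MSP+ internal cytosine
methylation, HPA−/MSP− ambiguous (hypermethylation confounded with target
absence). Loci whose frequency of methylation-indicative patterns exceeds an
error threshold (default 5%) are methylation-susceptible loci (MSL); the
rest (NML) double as dominant AFLP genetic markers. Per individual the
pipeline returns the proportion of loci scored methylated,
p̂ᵢ = mᵢ / nᵢ over scorable MSL cells.

**Population genetics.** Per locus and pooled: Na, H_o, H_e = 1 − Σp²,
multilocus F_IS = 1 − H̄_o/H̄_e; individual homozygosity by locus
HL = Σ_hom E_ℓ / (Σ_hom E_ℓ + Σ_het E_ℓ) with E_ℓ the locus expected
heterozygosity; the equilibrium selfing rate ŝ = 2F/(1+F); and q-threshold
classification (selfed iff max q ≥ 0.9).

**Differentiation.** One-level AMOVA on squared pairwise distances with
Φ_ST = σ²_a/(σ²_a+σ²_b) and permutation tests (p never zero, inclusive
estimator), pairwise Φ_ST, principal coordinates analysis, and Mantel tests
between epigenetic and genetic distance matrices — all implemented from
first principles on top of numpy.

**Parasites.** Scaled parasite load Σᵢ Nᵢ/Nᵢ,max (each morphotype normalized
by its sample maximum), prevalence, Kruskal–Wallis and Mann–Whitney tests.

**Methylation modeling.** A binomial GLM (logit link, IRLS) of the
(methylated, scored) count pair against selfing lineage, sampling site,
scaled parasite load (or bacterial-cyst count) and inbreeding status, with
exhaustive candidate enumeration under marginality and AICc multimodel
comparison: ΔAICc, Akaike weights wᵢ = exp(−Δᵢ/2)/Σexp(−Δⱼ/2), evidence
ratios.

**Simulator.** A forward-in-time mixed-mating simulator (`synthetic_data`)
generates complete datasets with known truth — K selfing lineages, selfing
probability s (heterozygosity halves per selfed generation), within-site
outcrossing, negative-binomial parasite counts, and methylation states whose
logit depends on lineage, parasite load, inbreeding and their interactions —
for calibration and parameter-recovery testing.

## Worked example

```python
from selfmeth import default_study_config, simulate, run_study, PipelineConfig

genotypes, bands, qmat, parasites, truth = simulate(default_study_config(rng_seed=1))
report = run_study(genotypes, bands, qmat, parasites,
                   PipelineConfig(n_permutations=10_000, rng_seed=1))
print(report.diversity[["N", "Na", "Ho", "He", "Fis", "HL", "S"]].round(3))
```

```
           N     Na     Ho     He    Fis     HL      S
site1   68.0  5.185  0.082  0.722  0.886  0.916  0.940
site2   42.0  3.111  0.082  0.475  0.827  0.917  0.906
site3   18.0  1.630  0.000  0.254  1.000  1.000  1.000
all    128.0  6.630  0.071  0.765  0.908  0.928  0.952
```

The 128 simulated fish are overwhelmingly homozygous (H_o ≈ 0.07 against
H_e ≈ 0.77), giving a multilocus inbreeding coefficient of 0.91 and an
equilibrium selfing-rate estimate of 0.95 — the hallmark of a population
reproducing almost entirely by self-fertilization.

```python
print(report.amova_table[["marker", "grouping", "phi_ST", "pct_among", "p_value"]])
```

```
marker grouping  phi_ST  pct_among  p_value
  msat    sites  0.4415    44.1471   0.0001
  msat lineages  0.6057    60.5736   0.0001
  msat   status  0.1084    10.8417   0.0001
   NML    sites  0.6024    60.2398   0.0001
   NML lineages  0.8662    86.6179   0.0001
   NML   status  0.1409    14.0851   0.0001
   MSL    sites  0.0185     1.8459   0.0001
   MSL lineages  0.0202     2.0195   0.0001
   MSL   status  0.0010     0.0970   0.4050
```

Genetic markers (microsatellites, NML/AFLP) show strong structuring by site
and selfing lineage; epigenetic differentiation (MSL) is an order of
magnitude weaker, and selfed vs outcrossed groups are epigenetically
indistinguishable (p = 0.41 at 10,000 permutations).

```python
print(report.model_results_all.summary(top=3))
```

```
Methylation-proportion binomial GLM screen (scope=all_sites, predictor=scaled_load)
21 candidate models; top 3 by AICc:
                                                                                  model  k  AICc  dAICc  weight  evidence_ratio
                                      ~ 1 + lineage + scaled_load + lineage:scaled_load 12   990      0  0.5079               1
                         ~ 1 + lineage + scaled_load + inbreeding + lineage:scaled_load 13 991.1  1.054  0.2999           1.694
~ 1 + lineage + scaled_load + inbreeding + lineage:scaled_load + scaled_load:inbreeding 14 991.9  1.943  0.1922           2.642
```

The AICc screen ranks the model with the lineage × parasite-load interaction
first (Akaike weight 0.51) — exactly the structure the simulator generated —
so methylation responds to parasites in a lineage-specific way.

A `selfmeth` command-line tool wraps the same functionality
(`selfmeth simulate|validate|convert-peaks|popgen|msap|parasites|amova|glm`).

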