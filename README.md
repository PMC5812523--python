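# raretaxa

Analysis of the **rare biosphere** in amplicon OTU communities — built for
surveys of a single functional guild, such as methanogenic archaea profiled
with the *mcrA* marker gene, where a handful of abundant OTUs coexist with a
long tail of rare ones and the question is what that tail contributes to
community structure and to ecosystem function.

## What it computes

Given an OTU count table (OTUs × samples) the pipeline:

1. **Classifies rarity.** An OTU with mean relative abundance
   $\bar X_i > 1\%$ across all samples is *abundant*; the rest form the rare
   pool, subdivided by the fluctuation ratio
   $\rho_i = \max_j X_{ij} / \min_{j:\,X_{ij}>0} X_{ij}$:
   *CRT* (conditionally rare, $\rho \ge 100$ — blooms in a few samples),
   *PER* (permanently rare, $\rho < 5$ — flat, includes all absolute
   singletons, which have $\rho = 1$), and *RARE* in between. All cutoffs are
   configurable.
2. **Partitions beta diversity.** Bray-Curtis dissimilarity
   $BC_{jk} = \sum_i |X_{ij} - X_{ik}| \big/ \sum_i (X_{ij} + X_{ik})$
   decomposes additively over any OTU partition by restricting the numerator
   to one class while keeping the full denominator; the per-class shares sum
   to the total BC for every sample pair, quantifying how much community
   turnover each rarity class carries.
3. **Estimates alpha diversity and its link to function.** Chao1
   ($S_{obs} + f_1(f_1-1)/(2(f_2+1))$), ACE, Shannon and analytic
   (hypergeometric) rarefaction per sample, computed on the whole community
   or restricted to the abundant/rare fraction, with Pearson correlations
   against functional metadata (methane production rates, *mcrA* gene
   copies).
4. **Tests dendrogram robustness.** Rare subsets are rebuilt along a
   threshold gradient (1% → 0.1% in 0.05% steps, 19 levels); each subset's
   BC matrix is clustered (UPGMA by default) and every pair of dendrograms
   is compared with the **Baker's Gamma Index** — the Goodman-Kruskal gamma
   $(N_c - N_d)/(N_c + N_d)$ between the cophenetic merge levels of the two
   trees (1 = identical structure, −1 = perfect inversion, ≈0 = unrelated).
5. **Maps shared vs indigenous taxa.** Venn-style counts of OTUs shared
   among sites or exclusive to one site, at decreasing rarity thresholds.

A seeded synthetic-community generator (`raretaxa.simulate`) plants all of
this structure — abundant lognormal core, blooming CRT, flat PER with
singletons, site-endemic rare taxa, and a methane-production rate coupled to
rare richness — so the whole pipeline is testable end to end without any
sequencing data.

## Worked example

```sh
raretaxa run-all --out-dir demo --seed 42
```

simulates the default 4-site, 19-sample, 175-OTU community and runs every
stage. The printed summary:

```
OTUs: 175  samples: 19
classes: abundant=25 CRT=18 RARE=55 PER=77 (rare pool 150)
richness share: abundant 14.3%, rare 85.7% (PER 44.0%)
read share: abundant 88.3%, rare 11.7%
BC contribution ABUNDANT_of_total: mean 52.5% (range 22.4-86.0%)
BC contribution CRT_of_total: mean 25.2% (range 1.0-49.9%)
BC contribution CRT_of_rare: mean 51.9% (range 3.1-88.9%)
pearson chao1[all] ~ rate_ac: r=0.94 p=1.84e-09 ***
pearson chao1[abundant] ~ rate_ac: r=0.04 p=0.876
pearson chao1[rare] ~ rate_ac: r=0.95 p=9.5e-10 ***
```

Reading it: the 150 rare OTUs hold 85.7% of the richness but only 11.7% of
the reads; among the rare classes the CRT carry about half of the rare
biosphere's beta diversity despite being its smallest class; and rare-scope
Chao1 tracks the methane production rate strongly while abundant-scope
richness shows no association — alpha diversity predicts function only once
the rare taxa are counted. `demo/` also receives the per-OTU profiles,
per-pair BC partition, the 19×19 Baker's Gamma matrix, Newick dendrograms
and the Venn region counts as TSV.

The same stages are available as `simulate`, `classify`, `diversity`,
`betapart`, `dendro` and `venn` subcommands, and as plain library calls
(`raretaxa.classify`, `raretaxa.partition_bc`, ...).

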