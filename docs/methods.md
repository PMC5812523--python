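# Methods

## Rarity model

Let $X_{ij}$ be the relative abundance of OTU $i$ in sample $j$ (column-wise
counts over sample depth; columns sum to 1). The classification operates on
two per-OTU statistics:

* mean relative abundance $\bar X_i$ over **all** samples, zeros included —
  a pooled-read proportion would weight deep samples more, which is exactly
  what skipping rarefaction is meant to avoid;
* fluctuation ratio $\rho_i = \max_j X_{ij} / \min_{j : X_{ij} > 0} X_{ij}$,
  the minimum taken over occupied samples only. With zeros included the
  ratio would be infinite for nearly every rare OTU; the nonzero convention
  is also the only one under which an absolute singleton (one read in one
  sample) has $\rho = 1$ and therefore always lands in PER.

Defaults (all exposed in `RarityConfig`): abundant iff $\bar X_i > 1\%$
(strict; a tie at exactly 1% stays rare), CRT iff $\rho \ge 100$
(`crt_strict` switches to a strict comparison — the verbal definition
"at least 100 times" and the notation "> 100" disagree, so both are
available), PER iff $\rho < 5$, RARE otherwise. The four classes always
partition the community.

**No rarefaction.** Counts are never subsampled; normalization is
per-sample relative abundance. Richness estimators are the exception in the
other direction: they are computed on raw integer counts, because Chao1/ACE
are defined on observed frequencies of counts (a "singleton" is a
count of 1, not a relative abundance).

## Beta-diversity partition

$BC_{jk} = \sum_i |X_{ij} - X_{ik}| / \sum_i (X_{ij} + X_{ik})$. The
numerator is a sum over taxa, so for any partition of the OTUs into classes
the per-class numerators (with the full-community denominator) add up
exactly to $BC_{jk}$; this additivity is enforced in tests to $10^{-12}$.
On relative-abundance input the denominator is exactly 2. Two summary
modes: share of the pair's total BC, and share of the rare pool's own
numerator (how much of the rare biosphere's turnover one class carries).
Pairs with a zero denominator (identical samples, or no rare signal) are
excluded from quantile summaries and counted separately rather than
reported as 0/0.

## Alpha diversity

* Shannon $H = -\sum p_i \ln p_i$ in nats (base configurable).
* Chao1 in the bias-corrected form $S_{obs} + f_1(f_1-1)/(2(f_2+1))$,
  defined even when $f_2 = 0$; the classic $f_1^2/(2f_2)$ form is behind a
  flag and falls back to the corrected form at $f_2 = 0$.
* ACE with rare-group cutoff 10; coverage $C = 1 - f_1/N_{rare}$; when every
  rare OTU is a singleton ($C = 0$) the estimate falls back to Chao1, and
  with no rare group it equals $S_{obs}$ — the conventional degenerate
  branches.
* Rarefaction is the analytic hypergeometric expectation
  $E[S_m] = \sum_i (1 - \binom{N-N_i}{m}/\binom{N}{m})$, evaluated in log
  space (`gammaln`) for numerical safety; verified against subsampling
  simulation.

Scoped indices (all / abundant / rare) restrict the count vector to the
OTUs of one fraction before estimating. Correlations with metadata use
`scipy.stats.pearsonr` on pairwise-complete observations; zero-variance or
n < 3 cases are flagged undefined instead of emitting NaN silently. The
default star convention grades down to p < 0.1 ('\*\*\*' p<0.01, '\*\*'
p<0.05, '\*' p<0.1), matching the loose convention common in
diversity-function tables; the conventional mapping is a flag away.

## Dendrogram robustness

Rare subsets along the threshold gradient are taken as
$\{i : \bar X_i < t\}$ (strict, matching "<1%" notation) for
$t = 1\%, 0.95\%, \dots, 0.1\%$ — 19 nested subsets; the gradient is
validated to land exactly on its endpoint. Each subset's rows of $X$ are
re-used as-is (no renormalization — the BC denominator is then the pair's
rare mass), clustered with scipy's linkage (UPGMA default; complete, single,
ward accepted).

Baker's Gamma compares cophenetic **merge-step levels**, not raw heights,
making it invariant under monotone transforms of the linkage heights. The
computation enumerates all pairs of leaf-pairs ($O(m^2)$ with
$m = n(n-1)/2$), counting concordant and discordant pairs with ties
excluded from both — fine for $n \le 50$ samples. Determinism under input
reordering comes from sorting leaves lexicographically before clustering and
relying on scipy's index-order tie-breaking; this is a deliberate
simplification of per-merge lexicographic tie-breaking, equivalent for the
purpose (reproducible trees) and much simpler than re-implementing linkage.

A threshold whose subset has no nonzero abundance is flagged and excluded
from the BGI matrix rather than failing the run.

## Synthetic communities

`SyntheticSpec` defaults describe a 4-site survey (site labels DCL, GAN,
HAI, HUA; 5+6+4+4 depth-profile samples) of 175 OTUs: 25 abundant, 18 CRT,
48 RARE, 84 PER of which 40 are absolute singletons. Sequencing depth is
deliberately uneven: most samples draw 5,000–10,000 reads and two shallow
samples draw 1,100–3,000, the typical profile of an unevenly loaded
amplicon run.

Expected abundances are built class by class and column-normalized:

* abundant: lognormal shares scaled to 85% of the mass, floored at 1.8% so
  every abundant OTU stays above the 1% cutoff after normalization; mild
  per-sample lognormal noise (σ = 0.15) and 5% dropout (an abundant OTU
  occasionally missed in a sample — this also gives the abundant-scope
  richness the small, function-independent variation real tables show);
* CRT: per-OTU mean ~0.3% (clipped ≤ 0.6%), 1–2 bloom samples at 300× the
  baseline minimum;
* RARE: per-OTU mean ~0.11%, planted ratio uniform in [10, 50] with the
  minimum and maximum anchored exactly;
* PER: per-OTU mean ~0.01%, multipliers within [1, 2]; singletons get a
  vanishing expectation in one sample and their realized count is forced to
  exactly one read (realized counts define singleton status).

Planted ratios therefore sit ≥ 2× away from the 5 and 100 cutoffs, so
classification of the noiseless expectation matrix recovers the planted
labels exactly (a tested invariant); column normalization perturbs ratios by
at most ~±15%, within those margins.

Half of the RARE + non-singleton PER pool is endemic to one site. A single
Dirichlet(1) draw over sites sets both the endemic allocation and a site
"habitat quality" multiplier on rare-taxon occupancy (clipped to
[0.5, 1.6]): favorable sites hold more endemics *and* more of the shared
rare pool, so sites differ substantially in rare richness — the situation
in real multi-site surveys, where alpha diversity is highest where activity
is highest. Functional metadata is linear in planted rare richness:
rate = 0.5 + 0.15·richness + N(0, 0.6) (and analogously for gene copies),
with the noise scale chosen so the *measured* rare-scope Chao1–rate
correlation lands in the r ≈ 0.6–0.9 band typical of reported
diversity-function associations.

Counts are drawn per sample from a multinomial at the sample's depth.
Post-draw adjustments keep the table valid without breaking depth sums: a
planted singleton's read, and one read for any OTU the multinomial left
empty, are taken from the most abundant OTU of the target sample (always
within an endemic's home site, since expectations are zero elsewhere).

**What passing tests do not show.** The generator has no phylogenetic or
compositional correlation structure between OTUs, no chimeras or sequencing
error, no depth-site confounding, and its rarity classes are cleanly
separated by construction; recovery statistics on it are upper bounds on
what noisy field data would give, and the diversity-function coupling is
linear by fiat rather than an ecological finding.

## Problem sizes and determinism

Default analyses run on 175 OTUs × 19 samples; statistical checks use 20–50
seeded replicates, and the dendrogram null is 200 random 8-leaf tree pairs
— everything completes in seconds on one core. All randomness flows from a
single `numpy.random.default_rng(seed)`; the seed is recorded in every
output header and in `config.json`, and identical configs produce
byte-identical reports.

## Known limitations

* Goodman-Kruskal gamma is exhaustively enumerated; beyond ~50 samples the
  $O(n^4)$ cost calls for a merge-sort inversion count instead.
* Venn region counting is exponential in the number of sites ($2^S - 1$
  regions); intended for the handful of sites typical of such surveys.
* ACE variance is high on very small samples; no confidence intervals are
  provided for any estimator.
* The reader accepts only TSV (plain or BIOM-style headers), not HDF5 BIOM.
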