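# Methods

`phyloabc` implements a complete, testable pipeline for the phylogeographic
question posed by the trans-Pacific history of the Sitka periwinkle
*Littorina sitkana*: did northeastern Pacific (NEP) populations descend
recently from the northwestern Pacific (NWP), and when?  The pipeline has
three layers — descriptive population-genetic statistics, a coalescent
simulator of competing multi-population divergence scenarios, and an
approximate Bayesian computation (ABC) engine for scenario choice and
parameter estimation — plus a synthetic-data generator that reproduces the
empirical sampling design so every stage can be exercised without the
original GenBank sequences.

## Data model

The universal carrier is a `SequencePanel`: aligned haplotype copies at one
or more loci, each tagged with individual, population and region.  mtDNA
loci contribute one copy per individual; nuclear loci contribute two.
Nuclear allele records are treated as phase-known haplotypes, because the
cloning protocol that generated the original data yields phased alleles.
Alignments are assumed pre-aligned.  Sites with a gap or ambiguity code in
*any* sequence are excluded listwise from all statistics (the common
Arlequin/DnaSP default), so statistics are comparable across tools.
Internal site indices are 0-based; all reported positions are 1-based.

The built-in study design has seven populations — ERI, KHO, STA, PET (NWP)
and KOD, COR, JUN (NEP), with 11/16/8/16/9/12/8 individuals respectively
(80 in total) — and four loci: CYTB (mtDNA, 433 bp), ATPSα (881 bp),
ATPSβ (612 bp), APN54 (597 bp).

## Diversity and neutrality statistics

For each population × locus the package reports the haplotype count H,
Nei's haplotype diversity h = n/(n−1)(1 − Σp²), segregating sites S, mean
pairwise differences k with its pair-level variance, and nucleotide
diversity π = k / usable sites.  Neutrality tests:

* **Tajima's D** with the standard 1989 constants; undefined when S = 0 or
  n < 4 (the variance constants degenerate at n ≤ 3).
* **Fu's Fs** = ln(S′/(1−S′)) with S′ = P(K ≥ K_obs | θ̂ = k) under the
  Ewens sampling formula, computed exactly from unsigned Stirling numbers
  of the first kind in log space; undefined when k = 0.
* **Ramos-Onsins & Rozas R2** = √((1/n)Σᵢ(Uᵢ − k/2)²)/S with Uᵢ the
  singletons carried by copy i; undefined when S = 0.

Significance for all three comes from neutral constant-size coalescent
simulations conditioned on the sample size and the *observed* S (the DnaSP
"given S" convention; the alternative of conditioning on θ̂ gives slightly
different nulls, and the choice is stated here because published analyses
used both).  Small values count as significant for Fs and R2 (one-tailed);
D is two-tailed; all p-values carry the add-one correction
p = (b+1)/(n_sims+1).

**Pairwise Φ_ST** is a two-level AMOVA on the matrix of pairwise Hamming
differences, with the Hamming count playing the role of the squared
inter-haplotype distance (Arlequin's molecular-distance convention):
σ²_within = SSD_within/(N−2), σ²_among = (SSD_among − σ²_within)/n̄ with
the standard unequal-size coefficient n̄ = N − (n₁²+n₂²)/N, and
Φ_ST = σ²_a/(σ²_a+σ²_b).  Significance is a label-permutation test
(default 10,000 permutations, add-one corrected).  Distances are
uncorrected by default; substitution-model corrections are vacuous on
infinite-sites synthetic data, and model selection is out of scope.

## Recombination screen

Coalescent analyses here assume no intra-locus recombination, so nuclear
loci are screened and, when necessary, filtered:

* `phi_test` is a pairwise homoplasy index (Φ_w).  The incompatibility
  score of a biallelic site pair is the binary four-gamete indicator; Φ_w
  averages the score over parsimony-informative pairs within `window_w`
  (default 100) alignment base pairs of each other.  Because recombination
  makes incompatibility grow with distance, an unusually *small* windowed
  mean signals recombination: p is the fraction of site-order permutations
  with Φ_w ≤ observed.  The binary score simplifies the refined
  multi-state incompatibility used by SplitsTree; the study's loci are
  overwhelmingly biallelic per site and the simplification preserves the
  test's logic.
* `filter_recombinant_sites` greedily removes the site participating in
  the most remaining four-gamete-violating pairs (leftmost on ties) until
  none remain.  This replaces IMgc-style joint sequence-and-site
  optimization with a deterministic, auditable rule; its output provably
  passes the four-gamete test and the filter is idempotent.  Infinite-sites
  data are never modified.

## Haplotype networks

Networks are ε = 0 minimum spanning networks over haplotype Hamming
distances (the union of all minimum spanning trees, PopART's
minimum-spanning default): edges are added in ascending weight and every
edge of a tied weight class that joins components distinct *before* that
class is kept.  Median (inferred) vertices are not added.  Nodes carry
total and per-region counts; edge weights count mutational steps.

## Coalescent scenario simulator

Scenarios are rooted population trees: each extant or ancestral branch has
one size parameter N (a branch keeps its size for its whole duration —
the published scenario-1 fit has exactly one size per extant population
and no separate ancestral sizes), and each backward-in-time merge has one
time parameter in generations.  Within a branch, lineage pairs coalesce at
rate 1/(c·2N) where c is the inheritance scalar (1.0 nuclear, 0.25 mtDNA);
at a merge the source branch's remaining lineages transfer to the
destination.  There is no migration in any scenario: the original analyses
could detect no gene flow between any populations, so migration rates are
structurally zero.  Mutations fall as a Poisson process at rate
u = μ_site × L per lineage-generation and land on fresh sites
(infinite sites; if mutations ever exceed L the simulator falls back to
finite sites with repeated hits toggling state).  Output is encoded over
{A, G} so downstream statistics see ordinary alignments.

The four built-in scenarios:

1. single colonization — the NEP clade {KOD, COR, JUN} merges into the PET
   (Kamchatka) lineage, then into the NWP backbone;
2. two colonizations — {KOD} and {COR, JUN} merge into PET independently;
3. reverse direction — PET derives from the NEP ancestral lineage;
4. null — the NEP clade is sister to all NWP populations.

The drawings of scenarios 2 and 4 are not fully determined by their verbal
descriptions, so both are explicit, configurable structures: scenario 2 as
two independent merges into PET at distinct times, scenario 4 with the NEP
clade joining at the root after every NWP merge.

**Priors.** The original supplementary prior table is not reproduced in
the main text, so defaults bracket all published estimates: every size
~ U(100, 10⁶) individuals, every time ~ U(10, 6×10⁵) generations, fully
configurable.  Ordering constraints (structural ones derived from the tree
plus declared ones) are enforced by rejection sampling.

**Mutation rates.** The mtDNA rate comes from a sequence divergence rate
of 1% per Myr (0.5% per lineage), i.e. 5×10⁻⁹ /site/year × generation
time g (default 1 year, appropriate for an annual-breeding littorinid).
No published rate exists for the nuclear introns; the default 10⁻⁹
/site/year reflects typical invertebrate nuclear rates being several-fold
below mtDNA, and is configurable.  Loci use fixed per-locus rates rather
than a shared mean-rate hyperprior.

**Reproducibility.** One master seed governs everything; child generator
i is seeded from `SeedSequence((master_seed, i))`, so reference tables are
reproducible row by row.

## ABC engine

**Summary statistics.**  Per population × locus group: {H, S, k, var k,
Tajima's D}; per population pair × locus group: {pooled S,
between-population mean pairwise differences, Φ_ST}.  The mtDNA locus is
one group; the nuclear loci are averaged into a second, respecting their
different inheritance.  This one-sample set covers every one-sample
statistic reported elsewhere in the pipeline.  With 7 populations the
vector has 196 entries.  Undefined entries are encoded as 0 with an
undefined flag, identically for observed and simulated data.  The
two-sample fixation index is the same AMOVA Φ_ST as the descriptive layer
(labelled F_ST in outputs, following common usage).

**Rejection** uses Euclidean distance on MAD-normalized statistics (MAD of
a constant column is replaced by 1 with a warning); ties at the cutoff
break by row index via a stable sort.

**Model choice** fits a multinomial ("polychotomous") logistic regression
of the scenario label on the retained rows' centred statistics and
evaluates fitted probabilities at the observed point.  A fixed mild ridge
penalty (inverse strength C = 100) keeps the fit defined under perfect
separation; 95% CIs come from a nonparametric bootstrap of the retained
rows (the original software's internal CI method is unpublished, so the
bootstrap is used deliberately).

**Error rates** are estimated from pseudo-observed datasets: the
false-positive rate of a focal scenario is the share of alternative-
scenario pods for which the focal scenario is chosen; the false-negative
rate is the share of focal pods for which an alternative is chosen.  The
"a posteriori" design simulates the focal scenario at a fixed posterior
parameter point (e.g. the published posterior modes) while alternatives
draw from their priors; a fully prior-drawn design is a flag away.

**Parameter estimation** follows the local-linear adjustment: parameters
are mapped by a logit onto their prior bounds (clamped 10⁻⁸ off the
bounds), regressed on the centred normalized statistics of the closest 1%
of the scenario's rows with Epanechnikov weights (bandwidth = max retained
distance), and the fitted trend is subtracted before back-transforming.
Modes come from a weighted Gaussian KDE (Silverman bandwidth, 512-point
grid); credible intervals are weighted 2.5/97.5% quantiles.  A singular
regression falls back to the unadjusted rejection sample and is flagged.

The retained count is floored at 15 observations per regressor.  With a
196-statistic schema, retaining 1% of a desk-scale table (100 of 10⁴
rows) leaves the weighted least-squares system underdetermined — the fit
interpolates and the adjusted sample collapses — and anything close to
the regressor count still overfits the local trend and shrinks credible
intervals below nominal coverage.  Fifteen rows per regressor is the
conservative end of standard events-per-variable practice; at the
original study's scale (1% of 10⁶ ≫ 15 × 197) the floor never binds.

**Unit scaling.** θ → N = θ/(4·u·c); generations → years via g; a
mutation-scaled time t converts to years as t/(μ_site,year·L), with the 1%
per Myr divergence rate giving μ_site,year = 5×10⁻⁹.

## Problem sizes

Desk-scale defaults are 10⁴ simulations per scenario, 500 retained rows
for model choice, and the closest 1% for parameter estimation; the
original study's 10⁶/scenario and 50,000 retained are available by
configuration.  The acceptance script uses 10⁴/scenario and 500 pods per
scenario; the test suite shares one 10⁴/scenario table across its ABC
checks and uses 100–167 pods per experiment, sizes chosen so the whole
suite stays desk-scale.

## What the synthetic data do and do not show

The generator reproduces the empirical design (populations, sample sizes,
locus lengths, ploidy) and neutral coalescent variation under the four
scenario topologies.  It does not emulate substitution-model complexity
(multiple hits, transition bias), intra-locus recombination, population
growth within branches, migration, or sequencing/phasing error.  Passing
tests therefore demonstrate the correctness and calibration of the
machinery under the neutral infinite-sites model, not the robustness of
the biological conclusions to model misspecification.

## Known limitations

* Scenarios 1 and 3 differ only in the direction of the PET/NEP-ancestor
  merge; under exchangeable priors they are intrinsically hard to
  distinguish, which inflates pod-based confusion between them relative
  to an analysis at 10⁶ simulations per scenario.
* The greedy four-gamete filter removes sites only (never sequences) and
  can discard more sites than the data-maximizing optimum.
* Φ_w uses the binary incompatibility score; loci with many multi-state
  sites would need the full refined score.
* Multi-level (region × population) AMOVA and median-joining networks are
  out of scope.
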