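# Methods

## The problem

SNP arrays are designed around variants discovered in a small panel of
source ("discovery") populations, retained only if common there.  Diversity
statistics computed from such arrays are systematically distorted: observed
heterozygosity (Ho) is inflated in populations close to the discovery panel
and depressed in diverged ones, in proportion to their divergence.  The
pipeline implemented here reduces this ascertainment bias for cattle-style
data by restricting analysis to *ancestral polymorphisms* — array loci that
are also polymorphic within deeply diverged wild outgroup populations — and
then quantifies what the restriction does to the usual population-genetic
summaries.

## Pipeline

Stages run in this order; each is a pure function of (inputs, parameters,
seed) and is recorded in a JSON run manifest with locus counts and output
checksums.

1. **QC** (`qc.filter_loci`).  A locus is retained iff its missing-call
   fraction is strictly below 10%, its pooled minor-allele frequency is
   strictly above 1%, and it has a known autosomal map position.  The
   strict inequalities follow the verbal rule being reproduced; PLINK's
   `--geno/--maf` use inclusive thresholds, so a `plink_compat` switch
   flips the comparisons for tool-to-tool comparison.  MAF is pooled over
   *all* samples (outgroups included) because QC precedes any population
   stratification; the choice is recorded in the manifest.

2. **Ancestral selection** (`panel.select_ancestral`).  A locus qualifies
   iff both alleles are observed among the non-missing genotypes of at
   least one named outgroup population *considered alone* (any
   heterozygote, or both homozygote classes).  Hybrid populations are never
   consulted unless explicitly listed.

3. **LD pruning** (`panel.ld_prune`), defaults 2000 kb window / step 10
   variants / r² > 0.2.  r² is the squared Pearson correlation of genotype
   dosages (composite LD) over samples called at both loci — no phasing is
   needed.  Within a violating pair the lower-pooled-MAF locus is removed;
   ties drop the locus later in map order.  The stepped-window greedy pass
   is followed by an audit loop that re-anchors a window at every retained
   locus and resolves residual violations with the same removal rule:
   stepping alone cannot guarantee the advertised post-condition, because a
   violating pair can sit inside a window anchored *between* two step
   positions.  After convergence an exhaustive within-window scan finds no
   retained pair above the threshold (asserted in tests up to 500 loci).

4. **Diversity** (`diversity`).  Per individual, Ho_i = heterozygous /
   non-missing calls over the panel; F_i = 1 − Ho_i/He_i with He_i the mean
   of h_l = 2p_l(1−p_l) over that individual's called loci.  The reference
   frequencies p_l are **pooled** over the whole sample by default.  This
   choice is *derived*, not assumed: in the published per-breed table this
   pipeline mirrors, Ho/(1−F) is a single constant (≈0.40 ± 0.02) across
   breeds whose Ho spans 0.112–0.370, which is only possible if every
   breed's F was referenced to one common (pooled) expected
   heterozygosity.  The test suite re-performs this check.  Under pooled
   referencing F mixes inbreeding proper with Wahlund-type divergence from
   the pooled average — that is why wild outgroups show the largest values;
   `f_reference="within"` recomputes p_l inside each population, where F
   measures only the departure from within-population Hardy–Weinberg
   proportions (≈0 on the simulated HWE data, up to the −1/(2n−1) plug-in
   bias of sample frequencies).  Population summaries are means and sample
   standard deviations (n−1) over individuals; F is never clipped.

5. **Permutation test** (`permutation`).  Null: n = 1,000 replicates, each
   drawing m = |ancestral panel| loci without replacement from the full
   array panel and recomputing population-level Ho.  One draw is shared by
   all populations within a replicate — the panel is what is being
   resampled, not the population data (a config switch provides
   per-population draws).  Empirical p-value: pval = (1+r)/(1+n) with r the
   count of null values **greater than or equal to** the observed one, so
   the attainable minimum is 1/(1+n) ≈ 0.000999, never 0.  Per-replicate
   RNG streams are derived from (seed, replicate-index) counters, making
   results independent of execution order.

6. **Reynolds' distance** (`distance_pca`).  For biallelic loci,
   θ = Σ_l (p1l−p2l)² / Σ_l (1 − p1l p2l − q1l q2l) over loci with defined
   frequencies in both populations.  The default is this frequency-only
   estimator; `corrected=True` subtracts within-population sampling
   variance per the least-squares coancestry estimator with per-locus
   sample sizes (the choice is recorded in the manifest — which variant a
   given published figure used is generally not knowable).  θ is not
   linearised (no −ln(1−θ)).  Matrices export as PHYLIP square or NEXUS
   DISTANCES blocks for SplitsTree-style network rendering; network
   construction itself is out of scope.

7. **PCA** (`distance_pca.pca`).  Missing calls are mean-imputed per locus;
   columns are centred by 2p and scaled by √(2p(1−p)) with pooled p
   (variance-standardised convention); scores come from the SVD.
   Monomorphic columns contribute zeros.  Component signs are fixed by
   making the largest-magnitude locus loading positive (first index wins
   ties), so results are fully deterministic.

## Synthetic data generator

The generator plants exactly the structure the analysis assumes, with
closed-form truth for every population's allele frequencies.

**Drift.**  Hierarchy root → clade → population.  Each step draws the
daughter frequency from the Balding–Nichols law, Beta(p(1−F)/F,
(1−p)(1−F)/F), with mean p (the parent frequency) and variance F·p(1−p);
F ∈ [0,1) stands in for drift time (F = 0 copies the parent exactly).  This
gives desk-scale speed and exact expectations — it is not a coalescent and
makes no claim about real divergence times.

**Two locus classes.**

* *Ancestral polymorphisms* (fraction 1 − `young_frac`): root frequency
  uniform on [0.05, 0.95], drifted down the hierarchy.
* *Young variants* (`young_frac`, default 0.5): post-divergence mutations
  private to one clade — polymorphic there (frequency uniform in a
  per-clade band), absent (frequency 0) everywhere else.

The young class is essential, not decorative.  With drift alone,
ascertainment ("sample MAF above a cutoff in a discovery draw") can only
re-weight the ancestral frequency law toward intermediate values, which
*raises* expected heterozygosity in every population — the hallmark bias
(array Ho *below* genome-wide Ho in diverged populations) is impossible in
that model class.  What produces the bias in real arrays is exactly the
distinction between polymorphisms predating the species splits and
lineage-specific new variants: discovery-lineage young variants are common
where the array was designed and carry zero heterozygosity everywhere else,
while wild-lineage young variants never reach the array.

**Default layout** (reduced-scale mirror of a cattle-array study):
20,000 loci on 29 autosomes of 100 Mb; three discovery-clade populations
(clade F = 0.03, population F = 0.02, n = 24 each); two mid-divergence
domestic populations (clade F = 0.10, population F = 0.05, n = 20/16); one
feral population (n = 21) whose parent frequency is the mixture
0.7·discovery + 0.15·wild_a + 0.15·wild_b before its own drift (F = 0.05);
two wild outgroups in separate clades (F = 0.35 each, population F = 0.02,
n = 14 and 10).  Missing calls at 1%.  Ascertainment draws a fresh
30-individual discovery sample (array design precedes the study, so the
analysis samples are not reused) and keeps loci with sample MAF > 0.05.

Young-variant defaults: weights discovery 0.55 / domestic 0.05 / wild
0.20 + 0.20, frequency bands discovery (0.10, 0.40), domestic (0.10,
0.45), wild (0.20, 0.60).  The band locations increase with branch length —
variants on older branches have had longer to drift upward — and the
discovery weight reflects that array content is discovery-sequencing
derived.  These values were fixed from the model's closed-form
expectations so that the generator reproduces the phenomenon under study
with clear margins: every population gains Ho on the ancestral panel, the
relative gain is ordered discovery < feral < mid-divergence < wild, and
outgroup array Ho sits below outgroup genome-wide Ho.

**What the generator does not emulate.**  No linkage disequilibrium between
loci (an optional block-copy mode duplicates a fraction of loci with
genotype noise purely to exercise the pruning stage); no mutation model,
sex chromosomes, pedigree structure, or realistic site-frequency spectrum;
divergence parameters are stand-ins for time, not calibrated to real
species splits.  Passing recovery tests therefore demonstrates that the
pipeline's statistics respond to ascertainment exactly as the model
predicts — not that the generator is a faithful model of cattle genomes.

## Numerical and degenerate-input policy

* Internal missing sentinel is a single reserved value (−1), never a
  dosage; PED half-missing pairs ("A 0") are treated as missing.
* The counted allele per locus is the first allele observed in file order —
  deterministic, and every downstream statistic is invariant to flipping it
  (g → 2−g), which is asserted end-to-end in tests.
* r² with fewer than two complete pairs, or a locus monomorphic on the
  complete-pairs subset, is "no constraint" (0 for pruning).
* Ho undefined (no calls) or F undefined (He = 0) excludes the individual
  from population means with a warning; a population with no usable
  individuals is omitted from the table; an all-loci-filtered QC result is
  an explicit error rather than an empty dataset.
* Reynolds with a zero denominator (both populations identically fixed at
  every shared locus) returns 0.
* Problem sizes: tests run the full design at 20,000 loci and the
  permutation test at 1,000 replicates — the same sizes the pipeline
  defaults to — in a few seconds on one CPU.

## Known limitations

* The pooled-reference F is a descriptive index (inbreeding + divergence),
  not an estimate of individual autozygosity.
* The LD-pruned set is greedy-maximal under the stated removal rule, not a
  maximum independent set.
* The small-sample-corrected Reynolds variant assumes ≥ 2 diploid
  individuals per population per locus and skips loci below that.
* PED/MAP text is the only input format; binary PLINK and VCF are out of
  scope.
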