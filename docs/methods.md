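# Methods

## Problem and scope

The package implements a candidate-gene screen for thermal local
adaptation in a common-garden RNA-seq experiment: larvae from localities
with contrasting water-temperature regimes are reared at two temperatures
and sampled at two developmental stages, and genes are called candidates
when they are both differentially expressed in response to temperature
within a locality (DE) and enriched for nonsynonymous polymorphism there
(PS, dN/dS > 1). The pipeline starts from a multi-sample VCF, coding
transcript sequences with ORF annotations, and a raw gene x sample count
matrix; upstream read processing, assembly and variant calling are out of
scope. Because no public accession exists for the motivating dataset,
a synthetic-data module generates inputs with the same statistical
structure, and all quantitative claims are made against simulation truth.

## SNP filter cascade

Variants pass, in order: site quality (phred) strictly above 20;
per-call genotype-quality masking (calls with GQ < 10 become missing —
records are not dropped on one bad call, matching per-genotype filtering
semantics); alternate-allele read support (summed depth over surviving
carrier calls >= 4); site missingness <= 20%; minor allele frequency
>= 0.01 computed over all samples pooled, after masking; biallelic only.
Masking is applied before the read-support step so the cascade is
idempotent — carrier status is judged on the calls that actually survive,
and re-filtering a filtered panel is a no-op. Whether "supporting reads"
should instead mean total site depth is not decidable from the filter's
usual description; a `read_support_mode="site_total"` switch provides the
alternative.

The genome-wide MAF gate is inclusive (>= 0.01) while the within-locality
gate used by the selection screen is strict (> 0.01); both thresholds are
configurable and deliberately not unified, since the two filters serve
different purposes (panel hygiene vs "variable within locality").

## Weir–Cockerham F_ST

Per biallelic site, the variance components a (among populations),
b (among individuals within populations) and c (within individuals) are
computed from per-population sample sizes, alt-allele frequencies and
observed heterozygote frequencies, excluding missing calls site-wise;
sites with fewer than two called individuals in any population contribute
nothing. The multi-site estimate is the ratio of averages
sum(a) / sum(a+b+c) (the "weighted" aggregation used by standard VCF
tooling); an average-of-ratios summary is exposed as
`FstResult.mean_of_ratios` for sensitivity analysis. Per-site values may
be negative and are not clamped. Pairwise population estimates recompute
the components on each pair's samples.

## Genetic distance and dendrogram

Sample relatedness uses the allele-sharing distance
d(x, y) = mean over co-called sites of |g_x - g_y| / 2, which is 0 for
identical genotypes and 1 for opposite homozygotes. "Absolute genetic
distance" has no unique definition; this is the simplest metric
consistent with the name, and the distance function is a drop-in
replacement point. Trees are UPGMA (average linkage) with merge heights
equal to half the cluster distance, so the tree is ultrametric and two
samples at distance d coalesce at height d/2; ties break by scipy's
deterministic index ordering. Newick export carries branch lengths from
the merge heights.

## Coding-effect classification and the dN/dS screen

A point variant inside an annotated ORF is mapped strand-aware to its
codon and offset; it is synonymous iff the reference and alternate codons
translate identically under the standard genetic code. Stop gain/loss is
counted as nonsynonymous: the screen is binary and premature stops are
protein-altering. Positions outside the ORF are noncoding and ignored by
the screen.

Per gene and locality, nonsynonymous (N) and synonymous (S) tallies run
over the locality's variable SNPs (within-locality MAF > 0.01). The
default ratio is site-normalized, (N / N_sites) / (S / S_sites), with
Nei–Gojobori (1986) expected site counts from the reference ORF: each
position of each non-stop codon contributes the fraction of its three
possible point mutations that are nonsynonymous (mutations to stop count
as nonsynonymous, so N_sites + S_sites = 3 x non-stop codons). A raw N/S
count ratio is available as `mode="raw"`. A gene is positively selected
in a locality iff it has at least 5 variable SNPs there and its ratio
exceeds 1. S = 0 with N > 0 yields an infinite ratio and a positive call
(any pseudocount would be arbitrary; the inf flags the case); genes below
the SNP minimum get an undefined ratio and a negative call.

This is a polymorphism-based (pN/pS-style) screen computed within
localities, not a divergence-based dN/dS between species; with ~7
variants per gene it is a coarse enrichment filter, not an estimate of
selective pressure.

## Differential expression

Counts are filtered (CPM >= 0.25 in >= 6 samples, i.e. minimally
represented in two 3-replicate conditions), then normalized by
relative-log-expression size factors: the per-sample median ratio to the
per-gene geometric-mean reference, over genes positive in every sample.
Size factors absorb sequencing depth, so the GLM offset is
log(size factor) plus the log geometric-mean library size (the constant
keeps intercepts on the raw-count scale; shifting all factors by a
constant moves only the intercepts).

The model is log mu = l_i + d_ij + t_ik: per-locality intercepts,
stage-within-locality and temperature-within-locality effects, with
reference-level constraints d_{i,36} = 0 and t_{i,20} = 0, so t_{i,25} is
directly the 25-vs-20 log contrast in locality i. Errors are negative
binomial with per-gene dispersion phi (variance mu + phi mu^2). Fitting
is iteratively reweighted least squares with a log link and offsets,
vectorized across genes (one shared design matrix, batched normal
equations), converged when the relative deviance change falls below
1e-8 (max 100 iterations); linear predictors are clipped to |eta| <= 30
and non-finite fits are flagged and excluded from testing.

Dispersion: the common value maximizes the summed Cox–Reid adjusted
profile likelihood (APL = log-likelihood - 0.5 log det X'WX) over a
bounded scalar search on log phi in [1e-6, 10]. Tagwise values maximize
APL_g(phi) + prior_df x mean-gene APL(phi) on a 49-point log grid with
parabolic refinement of the argmax; prior_df = 10 by default (ten
genes'-worth of shared information), and prior_df = inf collapses every
gene to the common value. This captures the moderation idea of
empirical-Bayes shrinkage with a fully specified, testable algorithm.

Testing: per gene and locality, a likelihood-ratio test of the full model
against the reduced model with that locality's temperature term removed
(1 df for two temperatures), p from the chi-square upper tail,
Benjamini–Hochberg adjustment across genes within locality, DE iff
adjusted p <= 0.05 (configurable). The significance rule is the field
default; nothing in the screen depends on it being 0.05. The chi-square
reference is asymptotic: at 36 samples the null type-I rate runs slightly
above nominal (~0.052–0.055 at p <= 0.05 in calibration runs), which the
acceptance checks bound by the binomial confidence interval.

The outlier replicate known from the study design is handled by an
explicit drop list on the sample sheet (`drop_samples=("TAT20G42_r1",)`
reproduces the 35-sample layout); automated outlier detection is out of
scope.

MDS: the distance between two samples is the root-mean-square of their
top-k (default 500) largest absolute log2 differences of prior-count-2
log-CPM — a pairwise "leading log-fold-change" distance — embedded by
classical (Torgerson) double-centering MDS with a deterministic sign
convention (first non-zero coordinate of each dimension positive).

## Candidate screen and overlap arithmetic

Candidates are the per-locality intersection DE ∩ PS. The overlap
summary reports, for two localities, each set's size, the shared count,
unique counts (|A| - shared), percentages of each locality's own set and
of the summed total, the summed total |A| + |B| (the convention used for
a "total DE genes" figure; the union is also reported), and the summed
total as a fold of one locality's count. All arithmetic is integer and
satisfies inclusion–exclusion exactly; empty sets yield zero percentages
with an explicit flag. The control locality (FAR) is excluded from
screening, mirroring the genetic distinctness of the control population.

## Synthetic data

* **SNP panel** — Balding–Nichols: ancestral frequency p ~ Uniform(0.1,
  0.9); population frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F) with F the
  target F_ST (F below 1e-12 uses p exactly; the Beta parameterization
  degenerates); genotypes Binomial(2, freq); depth Poisson(mean 20),
  zero depth becomes a missing call; GQ = clip(3 x depth + N(0, 2), 0,
  60), a monotone proxy adequate for exercising the GQ/DP filters — real
  genotype-likelihood-based GQ is not modelled. The model has no
  linkage, no multi-allelic sites and no site-frequency-spectrum realism;
  it exists to give the estimators a known truth.
* **Counts** — the full-factorial design (default 3 localities x 2
  stages x 2 temperatures x 3 replicates = 36 samples, one droppable to
  mimic the excluded outlier). Per gene: baseline log-mean N(log 100,
  1.2); per-locality and per-(locality, stage) offsets N(0, 0.5) — the
  biology the nested model must adjust away; a fraction (default 0.1) of
  genes per locality gets a temperature offset of +-2 log2 units
  (direction random, localities independent); columns are scaled to
  library-size targets Uniform(0.8M, 1.2M); counts are NB with
  dispersion 0.1 (Poisson when 0). Values are typical of moderate-depth
  bulk RNA-seq; within-pool relatedness of the real samples (each pool =
  two full sibs) is not modelled, so a sample is one exchangeable unit.
* **Coding variants** — random ORFs (ATG + non-stop codons + stop,
  optional UTRs, ~30% minus-strand) with planted point variants whose
  truth labels come from translating the whole mutated ORF and comparing
  proteins — a deliberately different route from the codon-local
  classifier being tested.
* **Screen scenario** — couples counts and coding variants on one gene
  namespace; per screening locality it plants candidate genes (DE and
  nonsynonymous-enriched), DE-only and PS-only genes; PS-planted genes
  get 7 variants at 90% nonsynonymous, variable (frequency 0.3) only in
  their locality; null genes get 6 variants at 15% nonsynonymous. With
  these settings the expected per-gene PS miss rate is the binomial
  chance of drawing >= 2 synonymous variants (~15%), which is what the
  end-to-end recall floor of 0.8 reflects.

Passing tests on these generators show the estimators and the screen
recover known structure of the assumed models; they cannot show
robustness to features the generators lack (linkage, GC/length bias,
batch effects, pooled relatedness, mapping artifacts).

## Problem sizes and determinism

Default analysis sizes: 20,000-site panels for F_ST recovery (tolerance
+-0.02 at 2 x 50 samples), 2,000-gene count matrices for DE calibration,
300-gene end-to-end screens — sizes at which Monte-Carlo error is well
inside the stated tolerances while a full run stays in minutes on one
core. Every generator takes an explicit seed; the pipeline manifest
records content hashes of all artifacts, and equal config + seed
reproduces identical hashes.

## Known limitations

* The dN/dS screen is polymorphism-based and threshold-like; it does not
  estimate omega and is blind to selection signatures that do not change
  the N/S composition of segregating variants.
* The LRT's chi-square reference is asymptotic; small-sample moderation
  (quasi-likelihood F-tests) is deliberately out of scope.
* The filter cascade reports survivors per step in cascade order; with
  GQ masking disabled the surviving set is order-independent, with
  masking enabled order matters only through which calls are visible to
  later steps (documented above).
* `summarize_de_overlap` is defined for exactly two localities; the
  intersection table itself handles any number.
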