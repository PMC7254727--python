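# Methods

`rnamosaic` detects post-zygotic (mosaic) single-nucleotide variants in
multi-tissue, multi-individual RNA-seq cohorts, times them against an
embryogenesis lineage tree, and estimates per-nucleotide mosaic mutation
rates with exome extrapolation.  This note describes the statistical model,
the decisions behind every tunable parameter, the synthetic-data generator,
and the limits of what the simulation studies demonstrate.

## Error model and single-sample calling

Alternative-read counts at homozygous-reference positions are modelled per
sample (one individual-tissue pair) and per strand-collapsed substitution
class (A>C, A>T, A>G, C>A, C>T, C>G; G/T references map through the reverse
complement) as

    alt_count ~ Binomial(coverage, e),     e ~ Beta(alpha, beta),

i.e. a beta-binomial.  Fitting is by the method of moments on grouped sums
(pooled mean `p = sum k / sum n`; the intraclass correlation `rho` from the
excess of the residual sum of squares over the binomial expectation), with
an optional maximum-likelihood refinement (Nelder-Mead on `(log a, log b)`)
that falls back to the moments estimate when the optimum is non-finite.
Moments is the default because it is closed-form, robust on sparse classes,
and accurate at the sample sizes involved (on 10^4 sites simulated from
Beta(2, 998) the fitted mean error rate lands within a few percent of
truth).  Classes with fewer than `min_fit_sites` (default 500) reference
sites take a weakly informative fallback prior, alpha=1, beta=1000 (~0.1%
mean error, typical of cleaned Illumina data).

A site is a candidate when its upper-tail beta-binomial probability
P(X >= alt | coverage, alpha, beta), Benjamini-Hochberg-adjusted across the
sample, falls below q = 0.05 *and* it clears the hard filters: >= 4
alternative reads with base quality >= 20, coverage >= 10, VAF >= 5%, no
strand bias (Fisher exact on the ref/alt x forward/reverse table at
p >= 0.01), and no other candidate within 20 bp in the same sample (ties
remove both sites).  The FDR cutoff and the strand-bias statistic are
configurable; 0.05 and Fisher-at-0.01 are the defaults because the source
procedure names only "FDR correction" and "the same distribution as for
reference counts".

The vectorized cohort driver (`pipeline.step1_candidates`) computes the
upper tail as `1 - sum_{j<k} pmf(j)` with vectorized pmf evaluations (alt
counts are small, so this costs O(max alt) passes) and is property-tested
for exact agreement with the scalar per-sample reference implementation.

## Re-genotyping and the 3D array

Sites significant in at least one sample are re-evaluated in every sample
into a site x tissue x individual array with four states: NO_EXPRESSION
(coverage < 5), PASS (q < 0.05, alt >= 3, VAF >= 5%), LOW_QUALITY (alt >= 2
or significant-below-thresholds), HOM_REF (otherwise).  Strand-bias and
proximity filters are deliberately dropped at this stage to maximize
per-tissue sensitivity; alt >= 3 sits one read below the discovery minimum.
Never-assayed samples are kept distinct from NO_EXPRESSION, and exact
ref/alt counts are stored per cell.  The expression threshold of 5 reads is
a compromise: lenient enough to genotype weakly expressed tissues, while
the rate denominators separately require >= 10x ("callable").

Cohort filters drop whole sites (never mutate counts): germline variants of
*any* individual (allele-aware matching); population allele frequency
>= 1% (boundary inclusive); known RNA-editing sites; repeat and
low-complexity intervals (BED, 0-based half-open); externally supplied
systematic-error sites; sites PASS in every expressed cell (likely
systematic artifacts or germline de novo); sites with *significant*
low-quality signal in individuals without a PASS call, when more than 5% of
the cohort (and at least two individuals) show it; and sites PASS in more
than 2 individuals.  Restricting the LQ-recurrence count to significant,
PASS-free individuals matters: carriers of a genuine mosaic commonly show
marginal LQ cells in their own low-coverage tissues, and isolated alt>=2
noise cells carry no recurrence information — counting either would veto
true mosaics in small cohorts while adding nothing against systematic
errors, which by definition recur with significance across individuals.

## Random-forest call filter

A random forest (500 trees, sqrt-feature subsampling; the original tool's
hyperparameters are unpublished) separates true from false calls using six
features: alternative allele count, coverage, VAF, strand-bias p-value,
blacklisted-gene membership, and mean alternative base quality.  Training
data are balanced true:false and flattened across ten VAF bins (dense bins
downsampled to the median populated-bin size); training records with
VAF < 10% are duplicated once *after* the train/test split — duplicating
before the split, as a literal reading of the construction would allow,
leaks records across the partition.  The response threshold is the
maximum-F1 point on the training set over a 0.01 grid (ties take the lowest
threshold); a call must strictly exceed it.  Published thresholds from any
particular cohort are treated as dataset-specific and always recomputed.
In the cohort pipeline the filter is applied to discovery-stage candidate
calls (a site survives if any of its calls do), between single-sample
calling and re-genotyping; the site-level filters above then complete the
"classifier + filters" composition.

## Lineage timing

Each surviving mutation in each individual is mapped to the lowest common
ancestor (LCA) of its PASS-tissue leaves on a rooted embryogenesis tree
(zygote -> {ectoderm, mesendoderm}; mesendoderm -> {mesoderm, endoderm};
sub-lineage nodes; 49 tissue leaves).  The bundled tree encodes the
standard germ-layer assignment of the 49 GTEx tissue names; sub-lineage
topology below the germ layers is a pragmatic encoding, and all
classification rules depend only on the root-branch and germ-layer levels.
Only individuals with >= 10 assayed tissues and >= 2 germ layers each
represented by >= 2 tissues are classified.

Classes (a partition; each call gets exactly one):

- **DENOVO_SUSPECT** — PASS in all expressed tissues, or a multi-tissue
  call with mean VAF >= 0.35 (possible germline de novo variant); kept as
  an explicit class rather than silently removed, for auditability.
- **EEMM** — LCA is the zygote with both root branches carrying the
  variant after excluding the dual-origin adrenal gland, mean VAF < 0.35.
- **MEMM** — >= 2 carrier tissues confined to one root branch, non-root
  LCA, and a *coherent* tissue pattern: every child subtree of the LCA
  holding a carrier shows a detection fraction (carriers / expressed
  tissues in the subtree) >= 0.2, or holds a single expressed tissue.
  Incoherent patterns would require multiple independent origins and are
  classed SOMATIC.  The 0.2 fraction operationalizes a verbal criterion;
  it is exposed as `f_min`.
- **LEMM** — exactly one carrier tissue with >= 5 supporting reads and
  VAF >= 0.2, outside tissues with known clonal expansions (sun-exposed
  skin, esophagus mucosa, whole blood).  Single-tissue calls carry no VAF
  ceiling: a high-cell-fraction organ-confined variant is the LEMM
  phenotype itself, not a de novo suspect.
- **SOMATIC** — everything else.

"Most likely ancestral node" is realized as set-cover LCA; no probabilistic
weighting is attempted (the hook is exposed for alternatives).  Mean VAF
over PASS tissues drives the 0.35 guard; the per-tissue VAF drives the
LEMM threshold (n_pass = 1 there).

## Rates

For a constitutively expressed gene set (metric >= threshold in strictly
more than 75% of samples; four bundled definitions: TPM >= 5, TPM >= 10,
COV >= 20, COV >= 30), the mosaic rate is

    rate = n_mutations / (L x n_individuals),

with L the summed exonic length of member genes.  Expected exome burden is
`rate x 4.5e7` (45-Mbp coding exome), and the performance correction
multiplies the *rounded* exome count by precision/sensitivity (defaults
0.85/0.71), reproducing the printed arithmetic of the source analysis
(0.37 -> 0.44; 0.23 -> 0.275).  Confidence intervals are seeded percentile
bootstraps over individuals (1000 replicates); the upstream analysis
reports CIs without naming a method, so no attempt is made to match its
numeric bounds.  LEMM rates are per tissue over per-sample expressed gene
sets; the cohort total is the mean per-tissue exome count times the number
of examined tissues.

Tissue-specific postnatal rates (mutations per callable site, coverage
>= 10) are adjusted by OLS on technical confounders —
`rate ~ duplicates + cohort + RIN + TRISCHD + DP_median` — after sample QC
(top-5% duplicate rates, top/bottom-1% callable sites, bottom-1% RIN,
top-1% rate, cultured-cell tissues, cancer-affected donors, tissues with
< 50 samples).  Residuals are tested per tissue for Spearman correlation
with donor age, BH-corrected *across* tissues.

## Signatures

Catalogs use the COSMIC 96-context convention (6 pyrimidine-reference
substitutions x 16 flanking contexts, substitution-major then 5' then 3'
base; purine-reference mutations are reverse-complemented).  Refitting
solves

    min ||normalize(catalog) - R w||_2   s.t.  w >= 0, sum(w) <= 1

— plain NNLS when already feasible, otherwise SLSQP from the rescaled NNLS
start.  This deterministic convex program replaces the iterative
forward-selection of the commonly used refitting tool; on well-separated
signatures the optima coincide, and determinism is worth the documented
deviation.  Weights <= 0.1 are zeroed in the report view only (raw weights
retained).  Catalog normalization is by mutation count; no genome/exome
trinucleotide-frequency renormalization is applied by default (the
upstream tool's setting is unpublished; a weighting hook exists).  Group
exposures are compared with a two-sided Mann-Whitney U test.

## Synthetic-data generator

The generator emulates every pipeline input.  Mutations are placed on the
lineage tree per individual; a mutation at division `d` has cell fraction
`0.5^d` and, assuming diploid heterozygosity and no allele-specific
expression, VAF `0.5^(d+1)` in carrier tissues.  Tissue-to-tissue
variability in early-cell contributions is modelled by a per-tissue
carriage pattern (each eligible tissue carries with probability 0.7,
constrained to the class-defining topology: both root branches for
zygote-stage mutations, one branch for germ-layer mutations, one organ for
organogenesis-stage mutations) plus an optional gamma-weighted
asymmetric-contribution mode (mean-preserving).  This carriage dropout is
what makes zygote-stage mutations detectable in most but not all expressed
tissues — the published observation motivating the mean-63.6%-detectability
and blood-dropout discussions.  Default burdens are 2 EEMM + 2 MEMM +
2 LEMM + 2 postnatal somatic planted mutations per individual: rate-
realistic burdens (~3 genome-wide mutations per cell division, also
exposed) would yield almost no events in a desk-scale region, so planted
counts define the test conditions while the per-division rate remains
available for expectation arithmetic.

Counts: coverage is negative binomial with mean 100 and dispersion 0.3
(var = mu + 0.3 mu^2, typical of RNA-seq exonic coverage); expression
dropout is Bernoulli(0.15) per gene x tissue x individual; true-variant
reads are Binomial(coverage, VAF); error reads are Binomial with an error
propensity drawn iid per cell from the class Beta — exactly the calling
model's noise assumption.  The default error scale is Beta(1, 3000) (mean
~3.3 x 10^-4): substitution-specific miscall rates after read-end trimming,
mapping-quality and mismatch filtering sit at a few 10^-4, which is also
the only regime consistent with the method's own evidence thresholds
(>= 4 alt reads at >= 10x).  Error reads carry lower base qualities
(Normal(26, 6) vs Normal(37, 2) for true reads) — the physical reason base
quality is both a hard filter and a classifier feature.  Planted artifacts
exercise each cohort filter: per-individual germline heterozygotes (VAF
0.5, written to VCF), recurrent editing sites, systematic error hotspots
(site-level propensity 0.03 shared across samples), and common population
variants with catalog frequencies.

The generator does *not* emulate: mapping and alignment artifacts with
positional structure, allele-specific expression and nonsense-mediated
decay (an ASE perturbation hook exists), splice-aware coverage profiles,
true trinucleotide context biases in errors, or linkage between nearby
sites.  Passing end-to-end tests therefore demonstrates the pipeline's
statistical correctness under its own model assumptions — calibration,
filter logic, timing rules, estimator behaviour — not robustness to every
artifact class in real RNA-seq.

## Simulation-study sizes and numerical choices

The end-to-end study uses 50 individuals x 20 germ-layer-balanced tissues,
60 genes, 3000 background sites (500 per substitution class, exactly the
per-sample fitting minimum) and coverage 100 — a scale chosen to exercise
every filter with comfortable statistics while a full run stays in the
tens of seconds.  On the noise-free variant (fixed coverage, exact counts,
no dropout) recovery is exact: 100% sensitivity, zero false discoveries,
100% timing-class accuracy.  Under default noise, sensitivity for VAF
>= 0.1 mutations is ~98-99% with ~0-1% false discovery.  Sensitivity is
reported against expressed mutations (>= 1 carrier tissue at >= 10x):
RNA-based calling cannot interrogate silent loci, mirroring the
interrogated-region convention of the rate estimates; the raw-denominator
value is reported alongside.

Degenerate inputs are defined, not fatal: zero coverage yields p = 1
flagged `no_expression`; empty candidate lists and single-class training
sets raise informative errors; constant vectors in correlation tests are
flagged undefined rather than returned as 0.  BH is order-preserving with
q >= p; upper-tail probabilities are clipped to [0, 1]; the moments fit
clips the intraclass correlation away from 0 and 1 before inversion.

## Known limitations

- The bundled tree fixes one plausible sub-lineage topology; users with a
  different developmental model should supply their own JSON/newick tree.
- The coherence rule and the LQ-recurrence fraction are verbal criteria
  made quantitative here (f_min = 0.2; > 5% of individuals, >= 2, with
  significance); both are configurable.
- Whether the 75% constitutive-expression quorum counts samples or
  individuals is ambiguous upstream; samples is the default, with a flag.
- The signature refit is count-normalized; exposures from
  context-frequency-corrected tools are comparable only after applying the
  same weighting.
- LEMM rates inherit the published caveat that organogenesis-stage and
  postnatal clonal-expansion mutations are indistinguishable in a single
  tissue; the clonal-tissue exclusion mitigates but cannot remove this.
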