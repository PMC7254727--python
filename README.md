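# rnamosaic

Mosaic (post-zygotic) mutations arise during embryogenesis, affect only a
subset of an individual's cells and organs, and are routinely missed by
blood-based sequencing.  `rnamosaic` detects them from **multi-tissue,
multi-individual RNA-seq count data**, infers *when* during development each
mutation arose, and estimates per-nucleotide mosaic mutation rates.  It is
aimed at analysts working with cohorts like GTEx — many tissues per donor,
RNA only — and at methods developers who need a fully synthetic,
truth-labelled test bed for RNA-based somatic calling.

## The method

**Calling.**  Per sample and per substitution class, alternative-read counts
at reference positions follow a beta-binomial,

&nbsp;&nbsp;&nbsp;&nbsp;alt ~ Bin(coverage, e),&nbsp;&nbsp; e ~ Beta(α, β),

fitted by method of moments (MLE optional).  Sites with a significant
upper-tail excess (BH, q < 0.05) that pass hard filters (≥ 4 alt reads at
BQ ≥ 20, coverage ≥ 10, VAF ≥ 5%, no strand bias, ≥ 20 bp apart) are
candidates.  A random forest on six call features (alt count, coverage,
VAF, strand-bias p, blacklisted gene, mean alt BQ) with a max-F1 response
threshold removes residual artifacts.

**The 3D genotype array.**  Candidates are re-genotyped in *every* sample
into a site × tissue × individual array with four states (NO_EXPRESSION,
HOM_REF, LOW_QUALITY, PASS), then cleaned by cohort filters: germline
subtraction, population AF ≥ 1%, RNA-editing sites, repeats/low-complexity,
systematic errors, ubiquitous calls, recurrent low-quality sites, and calls
in > 2 individuals.

**Timing.**  Each surviving mutation maps to the lowest common ancestor of
its carrier tissues on an embryogenesis tree (zygote → ectoderm /
mesendoderm → germ layers → 49 tissues, bundled):

| class | origin | rule |
|---|---|---|
| EEMM | first zygotic divisions | both root branches, VAF < 0.35, not in all expressed tissues (adrenal excluded) |
| MEMM | gastrulation/neurulation | ≥ 2 tissues, one germ-layer branch, coherent pattern |
| LEMM | organogenesis | single tissue, ≥ 5 reads, VAF ≥ 0.2, no clonal-expansion tissue |
| SOMATIC / DENOVO_SUSPECT | postnatal / suspect germline | everything else |

**Rates.**  On constitutively expressed gene sets (e.g. TPM ≥ 5 in > 75% of
samples), rate = n / (L × N individuals), extrapolated to the 45-Mbp exome
and corrected for calling performance (× precision / sensitivity), with
bootstrap CIs.  Tissue-specific somatic rates are confounder-corrected by
OLS (`rate ~ duplicates + cohort + RIN + TRISCHD + DP_median`) and tested
for age association (Spearman, BH across tissues).  Mutational spectra are
refit against a reference signature matrix by simplex-constrained NNLS.

A bundled simulator (`rnamosaic.simdata`) generates complete synthetic
cohorts — lineage-placed mutations with stage-determined VAFs,
beta-binomial noise, expression dropout, and planted germline/editing/
hotspot artifacts — so the whole pipeline runs and is tested with no
external data.

## Worked example

```python
from rnamosaic.simdata import SimConfig, simulate_cohort
from rnamosaic.pipeline import run_cohort_pipeline
from rnamosaic.rates import extrapolate, correct_for_performance

cfg = SimConfig(seed=42, n_individuals=20, n_tissues=16)
cohort = simulate_cohort(cfg)                 # counts, truth, artifacts
result = run_cohort_pipeline(cohort)          # call -> RF -> array -> classify

print(result.calls["klass"].value_counts().to_dict())
print({k: round(v, 3) for k, v in result.metrics.items()
       if isinstance(v, float)})
print(f"printed-rate check: {extrapolate(8.1164e-9):.2f} -> "
      f"{correct_for_performance(round(extrapolate(8.1164e-9), 2)):.2f} corrected")
```

prints

```
{'EEMM': 40, 'MEMM': 38, 'LEMM': 34, 'SOMATIC': 26}
{'sensitivity': 0.981, 'sensitivity_raw': 0.981, 'fdr': 0.0, 'klass_accuracy': 0.957}
printed-rate check: 0.37 -> 0.44 corrected
```

The cohort planted 2 mutations of each class per individual (160 total);
the pipeline recovers 98% of expressed mutations with VAF ≥ 0.1, zero
false discoveries, and assigns the correct developmental stage to ~96% of
recovered calls (100% in noise-free runs).  The last line is the rate
arithmetic used for cohort-level estimates: a rate of 8.1164 × 10⁻⁹
early-embryonic mutations per nucleotide per individual corresponds to
0.37 expected exonic mutations in a newborn — 0.44 after correcting for
calling precision (0.85) and sensitivity (0.71).  Note that rates computed
*within* a simulated cohort reflect its planted burden over a ~100-kb
region, not a biological estimate.

A CLI mirrors the library:
`rnamosaic simulate | call | recall | cohort-filter | rf-train | rf-apply |
classify | rates | signatures` (see `rnamosaic --help`).

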