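# lohkit

HLA loss-of-heterozygosity (LOH) calling and grading, genomic biomarker
scores, and a combined predictor of immunotherapy benefit for lung-cancer
cohorts — with a synthetic-data generator so that every stage is testable
with known ground truth.

## The problem

Tumor cells present mutant peptides to CD8⁺ T cells through HLA class I
(the HLA-A/B/C genes). Somatic loss of one parental HLA haplotype (HLA LOH)
removes part of that presentation repertoire and is a suspected mechanism
of resistance to immune-checkpoint inhibitors (ICIs). This package
implements the quantitative machinery needed to study that question in a
tumor/normal targeted-sequencing cohort:

1. **HLA LOH calling** (`lohkit.hla_loh`). At each heterozygous site of an
   HLA gene, the library-size-normalized tumor/normal coverage ratio
   *r* of each allele is converted to an allele copy number using sample
   purity ρ and ploidy ψ:

   ĉ = ( r·(ρψ + 2(1−ρ))/2 − (1−ρ) ) / ρ

   Per-gene allele copy numbers are medians over sites. A gene is LOH when
   **both** the minor-allele copy number is < 0.5 **and** a two-sided paired
   t-test of the per-site copy numbers of the two alleles gives p < 0.01.
   Patients are graded by the fraction of their distinct HLA alleles (3–6)
   with LOH: *negative* (none), *low* (1/6, 2/6, 1/5), *high* (1/3, 1/4,
   ≥3/6, ≥2/5).
2. **Genomic scores** (`lohkit.genomic_scores`). TMB (nonsynonymous
   mutations/Mb), TNB (mutations yielding ≥1 predicted MHC-I binder with
   IC50 ≤ 500 nM among all 8–11-mer windows covering the mutated residue;
   binding prediction is pluggable — a lookup table for real NetMHCpan
   output, or a deterministic mock), and a chromosomal-instability (CIN)
   score: the mean over the 22 autosomes of the percent of segmented
   length gained or lost relative to sample ploidy.
3. **Cohort statistics** (`lohkit.cohort_stats`). Fisher-exact gene and
   pathway alteration-frequency comparisons with BH q-values,
   Kruskal–Wallis, Kaplan–Meier/log-rank, multivariate Cox.
4. **Biomarker model** (`lohkit.biomarker_model`). The four binarized
   markers (LOH presence, TMB-high, PD-L1 TPS > 1 %, CD8 ≥ median) feed a
   small CART decision tree predicting durable clinical benefit (DCB),
   evaluated by leave-one-out F1 with tree depth selected over 3–20.
5. **Synthetic data** (`lohkit.synthetic_data`). Seeded generators for
   every input above, with planted LOH events, exact aberrant fractions,
   controlled binder fractions, and biomarker-dependent response/survival.

## Worked example

The numbered scripts under `analysis/` run the full study on simulated
cohorts (a 425-patient panel cohort and an 89-patient ICI cohort):

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_call_hla_loh.py
python analysis/05_survival_analysis.py
```

Script 02 re-derives every patient's grade from raw site counts and prints

```
Cohort grade distribution:
   grade   n   pct
negative 328 77.18
     low  92 21.65
    high   5  1.18

Grade agreement with generative truth: 100.0% (425 patients)
```

i.e. the caller recovers the planted LOH status of all 425 patients.
Script 05 compares survival of the simulated ICI cohort by LOH status:

```
  median OS [loh]: 5.1 months
  median OS [negative]: 12.4 months
  log-rank OS: chi2 = 14.42, p = 0.000146
...
Multivariate Cox (OS):
  covariate    hr  ci95_low  ci95_high  p_value
loh_present 2.628     1.532      4.508    0.000
```

The generator planted an OS hazard ratio of 2 on LOH presence and no effect
for the other markers; the fitted Cox model recovers that pattern. Script
06 runs the depth search 3–20 and, like the study design it emulates,
selects a depth-3 tree by leave-one-out F1.

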