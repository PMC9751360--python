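# Methods

## Allele-specific HLA copy number and the LOH call

The caller assumes paired tumor/normal sequencing with allele-resolved
read counts at heterozygous sites of HLA-A/B/C, and that the matched
normal is diploid at the locus. For allele *a* at site *j*, the
library-size-normalized coverage ratio is

    r_aj = (tumor_count_aj / normal_count_aj) · (normal_lib_size / tumor_lib_size)

Under a tumor with purity ρ (tumor-cell fraction) and ploidy ψ (average
tumor genome copy number), an allele present at c copies in the tumor has
expected ratio r = (ρc + (1−ρ)) / ((ρψ + 2(1−ρ))/2): the numerator is the
allele's copy mass per cell in the admixed sample, the denominator the
average per-haploid-copy depth normalization. Inverting gives the per-site
estimate

    ĉ_aj = ( r_aj · (ρψ + 2(1−ρ))/2 − (1−ρ) ) / ρ

which is exact when counts equal their expectations (property-tested over
ρ ∈ (0,1], ψ > 0, c ≥ 0). Estimates are reported unclamped — sampling
noise can push them below zero — and aggregated per gene by the **median**
over sites, which is robust to capture artifacts at single sites. Sites
with zero normal coverage at either allele are dropped from both alleles
so the pairing is preserved; at least two usable sites are required.

**Allelic imbalance** is tested with a two-sided paired Student's t-test
on the per-site differences ĉ₁ⱼ − ĉ₂ⱼ. The method named "the two
distributions" without defining them; we pair per-site copy-number
estimates of the two alleles, consistent with the mismatch-site pairing of
LOHHLA-style callers. Degenerate inputs are pinned by convention: all
differences exactly zero → p = 1; zero variance with nonzero mean → p = 0.

**The LOH rule** is the conjunction: minor-allele copy number < 0.5 *and*
p < 0.01. Both thresholds are parameters; tightening either can only
remove calls (a tested monotonicity property).

**Grading.** A patient carries 3–6 distinct HLA alleles. Homozygous genes
are not assessable for LOH; they contribute one allele to the denominator
and zero to the count — this reproduces exactly the denominators 3–6 of
the published three-tier rule. The lookup is: n_loh = 0 → negative;
denominator 6: 1–2 → low, ≥3 → high; denominator 5: 1 → low, ≥2 → high;
denominators 4 and 3: any LOH → high. Fractions the published rule does
not list (2/4, 3/5, 2/3) are extended monotonically: anything at least as
extreme as the smallest listed "high" fraction for its denominator is
high. The listed "high" fractions 1/3 and 1/4 imply LOH counted against
denominators that include unassessable homozygous genes; the lookup is
implemented literally, and the ambiguity is noted here.

## Genomic scores

**TMB** = nonsynonymous mutations / panel megabases. The panel footprint
(`panel_mb`) is a required configuration value, never inferred from the
data; targeted panels differ and the denominator changes every burden
estimate. Copy-number alterations never count toward TMB.

**TNB.** Each nonsynonymous mutation arrives with a ≤21-mer protein
context (10 amino acids of flank on each side of the mutated residue). All
8–11-mer windows containing the mutated position are enumerated
(deduplicated, ordered by length then offset; a full 21-mer with a central
mutation yields 8+9+10+11 = 38 windows). A mutation is a neoantigen iff at
least one window is predicted to bind at least one of the patient's
class-I alleles with IC50 ≤ 500 nM — the threshold is inclusive. Multiple
binding peptides from one mutation count once; `count="peptide"` switches
to peptide-level counting for sensitivity analyses. Binding prediction is
an interface: `TablePredictor` reads precomputed (peptide, allele, IC50)
tables, e.g. NetMHCpan output; `MockAnchorPredictor` is a deterministic
synthetic rule (second-residue anchor per HLA gene: A→L, B→Y, C→F; binders
50 nM, others 5000 nM) that makes binder fractions exactly controllable in
simulations. It is not a trained model and predicts nothing about real
peptides.

**CIN.** A segment is aberrant when |cn_total − ψ| ≥ 0.5; the half-copy
margin (configurable) separates real gains/losses from segmentation noise
around the sample ploidy. Per autosome, the percent of *segmented* length
that is aberrant is computed — segmented rather than physical length,
because a targeted panel does not tile chromosomes — and the CIN score is
the mean of this percentage over the 22 autosomes, with uncovered
autosomes contributing 0%. The score is invariant to splitting segments
(tested) and lies in [0, 100].

## The combined biomarker model

Features are binarized once over the full cohort: LOH present (grade ≠
negative), TMB ≥ cutoff (the cutoff is cohort-specific and must be
supplied; no default), PD-L1 TPS strictly > 1%, CD8 ≥ cohort median (ties
count as high). The PD-L1 three-tier IHC grading (negative < 1% ≤
intermediate < 50% ≤ high) is provided separately.

The classifier is a binary CART over the four boolean features, written
in-package because its determinism contract is strict: Gini impurity
(entropy optional), feature ties broken by the fixed order (loh_present,
tmb_high, pdl1_high, cd8_high), leaf ties predicting NDB (conservative:
ambiguous evidence never predicts benefit). When no split reduces
impurity but the node is impure and some feature still varies, a zero-gain
split on the smallest-index varying feature is taken; this makes any
labeling that is a deterministic function of the features fit exactly once
depth permits (XOR-like labelings have no impurity-reducing first split),
and growth still terminates because each feature can be consumed once per
path. Leaves are forced at max depth, purity, or feature exhaustion.

Evaluation is leave-one-out: refit on each n−1 subset, predict the
held-out patient, pool the n predictions, and compute F1 with DCB as the
positive class. Degenerate conventions: no predicted positives → F1 = 1
if there are also no true positives, else 0. Tree depth is selected over
3–20 by maximal LOO F1, smallest depth on ties (with four binary features
trees saturate at depth 4, so the curve is flat beyond it). The CD8 median
is computed once on the full cohort, not per fold, matching binarization
preceding modeling. ROC AUC is the rank-sum estimator,
P(score_pos > score_neg) + ½P(tie).

## Cohort statistics

Fisher's exact test (2×2) and Kruskal–Wallis are delegated to scipy;
Kaplan–Meier, log-rank and Cox regression to lifelines; BH q-values to
statsmodels. Cox ties use Efron's method (the lifelines default). Note
that Efron's correction is only approximately invariant to duplicating
every record, since duplication creates ties at every event time. Tables
larger than 2×2 use a seeded Monte-Carlo Fisher test (≥10⁵ draws of tables
with the observed margins via label permutation; add-one p estimate).
Zero-margin tables return p = 1 with a warning. Per-gene and per-pathway
frequency comparisons are two-sided, use set semantics (a patient is
altered for a gene if any record of any alteration type names it), and
report BH q-values alongside raw p-values; headline comparisons use raw
p < 0.05. The packaged pathway sets are compact curated subsets of the
oncogenic signaling pathways recurrently altered in lung cancer (TP53,
cell cycle, Hippo, WNT, RTK–RAS) and can be replaced by any
pathway → gene-set mapping. The KM median is the smallest time with
S(t) ≤ 0.5, undefined if the curve never reaches 0.5.

## Synthetic data: what it emulates, and what it does not

Coverage at a heterozygous site j uses a shared LogNormal(0, σ=0.1) site
factor scaling both tumor and normal Poisson depths — capture efficiency
varies per probe but affects both libraries — with tumor allele rates
following exactly the forward model the caller inverts (lost allele c = 0,
kept c = 1). This yields overdispersed marginal counts while keeping the
paired imbalance test calibrated (null p-values are KS-uniform in the
acceptance suite). Defaults are the study conditions: purity 0.4–0.9,
ploidy 1.8–4.0, 100× site depth, 30 sites per gene, homozygosity rate 0.1
per gene, per-gene LOH event rate 0.09 (≈76% LOH-negative patients with
three heterozygous genes), 1 Mb panel, 2–30 mutations per patient, binder
fraction 0.3.

Copy-number profiles place one covered megabase per autosome and assign
exactly the requested fraction of covered length (to base-pair rounding)
to ψ±1, so the CIN score is closed-form: 100·f. Mutation catalogs plant
the mock anchor immediately after the central mutant residue in a
controlled count of contexts and draw all other residues from the
non-anchor alphabet, so the planted binder count is exact. The ICI cohort
draws response from a logistic model over the four binarized features
(intercept −2.0, ≈40% DCB under the default log-odds −1/+1/+1/+1,
matching realistic ICI benefit rates) and OS/PFS from exponential
survival with independent uniform censoring on 6–36 months; the default
planted effect is an OS/PFS hazard ratio of 2 on LOH presence and null
effects elsewhere, mirroring a cohort where only HLA LOH is prognostic.
All randomness descends from one seed through named SeedSequence spawn
keys (stream, patient), so adding patients never perturbs earlier ones.

Known limitations. LOH events are independent per gene, as configured;
real HLA LOH is usually a single 6p21 haplotype loss spanning all three
genes, so simulated cohorts under-represent grade-high patients relative
to real ones (most simulated events are 1/6, i.e. low). Site counts are
Poisson given the site factor — no mapping bias toward the reference
allele, no FFPE artifacts; allele frequencies are uniform over a small
packaged pool; survival is exponential (Weibull shape effects absent);
mutational contexts are i.i.d. residues, not real proteome windows.
Passing tests therefore demonstrate correctness of the estimators and
decision rules under their own generative assumptions, not robustness to
the full mess of clinical sequencing data.

## Problem sizes and numerical choices

The acceptance experiments use a 60-patient cohort (LOH event rate 0.2,
giving ≥20 planted events) for sensitivity/specificity, 500 no-LOH genes
for null calibration, 1,000 random cases for the enumeration oracle, 200
random cohorts of n ≤ 12 for the exhaustive LOO-F1 oracle, 2,000 null
replicates for type-I error of Kruskal–Wallis and log-rank, and n = 500
for Cox hazard-ratio recovery — sizes at which each check is decisive
while the whole suite runs in minutes on one core. Tie-breaks and
degenerate-input conventions (zero-variance t-test, leaf ties, F1 with no
positive predictions, smallest-depth maximizer) are fixed as described
above so every result is deterministic given the seed.
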