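"""HLA loss-of-heterozygosity calling and grading.

The caller follows the allele-specific coverage logic of LOHHLA-style
methods: at each heterozygous site of an HLA gene, the tumor/normal read
ratio for each allele is converted into an integer-scale allele copy number
using the sample's purity (rho) and ploidy (psi), assuming the normal is
diploid at the locus.

Forward model for one allele with tumor copy number c at purity rho:

    r = (rho * c + (1 - rho)) / ((rho * psi + 2 * (1 - rho)) / 2)

where r is the library-size-normalized tumor/normal coverage ratio of the
allele. Inverting gives the per-site estimate

    c_hat = (r * (rho * psi + 2 * (1 - rho)) / 2 - (1 - rho)) / rho

which is exact when counts equal their noise-free expectations. Per-gene
allele copy numbers are the medians over sites (robust to site outliers).

A gene is called LOH when BOTH hold:
  1) the minor-allele copy number is below 0.5, and
  2) allelic imbalance is significant at p < 0.01 by a two-sided paired
     Student's t-test over the per-site copy-number estimates of the two
     alleles.

Patient-level grading counts LOH alleles against the number of distinct
HLA alleles carried (3-6):
  negative: no allele with LOH;
  low:      1/6, 2/6 or 1/5;
  high:     1/3, 1/4, >=3/6 or >=2/5 (and, extending the rule monotonically,
            any fraction at least as extreme for its denominator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GENES, HlaGenotype, PuritySample, SiteCountTable


class InsufficientDataError(ValueError):
    """Too few usable sites to estimate allele copy number or test imbalance."""


@dataclass(frozen=True)
class AlleleCnEstimate:
    """Per-site and aggregated allele copy-number estimates for one gene.

    Estimates are reported unclamped; sampling noise can push them below 0.
    """

    gene: str
    per_site_cn_allele1: tuple[float, ...]
    per_site_cn_allele2: tuple[float, ...]
    cn_allele1: float
    cn_allele2: float
    n_sites: int


@dataclass(frozen=True)
class LohCall:
    gene: str
    is_loh: bool
    lost_allele: str | None
    kept_allele: str | None
    minor_cn: float
    p_value: float


@dataclass(frozen=True)
class LohGrade:
    patient_id: str
    n_loh: int
    n_alleles: int
    grade: str


def estimate_allele_cn(counts: SiteCountTable, sample: PuritySample) -> AlleleCnEstimate:
    """Estimate the copy number of both alleles of one heterozygous gene.

    Sites where either allele has zero normal coverage are dropped from both
    alleles (pairing preserved). Requires at least two usable sites.
    """
    rho, psi = sample.purity, sample.ploidy
    if rho <= 0:
        raise ValueError(f"purity must be positive, got {rho}")
    arr = np.asarray(counts.sites, dtype=float)
    if arr.size == 0:
        raise InsufficientDataError(f"{counts.patient_id}/{counts.gene}: no sites")
    t1, t2, n1, n2 = arr[:, 1], arr[:, 2], arr[:, 3], arr[:, 4]
    usable = (n1 > 0) & (n2 > 0)
    if usable.sum() < 2:
        raise InsufficientDataError(
            f"{counts.patient_id}/{counts.gene}: fewer than 2 sites with nonzero normal coverage"
        )
    scale = counts.normal_lib_size / counts.tumor_lib_size
    k = (rho * psi + 2.0 * (1.0 - rho)) / 2.0
    c1 = ((t1[usable] / n1[usable]) * scale * k - (1.0 - rho)) / rho
    c2 = ((t2[usable] / n2[usable]) * scale * k - (1.0 - rho)) / rho
    return AlleleCnEstimate(
        gene=counts.gene,
        per_site_cn_allele1=tuple(c1),
        per_site_cn_allele2=tuple(c2),
        cn_allele1=float(np.median(c1)),
        cn_allele2=float(np.median(c2)),
        n_sites=int(usable.sum()),
    )


def test_allelic_imbalance(est: AlleleCnEstimate) -> float:
    """Two-sided paired t-test of per-site copy numbers of the two alleles.

    Degenerate cases: all per-site differences exactly zero -> p = 1; zero
    variance with nonzero mean -> p = 0.
    """
    if est.n_sites < 2:
        raise InsufficientDataError(f"{est.gene}: paired t-test needs >= 2 sites")
    d = np.asarray(est.per_site_cn_allele1) - np.asarray(est.per_site_cn_allele2)
    if np.ptp(d) == 0.0:
        return 1.0 if d[0] == 0.0 else 0.0
    return float(stats.ttest_rel(est.per_site_cn_allele1, est.per_site_cn_allele2).pvalue)


def call_gene_loh(
    est: AlleleCnEstimate,
    cn_threshold: float = 0.5,
    alpha: float = 0.01,
    allele_names: tuple[str, str] | None = None,
) -> LohCall:
    """Call LOH for one gene: minor CN < ``cn_threshold`` AND imbalance
    p < ``alpha``."""
    p = test_allelic_imbalance(est)
    names = allele_names if allele_names is not None else ("allele1", "allele2")
    if est.cn_allele1 <= est.cn_allele2:
        minor_cn, minor, major = est.cn_allele1, names[0], names[1]
    else:
        minor_cn, minor, major = est.cn_allele2, names[1], names[0]
    is_loh = (minor_cn < cn_threshold) and (p < alpha)
    return LohCall(
        gene=est.gene,
        is_loh=is_loh,
        lost_allele=minor if is_loh else None,
        kept_allele=major if is_loh else None,
        minor_cn=float(minor_cn),
        p_value=p,
    )


def grade_lookup(n_loh: int, n_alleles: int) -> str:
    """Three-tier grade from the LOH-allele fraction.

    Total and deterministic over 0 <= n_loh <= 3, n_alleles in {3..6};
    monotone in n_loh for each denominator.
    """
    if n_alleles not in (3, 4, 5, 6):
        raise ValueError(f"n_alleles must be in 3..6, got {n_alleles}")
    if n_loh < 0 or n_loh > 3:
        raise ValueError(f"n_loh must be in 0..3, got {n_loh}")
    if n_loh == 0:
        return "negative"
    if n_alleles == 6:
        return "low" if n_loh <= 2 else "high"
    if n_alleles == 5:
        return "low" if n_loh == 1 else "high"
    # denominators 4 and 3: any LOH is high
    return "high"


def grade_patient_loh(calls: Sequence[LohCall], genotype: HlaGenotype) -> LohGrade:
    """Grade a patient from per-gene LOH calls.

    Calls are accepted only for heterozygous genes; homozygous genes are not
    assessable and contribute a single allele to the denominator and zero to
    the LOH count.
    """
    het = genotype.heterozygous
    seen: set[str] = set()
    for call in calls:
        if call.gene not in het:
            raise ValueError(f"{genotype.patient_id}: unknown gene {call.gene!r}")
        if not het[call.gene]:
            raise ValueError(
                f"{genotype.patient_id}: LOH call supplied for homozygous gene {call.gene}"
            )
        if call.gene in seen:
            raise ValueError(f"{genotype.patient_id}: duplicate call for gene {call.gene}")
        seen.add(call.gene)
    n_loh = sum(c.is_loh for c in calls)
    n_alleles = genotype.n_distinct_alleles
    return LohGrade(genotype.patient_id, n_loh, n_alleles, grade_lookup(n_loh, n_alleles))


def call_cohort_loh(
    tables: Sequence[SiteCountTable],
    samples: Sequence[PuritySample],
    genotypes: Sequence[HlaGenotype],
    cn_threshold: float = 0.5,
    alpha: float = 0.01,
    missing_gene: Literal["assume_intact", "skip_patient"] = "assume_intact",
) -> list[LohGrade]:
    """Call and grade HLA LOH for every genotyped patient.

    A heterozygous gene with no coverage table is reported with a warning and
    either treated as no-LOH (``assume_intact``, default) or causes the
    patient to be skipped (``skip_patient``).
    """
    geno_by_pid = {g.patient_id: g for g in genotypes}
    purity_by_pid = {s.patient_id: s for s in samples}
    tables_by_pid: dict[str, dict[str, SiteCountTable]] = {}
    for t in tables:
        if t.patient_id not in geno_by_pid:
            raise ValueError(f"count table for unknown patient {t.patient_id!r}")
        tables_by_pid.setdefault(t.patient_id, {})[t.gene] = t

    grades: list[LohGrade] = []
    for geno in genotypes:
        pid = geno.patient_id
        if pid not in purity_by_pid:
            raise ValueError(f"no purity/ploidy sample for patient {pid!r}")
        sample = purity_by_pid[pid]
        calls: list[LohCall] = []
        incomplete = False
        for gene in GENES:
            if not geno.heterozygous[gene]:
                continue
            table = tables_by_pid.get(pid, {}).get(gene)
            if table is None:
                warnings.warn(
                    f"{pid}: no coverage for heterozygous gene {gene}; "
                    + ("treated as no-LOH" if missing_gene == "assume_intact"
                       else "patient skipped"),
                    stacklevel=2,
                )
                if missing_gene == "skip_patient":
                    incomplete = True
                    break
                continue
            est = estimate_allele_cn(table, sample)
            calls.append(call_gene_loh(est, cn_threshold, alpha,
                                       allele_names=geno.alleles[gene]))
        if incomplete:
            continue
        grades.append(grade_patient_loh(calls, geno))
    return grades


def cohort_loh_report(
    tables: Sequence[SiteCountTable],
    samples: Sequence[PuritySample],
    genotypes: Sequence[HlaGenotype],
    cn_threshold: float = 0.5,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Tidy per-gene report: one row per assessable (patient, gene)."""
    geno_by_pid = {g.patient_id: g for g in genotypes}
    purity_by_pid = {s.patient_id: s for s in samples}
    grades = {
        g.patient_id: g
        for g in call_cohort_loh(tables, samples, genotypes, cn_threshold, alpha)
    }
    rows = []
    for t in tables:
        geno = geno_by_pid[t.patient_id]
        est = estimate_allele_cn(t, purity_by_pid[t.patient_id])
        call = call_gene_loh(est, cn_threshold, alpha, allele_names=geno.alleles[t.gene])
        grade = grades[t.patient_id]
        rows.append({
            "patient_id": t.patient_id, "gene": t.gene,
            "cn_allele1": est.cn_allele1, "cn_allele2": est.cn_allele2,
            "p_value": call.p_value, "is_loh": call.is_loh,
            "lost_allele": call.lost_allele or "",
            "n_loh": grade.n_loh, "n_alleles": grade.n_alleles, "grade": grade.grade,
        })
    return pd.DataFrame(rows)


def summarize_grades(grades: Sequence[LohGrade] | Mapping[str, int]) -> pd.DataFrame:
    """Cohort grading summary: patient counts and percentages per grade.

    Accepts either per-patient grades or a precomputed ``grade -> count``
    mapping. Percentages are reported to two decimals, as in cohort reports.
    """
    if isinstance(grades, Mapping):
        counts = {g: int(grades.get(g, 0)) for g in ("negative", "low", "high")}
    else:
        counts = {g: 0 for g in ("negative", "low", "high")}
        for grade in grades:
            counts[grade.grade] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty cohort")
    return pd.DataFrame(
        [{"grade": g, "n": n, "pct": round(100.0 * n / total, 2)}
         for g, n in counts.items()]
    )
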