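"""Allele copy-number estimation, imbalance testing, LOH calling and grading."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from lohkit.hla_loh import (
    AlleleCnEstimate,
    InsufficientDataError,
    call_cohort_loh,
    call_gene_loh,
    estimate_allele_cn,
    grade_lookup,
    grade_patient_loh,
    summarize_grades,
    test_allelic_imbalance as imbalance_p,
)
from lohkit.io_formats import HlaGenotype, PuritySample, SiteCountTable
from lohkit.synthetic_data import SimConfig, simulate_genotypes, simulate_site_counts


def _table(t1, t2, n1, n2, tlib=1000, nlib=1000):
    sites = tuple(
        (i + 1, a, b, c, d) for i, (a, b, c, d) in enumerate(zip(t1, t2, n1, n2))
    )
    return SiteCountTable("P1", "A", sites, tlib, nlib)


def _expected_counts(c, rho, psi, depth=100):
    """Noise-free forward model: expected tumor count for allele copy c."""
    k = (rho * psi + 2 * (1 - rho)) / 2
    return depth * (rho * c + (1 - rho)) / k / 2


# ---------------------------------------------------------------------------
# copy-number estimation
# ---------------------------------------------------------------------------

def test_pure_balanced_tumor_gives_cn_one():
    # rho=1, psi=2, tumor/normal ratio 1 at every site -> c = 1 exactly
    tab = _table([50, 60, 70], [50, 60, 70], [50, 60, 70], [50, 60, 70])
    est = estimate_allele_cn(tab, PuritySample("P1", 1.0, 2.0))
    assert est.cn_allele1 == pytest.approx(1.0)
    assert est.cn_allele2 == pytest.approx(1.0)


@pytest.mark.parametrize("rho,psi,ratio,expected", [
    (0.5, 2.0, 0.5, 0.0),   # lost allele at half purity
    (0.5, 3.0, 1.2, 2.0),   # amplified allele in triploid tumor
])
def test_forward_model_inversion(rho, psi, ratio, expected):
    normal = [100, 100, 100]
    tumor = [int(round(ratio * n)) for n in normal]
    est = estimate_allele_cn(_table(tumor, tumor, normal, normal),
                             PuritySample("P1", rho, psi))
    assert est.cn_allele1 == pytest.approx(expected)


@given(
    rho=st.floats(0.05, 1.0),
    psi=st.floats(0.5, 6.0),
    c=st.floats(0.0, 4.0),
)
def test_estimator_exact_on_noise_free_expectations(rho, psi, c):
    """Inversion recovers any allele copy number exactly when counts equal
    their expectations (library sizes equal)."""
    depth = 1e6  # large so expectations are representable exactly enough
    lam_t = _expected_counts(c, rho, psi, depth)
    lam_n = depth / 2
    tab = _table([lam_t] * 3, [lam_t] * 3, [lam_n] * 3, [lam_n] * 3)
    est = estimate_allele_cn(tab, PuritySample("P1", rho, psi))
    assert est.cn_allele1 == pytest.approx(c, abs=1e-9)


def test_sites_with_zero_normal_dropped_pairwise():
    tab = _table([50, 50, 99], [50, 50, 99], [50, 50, 0], [50, 50, 50])
    est = estimate_allele_cn(tab, PuritySample("P1", 1.0, 2.0))
    assert est.n_sites == 2
    assert est.cn_allele2 == pytest.approx(1.0)  # the 99/50 site is gone for both


def test_too_few_usable_sites_raises():
    tab = _table([50, 50], [50, 50], [50, 0], [50, 50])
    with pytest.raises(InsufficientDataError):
        estimate_allele_cn(tab, PuritySample("P1", 1.0, 2.0))


# ---------------------------------------------------------------------------
# paired imbalance test
# ---------------------------------------------------------------------------

def _est(c1, c2):
    return AlleleCnEstimate("A", tuple(c1), tuple(c2),
                            float(np.median(c1)), float(np.median(c2)), len(c1))


def test_identical_allele_profiles_give_p_one():
    assert imbalance_p(_est([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])) == 1.0


def test_constant_nonzero_difference_gives_p_zero():
    assert imbalance_p(_est([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])) == 0.0


def test_zero_mean_differences_give_p_one():
    # differences [1, -1, 1, -1] -> t = 0 -> p = 1
    p = imbalance_p(_est([2.0, 1.0, 2.0, 1.0], [1.0, 2.0, 1.0, 2.0]))
    assert p == pytest.approx(1.0)


def test_strong_imbalance_matches_t_distribution_oracle():
    c1 = [1.9, 2.1, 2.0, 1.95, 2.05]
    c2 = [0.1, -0.1, 0.0, 0.05, -0.05]
    d = np.array(c1) - np.array(c2)
    t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    expected = 2 * stats.t.sf(abs(t), df=len(d) - 1)
    p = imbalance_p(_est(c1, c2))
    assert p == pytest.approx(expected)
    assert p == pytest.approx(9e-6, rel=0.1)
    assert p < 0.01


def test_single_site_raises():
    with pytest.raises(InsufficientDataError):
        imbalance_p(_est([1.0], [0.0]))


# ---------------------------------------------------------------------------
# gene-level calls
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("minor_cn,p,expected", [
    (0.2, 0.001, True),   # both conditions met
    (0.2, 0.05, False),   # imbalance not significant
    (0.8, 0.001, False),  # minor CN not below threshold
])
def test_loh_requires_both_conditions(minor_cn, p, expected, monkeypatch):
    est = _est([1.8] * 5, [minor_cn] * 5)
    monkeypatch.setattr("lohkit.hla_loh.test_allelic_imbalance", lambda e: p)
    call = call_gene_loh(est, allele_names=("A*01:01", "A*02:01"))
    assert call.is_loh is expected
    assert call.minor_cn == pytest.approx(minor_cn)
    if expected:
        assert call.lost_allele == "A*02:01"
        assert call.kept_allele == "A*01:01"
    else:
        assert call.lost_allele is None


@given(
    cn=st.floats(-0.5, 3.0), p=st.floats(0.0, 1.0),
    thr=st.floats(0.1, 0.5), alpha=st.floats(0.001, 0.01),
)
def test_tightening_thresholds_never_creates_loh(cn, p, thr, alpha):
    """Lowering cn_threshold or alpha can only remove LOH calls."""
    from unittest.mock import patch

    est = _est([1.8] * 5, [cn] * 5)
    with patch("lohkit.hla_loh.test_allelic_imbalance", lambda e: p):
        loose = call_gene_loh(est, cn_threshold=0.5, alpha=0.01).is_loh
        tight = call_gene_loh(est, cn_threshold=thr, alpha=alpha).is_loh
    assert not (tight and not loose)


# ---------------------------------------------------------------------------
# grading
# ---------------------------------------------------------------------------

PRINTED_GRADES = {
    # all printed fractions of the three-tier rule
    (0, 6): "negative", (0, 5): "negative", (0, 4): "negative", (0, 3): "negative",
    (1, 6): "low", (2, 6): "low", (1, 5): "low",
    (1, 3): "high", (1, 4): "high", (3, 6): "high", (2, 5): "high", (3, 5): "high",
}


@pytest.mark.parametrize("key,expected", sorted(PRINTED_GRADES.items()))
def test_grading_matches_printed_rule(key, expected):
    assert grade_lookup(*key) == expected


def test_grading_total_and_monotone():
    """Defined for every feasible pair; never decreases as n_loh grows."""
    order = {"negative": 0, "low": 1, "high": 2}
    for n_alleles in (3, 4, 5, 6):
        grades = [grade_lookup(n, n_alleles) for n in range(0, 4)]
        assert grades[0] == "negative"
        assert all(g != "negative" for g in grades[1:])
        assert all(order[a] <= order[b] for a, b in zip(grades, grades[1:]))


def _genotype(pid="P1", hom=()):
    alleles = {
        "A": ("A*01:01", "A*01:01") if "A" in hom else ("A*01:01", "A*02:01"),
        "B": ("B*07:02", "B*07:02") if "B" in hom else ("B*07:02", "B*08:01"),
        "C": ("C*07:01", "C*07:01") if "C" in hom else ("C*07:01", "C*07:02"),
    }
    return HlaGenotype(pid, alleles)


def _call(gene, is_loh):
    if is_loh:
        est = AlleleCnEstimate(gene, (1.9, 2.1, 2.0), (0.05, -0.05, 0.0), 2.0, 0.0, 3)
    else:
        est = AlleleCnEstimate(gene, (1.0, 1.1, 0.9), (1.0, 1.1, 0.9), 1.0, 1.0, 3)
    call = call_gene_loh(est)
    assert call.is_loh is is_loh
    return call


def test_grade_patient_counts_loh_calls():
    geno = _genotype()
    calls = [_call("A", True), _call("B", True), _call("C", False)]
    grade = grade_patient_loh(calls, geno)
    assert (grade.n_loh, grade.n_alleles, grade.grade) == (2, 6, "low")


def test_homozygous_gene_call_is_rejected():
    geno = _genotype(hom=("A",))
    with pytest.raises(ValueError, match="homozygous"):
        grade_patient_loh([_call("A", False)], geno)


def test_homozygous_genes_shrink_denominator():
    geno = _genotype(hom=("A", "B"))
    assert geno.n_distinct_alleles == 4
    grade = grade_patient_loh([_call("C", True)], geno)
    assert grade.grade == "high"  # 1/4 is high


# ---------------------------------------------------------------------------
# cohort calling
# ---------------------------------------------------------------------------

def test_empty_cohort():
    assert call_cohort_loh([], [], []) == []


def test_balanced_patient_grades_negative(rng):
    cfg = SimConfig(seed=5, n_patients=1, homozygosity_rate=0.0)
    (geno,) = simulate_genotypes(cfg)
    tables = simulate_site_counts(geno, {}, 0.8, 2.0, cfg, rng)
    grades = call_cohort_loh(list(tables.values()),
                             [PuritySample(geno.patient_id, 0.8, 2.0)], [geno])
    assert grades[0].grade == "negative"


def test_planted_single_loss_grades_low(rng):
    cfg = SimConfig(seed=5, n_patients=1, homozygosity_rate=0.0)
    (geno,) = simulate_genotypes(cfg)
    tables = simulate_site_counts(geno, {"A": True}, 0.8, 2.0, cfg, rng)
    grades = call_cohort_loh(list(tables.values()),
                             [PuritySample(geno.patient_id, 0.8, 2.0)], [geno])
    assert (grades[0].n_loh, grades[0].n_alleles, grades[0].grade) == (1, 6, "low")


def test_unknown_patient_in_tables_raises(rng):
    cfg = SimConfig(seed=5, n_patients=1, homozygosity_rate=0.0)
    (geno,) = simulate_genotypes(cfg)
    tables = list(simulate_site_counts(geno, {}, 0.8, 2.0, cfg, rng).values())
    with pytest.raises(ValueError, match="unknown patient"):
        call_cohort_loh(tables, [PuritySample(geno.patient_id, 0.8, 2.0)], [])


def test_missing_gene_warns_and_assumes_intact(rng):
    cfg = SimConfig(seed=5, n_patients=1, homozygosity_rate=0.0)
    (geno,) = simulate_genotypes(cfg)
    tables = simulate_site_counts(geno, {}, 0.8, 2.0, cfg, rng)
    partial = [tables["A"], tables["B"]]
    sample = [PuritySample(geno.patient_id, 0.8, 2.0)]
    with pytest.warns(UserWarning, match="no coverage"):
        grades = call_cohort_loh(partial, sample, [geno])
    assert grades[0].grade == "negative"
    with pytest.warns(UserWarning):
        skipped = call_cohort_loh(partial, sample, [geno], missing_gene="skip_patient")
    assert skipped == []


def test_summarize_grades_from_counts():
    df = summarize_grades({"negative": 3, "low": 1, "high": 1})
    assert df.loc[df.grade == "negative", "pct"].item() == 60.0
    assert df.n.sum() == 5
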