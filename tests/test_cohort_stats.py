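"""Fisher/Kruskal-Wallis tests, alteration-frequency comparisons, survival."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from lohkit.cohort_stats import (
    DEFAULT_PATHWAYS,
    cox_multivariate,
    fisher_exact,
    gene_frequency_compare,
    km_estimate,
    kruskal_wallis,
    logrank_test,
    pathway_alteration_frequency,
)
from lohkit.io_formats import MutationRecord
from lohkit.synthetic_data import SimConfig, simulate_cohort


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

from oracles import hypergeom_two_sided


def test_fisher_worked_example():
    # margins (2,2)/(2,2): only the diagonal tables are as extreme
    assert fisher_exact([[2, 0], [0, 2]]) == pytest.approx(1 / 3)


def test_fisher_symmetric_table():
    assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)


def test_fisher_zero_margin_warns():
    with pytest.warns(UserWarning, match="zero margin"):
        assert fisher_exact([[0, 0], [3, 4]]) == 1.0


def test_fisher_agrees_with_enumeration_small_n():
    """Exhaustive agreement with the hypergeometric oracle, N <= 12
    (the acceptance suite extends this to N <= 30)."""
    for n in range(1, 13):
        for a, b, c in itertools.product(range(n + 1), repeat=3):
            d = n - a - b - c
            if d < 0:
                continue
            if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
                continue
            assert fisher_exact([[a, b], [c, d]]) == pytest.approx(
                hypergeom_two_sided(a, b, c, d), abs=1e-9
            ), (a, b, c, d)


def test_fisher_monte_carlo_reproducible_and_calibrated():
    table = [[8, 2, 1], [3, 7, 4]]
    p1 = fisher_exact(table, seed=42, n_draws=20_000)
    p2 = fisher_exact(table, seed=42, n_draws=20_000)
    assert p1 == p2
    # cross-check against scipy's exact chi2-free alternative on a collapsed
    # scale: MC p should be within MC error of R-style exact p (~0.047)
    assert 0.01 < p1 < 0.12


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def test_kruskal_identical_groups():
    assert kruskal_wallis([[1.0, 1.0], [1.0, 1.0]]) == (0.0, 1.0)


def test_kruskal_hand_computed_example():
    h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
    # ranks 1..6, mean ranks 2 and 5: H = 12/42 * (3*2.25 + 3*2.25) = 3.857
    assert h == pytest.approx(3.857, abs=1e-3)
    assert p == pytest.approx(stats.chi2.sf(h, df=1))


def test_kruskal_group_order_symmetry():
    g = [[1.0, 5.0, 3.0], [2.0, 8.0], [0.5, 9.0, 4.0]]
    assert kruskal_wallis(g) == kruskal_wallis(g[::-1])


def test_kruskal_empty_group_raises():
    with pytest.raises(ValueError):
        kruskal_wallis([[1.0], []])


def test_kruskal_type_one_error_near_nominal(rng):
    rejections = 0
    reps = 2000
    for _ in range(reps):
        groups = [rng.normal(size=8), rng.normal(size=8), rng.normal(size=8)]
        _, p = kruskal_wallis(groups)
        rejections += p < 0.05
    assert rejections / reps == pytest.approx(0.05, abs=0.02)


# ---------------------------------------------------------------------------
# alteration-frequency comparisons
# ---------------------------------------------------------------------------

def _mut(pid, gene):
    return MutationRecord(pid, gene, "nonsynonymous", "mutation", "ACDEFGHIKA", 5)


GRADES = {"H1": "high", "H2": "high", "H3": "high",
          "N1": "negative", "N2": "negative", "N3": "negative", "L1": "low"}


def test_gene_frequency_perfect_separation():
    muts = {p: [_mut(p, "TP53")] for p in ("H1", "H2", "H3")}
    df = gene_frequency_compare(muts, GRADES, ["TP53", "EGFR"])
    row = df[df.gene == "TP53"].iloc[0]
    assert (row.freq_high, row.freq_negative) == (1.0, 0.0)
    assert row.p_value == pytest.approx(hypergeom_two_sided(3, 0, 0, 3))
    absent = df[df.gene == "EGFR"].iloc[0]
    assert (absent.freq_high, absent.freq_negative, absent.p_value) == (0, 0, 1.0)


def test_gene_frequency_set_semantics_and_low_excluded():
    muts = {"H1": [_mut("H1", "TP53"), _mut("H1", "TP53")],
            "L1": [_mut("L1", "TP53")]}
    df = gene_frequency_compare(muts, GRADES, ["TP53"])
    assert df.iloc[0].freq_high == pytest.approx(1 / 3)  # duplicates count once


def test_gene_frequency_requires_both_groups():
    with pytest.raises(ValueError):
        gene_frequency_compare({}, {"H1": "high"}, ["TP53"])


def test_pathway_single_gene_reduces_to_gene_compare():
    muts = {p: [_mut(p, "TP53")] for p in ("H1", "H2", "N1")}
    genes = gene_frequency_compare(muts, GRADES, ["TP53"])
    with pytest.warns(UserWarning):  # the other pathways have no altered gene
        paths = pathway_alteration_frequency(muts, GRADES,
                                             {"solo": {"TP53"}, "empty_hit": {"ZZZ9"}})
    solo = paths[paths.pathway == "solo"].iloc[0]
    assert solo.p_value == pytest.approx(genes.iloc[0].p_value)
    assert solo.freq_high == genes.iloc[0].freq_high


def test_pathway_membership_is_any_member_gene():
    muts = {"H1": [_mut("H1", "MDM2")], "N1": [_mut("N1", "KRAS")]}
    df = pathway_alteration_frequency(muts, GRADES, DEFAULT_PATHWAYS)
    tp53 = df[df.pathway == "TP53"].iloc[0]
    rtk = df[df.pathway == "RTK-RAS"].iloc[0]
    assert tp53.freq_high == pytest.approx(1 / 3)
    assert tp53.freq_negative == 0.0
    assert rtk.freq_negative == pytest.approx(1 / 3)


def test_planted_pathway_enrichment_detected(rng):
    """A pathway altered in most high-grade patients scores lower p than
    null pathways."""
    grades = {f"H{i}": "high" for i in range(20)}
    grades.update({f"N{i}": "negative" for i in range(20)})
    muts = {}
    for pid in grades:
        genes = []
        if pid.startswith("H") or rng.random() < 0.1:
            genes.append("TP53")
        if rng.random() < 0.3:
            genes.append("KRAS")  # null background
        muts[pid] = [_mut(pid, g) for g in genes]
    df = pathway_alteration_frequency(
        muts, grades, {"planted": {"TP53"}, "null": {"KRAS"}})
    planted = df.set_index("pathway").loc["planted"]
    null = df.set_index("pathway").loc["null"]
    assert planted.p_value < 0.001 < null.p_value


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def test_km_no_censoring_equals_empirical_survival():
    curve = km_estimate([1, 2, 3, 4, 5], [True] * 5)
    drops = dict(zip(curve.times, curve.survival))
    assert drops[3.0] == pytest.approx(0.4)
    assert curve.median == 3.0
    assert curve.survival[-1] == pytest.approx(0.0)


def test_km_all_censored():
    curve = km_estimate([1, 2, 3], [False] * 3)
    assert all(s == 1.0 for s in curve.survival)
    assert curve.median is None


def test_km_single_event():
    curve = km_estimate([1.0], [True])
    assert curve.survival[-1] == 0.0
    assert curve.median == 1.0


def test_km_empty_raises():
    with pytest.raises(ValueError):
        km_estimate([], [])


def test_logrank_identical_groups_and_symmetry():
    t = [1, 2, 3, 4, 5]
    e = [True, True, False, True, False]
    chi2, p = logrank_test(t, e, t, e)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)
    ta, ea = [1, 2, 5, 7], [True, True, False, True]
    tb, eb = [3, 4, 6], [True, False, True]
    assert logrank_test(ta, ea, tb, eb) == pytest.approx(logrank_test(tb, eb, ta, ea))


def test_logrank_no_events_warns():
    with pytest.warns(UserWarning):
        chi2, p = logrank_test([1, 2], [False, False], [3, 4], [False, False])
    assert p == 1.0


def test_logrank_detects_strong_hazard_separation(rng):
    n = 100
    ta = rng.exponential(1.0, n)
    tb = rng.exponential(4.0, n)
    _, p = logrank_test(ta, [True] * n, tb, [True] * n)
    assert p < 0.01


def test_logrank_type_one_error_near_nominal(rng):
    rejections, reps = 0, 2000
    for _ in range(reps):
        t = rng.exponential(1.0, (2, 25))
        c = rng.uniform(0, 3.0, (2, 25))
        times = np.minimum(t, c)
        events = t <= c
        _, p = logrank_test(times[0], events[0], times[1], events[1])
        rejections += p < 0.05
    assert rejections / reps == pytest.approx(0.05, abs=0.02)


def test_cox_recovers_planted_hazard_ratio():
    cfg = SimConfig(seed=7, n_patients=500, loh_event_rate=0.25,
                    os_log_hr={"loh_present": math.log(2.0)})
    sim = simulate_cohort(cfg)
    df = cox_multivariate(sim.cohort, tmb_cut=cfg.tmb_high_cut, endpoint="os")
    loh = df.set_index("covariate").loc["loh_present"]
    assert 1.6 <= loh.hr <= 2.5
    assert loh.ci95_low <= 2.0 <= loh.ci95_high
    assert loh.p_value < 0.05


def test_cox_null_covariates_cover_one():
    cfg = SimConfig(seed=7, n_patients=500, loh_event_rate=0.25,
                    os_log_hr={"loh_present": math.log(2.0)})
    sim = simulate_cohort(cfg)
    df = cox_multivariate(sim.cohort, tmb_cut=cfg.tmb_high_cut, endpoint="os")
    for cov in ("tmb_high", "pdl1_high", "cd8_high"):
        row = df.set_index("covariate").loc[cov]
        assert row.ci95_low <= 1.0 <= row.ci95_high


def test_cox_duplicated_records_same_estimates():
    cfg = SimConfig(seed=13, n_patients=120, loh_event_rate=0.25)
    sim = simulate_cohort(cfg)
    df1 = cox_multivariate(sim.cohort, tmb_cut=cfg.tmb_high_cut)
    df2 = cox_multivariate(list(sim.cohort) * 2, tmb_cut=cfg.tmb_high_cut)
    # duplication creates ties at every event time; Efron's correction makes
    # the partial likelihood only approximately duplication-invariant
    assert np.allclose(df1.hr, df2.hr, rtol=1e-2)


def test_cox_constant_covariate_named():
    cfg = SimConfig(seed=13, n_patients=60, loh_event_rate=0.0)
    sim = simulate_cohort(cfg)
    with pytest.raises(ValueError, match="loh_present"):
        cox_multivariate(sim.cohort, tmb_cut=cfg.tmb_high_cut)
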