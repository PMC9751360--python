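"""Cohort-level statistics: group comparisons, gene/pathway alteration
frequencies, and survival analysis.

Standard tests are delegated: Fisher's exact (2x2) and Kruskal-Wallis to
scipy, Kaplan-Meier / log-rank / Cox (Efron ties) to lifelines,
Benjamini-Hochberg to statsmodels. Larger-than-2x2 contingency tables use a
seeded Monte-Carlo Fisher test. Per-gene and per-pathway outputs carry BH
q-values alongside raw p-values; the headline comparisons use raw p < 0.05.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .biomarker_model import FEATURE_ORDER, binarize_features
from .io_formats import CohortRecord, MutationRecord
from .hla_loh import LohGrade

#: Compact curated subsets of the oncogenic signaling pathways most often
#: altered in lung cancer; user-overridable via any pathway->genes mapping.
DEFAULT_PATHWAYS: dict[str, frozenset[str]] = {
    "TP53": frozenset({"TP53", "MDM2", "MDM4", "ATM", "CHEK2", "RPS6KA3"}),
    "Cell cycle": frozenset({"CDKN2A", "CDKN2B", "CCND1", "CCNE1", "CDK4", "CDK6", "RB1"}),
    "Hippo": frozenset({"NF2", "LATS1", "LATS2", "FAT1", "TAOK1", "TAOK2", "YAP1"}),
    "WNT": frozenset({"APC", "CTNNB1", "AXIN1", "AXIN2", "RNF43", "TCF7L2", "AMER1"}),
    "RTK-RAS": frozenset({"EGFR", "KRAS", "NRAS", "HRAS", "BRAF", "ERBB2", "MET",
                          "ALK", "ROS1", "RET", "NF1", "SOS1", "PTPN11"}),
}


def fisher_exact(
    table: Sequence[Sequence[int]],
    seed: int | None = None,
    n_draws: int = 100_000,
) -> float:
    """Two-sided Fisher's exact p-value.

    2x2 tables are exact (sum of hypergeometric probabilities not exceeding
    the observed table's). Larger tables use a Monte-Carlo test over tables
    with the observed margins (``n_draws`` draws, seeded). A zero row or
    column margin yields p = 1 with a warning.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        warnings.warn("zero margin in contingency table; p = 1", stacklevel=2)
        return 1.0
    if t.shape == (2, 2):
        return float(stats.fisher_exact(t, alternative="two-sided")[1])
    return _fisher_monte_carlo(t, seed=seed, n_draws=n_draws)


def _log_table_prob(t: np.ndarray, lgam: np.ndarray) -> float:
    # log multivariate hypergeometric mass given fixed margins
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    return float(
        lgam[rows].sum() + lgam[cols].sum() - lgam[t.sum()] - lgam[t].sum()
    )


def _fisher_monte_carlo(t: np.ndarray, seed: int | None, n_draws: int) -> float:
    rng = np.random.default_rng(seed)
    n = int(t.sum())
    lgam = np.array([math.lgamma(k + 1) for k in range(n + 1)])
    obs = _log_table_prob(t, lgam)
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    col_labels = np.repeat(np.arange(t.shape[1]), cols)
    row_edges = np.cumsum(rows)[:-1]
    hits = 0
    for _ in range(n_draws):
        rng.shuffle(col_labels)
        sim = np.zeros_like(t)
        for i, chunk in enumerate(np.split(col_labels, row_edges)):
            sim[i] = np.bincount(chunk, minlength=t.shape[1])
        if _log_table_prob(sim, lgam) <= obs + 1e-9:
            hits += 1
    return (hits + 1) / (n_draws + 1)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p (k-1 df).

    All observations identical across groups -> (0, 1).
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(flat) == 0.0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def _split_by_grade(
    grades: Sequence[LohGrade] | Mapping[str, str],
) -> tuple[list[str], list[str]]:
    """Patient ids in the LOH-high and LOH-negative groups."""
    if isinstance(grades, Mapping):
        items = grades.items()
    else:
        items = ((g.patient_id, g.grade) for g in grades)
    high, negative = [], []
    for pid, grade in items:
        if grade == "high":
            high.append(pid)
        elif grade == "negative":
            negative.append(pid)
    if not high or not negative:
        raise ValueError("both the LOH-high and LOH-negative groups must be non-empty")
    return high, negative


def _altered_genes(muts: Sequence[MutationRecord]) -> set[str]:
    # any record of any alteration_type marks the gene altered (set semantics)
    return {m.gene_symbol for m in muts}


def gene_frequency_compare(
    muts_by_patient: Mapping[str, Sequence[MutationRecord]],
    grades: Sequence[LohGrade] | Mapping[str, str],
    gene_universe: Sequence[str],
) -> pd.DataFrame:
    """Per-gene alteration frequency in LOH-high vs LOH-negative patients,
    with two-sided Fisher p and BH q. Sorted by p."""
    high, negative = _split_by_grade(grades)
    alt = {pid: _altered_genes(muts_by_patient.get(pid, [])) for pid in high + negative}
    rows = []
    for gene in gene_universe:
        a_high = sum(gene in alt[p] for p in high)
        a_neg = sum(gene in alt[p] for p in negative)
        p_val = fisher_exact([[a_high, len(high) - a_high],
                              [a_neg, len(negative) - a_neg]])
        rows.append({
            "gene": gene,
            "freq_high": a_high / len(high),
            "freq_negative": a_neg / len(negative),
            "p_value": p_val,
        })
    df = pd.DataFrame(rows)
    df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)


def pathway_alteration_frequency(
    muts_by_patient: Mapping[str, Sequence[MutationRecord]],
    grades: Sequence[LohGrade] | Mapping[str, str],
    pathways: Mapping[str, frozenset[str] | set[str]] = DEFAULT_PATHWAYS,
) -> pd.DataFrame:
    """Per-pathway alteration frequency (patient altered iff any member gene
    altered) in LOH-high vs LOH-negative, with Fisher p and BH q."""
    high, negative = _split_by_grade(grades)
    alt = {pid: _altered_genes(muts_by_patient.get(pid, [])) for pid in high + negative}
    universe = set().union(*alt.values()) if alt else set()
    rows = []
    for name, genes in pathways.items():
        genes = set(genes)
        if not genes:
            raise ValueError(f"pathway {name!r} has no genes")
        if not genes & universe:
            warnings.warn(
                f"pathway {name!r} has no member gene altered in the cohort",
                stacklevel=2,
            )
        a_high = sum(bool(genes & alt[p]) for p in high)
        a_neg = sum(bool(genes & alt[p]) for p in negative)
        p_val = fisher_exact([[a_high, len(high) - a_high],
                              [a_neg, len(negative) - a_neg]])
        rows.append({
            "pathway": name,
            "freq_high": a_high / len(high),
            "freq_negative": a_neg / len(negative),
            "p_value": p_val,
        })
    df = pd.DataFrame(rows)
    df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class SurvivalCurve:
    """Kaplan-Meier product-limit curve.

    ``median`` is the smallest time with S(t) <= 0.5, or None if the curve
    never reaches 0.5.
    """

    times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...]
    median: float | None


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> SurvivalCurve:
    """Kaplan-Meier estimate of the survival function."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty input")
    if (times < 0).any():
        raise ValueError("times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(timeline, fill_value=0).to_numpy(dtype=int)
    median = None
    below = surv <= 0.5
    if below.any():
        median = float(timeline[below][0])
    return SurvivalCurve(tuple(timeline), tuple(surv), tuple(at_risk), median)


def logrank_test(
    times_a: Sequence[float], events_a: Sequence[bool],
    times_b: Sequence[float], events_b: Sequence[bool],
) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square, p) with 1 df."""
    ea, eb = np.asarray(events_a, dtype=bool), np.asarray(events_b, dtype=bool)
    if len(times_a) == 0 or len(times_b) == 0:
        raise ValueError("both groups must be non-empty")
    if not ea.any() and not eb.any():
        warnings.warn("no events in either group; p = 1", stacklevel=2)
        return 0.0, 1.0
    res = _ll_logrank(times_a, times_b, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def cox_multivariate(
    records: Sequence[CohortRecord],
    tmb_cut: float,
    covariates: Sequence[str] = FEATURE_ORDER,
    endpoint: str = "os",
) -> pd.DataFrame:
    """Multivariate Cox proportional-hazards fit over the binarized
    biomarkers.

    Returns per-covariate hazard ratio, Wald 95% CI and p. Ties are handled
    by Efron's method. A constant covariate or a non-converging fit raises,
    naming the covariate where identifiable.
    """
    if endpoint not in ("os", "pfs"):
        raise ValueError(f"endpoint must be 'os' or 'pfs', got {endpoint!r}")
    unknown = set(covariates) - set(FEATURE_ORDER)
    if unknown:
        raise ValueError(f"unknown covariates {sorted(unknown)}")
    fvs = binarize_features(records, tmb_cut=tmb_cut)
    df = pd.DataFrame({
        "duration": [getattr(r, f"{endpoint}_months") for r in records],
        "event": [int(getattr(r, f"{endpoint}_event")) for r in records],
        **{c: [int(getattr(fv, c)) for fv in fvs] for c in covariates},
    })
    if len(df) <= len(covariates):
        raise ValueError("need more records than covariates")
    if df["event"].sum() == 0:
        raise ValueError("no events observed")
    for c in covariates:
        if df[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant; model not identifiable")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="duration", event_col="event")
    except Exception as exc:  # lifelines ConvergenceError and friends
        raise RuntimeError(
            f"Cox fit failed for covariates {list(covariates)}: {exc}"
        ) from exc
    summary = cph.summary
    return pd.DataFrame({
        "covariate": summary.index,
        "hr": np.exp(summary["coef"]).to_numpy(),
        "ci95_low": np.exp(summary["coef lower 95%"]).to_numpy(),
        "ci95_high": np.exp(summary["coef upper 95%"]).to_numpy(),
        "p_value": summary["p"].to_numpy(),
    }).reset_index(drop=True)
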