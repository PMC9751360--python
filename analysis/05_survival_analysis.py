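#!/usr/bin/env python
"""Survival analysis of the immunotherapy cohort by HLA-LOH status.

Kaplan-Meier curves with median OS/PFS for LOH vs LOH-negative patients,
log-rank tests (overall and within histology), and the multivariate Cox
model over the four binarized biomarkers.
"""

import argparse
from pathlib import Path

import pandas as pd

from lohkit.cohort_stats import cox_multivariate, km_estimate, logrank_test
from lohkit.io_formats import read_cohort

ROOT = Path(__file__).resolve().parent.parent
TMB_CUT = 10.0  # mutations/Mb, the cohort's predefined high/low boundary


def _arm(records, endpoint):
    times = [getattr(r, f"{endpoint}_months") for r in records]
    events = [getattr(r, f"{endpoint}_event") for r in records]
    return times, events


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--datadir", type=Path, default=ROOT / "results" / "data" / "ici")
    parser.add_argument("--outdir", type=Path, default=ROOT / "results")
    args = parser.parse_args()

    cohort = read_cohort(args.datadir / "cohort.tsv")
    loh = [r for r in cohort if r.loh_grade != "negative"]
    neg = [r for r in cohort if r.loh_grade == "negative"]
    print(f"{len(cohort)} patients: {len(loh)} with HLA LOH, {len(neg)} negative")

    rows = []
    for endpoint in ("os", "pfs"):
        curves = {}
        for name, arm in (("loh", loh), ("negative", neg)):
            curve = km_estimate(*_arm(arm, endpoint))
            curves[name] = curve
            med = "not reached" if curve.median is None else f"{curve.median:.1f}"
            print(f"  median {endpoint.upper()} [{name}]: {med} months")
        chi2, p = logrank_test(*_arm(loh, endpoint), *_arm(neg, endpoint))
        print(f"  log-rank {endpoint.upper()}: chi2 = {chi2:.2f}, p = {p:.3g}")
        rows.append({"endpoint": endpoint, "chi2": chi2, "p_value": p,
                     "median_loh": curves["loh"].median,
                     "median_negative": curves["negative"].median})
        for histology in ("LUAD", "LUSC"):
            sub_loh = [r for r in loh if r.histology == histology]
            sub_neg = [r for r in neg if r.histology == histology]
            if len(sub_loh) < 3 or len(sub_neg) < 3:
                continue
            chi2, p = logrank_test(*_arm(sub_loh, endpoint), *_arm(sub_neg, endpoint))
            print(f"    {histology}: chi2 = {chi2:.2f}, p = {p:.3g}")
    pd.DataFrame(rows).to_csv(args.outdir / "survival_logrank.tsv", sep="\t", index=False)

    cox = cox_multivariate(cohort, tmb_cut=TMB_CUT, endpoint="os")
    cox.to_csv(args.outdir / "cox_multivariate_os.tsv", sep="\t", index=False)
    print("\nMultivariate Cox (OS):")
    print(cox.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
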