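"""Synthetic cohort generator with known ground truth.

Emulates every input the pipeline consumes: HLA class-I genotypes,
allele-specific tumor/normal coverage at heterozygous HLA sites under a
purity/ploidy/allele-copy model with planted LOH events, copy-number
segment profiles with an exact aberrant fraction, mutation catalogs with a
controlled fraction of MHC-binding neopeptides (under the package's mock
anchor predictor), and an immunotherapy cohort whose response and survival
depend on the four biomarkers.

Coverage model: at site j a shared factor s_j ~ LogNormal(0, sigma) scales
both tumor and normal depth (capturing capture-efficiency variation);
normal allele counts are Poisson(depth * s_j / 2), tumor allele counts
Poisson(depth * s_j * (rho*c_a + (1-rho)) / ((rho*psi + 2(1-rho))/2) / 2)
with allele copy c = 0 for a lost allele and 1 otherwise — i.e. the exact
forward model the caller inverts. The shared factor induces realistic
overdispersion in marginal counts while keeping the paired imbalance test
well calibrated.

Randomness: all draws descend from ``SimConfig.seed`` through numpy
``SeedSequence(seed, spawn_key=(stream, patient_index))`` children, one
stream per component (0 genotypes, 1 purity/ploidy + LOH flags, 2 site
counts, 3 segments, 4 mutations, 5 clinical). No global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_scores import MOCK_ANCHORS, compute_cin
from .hla_loh import grade_lookup
from .io_formats import (
    AA_ALPHABET,
    CnSegmentProfile,
    CohortRecord,
    GENES,
    HlaGenotype,
    MutationRecord,
    PuritySample,
    SiteCountTable,
    write_cohort,
    write_hla_typing,
    write_mutations,
    write_purity,
    write_segments,
    write_site_counts,
)

#: Common class-I alleles used as the simulation allele pool.
ALLELE_POOL: dict[str, tuple[str, ...]] = {
    "A": ("A*01:01", "A*02:01", "A*03:01", "A*11:01", "A*24:02", "A*26:01"),
    "B": ("B*07:02", "B*08:01", "B*15:01", "B*35:01", "B*40:01", "B*44:02"),
    "C": ("C*03:04", "C*04:01", "C*06:02", "C*07:01", "C*07:02", "C*08:01"),
}

#: Genes recurrently altered in lung cancer; used for simulated catalogs.
GENE_POOL = (
    "EGFR", "TP53", "KRAS", "PIK3CA", "KEAP1", "ZFHX4", "RBM10", "FAT1",
    "CDKN2A", "CTNNB1", "RB1", "TRRAP", "ERBB2", "BCL6", "APC", "BRAF",
    "STK11", "MET", "ALK", "SMARCA4",
)

# residues that are never a mock anchor, so windows drawn from them bind
# no allele
_SAFE_ALPHABET = "".join(a for a in AA_ALPHABET if a not in set(MOCK_ANCHORS.values()))

_SEG_START = 1_000_000
_SEG_LEN = 1_000_000  # covered length per autosome


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulated cohorts.

    Defaults emulate a targeted-panel ICI cohort: 89 patients, purity
    0.4-0.9, 100x site depth with 30 heterozygous sites per HLA gene, a
    per-gene LOH event rate of 0.09 (~76% LOH-negative patients with three
    heterozygous genes), a 1 Mb panel, and exponential survival whose only
    prognostic biomarker is HLA-LOH presence (OS/PFS hazard ratio 2).
    """

    seed: int
    n_patients: int = 89
    purity_range: tuple[float, float] = (0.4, 0.9)
    ploidy_range: tuple[float, float] = (1.8, 4.0)
    site_depth: float = 100.0
    n_sites_per_gene: int = 30
    loh_event_rate: float = 0.09
    homozygosity_rate: float = 0.1
    site_factor_sigma: float = 0.1
    panel_mb: float = 1.0
    n_mutations_range: tuple[int, int] = (2, 30)
    binder_fraction: float = 0.3
    cin_aberrant_fraction_range: tuple[float, float] = (0.0, 0.6)
    tmb_high_cut: float = 10.0
    lib_size: int = 1_000_000
    os_baseline_hazard: float = math.log(2) / 12.0   # per month
    pfs_baseline_hazard: float = math.log(2) / 6.0
    os_log_hr: Mapping[str, float] = field(default_factory=lambda: {
        "loh_present": math.log(2), "tmb_high": 0.0, "pdl1_high": 0.0, "cd8_high": 0.0,
    })
    pfs_log_hr: Mapping[str, float] = field(default_factory=lambda: {
        "loh_present": math.log(2), "tmb_high": 0.0, "pdl1_high": 0.0, "cd8_high": 0.0,
    })
    dcb_intercept: float = -2.0
    dcb_log_odds: Mapping[str, float] = field(default_factory=lambda: {
        "loh_present": -1.0, "tmb_high": 1.0, "pdl1_high": 1.0, "cd8_high": 1.0,
    })
    censor_range: tuple[float, float] = (6.0, 36.0)

    def __post_init__(self) -> None:
        for name in ("loh_event_rate", "homozygosity_rate", "binder_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_patients < 0 or self.site_depth <= 0:
            raise ValueError("n_patients must be >= 0 and site_depth > 0")


@dataclass(frozen=True)
class TruthRecord:
    """Generative ground truth for one simulated patient."""

    patient_id: str
    loh_flags: Mapping[str, bool]         # per heterozygous gene; False if homozygous
    grade: str
    aberrant_fraction: float              # realized fraction of covered length
    n_neoantigen_mutations: int
    dcb_probability: float


def _rng(seed: int, stream: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream, index)))


def simulate_genotypes(cfg: SimConfig) -> list[HlaGenotype]:
    """Draw genotypes from the packaged allele pool; each gene is homozygous
    with probability ``homozygosity_rate``."""
    out = []
    for i in range(cfg.n_patients):
        rng = _rng(cfg.seed, 0, i)
        alleles = {}
        for gene in GENES:
            pool = ALLELE_POOL[gene]
            if rng.random() < cfg.homozygosity_rate:
                a = pool[rng.integers(len(pool))]
                alleles[gene] = (a, a)
            else:
                pair = rng.choice(len(pool), size=2, replace=False)
                alleles[gene] = (pool[pair[0]], pool[pair[1]])
        out.append(HlaGenotype(patient_id=f"P{i + 1:04d}", alleles=alleles))
    return out


def simulate_site_counts(
    genotype: HlaGenotype,
    truth_loh: Mapping[str, bool],
    purity: float,
    ploidy: float,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> dict[str, SiteCountTable]:
    """Simulate paired tumor/normal allele counts for each heterozygous gene.

    A planted LOH event sets the lost allele's tumor copy number to 0 (kept
    allele stays at 1); which allele is lost is drawn at random.
    """
    if cfg.site_depth <= 0:
        raise ValueError("site depth must be positive")
    for gene, flag in truth_loh.items():
        if flag and not genotype.heterozygous[gene]:
            raise ValueError(f"planted LOH at homozygous gene {gene}")
    k = (purity * ploidy + 2.0 * (1.0 - purity)) / 2.0
    out: dict[str, SiteCountTable] = {}
    for gene in GENES:
        if not genotype.heterozygous[gene]:
            continue
        copies = [1.0, 1.0]
        if truth_loh.get(gene, False):
            copies[int(rng.integers(2))] = 0.0
        s = rng.lognormal(0.0, cfg.site_factor_sigma, cfg.n_sites_per_gene)
        lam_n = cfg.site_depth * s / 2.0
        rows = []
        for j in range(cfg.n_sites_per_gene):
            t = [
                rng.poisson(cfg.site_depth * s[j]
                            * (purity * c + (1.0 - purity)) / k / 2.0)
                for c in copies
            ]
            n = [rng.poisson(lam_n[j]), rng.poisson(lam_n[j])]
            rows.append((500 + 100 * j, int(t[0]), int(t[1]), int(n[0]), int(n[1])))
        out[gene] = SiteCountTable(
            patient_id=genotype.patient_id, gene=gene, sites=tuple(rows),
            tumor_lib_size=cfg.lib_size, normal_lib_size=cfg.lib_size,
        )
    return out


def simulate_cn_segments(
    cfg: SimConfig, purity_sample: PuritySample, aberrant_fraction: float
) -> CnSegmentProfile:
    """One covered megabase per autosome, of which exactly
    ``aberrant_fraction`` (up to integer rounding of base pairs) is at
    ploidy +/- 1 and the rest copy-neutral. The construction makes the CIN
    score closed-form: 100 x (realized fraction)."""
    if not (0.0 <= aberrant_fraction <= 1.0):
        raise ValueError("aberrant_fraction must lie in [0, 1]")
    psi = purity_sample.ploidy
    ab_len = round(aberrant_fraction * _SEG_LEN)
    segments = []
    for chrom in range(1, 23):
        start = _SEG_START
        end = start + _SEG_LEN - 1
        # gains on odd autosomes, losses on even (gains only if a full-copy
        # loss would not be distinguishable from neutral)
        delta = 1.0 if (chrom % 2 == 1 or psi < 1.5) else -1.0
        if ab_len == 0:
            segments.append((chrom, start, end, psi))
        elif ab_len == _SEG_LEN:
            segments.append((chrom, start, end, psi + delta))
        else:
            segments.append((chrom, start, start + ab_len - 1, psi + delta))
            segments.append((chrom, start + ab_len, end, psi))
    return CnSegmentProfile(
        patient_id=purity_sample.patient_id,
        segments=tuple(segments),
        purity_sample=purity_sample,
    )


def simulate_mutations(
    cfg: SimConfig,
    patient_id: str,
    rng: np.random.Generator,
    n_mutations: int | None = None,
    binder_fraction: float | None = None,
) -> tuple[list[MutationRecord], int]:
    """Simulate nonsynonymous mutations with 21-mer contexts.

    A controlled count ``round(binder_fraction * n)`` of mutations carries
    the mock predictor's HLA-A anchor residue immediately after the central
    mutant position, so exactly one enumerable window per binder mutation
    has it at peptide position 2; the remaining contexts use only
    non-anchor residues and bind nothing. Returns (records, binder count).
    """
    if n_mutations is None:
        lo, hi = cfg.n_mutations_range
        n_mutations = int(rng.integers(lo, hi + 1))
    bf = cfg.binder_fraction if binder_fraction is None else binder_fraction
    n_bind = int(round(bf * n_mutations))
    safe = np.array(list(_SAFE_ALPHABET))
    records = []
    for i in range(n_mutations):
        context = rng.choice(safe, size=21)
        if i < n_bind:
            context[11] = MOCK_ANCHORS["A"]  # every patient carries HLA-A alleles
        records.append(MutationRecord(
            patient_id=patient_id,
            gene_symbol=GENE_POOL[int(rng.integers(len(GENE_POOL)))],
            variant_class="nonsynonymous",
            alteration_type="mutation",
            context_peptide="".join(context),
            mutant_position=11,
        ))
    return records, n_bind


@dataclass
class SimulatedCohort:
    """Everything the pipeline consumes, plus the generative truth."""

    config: SimConfig
    genotypes: list[HlaGenotype]
    purity_samples: list[PuritySample]
    count_tables: list[SiteCountTable]
    segment_profiles: list[CnSegmentProfile]
    mutations: dict[str, list[MutationRecord]]
    cohort: list[CohortRecord]
    truth: list[TruthRecord]


def simulate_cohort(cfg: SimConfig, outdir: str | Path | None = None) -> SimulatedCohort:
    """Simulate a full ICI cohort and (optionally) write every input TSV.

    Response ~ Bernoulli(logistic(intercept + sum log-odds x feature));
    OS/PFS are exponential with hazard baseline x exp(sum log-HR x feature)
    under independent uniform censoring.
    """
    genotypes = simulate_genotypes(cfg)
    purity_samples: list[PuritySample] = []
    count_tables: list[SiteCountTable] = []
    segment_profiles: list[CnSegmentProfile] = []
    mutations: dict[str, list[MutationRecord]] = {}
    truth: list[TruthRecord] = []
    biomarkers: list[dict] = []

    for i, geno in enumerate(genotypes):
        pid = geno.patient_id
        rng_p = _rng(cfg.seed, 1, i)
        purity = float(rng_p.uniform(*cfg.purity_range))
        ploidy = float(rng_p.uniform(*cfg.ploidy_range))
        sample = PuritySample(pid, purity, ploidy)
        purity_samples.append(sample)

        loh_flags = {
            gene: bool(geno.heterozygous[gene] and rng_p.random() < cfg.loh_event_rate)
            for gene in GENES
        }
        count_tables.extend(
            simulate_site_counts(geno, loh_flags, purity, ploidy, cfg,
                                 _rng(cfg.seed, 2, i)).values()
        )

        rng_seg = _rng(cfg.seed, 3, i)
        frac = float(rng_seg.uniform(*cfg.cin_aberrant_fraction_range))
        profile = simulate_cn_segments(cfg, sample, frac)
        segment_profiles.append(profile)

        muts, n_bind = simulate_mutations(cfg, pid, _rng(cfg.seed, 4, i))
        mutations[pid] = muts

        n_loh = sum(loh_flags.values())
        grade = grade_lookup(n_loh, geno.n_distinct_alleles)
        rng_c = _rng(cfg.seed, 5, i)
        u = rng_c.random()
        if u < 0.3:
            tps = 0.0
        elif u < 0.75:
            tps = float(rng_c.uniform(1.0, 50.0))
        else:
            tps = float(rng_c.uniform(50.0, 100.0))
        cd8 = float(rng_c.lognormal(0.0, 1.0))
        histology = ("LUAD", "LUSC", "other")[
            int(rng_c.choice(3, p=[0.6, 0.3, 0.1]))
        ]
        biomarkers.append({
            "pid": pid, "grade": grade, "loh_flags": loh_flags,
            "tmb": len(muts) / cfg.panel_mb, "tnb": n_bind / cfg.panel_mb,
            "cin": compute_cin(profile), "tps": tps, "cd8": cd8,
            "histology": histology, "aberrant_fraction": frac, "n_bind": n_bind,
        })

    cd8_median = float(np.median([b["cd8"] for b in biomarkers])) if biomarkers else 0.0
    cohort: list[CohortRecord] = []
    for i, b in enumerate(biomarkers):
        features = {
            "loh_present": b["grade"] != "negative",
            "tmb_high": b["tmb"] >= cfg.tmb_high_cut,
            "pdl1_high": b["tps"] > 1.0,
            "cd8_high": b["cd8"] >= cd8_median,
        }
        logit = cfg.dcb_intercept + sum(
            cfg.dcb_log_odds.get(f, 0.0) for f, on in features.items() if on
        )
        p_dcb = 1.0 / (1.0 + math.exp(-logit))
        rng_o = _rng(cfg.seed, 6, i)
        response = "DCB" if rng_o.random() < p_dcb else "NDB"
        times: dict[str, tuple[float, bool]] = {}
        for endpoint, base, log_hr in (
            ("os", cfg.os_baseline_hazard, cfg.os_log_hr),
            ("pfs", cfg.pfs_baseline_hazard, cfg.pfs_log_hr),
        ):
            hazard = base * math.exp(sum(
                log_hr.get(f, 0.0) for f, on in features.items() if on
            ))
            t_event = float(rng_o.exponential(1.0 / hazard))
            t_censor = float(rng_o.uniform(*cfg.censor_range))
            times[endpoint] = (min(t_event, t_censor), t_event <= t_censor)
        cohort.append(CohortRecord(
            patient_id=b["pid"], tmb=b["tmb"], tnb=b["tnb"], cin=b["cin"],
            pdl1_tps=b["tps"], cd8_level=b["cd8"], loh_grade=b["grade"],
            histology=b["histology"], response=response,
            os_months=times["os"][0], pfs_months=times["pfs"][0],
            os_event=times["os"][1], pfs_event=times["pfs"][1],
        ))
        truth.append(TruthRecord(
            patient_id=b["pid"], loh_flags=b["loh_flags"], grade=b["grade"],
            aberrant_fraction=round(b["aberrant_fraction"] * _SEG_LEN) / _SEG_LEN,
            n_neoantigen_mutations=b["n_bind"], dcb_probability=p_dcb,
        ))

    sim = SimulatedCohort(
        config=cfg, genotypes=genotypes, purity_samples=purity_samples,
        count_tables=count_tables, segment_profiles=segment_profiles,
        mutations=mutations, cohort=cohort, truth=truth,
    )
    if outdir is not None:
        write_cohort_files(sim, outdir)
    return sim


def write_cohort_files(sim: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write every TSV the pipeline reads, plus the truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / f"{name}.tsv" for name in
             ("typing", "counts", "purity", "segments", "cohort", "mutations", "truth")}
    write_hla_typing(sim.genotypes, paths["typing"])
    write_site_counts(sim.count_tables, paths["counts"])
    write_purity(sim.purity_samples, paths["purity"])
    write_segments(sim.segment_profiles, paths["segments"])
    write_cohort(sim.cohort, paths["cohort"])
    write_mutations(
        [m for pid in sorted(sim.mutations) for m in sim.mutations[pid]],
        paths["mutations"],
    )
    pd.DataFrame([{
        "patient_id": t.patient_id,
        **{f"loh_{g}": int(t.loh_flags.get(g, False)) for g in GENES},
        "grade": t.grade,
        "aberrant_fraction": t.aberrant_fraction,
        "n_neoantigen_mutations": t.n_neoantigen_mutations,
        "dcb_probability": t.dcb_probability,
    } for t in sim.truth]).to_csv(paths["truth"], sep="\t", index=False)
    return paths
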