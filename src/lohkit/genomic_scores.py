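"""Genomic biomarker scores: TMB, TNB and the chromosomal-instability score.

TMB is the number of nonsynonymous somatic mutations per megabase of
sequenced territory (the panel footprint is a required configuration value,
not inferred). TNB counts mutations yielding at least one predicted
MHC-I-binding peptide (IC50 <= 500 nM for at least one of the patient's
class-I alleles) per megabase; candidate peptides are all 8-11-mers from the
21-mer protein context that cover the mutated residue (sliding window).
Binding prediction is abstracted behind :class:`AffinityPredictor` so real
NetMHCpan output can be plugged in as a lookup table; a deterministic
anchor-motif mock ships for testing.

The CIN score is the mean, over the 22 autosomes, of the percentage of
segmented genomic material whose total copy number deviates from the sample
ploidy by at least half a copy. Percentages are computed over segmented
(covered) length, since a targeted panel does not tile whole chromosomes;
autosomes with no segments contribute 0%.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Protocol, Sequence

import pandas as pd

from .io_formats import CnSegmentProfile, HlaGenotype, MutationRecord


class PredictionError(RuntimeError):
    """The affinity predictor failed for a peptide/allele pair."""


@dataclass(frozen=True)
class ScoreConfig:
    """Scoring parameters.

    panel_mb: megabases of genome examined (TMB/TNB denominator); required.
    ic50_threshold_nm: binder cutoff, peptides with IC50 <= threshold count.
    peptide_lengths: window lengths for neopeptide enumeration.
    flank_aa: amino acids of context flanking the mutant residue.
    cin_neutral_margin: |cn - ploidy| below this is copy-neutral.
    """

    panel_mb: float
    ic50_threshold_nm: float = 500.0
    peptide_lengths: tuple[int, ...] = (8, 9, 10, 11)
    flank_aa: int = 10
    cin_neutral_margin: float = 0.5

    def __post_init__(self) -> None:
        if self.panel_mb <= 0:
            raise ValueError(f"panel_mb must be positive, got {self.panel_mb}")
        if self.ic50_threshold_nm <= 0 or self.cin_neutral_margin <= 0:
            raise ValueError("thresholds must be positive")


class AffinityPredictor(Protocol):
    """Peptide-MHC binding predictor interface (IC50 in nM, deterministic)."""

    def predict(
        self, peptides: Sequence[str], alleles: Sequence[str]
    ) -> Mapping[tuple[str, str], float]: ...


#: Anchor residue at peptide position 2 that the mock treats as a binder,
#: per HLA gene.
MOCK_ANCHORS = {"A": "L", "B": "Y", "C": "F"}
MOCK_BINDER_IC50 = 50.0
MOCK_NONBINDER_IC50 = 5000.0


class MockAnchorPredictor:
    """Deterministic stand-in predictor with a simple anchor-motif rule.

    A peptide binds an allele (IC50 50 nM) iff its second residue equals the
    allele's anchor letter (by HLA gene: A->L, B->Y, C->F); otherwise
    IC50 5000 nM. This makes binder fractions fully controllable in
    simulations and tests. It is a synthetic rule, not a trained model.
    """

    def predict(
        self, peptides: Sequence[str], alleles: Sequence[str]
    ) -> dict[tuple[str, str], float]:
        out: dict[tuple[str, str], float] = {}
        for allele in alleles:
            anchor = MOCK_ANCHORS.get(allele[0])
            if anchor is None:
                raise PredictionError(f"unknown HLA gene for allele {allele!r}")
            for pep in peptides:
                out[(pep, allele)] = (
                    MOCK_BINDER_IC50 if len(pep) >= 2 and pep[1] == anchor
                    else MOCK_NONBINDER_IC50
                )
        return out


class TablePredictor:
    """Affinity lookup from a (peptide, allele, ic50_nm) TSV.

    Lets precomputed NetMHCpan output drive TNB without invoking the tool.
    Missing pairs raise :class:`PredictionError` naming the peptide.
    """

    def __init__(self, path: str | Path):
        df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "allele": str})
        for col in ("peptide", "allele", "ic50_nm"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col!r}")
        self._table = {
            (r.peptide, r.allele): float(r.ic50_nm) for r in df.itertuples()
        }

    def predict(
        self, peptides: Sequence[str], alleles: Sequence[str]
    ) -> dict[tuple[str, str], float]:
        out = {}
        for pep in peptides:
            for allele in alleles:
                try:
                    out[(pep, allele)] = self._table[(pep, allele)]
                except KeyError:
                    raise PredictionError(
                        f"no affinity entry for peptide {pep!r} / allele {allele!r}"
                    ) from None
        return out


def _check_single_patient(muts: Sequence[MutationRecord]) -> None:
    pids = {m.patient_id for m in muts}
    if len(pids) > 1:
        raise ValueError(f"mutations from multiple patients: {sorted(pids)}")


def compute_tmb(muts: Sequence[MutationRecord], cfg: ScoreConfig) -> float:
    """Nonsynonymous mutations per megabase. Only alteration_type='mutation'
    records count; copy-number alterations do not."""
    _check_single_patient(muts)
    n = sum(
        1 for m in muts
        if m.alteration_type == "mutation" and m.variant_class == "nonsynonymous"
    )
    return n / cfg.panel_mb


def enumerate_neopeptides(
    context_peptide: str, mutant_position: int, cfg: ScoreConfig
) -> list[tuple[str, int]]:
    """All 8-11-mer windows of the context covering the mutated residue.

    Returns (peptide, offset) with 0-based offsets, ordered by length then
    offset; duplicate peptide strings are dropped keeping the first offset.
    Contexts shorter than the smallest window yield an empty list.
    """
    if not (1 <= mutant_position <= len(context_peptide)):
        raise ValueError(
            f"mutant_position {mutant_position} outside context of length "
            f"{len(context_peptide)}"
        )
    mut_idx = mutant_position - 1
    out: list[tuple[str, int]] = []
    seen: set[str] = set()
    for length in sorted(cfg.peptide_lengths):
        lo = max(0, mut_idx - length + 1)
        hi = min(len(context_peptide) - length, mut_idx)
        for offset in range(lo, hi + 1):
            pep = context_peptide[offset:offset + length]
            if pep not in seen:
                seen.add(pep)
                out.append((pep, offset))
    return out


def compute_tnb(
    muts: Sequence[MutationRecord],
    genotype: HlaGenotype,
    predictor: AffinityPredictor,
    cfg: ScoreConfig,
    count: Literal["mutation", "peptide"] = "mutation",
) -> float:
    """Neoantigen burden per megabase.

    A nonsynonymous mutation is a neoantigen iff at least one of its
    enumerated peptides has IC50 <= threshold for at least one of the
    patient's alleles; multiple binding peptides from one mutation count
    once (``count='peptide'`` switches to peptide-level counting).
    """
    _check_single_patient(muts)
    alleles = genotype.distinct_alleles
    if not alleles:
        raise ValueError("genotype carries no alleles")
    total = 0
    for m in muts:
        if m.alteration_type != "mutation" or m.variant_class != "nonsynonymous":
            continue
        peptides = [p for p, _ in enumerate_neopeptides(m.context_peptide,
                                                        m.mutant_position, cfg)]
        if not peptides:
            continue
        affinities = predictor.predict(peptides, alleles)
        if count == "mutation":
            if any(
                affinities[(p, a)] <= cfg.ic50_threshold_nm
                for p in peptides for a in alleles
            ):
                total += 1
        else:
            total += sum(
                1 for p in peptides
                if any(affinities[(p, a)] <= cfg.ic50_threshold_nm for a in alleles)
            )
    return total / cfg.panel_mb


def compute_cin(profile: CnSegmentProfile, cin_neutral_margin: float = 0.5) -> float:
    """Mean over the 22 autosomes of the percent of segmented length with
    |cn_total - ploidy| >= ``cin_neutral_margin``."""
    psi = profile.purity_sample.ploidy
    if psi <= 0:
        raise ValueError(f"ploidy must be positive, got {psi}")
    if not profile.segments:
        raise ValueError(f"{profile.patient_id}: profile has no segments")
    covered = {c: 0 for c in range(1, 23)}
    aberrant = {c: 0 for c in range(1, 23)}
    for chrom, start, end, cn in profile.segments:
        length = end - start + 1
        covered[chrom] += length
        if abs(cn - psi) >= cin_neutral_margin:
            aberrant[chrom] += length
    pct_sum = sum(
        100.0 * aberrant[c] / covered[c] for c in range(1, 23) if covered[c] > 0
    )
    return pct_sum / 22.0


def score_cohort(
    muts_by_patient: Mapping[str, Sequence[MutationRecord]],
    profiles: Iterable[CnSegmentProfile],
    genotypes: Iterable[HlaGenotype],
    predictor: AffinityPredictor,
    cfg: ScoreConfig,
) -> pd.DataFrame:
    """Per-patient TMB/TNB/CIN table for all patients with a genotype."""
    profile_by_pid = {p.patient_id: p for p in profiles}
    rows = []
    for geno in genotypes:
        pid = geno.patient_id
        muts = list(muts_by_patient.get(pid, []))
        profile = profile_by_pid.get(pid)
        rows.append({
            "patient_id": pid,
            "tmb": compute_tmb(muts, cfg) if muts else 0.0,
            "tnb": compute_tnb(muts, geno, predictor, cfg) if muts else 0.0,
            "cin": compute_cin(profile, cfg.cin_neutral_margin)
                   if profile is not None else float("nan"),
        })
    return pd.DataFrame(rows)
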