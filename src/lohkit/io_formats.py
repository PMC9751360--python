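"""Tabular I/O and shared domain types for the HLA-LOH biomarker pipeline.

All files are UTF-8, tab-delimited with a header row. Genomic coordinates
are 1-based inclusive throughout (SEG convention); no reader or writer
reinterprets them. Chromosome names may arrive as ``1`` or ``chr1`` and are
normalized to bare integers; sex chromosomes are excluded (the CIN score is
defined over the 22 autosomes only).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd

GENES = ("A", "B", "C")
#: 4-digit-resolution class-I allele name, e.g. "A*02:01".
ALLELE_RE = re.compile(r"^[ABC]\*\d{2,3}:\d{2,3}$")
VARIANT_CLASSES = ("nonsynonymous", "synonymous", "other")
ALTERATION_TYPES = ("mutation", "amplification", "deletion")
LOH_GRADES = ("negative", "low", "high")
HISTOLOGIES = ("LUAD", "LUSC", "other")
RESPONSES = ("DCB", "NDB")
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


class FormatError(ValueError):
    """An input table violates the format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HlaGenotype:
    """A patient's six HLA class-I alleles (two per gene A/B/C)."""

    patient_id: str
    alleles: Mapping[str, tuple[str, str]]

    def __post_init__(self) -> None:
        if set(self.alleles) != set(GENES):
            raise FormatError(
                f"{self.patient_id}: genotype must cover exactly genes {GENES}, "
                f"got {sorted(self.alleles)}"
            )
        for gene, pair in self.alleles.items():
            for name in pair:
                if not ALLELE_RE.match(name):
                    raise FormatError(
                        f"{self.patient_id}: malformed allele name {name!r} for gene {gene}"
                    )
                if not name.startswith(gene + "*"):
                    raise FormatError(
                        f"{self.patient_id}: allele {name!r} does not belong to gene {gene}"
                    )

    @property
    def heterozygous(self) -> dict[str, bool]:
        return {g: self.alleles[g][0] != self.alleles[g][1] for g in GENES}

    @property
    def n_distinct_alleles(self) -> int:
        return len({a for pair in self.alleles.values() for a in pair})

    @property
    def distinct_alleles(self) -> list[str]:
        seen: list[str] = []
        for g in GENES:
            for a in self.alleles[g]:
                if a not in seen:
                    seen.append(a)
        return seen


@dataclass(frozen=True)
class SiteCountTable:
    """Paired allele-specific tumor/normal read counts at heterozygous sites
    of one HLA gene.

    ``sites`` rows are (position, tumor_count_allele1, tumor_count_allele2,
    normal_count_allele1, normal_count_allele2); positions strictly
    increasing.
    """

    patient_id: str
    gene: str
    sites: tuple[tuple[int, int, int, int, int], ...]
    tumor_lib_size: int
    normal_lib_size: int

    def __post_init__(self) -> None:
        if self.gene not in GENES:
            raise FormatError(f"{self.patient_id}: unknown HLA gene {self.gene!r}")
        if self.tumor_lib_size <= 0 or self.normal_lib_size <= 0:
            raise FormatError(f"{self.patient_id}/{self.gene}: library sizes must be positive")
        prev = 0
        for row in self.sites:
            pos = row[0]
            if pos <= prev:
                raise FormatError(
                    f"{self.patient_id}/{self.gene}: positions must be strictly increasing"
                )
            prev = pos
            if any(c < 0 for c in row[1:]):
                raise FormatError(f"{self.patient_id}/{self.gene}: negative read count")

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class PuritySample:
    """Sample purity rho (tumor-cell fraction) and ploidy psi."""

    patient_id: str
    purity: float
    ploidy: float

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise FormatError(f"{self.patient_id}: purity must be in (0, 1], got {self.purity}")
        if self.ploidy <= 0:
            raise FormatError(f"{self.patient_id}: ploidy must be > 0, got {self.ploidy}")


@dataclass(frozen=True)
class CnSegmentProfile:
    """Total copy-number segments on the 22 autosomes plus purity/ploidy.

    Segments are (chrom, start, end, cn_total) with 1-based inclusive
    coordinates, non-overlapping within each chromosome.
    """

    patient_id: str
    segments: tuple[tuple[int, int, int, float], ...]
    purity_sample: PuritySample

    def __post_init__(self) -> None:
        by_chrom: dict[int, list[tuple[int, int]]] = {}
        for chrom, start, end, cn in self.segments:
            if chrom not in range(1, 23):
                raise FormatError(f"{self.patient_id}: chromosome {chrom} is not an autosome 1-22")
            if end < start or start < 1:
                raise FormatError(
                    f"{self.patient_id}: bad segment interval {start}-{end} on chrom {chrom}"
                )
            if cn < 0:
                raise FormatError(f"{self.patient_id}: negative cn_total on chrom {chrom}")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                if s2 <= e1:
                    raise FormatError(
                        f"{self.patient_id}: overlapping segments on chrom {chrom}: "
                        f"{s1}-{e1} and {s2}-{e2}"
                    )


@dataclass(frozen=True)
class MutationRecord:
    """One somatic alteration with its 21-mer protein context (for SNVs)."""

    patient_id: str
    gene_symbol: str
    variant_class: str
    alteration_type: str
    context_peptide: str
    mutant_position: int  # 1-based index into context_peptide

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise FormatError(f"unknown variant_class {self.variant_class!r}")
        if self.alteration_type not in ALTERATION_TYPES:
            raise FormatError(f"unknown alteration_type {self.alteration_type!r}")
        pep = self.context_peptide
        if len(pep) > 21 or any(ch not in AA_ALPHABET for ch in pep):
            raise FormatError(
                f"{self.patient_id}/{self.gene_symbol}: invalid context peptide {pep!r}"
            )
        if not (1 <= self.mutant_position <= len(pep)):
            raise FormatError(
                f"{self.patient_id}/{self.gene_symbol}: mutant_position "
                f"{self.mutant_position} outside context of length {len(pep)}"
            )


@dataclass(frozen=True)
class CohortRecord:
    """One patient's biomarkers, ICI response label, and survival outcomes."""

    patient_id: str
    tmb: float
    tnb: float
    cin: float
    pdl1_tps: float
    cd8_level: float
    loh_grade: str
    histology: str
    response: str | None
    os_months: float
    pfs_months: float
    os_event: bool
    pfs_event: bool

    def __post_init__(self) -> None:
        pid = self.patient_id
        if self.tmb < 0 or self.tnb < 0 or self.cd8_level < 0:
            raise FormatError(f"{pid}: tmb/tnb/cd8_level must be non-negative")
        if not (0 <= self.cin <= 100):
            raise FormatError(f"{pid}: cin must lie in [0, 100]")
        if not (0 <= self.pdl1_tps <= 100):
            raise FormatError(f"{pid}: pdl1_tps must lie in [0, 100]")
        if self.loh_grade not in LOH_GRADES:
            raise FormatError(f"{pid}: unknown loh_grade {self.loh_grade!r}")
        if self.histology not in HISTOLOGIES:
            raise FormatError(f"{pid}: unknown histology {self.histology!r}")
        if self.response is not None and self.response not in RESPONSES:
            raise FormatError(f"{pid}: unknown response {self.response!r}")
        for name in ("os_months", "pfs_months"):
            val = getattr(self, name)
            if not math.isfinite(val) or val < 0:
                raise FormatError(f"{pid}: {name} must be finite and >= 0, got {val}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


_TYPING_COLS = ("patient_id", "A1", "A2", "B1", "B2", "C1", "C2")


def read_hla_typing(path: str | Path) -> list[HlaGenotype]:
    """Read a typing TSV (patient_id, A1, A2, B1, B2, C1, C2)."""
    df = _read_tsv(path, _TYPING_COLS)
    out: list[HlaGenotype] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        pid = row["patient_id"]
        if pid in seen:
            raise FormatError(f"{path}: duplicate patient_id {pid!r} at row {i + 2}")
        seen.add(pid)
        alleles = {}
        for gene in GENES:
            pair = (row[f"{gene}1"], row[f"{gene}2"])
            for col, name in zip((f"{gene}1", f"{gene}2"), pair):
                if not ALLELE_RE.match(name):
                    raise FormatError(
                        f"{path}: malformed allele name {name!r} at row {i + 2}, column {col}"
                    )
            alleles[gene] = pair
        out.append(HlaGenotype(patient_id=pid, alleles=alleles))
    return out


def write_hla_typing(genotypes: Sequence[HlaGenotype], path: str | Path) -> None:
    rows = []
    for g in genotypes:
        row = {"patient_id": g.patient_id}
        for gene in GENES:
            row[f"{gene}1"], row[f"{gene}2"] = g.alleles[gene]
        rows.append(row)
    pd.DataFrame(rows, columns=list(_TYPING_COLS)).to_csv(path, sep="\t", index=False)


_COUNT_COLS = (
    "patient_id", "gene", "position",
    "tumor_count_allele1", "tumor_count_allele2",
    "normal_count_allele1", "normal_count_allele2",
    "tumor_lib_size", "normal_lib_size",
)


def read_site_counts(path: str | Path) -> list[SiteCountTable]:
    """Read per-site allele-specific counts, one table per (patient, gene)."""
    df = _read_tsv(path, _COUNT_COLS)
    out: list[SiteCountTable] = []
    if df.empty:
        return out
    for (pid, gene), grp in df.groupby(["patient_id", "gene"], sort=False):
        try:
            sites = tuple(
                (int(r.position),
                 int(r.tumor_count_allele1), int(r.tumor_count_allele2),
                 int(r.normal_count_allele1), int(r.normal_count_allele2))
                for r in grp.itertuples()
            )
            tlib = int(grp["tumor_lib_size"].iloc[0])
            nlib = int(grp["normal_lib_size"].iloc[0])
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer count field for {pid}/{gene}: {exc}") from exc
        out.append(SiteCountTable(patient_id=pid, gene=gene, sites=sites,
                                  tumor_lib_size=tlib, normal_lib_size=nlib))
    return out


def write_site_counts(tables: Sequence[SiteCountTable], path: str | Path) -> None:
    rows = []
    for t in tables:
        for pos, t1, t2, n1, n2 in t.sites:
            rows.append({
                "patient_id": t.patient_id, "gene": t.gene, "position": pos,
                "tumor_count_allele1": t1, "tumor_count_allele2": t2,
                "normal_count_allele1": n1, "normal_count_allele2": n2,
                "tumor_lib_size": t.tumor_lib_size, "normal_lib_size": t.normal_lib_size,
            })
    pd.DataFrame(rows, columns=list(_COUNT_COLS)).to_csv(path, sep="\t", index=False)


def read_purity(path: str | Path) -> list[PuritySample]:
    df = _read_tsv(path, ("patient_id", "purity", "ploidy"))
    out = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        pid = row["patient_id"]
        if pid in seen:
            raise FormatError(f"{path}: duplicate patient_id {pid!r} at row {i + 2}")
        seen.add(pid)
        out.append(PuritySample(pid, float(row["purity"]), float(row["ploidy"])))
    return out


def write_purity(samples: Sequence[PuritySample], path: str | Path) -> None:
    pd.DataFrame(
        [{"patient_id": s.patient_id, "purity": s.purity, "ploidy": s.ploidy} for s in samples],
        columns=["patient_id", "purity", "ploidy"],
    ).to_csv(path, sep="\t", index=False)


def normalize_chrom(raw: str) -> int | None:
    """Map '1'/'chr1' -> 1; sex chromosomes and anything non-autosomal -> None."""
    name = str(raw)
    if name.lower().startswith("chr"):
        name = name[3:]
    if name in ("X", "Y", "x", "y", "23", "24"):
        return None
    try:
        chrom = int(name)
    except ValueError:
        raise FormatError(f"unrecognized chromosome name {raw!r}") from None
    if chrom not in range(1, 23):
        return None
    return chrom


def read_segments(
    path: str | Path,
    purity_path: str | Path,
    sex_chrom: Literal["drop", "error"] = "drop",
) -> list[CnSegmentProfile]:
    """Read a SEG-like TSV plus its companion purity/ploidy table.

    Coordinates are 1-based inclusive. ``sex_chrom`` controls whether
    non-autosomal rows are silently dropped or rejected.
    """
    purity = {s.patient_id: s for s in read_purity(purity_path)}
    df = _read_tsv(path, ("patient_id", "chrom", "start", "end", "cn_total"))
    segs_by_pid: dict[str, list[tuple[int, int, int, float]]] = {}
    for i, row in df.iterrows():
        chrom = normalize_chrom(row["chrom"])
        if chrom is None:
            if sex_chrom == "error":
                raise FormatError(
                    f"{path}: non-autosomal chromosome {row['chrom']!r} at row {i + 2}"
                )
            continue
        start, end = int(row["start"]), int(row["end"])
        if end < start:
            raise FormatError(f"{path}: end < start at row {i + 2}")
        segs_by_pid.setdefault(row["patient_id"], []).append(
            (chrom, start, end, float(row["cn_total"]))
        )
    out = []
    for pid, segs in segs_by_pid.items():
        if pid not in purity:
            raise FormatError(f"{path}: patient {pid!r} has segments but no purity/ploidy entry")
        out.append(CnSegmentProfile(pid, tuple(segs), purity[pid]))
    return out


def write_segments(profiles: Sequence[CnSegmentProfile], path: str | Path) -> None:
    rows = [
        {"patient_id": p.patient_id, "chrom": chrom, "start": start, "end": end, "cn_total": cn}
        for p in profiles
        for chrom, start, end, cn in p.segments
    ]
    pd.DataFrame(rows, columns=["patient_id", "chrom", "start", "end", "cn_total"]).to_csv(
        path, sep="\t", index=False
    )


_MUT_COLS = ("patient_id", "gene_symbol", "variant_class", "alteration_type",
             "context_peptide", "mutant_position")


def read_mutations(path: str | Path) -> list[MutationRecord]:
    """Read a minimal MAF-like mutation TSV.

    variant_class values outside {nonsynonymous, synonymous, other} are mapped
    to "other" with a warning.
    """
    df = _read_tsv(path, _MUT_COLS)
    out = []
    for i, row in df.iterrows():
        vclass = row["variant_class"]
        if vclass not in VARIANT_CLASSES:
            warnings.warn(
                f"{path}: row {i + 2}: unknown variant_class {vclass!r} mapped to 'other'",
                stacklevel=2,
            )
            vclass = "other"
        try:
            out.append(MutationRecord(
                patient_id=row["patient_id"],
                gene_symbol=row["gene_symbol"],
                variant_class=vclass,
                alteration_type=row["alteration_type"],
                context_peptide=row["context_peptide"],
                mutant_position=int(row["mutant_position"]),
            ))
        except FormatError as exc:
            raise FormatError(f"{path}: row {i + 2}: {exc}") from exc
    return out


def write_mutations(records: Sequence[MutationRecord], path: str | Path) -> None:
    pd.DataFrame(
        [{c: getattr(r, c) for c in _MUT_COLS} for r in records],
        columns=list(_MUT_COLS),
    ).to_csv(path, sep="\t", index=False)


_COHORT_COLS = ("patient_id", "tmb", "tnb", "cin", "pdl1_tps", "cd8_level", "loh_grade",
                "histology", "response", "os_months", "pfs_months", "os_event", "pfs_event")


def read_cohort(path: str | Path) -> list[CohortRecord]:
    """Read a cohort biomarker/outcome table. Empty ``response`` means missing."""
    df = _read_tsv(path, _COHORT_COLS)
    out = []
    for i, row in df.iterrows():
        try:
            out.append(CohortRecord(
                patient_id=row["patient_id"],
                tmb=float(row["tmb"]),
                tnb=float(row["tnb"]),
                cin=float(row["cin"]),
                pdl1_tps=float(row["pdl1_tps"]),
                cd8_level=float(row["cd8_level"]),
                loh_grade=row["loh_grade"],
                histology=row["histology"],
                response=row["response"] or None,
                os_months=float(row["os_months"]),
                pfs_months=float(row["pfs_months"]),
                os_event=_parse_bool(row["os_event"]),
                pfs_event=_parse_bool(row["pfs_event"]),
            ))
        except FormatError as exc:
            raise FormatError(f"{path}: row {i + 2}: {exc}") from exc
    return out


def _parse_bool(raw: str) -> bool:
    if raw in ("1", "True", "true"):
        return True
    if raw in ("0", "False", "false"):
        return False
    raise FormatError(f"expected boolean 0/1, got {raw!r}")


def write_cohort(records: Sequence[CohortRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in _COHORT_COLS}
        row["response"] = r.response or ""
        row["os_event"] = int(r.os_event)
        row["pfs_event"] = int(r.pfs_event)
        rows.append(row)
    pd.DataFrame(rows, columns=list(_COHORT_COLS)).to_csv(path, sep="\t", index=False)
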