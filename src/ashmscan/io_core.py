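"""Reading, writing and filtering of variant calls and cohort metadata.

Somatic single-nucleotide variants (SNVs) are the unit of analysis for
every downstream stage: hotspot enrichment, AID-context classification,
mutational-signature extraction and transcription-factor-binding-site
impact calls are all substitution based.  Indels are therefore rejected
at parse time (with a logged count) rather than silently dropped later.

Coordinate convention: VCF input is 1-based; :class:`VariantRecord.pos`
keeps the 1-based VCF position, while every *interval* in the package is
0-based half-open (:class:`GenomicInterval`).  The conversion between the
two happens in exactly one place, :func:`interval_contains`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")


class DataIntegrityError(ValueError):
    """Raised when an input contradicts the reference data it claims to match."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval, 0-based start (inclusive), end exclusive."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @classmethod
    def from_1based(cls, chrom: str, start1: int, end1: int) -> "GenomicInterval":
        """Build from 1-based inclusive coordinates (e.g. as printed in figures)."""
        return cls(chrom, start1 - 1, end1)


@dataclass
class VariantRecord:
    """One somatic SNV call in one sample."""

    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    sample_id: str
    filter_status: frozenset = frozenset({"PASS"})
    population_af: float | None = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValueError(f"ref/alt must be single bases, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if not isinstance(self.filter_status, frozenset):
            self.filter_status = frozenset(self.filter_status)


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    cohort: str
    ighv_status: str = "unknown"  # mutated / unmutated / unknown
    t11_14: str = "unknown"  # present / absent / unknown
    material: str = ""


def interval_contains(interval: GenomicInterval, chrom: str, pos: int) -> bool:
    """Half-open containment of a 1-based variant position."""
    return interval.chrom == chrom and interval.start <= pos - 1 < interval.end


# ---------------------------------------------------------------------------
# VCF input


def read_variants(
    path: str | Path,
    sample_id: str | None = None,
    af_fields: Sequence[str] = ("gnomAD_AF", "AF"),
) -> list[VariantRecord]:
    """Read SNVs from a VCF 4.x file (plain or bgzip).

    Parameters
    ----------
    path
        VCF file.  If the file has genotype columns and ``sample_id`` is not
        given, one record is emitted per carrying sample (any non-reference
        genotype counts as carriage).  Otherwise every site is attributed to
        ``sample_id`` (the per-file dialect, label usually from metadata).
    af_fields
        INFO keys probed in order for the population allele frequency.

    Multi-allelic sites are split into one record per ALT.  Indels and
    symbolic alleles are dropped with a logged count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    if not vcf_samples and sample_id is None:
        raise ValueError(f"{path}: VCF has no genotype columns; sample_id required")

    records: list[VariantRecord] = []
    n_indels = 0
    for v in vcf:
        filters = frozenset(v.FILTERS) if v.FILTERS else frozenset({"PASS"})
        af = None
        for key in af_fields:
            raw = v.INFO.get(key)
            if raw is not None:
                af = float(raw if not isinstance(raw, tuple) else raw[0])
                break
        if sample_id is not None:
            carriers = [sample_id]
        else:
            # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
            carriers = [s for s, g in zip(vcf_samples, v.gt_types) if g in (1, 3)]
        for alt in v.ALT:
            if len(v.REF) != 1 or len(alt) != 1 or alt not in VALID_BASES:
                n_indels += 1
                continue
            for carrier in carriers:
                records.append(
                    VariantRecord(
                        chrom=v.CHROM,
                        pos=v.POS,
                        ref=v.REF,
                        alt=alt,
                        sample_id=carrier,
                        filter_status=filters,
                        population_af=af,
                    )
                )
    if n_indels:
        logger.warning("%s: dropped %d non-SNV allele(s)", path, n_indels)
    return records


def read_variant_dir(
    vcf_dir: str | Path, meta: Sequence[SampleMeta], suffix: str = ".vcf"
) -> list[VariantRecord]:
    """Read one VCF per sample from a directory, named ``<sample_id><suffix>``."""
    records: list[VariantRecord] = []
    for m in meta:
        path = Path(vcf_dir) / f"{m.sample_id}{suffix}"
        if path.exists():
            records.extend(read_variants(path, sample_id=m.sample_id))
    return records


# ---------------------------------------------------------------------------
# Filters


def filter_variants(
    records: Iterable[VariantRecord],
    max_population_af: float = 0.005,
    require_pass: bool = True,
) -> list[VariantRecord]:
    """Apply the variant-level inclusion filters.

    A record is kept when its filter column contains PASS (if required) and
    its population allele frequency is either unknown or does not exceed
    ``max_population_af``.  An unknown frequency means the variant was not
    found in the population database and therefore cannot be a common
    polymorphism on that evidence; excluding unknowns would delete the
    somatic calls the analysis is about.  Input order is preserved and the
    operation is idempotent.
    """
    if max_population_af < 0:
        raise ValueError(f"max_population_af must be >= 0, got {max_population_af}")
    kept = []
    for r in records:
        if require_pass and "PASS" not in r.filter_status:
            continue
        if r.population_af is not None and r.population_af > max_population_af:
            continue
        kept.append(r)
    return kept


def count_samples_with_min_variants(
    records: Iterable[VariantRecord],
    meta: Sequence[SampleMeta],
    region: GenomicInterval,
    min_n: int = 5,
) -> dict[str, tuple[int, int, float | None]]:
    """Per-cohort fraction of samples with >= ``min_n`` variants in ``region``.

    The denominator is every sample of the cohort in the metadata table,
    including samples that contributed no variant at all.  Empty cohorts
    yield a fraction of ``None``.
    """
    known = {m.sample_id for m in meta}
    per_sample: dict[str, int] = {m.sample_id: 0 for m in meta}
    for r in records:
        if r.sample_id not in known:
            raise ValueError(f"sample {r.sample_id!r} missing from metadata")
        if interval_contains(region, r.chrom, r.pos):
            per_sample[r.sample_id] += 1
    out: dict[str, tuple[int, int, float | None]] = {}
    for cohort in sorted({m.cohort for m in meta}):
        samples = [m.sample_id for m in meta if m.cohort == cohort]
        num = sum(per_sample[s] >= min_n for s in samples)
        den = len(samples)
        out[cohort] = (num, den, num / den if den else None)
    return out


# ---------------------------------------------------------------------------
# Tabular formats

_TSV_COLUMNS = ["chrom", "pos", "ref", "alt", "sample_id", "filters", "population_af"]


def write_variant_tsv(records: Sequence[VariantRecord], path: str | Path) -> None:
    """Write the canonical variant table (tab-separated)."""
    rows = [
        {
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "sample_id": r.sample_id,
            "filters": ";".join(sorted(r.filter_status)),
            "population_af": "" if r.population_af is None else repr(r.population_af),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variant_tsv(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            VariantRecord(
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                sample_id=row.sample_id,
                filter_status=frozenset(row.filters.split(";")) if row.filters else frozenset(),
                population_af=float(row.population_af) if row.population_af else None,
            )
        )
    return records


def read_metadata(path: str | Path) -> list[SampleMeta]:
    """Read the sample metadata table (``sample_id cohort ighv_status t11_14 material``)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "cohort"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: metadata needs columns {sorted(required)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dups}")
    return [
        SampleMeta(
            sample_id=row.sample_id,
            cohort=row.cohort,
            ighv_status=getattr(row, "ighv_status", "unknown") or "unknown",
            t11_14=getattr(row, "t11_14", "unknown") or "unknown",
            material=getattr(row, "material", "") or "",
        )
        for row in df.itertuples(index=False)
    ]


def write_metadata(meta: Sequence[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "cohort": m.cohort,
                "ighv_status": m.ighv_status,
                "t11_14": m.t11_14,
                "material": m.material,
            }
            for m in meta
        ]
    ).to_csv(path, sep="\t", index=False)


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3 intervals (already 0-based half-open)."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            intervals.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return intervals


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
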