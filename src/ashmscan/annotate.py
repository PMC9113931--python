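"""Coding/non-coding partition and amino-acid consequence calls.

A variant is *coding* when it overlaps a CDS interval of any supplied
transcript; everything else — promoter, UTRs, introns, intergenic — is
*non-coding*, which keeps protein-level selection strictly out of the
regulatory analysis downstream.  Consequences are called by translating the
affected codon before and after the substitution with the standard genetic
code (strand aware, reverse-complementing for minus-strand transcripts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from ._seq import complement, fetch, revcomp
from .io_core import DataIntegrityError, GenomicInterval, VariantRecord, interval_contains


@dataclass(frozen=True)
class TranscriptModel:
    transcript_id: str
    chrom: str
    strand: str  # "+" | "-"
    exons: tuple[GenomicInterval, ...]
    cds: tuple[GenomicInterval, ...]  # genomic order; subset of the exons
    tss: int  # 1-based genomic position of the transcript 5' end

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        total = sum(len(iv) for iv in self.cds)
        if total % 3 != 0:
            raise ValueError(f"{self.transcript_id}: CDS length {total} not divisible by 3")
        starts = [iv.start for iv in self.exons]
        if starts != sorted(starts):
            raise ValueError(f"{self.transcript_id}: exons must be sorted")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.transcript_id}: overlapping exons")


@dataclass(frozen=True)
class ConsequenceCall:
    variant: VariantRecord
    category: str  # coding | non-coding
    effect: str  # synonymous | missense | nonsense | non-coding
    aa_change: str = ""  # e.g. "E36K"; empty unless missense/nonsense
    codon_index: int | None = None  # 1-based


def classify_region(
    variant: VariantRecord, regions: Mapping[str, GenomicInterval]
) -> set[str]:
    """Names of the regions containing the variant (half-open containment)."""
    return {
        name for name, iv in regions.items() if interval_contains(iv, variant.chrom, variant.pos)
    }


def _coding_sequence(transcript: TranscriptModel, genome) -> str:
    seq = "".join(fetch(genome, transcript.chrom, iv.start, iv.end) for iv in transcript.cds)
    return revcomp(seq) if transcript.strand == "-" else seq


def _cds_offset(transcript: TranscriptModel, pos0: int) -> int | None:
    """Offset of a genomic position within the transcript's coding sequence."""
    covered = 0
    if transcript.strand == "+":
        for iv in transcript.cds:
            if iv.start <= pos0 < iv.end:
                return covered + (pos0 - iv.start)
            covered += len(iv)
    else:
        for iv in reversed(transcript.cds):
            if iv.start <= pos0 < iv.end:
                return covered + (iv.end - 1 - pos0)
            covered += len(iv)
    return None


def call_consequence(
    variant: VariantRecord, transcript: TranscriptModel, genome
) -> ConsequenceCall:
    """Amino-acid consequence of a substitution against one transcript."""
    pos0 = variant.pos - 1
    ref_base = fetch(genome, variant.chrom, pos0, pos0 + 1)
    if ref_base != variant.ref:
        raise DataIntegrityError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: "
            f"genome has {ref_base!r}, record says {variant.ref!r}"
        )
    if variant.chrom != transcript.chrom:
        return ConsequenceCall(variant, "non-coding", "non-coding")
    offset = _cds_offset(transcript, pos0)
    if offset is None:
        return ConsequenceCall(variant, "non-coding", "non-coding")

    cds = _coding_sequence(transcript, genome)
    if transcript.strand == "+":
        ref_tx, alt_tx = variant.ref, variant.alt
    else:
        ref_tx, alt_tx = complement(variant.ref), complement(variant.alt)
    if cds[offset] != ref_tx:
        raise DataIntegrityError(
            f"{transcript.transcript_id}: coding sequence disagrees with genome at "
            f"{variant.chrom}:{variant.pos}"
        )
    codon_idx = offset // 3
    within = offset % 3
    codon = cds[3 * codon_idx : 3 * codon_idx + 3]
    mutated = codon[:within] + alt_tx + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    if aa_ref == aa_alt:
        return ConsequenceCall(variant, "coding", "synonymous", "", codon_idx + 1)
    effect = "nonsense" if aa_alt == "*" else "missense"
    return ConsequenceCall(
        variant, "coding", effect, f"{aa_ref}{codon_idx + 1}{aa_alt}", codon_idx + 1
    )


def split_coding_noncoding(
    records: Iterable[VariantRecord], transcripts: Sequence[TranscriptModel]
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Exhaustive, disjoint partition: coding iff overlapping any transcript's CDS."""
    coding, noncoding = [], []
    for r in records:
        in_cds = any(
            r.chrom == t.chrom and _cds_offset(t, r.pos - 1) is not None for t in transcripts
        )
        (coding if in_cds else noncoding).append(r)
    return coding, noncoding


# ---------------------------------------------------------------------------
# Transcript input formats


def read_transcripts_tsv(path) -> list[TranscriptModel]:
    """Minimal transcript table: ``transcript_id chrom strand exon_starts
    exon_ends cds_starts cds_ends tss`` with comma-separated coordinate lists
    (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for row in df.itertuples(index=False):
        exons = tuple(
            GenomicInterval(row.chrom, int(s), int(e))
            for s, e in zip(row.exon_starts.split(","), row.exon_ends.split(","))
        )
        cds = tuple(
            GenomicInterval(row.chrom, int(s), int(e))
            for s, e in zip(str(row.cds_starts).split(","), str(row.cds_ends).split(","))
            if s
        )
        out.append(
            TranscriptModel(
                transcript_id=row.transcript_id,
                chrom=row.chrom,
                strand=row.strand,
                exons=exons,
                cds=cds,
                tss=int(row.tss),
            )
        )
    return out


def write_transcripts_tsv(transcripts: Sequence[TranscriptModel], path) -> None:
    rows = []
    for t in transcripts:
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "chrom": t.chrom,
                "strand": t.strand,
                "exon_starts": ",".join(str(iv.start) for iv in t.exons),
                "exon_ends": ",".join(str(iv.end) for iv in t.exons),
                "cds_starts": ",".join(str(iv.start) for iv in t.cds),
                "cds_ends": ",".join(str(iv.end) for iv in t.cds),
                "tss": t.tss,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_bed12(path) -> list[TranscriptModel]:
    """Read transcripts from BED12 (thickStart/thickEnd delimit the CDS)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, _end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                GenomicInterval(chrom, start + o, start + o + s) for o, s in zip(offsets, sizes)
            )
            cds = tuple(
                GenomicInterval(chrom, max(iv.start, thick_start), min(iv.end, thick_end))
                for iv in exons
                if iv.start < thick_end and iv.end > thick_start
            )
            tss = exons[0].start + 1 if strand == "+" else exons[-1].end
            out.append(TranscriptModel(name, chrom, strand, exons, cds, tss))
    return out


def consequences_to_frame(calls: Iterable[ConsequenceCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.variant.chrom,
                "pos": c.variant.pos,
                "ref": c.variant.ref,
                "alt": c.variant.alt,
                "sample_id": c.variant.sample_id,
                "category": c.category,
                "effect": c.effect,
                "aa_change": c.aa_change,
            }
            for c in calls
        ]
    )
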