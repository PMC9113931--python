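"""Seeded synthetic fixtures with the statistical structure of a lymphoma
whole-genome cohort scan.

The generator emulates the inputs every analysis stage consumes: a random
reference sequence, per-sample somatic SNV calls with negative-binomial
count heterogeneity, cohort-specific hotspot intervals (rate multipliers),
AID-biased substitution contexts, trinucleotide-signature mixtures, planted
constructive/destructive binding-site clusters, and a two-group expression
matrix with a planted focal-gene effect.  Every run is fully reproducible
from the seed and ships a ground-truth manifest for closed-loop recovery
tests.

It does not emulate read-level noise, germline contamination, mappability
or the scale of a real human genome — see the methods note for what that
implies about test evidence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import aid_context
from ._seq import R, W, Y
from .annotate import GenomicInterval, TranscriptModel, write_transcripts_tsv
from .io_core import SampleMeta, VariantRecord, write_bed, write_metadata
from .motif_impact import PWM, write_jaspar

# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class PlantedCluster:
    """A hotspot interval with a cohort-specific rate multiplier.

    ``motif_mode`` plants a binding site in the interval: *destructive*
    writes the PWM consensus and draws variants breaking its most
    informative columns; *constructive* writes a near-site with 1-2
    mismatches and draws variants restoring the consensus; *none* draws
    uniform substitutions.
    """

    start: int
    end: int
    cohort: str
    multiplier: float
    motif_mode: str = "none"
    pwm_id: str | None = None

    def __post_init__(self) -> None:
        if self.multiplier < 1:
            raise ValueError("multiplier must be >= 1")
        if self.motif_mode not in ("none", "constructive", "destructive"):
            raise ValueError(f"unknown motif_mode {self.motif_mode!r}")


@dataclass(frozen=True)
class ExpressionConfig:
    n_genes: int = 200
    n_markers: int = 5  # per direction
    effect_sd: float = 3.0
    focal_gene: str = "CCND1"
    focal_shift: float = 2.0
    baseline: float = 8.0


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    chrom: str = "chrS"
    genome_length: int = 10_000
    gc_content: float = 0.45
    cohorts: tuple[tuple[str, int], ...] = (("MCL", 50), ("nonMCL", 150))
    per_sample_rate: float = 20.0
    dispersion: float = 0.3  # negative-binomial: var = mu + dispersion * mu^2
    planted_clusters: tuple[PlantedCluster, ...] = ()
    aid_fraction: float = 0.3
    signature_weights: tuple[tuple[str, tuple[float, ...]], ...] = (
        ("MCL", (0.7, 0.3)),
        ("nonMCL", (0.5, 0.5)),
    )
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)

    def __post_init__(self) -> None:
        if not 0.0 <= self.aid_fraction <= 1.0:
            raise ValueError("aid_fraction must be in [0, 1]")
        for _, w in self.signature_weights:
            if abs(sum(w) - 1.0) > 1e-9:
                raise ValueError("signature weights must sum to 1")


# ---------------------------------------------------------------------------
# Built-in truth profiles and motifs


def builtin_profiles() -> tuple[np.ndarray, list[str]]:
    """Two planted 96-context profiles: an AID-like one (C>T/C>G at W-flanked
    cytosines) and a replication-error-like one (T>C dominated)."""
    from .signatures import CONTEXTS_96

    aid = np.zeros(96)
    poleta = np.zeros(96)
    for i, ctx in enumerate(CONTEXTS_96):
        five, sub, three = ctx[0], ctx[2:5], ctx[6]
        if sub == "C>T" and five in "AT":
            aid[i] = 1.0
        elif sub == "C>G" and five in "AT":
            aid[i] = 0.5
        if sub == "T>C":
            poleta[i] = 1.0
        elif sub == "T>A":
            poleta[i] = 0.3
    aid /= aid.sum()
    poleta /= poleta.sum()
    return np.vstack([aid, poleta]), ["aid_like", "replication_like"]


def builtin_pwms() -> list[PWM]:
    """Strongly informative toy motifs used for planted binding-site clusters."""

    def counts_for(consensus: str, strong: int = 17, weak: int = 1) -> np.ndarray:
        mat = np.full((4, len(consensus)), weak, dtype=float)
        for j, base in enumerate(consensus):
            mat["ACGT".index(base), j] = strong
        return mat

    return [
        PWM("e2f_like", counts_for("TTTGGCGC")),
        PWM("cebp_like", counts_for("TTGCGCAA")),
        PWM("mef2_like", counts_for("CTATTTATAG")),
    ]


# ---------------------------------------------------------------------------
# Genome and context pools


def random_genome(length: int, gc_content: float, rng: np.random.Generator) -> list[str]:
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    bases = rng.choice(list("ACGT"), size=length, p=[at, gc, gc, at])
    return list(bases)


def context_positions(genome_seq: str, kind: str) -> list[tuple[int, str, str]]:
    """All (0-based position, ref, alt-alphabet) sites realizing an AID context.

    ``kind`` is ``c-AID``, ``nc-AID`` or ``none``-complement pools are not
    enumerated (the generator verifies "none" plantings by classification).
    """
    sites: list[tuple[int, str, str]] = []
    n = len(genome_seq)
    if kind == "c-AID":
        for i in range(2, n - 1):
            if genome_seq[i] == "C" and genome_seq[i - 2] in W and genome_seq[i - 1] in R and genome_seq[i + 1] in Y:
                sites.append((i, "C", "TG"))
            if genome_seq[i] == "G" and genome_seq[i - 1] in R and genome_seq[i + 1] in Y and i + 2 < n and genome_seq[i + 2] in W:
                sites.append((i, "G", "AC"))
    elif kind == "nc-AID":
        for i in range(1, n - 1):
            # exclude sites that also qualify as c-AID (precedence would flip the label)
            if genome_seq[i] == "A" and genome_seq[i - 1] in W:
                sites.append((i, "A", "CG"))
            if genome_seq[i] == "T" and genome_seq[i + 1] in W:
                sites.append((i, "T", "GC"))
    else:
        raise ValueError(f"no site pool for kind {kind!r}")
    return sites


def plant_variant_in_context(
    genome: dict[str, str],
    chrom: str,
    pools: dict[str, list[tuple[int, str, str]]],
    kind: str,
    rng: np.random.Generator,
) -> tuple[int, str, str]:
    """Draw (1-based pos, ref, alt) classifying as the requested AID kind."""
    if kind in ("c-AID", "nc-AID"):
        pool = pools.get(kind, [])
        order = rng.permutation(len(pool))
        for idx in order:
            pos0, ref, alts = pool[idx]
            alt = alts[rng.integers(len(alts))]
            v = VariantRecord(chrom, pos0 + 1, ref, alt, "probe")
            if aid_context.classify_aid(v, genome).label == kind:
                return pos0 + 1, ref, alt
        raise RuntimeError(f"exhausted {kind} site pool")
    if kind == "none":
        seq = genome[chrom]
        for _ in range(200):
            pos0 = int(rng.integers(3, len(seq) - 3))
            ref = seq[pos0]
            alt = "ACGT".replace(ref, "")[rng.integers(3)]
            v = VariantRecord(chrom, pos0 + 1, ref, alt, "probe")
            if aid_context.classify_aid(v, genome).label == "none":
                return pos0 + 1, ref, alt
        raise RuntimeError("exhausted attempts to plant a context-free variant")
    raise ValueError(f"unknown context kind {kind!r}")


def plant_motif_cluster(
    genome: list[str],
    interval: GenomicInterval,
    pwm: PWM,
    mode: str,
    rng: np.random.Generator,
    n_break_columns: int = 3,
) -> list[tuple[int, str, str]]:
    """Edit the genome inside ``interval`` and return the variant menu.

    Destructive mode writes the PWM consensus and returns variants changing
    its most informative columns to their least favoured base; constructive
    mode writes a near-site with mismatches at 2 informative columns and
    returns variants restoring the consensus.
    """
    L = pwm.length
    if len(interval) < L + 2:
        raise ValueError(f"interval {interval} too small for motif of length {L}")
    site = (interval.start + interval.end) // 2 - L // 2
    consensus = pwm.consensus()
    info_order = np.argsort(-pwm.information_content())
    probs = pwm.probabilities

    def worst_base(col: int) -> str:
        order = np.argsort(probs[:, col])
        for bi in order:
            if "ACGT"[bi] != consensus[col]:
                return "ACGT"[bi]
        raise AssertionError

    menu: list[tuple[int, str, str]] = []
    if mode == "destructive":
        for j, base in enumerate(consensus):
            genome[site + j] = base
        for col in info_order[:n_break_columns]:
            col = int(col)
            menu.append((site + col + 1, consensus[col], worst_base(col)))
    elif mode == "constructive":
        written = list(consensus)
        for col in info_order[:2]:
            col = int(col)
            written[col] = worst_base(col)
            menu.append((site + col + 1, written[col], consensus[col]))
        for j, base in enumerate(written):
            genome[site + j] = base
    else:
        raise ValueError(f"unknown motif mode {mode!r}")
    return menu


# ---------------------------------------------------------------------------
# Sampling helpers


def sample_variant_counts(
    n_samples: int, rate: float, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Negative-binomial per-sample variant counts (var = mu + dispersion*mu^2)."""
    if dispersion <= 0:
        return rng.poisson(rate, size=n_samples)
    r = 1.0 / dispersion
    p = r / (r + rate)
    return rng.negative_binomial(r, p, size=n_samples)


def _trinuc_pools(seq: str) -> dict[str, list[int]]:
    pools: dict[str, list[int]] = {}
    for i in range(1, len(seq) - 1):
        if seq[i] in "CT":  # pyrimidine-centred placement sites
            pools.setdefault(seq[i - 1 : i + 2], []).append(i)
    return pools


def simulate_spectra(
    profiles: np.ndarray,
    n_samples: int,
    n_variants: int,
    rng: np.random.Generator,
    alpha: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Directly sampled 96-context count matrix from mixed truth profiles.

    Per sample the mixing weights are Dirichlet(alpha) and the counts a
    multinomial draw of ``n_variants`` from the mixed profile.  Returns
    (m x 96 counts, m x k true weights).
    """
    k = profiles.shape[0]
    weights = rng.dirichlet(np.full(k, alpha), size=n_samples)
    counts = np.vstack(
        [rng.multinomial(n_variants, w @ profiles) for w in weights]
    ).astype(float)
    return counts, weights


# ---------------------------------------------------------------------------
# The bundle


@dataclass
class TruthManifest:
    planted_clusters: list[dict]
    variant_truth: list[str]  # parallel to records: background|c-AID|hotspot|motif
    signature_profiles: np.ndarray
    signature_names: list[str]
    signature_weights: dict[str, tuple[float, ...]]
    subtype_truth: dict[str, str]
    mut_truth: dict[str, bool]


@dataclass
class SimBundle:
    config: SimConfig
    genome: dict[str, str]
    territory: list[GenomicInterval]
    meta: list[SampleMeta]
    records: list[VariantRecord]
    transcript: TranscriptModel
    pwms: list[PWM]
    expression: pd.DataFrame
    markers: dict[str, int]
    truth: TruthManifest


# toy coding sequence: ATG then alternating Glu (GAG) / Ala (GCG) codons
_TOY_CDS = "ATG" + "GAGGCG" * 24 + "TAA"  # 150 bp


def _plant_transcript(genome: list[str], chrom: str, length: int) -> TranscriptModel:
    """Write a toy single-exon transcript with a CDS into the genome tail."""
    cds_len = len(_TOY_CDS)
    exon_start = length - cds_len - 120
    cds_start = exon_start + 60
    for j, base in enumerate(_TOY_CDS):
        genome[cds_start + j] = base
    exon = GenomicInterval(chrom, exon_start, cds_start + cds_len + 30)
    cds = GenomicInterval(chrom, cds_start, cds_start + cds_len)
    return TranscriptModel("TOY1", chrom, "+", (exon,), (cds,), tss=exon.start + 1)


def simulate(config: SimConfig, outdir: str | Path | None = None) -> SimBundle:
    """Generate the full fixture bundle (optionally written to ``outdir``)."""
    from .signatures import CONTEXTS_96

    rng = np.random.default_rng(config.seed)
    chrom = config.chrom
    genome_list = random_genome(config.genome_length, config.gc_content, rng)

    # planted binding sites edit the genome before any variant is placed
    pwm_by_id = {p.motif_id: p for p in builtin_pwms()}
    cluster_menus: list[list[tuple[int, str, str]]] = []
    for pc in config.planted_clusters:
        if pc.motif_mode == "none":
            cluster_menus.append([])
            continue
        pwm = pwm_by_id[pc.pwm_id or "e2f_like"]
        menu = plant_motif_cluster(
            genome_list, GenomicInterval(chrom, pc.start, pc.end), pwm, pc.motif_mode, rng
        )
        cluster_menus.append(menu)
    transcript = _plant_transcript(genome_list, chrom, config.genome_length)

    seq = "".join(genome_list)
    genome = {chrom: seq}
    territory = [GenomicInterval(chrom, 0, config.genome_length)]

    profiles, profile_names = builtin_profiles()
    weights = dict(config.signature_weights)
    trinucs = _trinuc_pools(seq)
    aid_pool = {"c-AID": context_positions(seq, "c-AID")}

    meta: list[SampleMeta] = []
    records: list[VariantRecord] = []
    variant_truth: list[str] = []

    for cohort, n_samples in config.cohorts:
        counts = sample_variant_counts(n_samples, config.per_sample_rate, config.dispersion, rng)
        mix = np.asarray(weights.get(cohort, np.full(profiles.shape[0], 1.0 / profiles.shape[0])))
        mixed_profile = mix @ profiles
        for i in range(n_samples):
            sample_id = f"{cohort}_{i:04d}"
            meta.append(
                SampleMeta(
                    sample_id=sample_id,
                    cohort=cohort,
                    ighv_status="mutated" if rng.random() < 0.6 else "unmutated",
                    t11_14="present",
                )
            )
            used: set[int] = set()
            for _ in range(int(counts[i])):
                if rng.random() < config.aid_fraction:
                    for _ in range(10):
                        pos, ref, alt = plant_variant_in_context(genome, chrom, aid_pool, "c-AID", rng)
                        if pos not in used:
                            break
                    truth = "c-AID"
                else:
                    pos, ref, alt = _signature_variant(seq, trinucs, mixed_profile, CONTEXTS_96, rng, used)
                    truth = "background"
                if pos in used:
                    continue
                used.add(pos)
                records.append(VariantRecord(chrom, pos, ref, alt, sample_id))
                variant_truth.append(truth)

    # hotspot / motif-cluster extra variants per cohort sample
    L_tot = config.genome_length
    planted_out: list[dict] = []
    for pc, menu in zip(config.planted_clusters, cluster_menus):
        lam = (pc.multiplier - 1.0) * config.per_sample_rate * (pc.end - pc.start) / L_tot
        cohort_samples = [m.sample_id for m in meta if m.cohort == pc.cohort]
        carriers = []
        for sample_id in cohort_samples:
            k = int(rng.poisson(lam))
            if k == 0:
                continue
            carriers.append(sample_id)
            if menu:
                take = rng.choice(len(menu), size=min(k, len(menu)), replace=False)
                chosen = [menu[int(t)] for t in take]
                truth = "motif"
            else:
                positions = rng.integers(pc.start, pc.end, size=k)
                chosen = []
                for pos0 in positions:
                    pos0 = int(pos0)
                    ref = seq[pos0]
                    alt = "ACGT".replace(ref, "")[rng.integers(3)]
                    chosen.append((pos0 + 1, ref, alt))
                truth = "hotspot"
            seen = set()
            for pos, ref, alt in chosen:
                if pos in seen:
                    continue
                seen.add(pos)
                records.append(VariantRecord(chrom, pos, ref, alt, sample_id))
                variant_truth.append(truth)
        planted_out.append(
            {
                "chrom": chrom,
                "start": pc.start,
                "end": pc.end,
                "cohort": pc.cohort,
                "multiplier": pc.multiplier,
                "motif_mode": pc.motif_mode,
                "pwm_id": pc.pwm_id or ("e2f_like" if pc.motif_mode != "none" else None),
                "menu": [list(m) for m in menu],
                "carriers": carriers,
            }
        )

    expression, markers, subtype_truth, mut_truth = _simulate_expression(
        config, meta, records, transcript, planted_out, rng
    )

    truth = TruthManifest(
        planted_clusters=planted_out,
        variant_truth=variant_truth,
        signature_profiles=profiles,
        signature_names=profile_names,
        signature_weights={c: tuple(w) for c, w in config.signature_weights},
        subtype_truth=subtype_truth,
        mut_truth=mut_truth,
    )
    bundle = SimBundle(
        config=config,
        genome=genome,
        territory=territory,
        meta=meta,
        records=records,
        transcript=transcript,
        pwms=builtin_pwms(),
        expression=expression,
        markers=markers,
        truth=truth,
    )
    if outdir is not None:
        write_bundle(bundle, Path(outdir))
    return bundle


def _signature_variant(
    seq: str,
    trinucs: dict[str, list[int]],
    profile: np.ndarray,
    contexts: Sequence[str],
    rng: np.random.Generator,
    used: set[int],
) -> tuple[int, str, str]:
    """Place one variant whose trinucleotide class follows the profile."""
    for _ in range(50):
        cls = contexts[int(rng.choice(96, p=profile / profile.sum()))]
        five, ref, alt, three = cls[0], cls[2], cls[4], cls[6]
        pool = trinucs.get(f"{five}{ref}{three}")
        if not pool:
            continue
        pos0 = pool[int(rng.integers(len(pool)))]
        if pos0 not in used:
            return pos0 + 1, ref, alt
    # fallback: uniform position, any substitution
    pos0 = int(rng.integers(1, len(seq) - 1))
    ref = seq[pos0]
    alt = "ACGT".replace(ref, "")[int(rng.integers(3))]
    return pos0 + 1, ref, alt


def _simulate_expression(
    config: SimConfig,
    meta: list[SampleMeta],
    records: list[VariantRecord],
    transcript: TranscriptModel,
    planted_out: list[dict],
    rng: np.random.Generator,
):
    """Two-subtype expression matrix for the focal cohort with a planted
    focal-gene shift in samples that genuinely satisfy the mutated-group rule."""
    ec = config.expression
    focal_cohort = config.cohorts[0][0]
    samples = [m.sample_id for m in meta if m.cohort == focal_cohort]
    subtype_truth = {s: ("cMCL" if rng.random() < 0.5 else "nnMCL") for s in samples}

    cds = transcript.cds[0]
    cluster_ivs = [
        (d["start"], d["end"]) for d in planted_out if d["cohort"] == focal_cohort
    ]
    cluster_counts = {s: 0 for s in samples}
    noncoding_counts = {s: 0 for s in samples}
    for r in records:
        if r.sample_id not in cluster_counts:
            continue
        pos0 = r.pos - 1
        if not (cds.start <= pos0 < cds.end):
            noncoding_counts[r.sample_id] += 1
        if any(lo <= pos0 < hi for lo, hi in cluster_ivs):
            cluster_counts[r.sample_id] += 1
    mut_truth = {
        s: subtype_truth[s] == "nnMCL"
        and cluster_counts[s] >= 2
        and noncoding_counts[s] >= 10
        for s in samples
    }

    genes = (
        [f"MARKER_P{i + 1}" for i in range(ec.n_markers)]
        + [f"MARKER_N{i + 1}" for i in range(ec.n_markers)]
        + [ec.focal_gene]
        + [f"GENE{i + 1:04d}" for i in range(ec.n_genes - 2 * ec.n_markers - 1)]
    )
    markers = {f"MARKER_P{i + 1}": +1 for i in range(ec.n_markers)}
    markers.update({f"MARKER_N{i + 1}": -1 for i in range(ec.n_markers)})

    X = ec.baseline + rng.normal(0.0, 1.0, size=(len(genes), len(samples)))
    df = pd.DataFrame(X, index=genes, columns=samples)
    for s in samples:
        if subtype_truth[s] == "cMCL":
            df.loc[[g for g, d in markers.items() if d > 0], s] += ec.effect_sd
        else:
            df.loc[[g for g, d in markers.items() if d < 0], s] += ec.effect_sd
        if mut_truth[s]:
            df.loc[ec.focal_gene, s] += ec.focal_shift
    return df, markers, subtype_truth, mut_truth


# ---------------------------------------------------------------------------
# File output


def write_vcf(records: Sequence[VariantRecord], path: Path, contig: str, length: int) -> None:
    """Write a minimal sites-only VCF 4.2 (one file per sample dialect)."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig},length={length}>",
        '##INFO=<ID=gnomAD_AF,Number=1,Type=Float,Description="Population allele frequency">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.alt)):
        info = "." if r.population_af is None else f"gnomAD_AF={r.population_af:g}"
        filt = ";".join(sorted(r.filter_status)) or "PASS"
        lines.append(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t{filt}\t{info}")
    path.write_text("\n".join(lines) + "\n")


def write_bundle(bundle: SimBundle, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chrom = bundle.config.chrom
    length = bundle.config.genome_length

    with open(outdir / "genome.fa", "w") as fh:
        fh.write(f">{chrom}\n")
        seq = bundle.genome[chrom]
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")

    vcf_dir = outdir / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    by_sample: dict[str, list[VariantRecord]] = {m.sample_id: [] for m in bundle.meta}
    for r in bundle.records:
        by_sample[r.sample_id].append(r)
    for sample_id, recs in by_sample.items():
        write_vcf(recs, vcf_dir / f"{sample_id}.vcf", chrom, length)

    write_metadata(bundle.meta, outdir / "meta.tsv")
    write_bed(bundle.territory, outdir / "territory.bed")
    write_transcripts_tsv([bundle.transcript], outdir / "transcript.tsv")
    write_jaspar(bundle.pwms, outdir / "motifs.jaspar")
    bundle.expression.to_csv(outdir / "expression.tsv", sep="\t", index_label="gene")
    pd.DataFrame(
        [{"gene": g, "direction": "+" if d > 0 else "-"} for g, d in bundle.markers.items()]
    ).to_csv(outdir / "markers.tsv", sep="\t", index=False)

    truth = bundle.truth
    manifest = {
        "planted_clusters": truth.planted_clusters,
        "signature_names": truth.signature_names,
        "signature_weights": truth.signature_weights,
        "subtype_truth": truth.subtype_truth,
        "mut_truth": truth.mut_truth,
    }
    (outdir / "truth.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    pd.DataFrame(
        {
            "chrom": [r.chrom for r in bundle.records],
            "pos": [r.pos for r in bundle.records],
            "ref": [r.ref for r in bundle.records],
            "alt": [r.alt for r in bundle.records],
            "sample_id": [r.sample_id for r in bundle.records],
            "truth": truth.variant_truth,
        }
    ).to_csv(outdir / "variant_truth.tsv", sep="\t", index=False)
    sigs = pd.DataFrame(
        truth.signature_profiles.T,
        columns=truth.signature_names,
    )
    from .signatures import CONTEXTS_96

    sigs.insert(0, "context", list(CONTEXTS_96))
    sigs.to_csv(outdir / "truth_signatures.tsv", sep="\t", index=False)
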