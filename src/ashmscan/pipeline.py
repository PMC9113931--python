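"""End-to-end orchestration: ingest -> annotate -> scan -> contexts ->
signatures -> motifs -> subtype -> report.

Every stage writes a plain TSV (with a provenance header line) into the run
directory, and every number in the summary is re-derivable from those stage
tables.  A stage failure aborts with the stage name while earlier outputs
are kept.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pyfaidx

from . import __version__, aid_context, annotate, enrich, io_core, motif_impact, pbstats, signatures, subtype

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    vcf_dir: str
    meta: str
    genome_fasta: str
    territory_bed: str
    transcripts: str
    pwm_file: str
    outdir: str
    expression: str | None = None
    markers: str | None = None
    reference_signatures: str | None = None
    regulatory_region: tuple[str, int, int] | None = None  # chrom, start0, end (default: territory)
    focal_cohort: str = "MCL"
    null_kind: str = "configuration"
    coarse_sizes: tuple[int, ...] = (10, 100, 1000, 10_000)
    fine_sizes: tuple[int, ...] = (5, 6, 7, 8, 9, 10)
    z_hi: float = 3.0
    z_lo: float = 2.0
    merge_gap: int = 2
    delta_min: float = 0.0
    pad: int = 15
    background_threshold: float = 0.75
    min_cluster_muts: int = 2
    min_noncoding: int = 10
    max_population_af: float = 0.005
    require_pass: bool = True
    k_signatures: int = 2
    exact_max_n: int = 200
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "regulatory_region" in data and data["regulatory_region"] is not None:
            data["regulatory_region"] = tuple(data["regulatory_region"])
        for key in ("coarse_sizes", "fine_sizes"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# ashm-scan v{__version__} seed={cfg.seed} config={cfg.config_hash()}\n")
        df.to_csv(fh, sep="\t", index=False)


def mutual_exclusivity_report(status: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Fisher's exact tests on a binary sample-by-category matrix.

    For each pair of mutation categories, the 2x2 table of carrier status is
    tested two-sided; a category carried by no sample yields an NA P value.
    """
    cats = list(status.columns)
    rows = []
    for i, a in enumerate(cats):
        for b in cats[i + 1 :]:
            va = status[a].astype(bool)
            vb = status[b].astype(bool)
            table = [
                [int((va & vb).sum()), int((va & ~vb).sum())],
                [int((~va & vb).sum()), int((~va & ~vb).sum())],
            ]
            if va.sum() == 0 or vb.sum() == 0:
                p = np.nan
            else:
                p = pbstats.fisher_exact_2x2(table)
            rows.append(
                {
                    "category_a": a,
                    "category_b": b,
                    "both": table[0][0],
                    "a_only": table[0][1],
                    "b_only": table[1][0],
                    "neither": table[1][1],
                    "fisher_p": p,
                }
            )
    return pd.DataFrame(rows)


def run_all(cfg: RunConfig) -> dict:
    """Run every stage in dependency order; returns the summary dictionary."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # -- pre-flight: every referenced input must exist before any computation
    required = [cfg.vcf_dir, cfg.meta, cfg.genome_fasta, cfg.territory_bed, cfg.transcripts, cfg.pwm_file]
    optional = [cfg.expression, cfg.markers, cfg.reference_signatures]
    for path in required + [p for p in optional if p]:
        if not Path(path).exists():
            raise FileNotFoundError(f"pre-flight: missing input {path}")

    summary: dict = {}
    stage = "ingest"
    try:
        meta = io_core.read_metadata(cfg.meta)
        raw = io_core.read_variant_dir(cfg.vcf_dir, meta)
        records = io_core.filter_variants(
            raw, max_population_af=cfg.max_population_af, require_pass=cfg.require_pass
        )
        io_core.write_variant_tsv(records, outdir / "variants.tsv")
        territory = io_core.read_bed(cfg.territory_bed)
        genome = pyfaidx.Fasta(cfg.genome_fasta)
        summary["n_samples"] = len(meta)
        summary["n_variants"] = len(records)

        stage = "annotate"
        transcripts = annotate.read_transcripts_tsv(cfg.transcripts)
        coding, noncoding = annotate.split_coding_noncoding(records, transcripts)
        calls = [annotate.call_consequence(r, transcripts[0], genome) for r in coding]
        calls += [annotate.ConsequenceCall(r, "non-coding", "non-coding") for r in noncoding]
        _write_tsv(annotate.consequences_to_frame(calls), outdir / "consequences.tsv", cfg)
        summary["n_coding"] = len(coding)
        summary["n_noncoding"] = len(noncoding)

        stage = "scan"
        sizes = [s for s in cfg.coarse_sizes if s <= sum(len(iv) for iv in territory)]
        scan = enrich.genome_scan(
            noncoding, meta, territory, sizes, cfg.focal_cohort,
            null_kind=cfg.null_kind, exact_max_n=cfg.exact_max_n,
        )
        _write_tsv(scan, outdir / "enrichment.tsv", cfg)
        if cfg.regulatory_region is not None:
            region = io_core.GenomicInterval(*cfg.regulatory_region)
        else:
            region = territory[0]
        fractions = io_core.count_samples_with_min_variants(noncoding, meta, region, min_n=5)
        frac_df = pd.DataFrame(
            [
                {"cohort": c, "n_ge5": n, "n_total": d, "fraction": f}
                for c, (n, d, f) in fractions.items()
            ]
        )
        _write_tsv(frac_df, outdir / "regulatory_fractions.tsv", cfg)

        stage = "clusters"
        zf, zb, grids = enrich.fine_scan_z(
            noncoding, meta, territory, cfg.fine_sizes, cfg.focal_cohort,
            null_kind=cfg.null_kind, exact_max_n=cfg.exact_max_n,
        )
        clusters = enrich.call_specific_clusters(
            zf, zb, grids, z_hi=cfg.z_hi, z_lo=cfg.z_lo, merge_gap=cfg.merge_gap
        )
        cl_df = pd.DataFrame(
            [
                {
                    "chrom": c.interval.chrom,
                    "start": c.interval.start,
                    "end": c.interval.end,
                    "z_focal": c.z_focal,
                    "z_background": c.z_background,
                    "class": c.specificity,
                }
                for c in clusters
            ]
        )
        _write_tsv(cl_df, outdir / "clusters.tsv", cfg)
        summary["n_clusters_focal_specific"] = sum(c.specificity == "focal-specific" for c in clusters)

        stage = "aid"
        aid_calls = [aid_context.classify_aid(r, genome) for r in noncoding]
        _write_tsv(aid_context.calls_to_frame(aid_calls), outdir / "aid_calls.tsv", cfg)
        cohort_of = {m.sample_id: m.cohort for m in meta}
        aid_summary = aid_context.summarize_contexts(
            aid_calls, group_key=lambda c: cohort_of[c.variant.sample_id]
        )
        _write_tsv(aid_summary, outdir / "aid_summary.tsv", cfg)

        stage = "signatures"
        by_sample: dict[str, list] = {}
        for r in noncoding:
            by_sample.setdefault(r.sample_id, []).append(r)
        spectra = [
            signatures.build_spectrum(v, genome, s) for s, v in sorted(by_sample.items())
        ]
        mat = signatures.spectra_matrix(spectra)
        keep = mat.sum(axis=1) > 0
        sigset = signatures.nmf_extract(
            mat[keep], k=cfg.k_signatures, seed=cfg.seed, n_starts=5, max_iter=2000
        )
        sig_df = pd.DataFrame(sigset.signatures.T, columns=[f"S{i+1}" for i in range(sigset.k)])
        sig_df.insert(0, "context", list(signatures.CONTEXTS_96))
        _write_tsv(sig_df, outdir / "signatures.tsv", cfg)
        if cfg.reference_signatures:
            ref = signatures.read_reference_catalog(cfg.reference_signatures)
            ref = ref.set_index("context") if "context" in ref.columns else ref
            sim = signatures.cosine_to_reference(sigset, ref, cfg.background_threshold)
            _write_tsv(sim, outdir / "signature_similarity.tsv", cfg)

        stage = "motifs"
        pwms = motif_impact.parse_jaspar(cfg.pwm_file)
        impact_rows = []
        cluster_summaries = []
        for ci, c in enumerate(clusters):
            if c.specificity != "focal-specific":
                continue
            in_cluster = [
                r for r in noncoding if io_core.interval_contains(c.interval, r.chrom, r.pos)
            ]
            seen = set()
            calls_m = []
            for r in in_cluster:
                key = (r.pos, r.alt)
                if key in seen:
                    continue
                seen.add(key)
                calls_m.extend(
                    motif_impact.classify_impact(r, genome, pwms, pad=cfg.pad, delta_min=cfg.delta_min)
                )
            impact_rows.append(motif_impact.impact_calls_to_frame(calls_m))
            for s in motif_impact.cluster_motif_summary(calls_m):
                cluster_summaries.append(
                    {
                        "cluster": f"{c.interval.chrom}:{c.interval.start}-{c.interval.end}",
                        "motif_id": s.motif_id,
                        "majority": s.majority,
                        "n_constructive": s.n_constructive,
                        "n_destructive": s.n_destructive,
                        "n_neutral": s.n_neutral,
                        "best_score": s.best_score,
                    }
                )
        impacts = (
            pd.concat(impact_rows, ignore_index=True) if impact_rows else pd.DataFrame()
        )
        _write_tsv(impacts, outdir / "motif_impacts.tsv", cfg)
        _write_tsv(pd.DataFrame(cluster_summaries), outdir / "cluster_motifs.tsv", cfg)

        stage = "subtype"
        if cfg.expression and cfg.markers:
            expr = pd.read_csv(cfg.expression, sep="\t", index_col=0)
            marker_df = pd.read_csv(cfg.markers, sep="\t")
            directions = {
                row.gene: (1 if row.direction == "+" else -1) for row in marker_df.itertuples()
            }
            calls_s = subtype.cluster_subtypes(expr, directions)
            specific = [c.interval for c in clusters if c.specificity == "focal-specific"]
            cluster_counts = {s: 0 for s in expr.columns}
            noncoding_counts = {s: 0 for s in expr.columns}
            for r in noncoding:
                if r.sample_id not in cluster_counts:
                    continue
                noncoding_counts[r.sample_id] += int(
                    io_core.interval_contains(region, r.chrom, r.pos)
                )
                cluster_counts[r.sample_id] += int(
                    any(io_core.interval_contains(iv, r.chrom, r.pos) for iv in specific)
                )
            calls_s = subtype.assign_mut_group(
                calls_s, cluster_counts, noncoding_counts,
                min_cluster_muts=cfg.min_cluster_muts, min_noncoding=cfg.min_noncoding,
            )
            _write_tsv(subtype.subtype_calls_to_frame(calls_s), outdir / "subtypes.tsv", cfg)
            summary["n_nnmcl_mut"] = sum(c.mut_group == "nnMCL_MUT" for c in calls_s)

        stage = "exclusivity"
        sample_ids = [m.sample_id for m in meta if m.cohort == cfg.focal_cohort]
        status = pd.DataFrame(False, index=sample_ids, columns=["non-coding", "missense", "synonymous"])
        for call in calls:
            if call.variant.sample_id not in status.index:
                continue
            if call.effect in ("missense", "nonsense"):
                status.loc[call.variant.sample_id, "missense"] = True
            elif call.effect == "synonymous":
                status.loc[call.variant.sample_id, "synonymous"] = True
            elif io_core.interval_contains(region, call.variant.chrom, call.variant.pos):
                status.loc[call.variant.sample_id, "non-coding"] = True
        excl = mutual_exclusivity_report(status)
        _write_tsv(excl, outdir / "mutual_exclusivity.tsv", cfg)

        stage = "synonymous-enrichment"
        groups: dict[str, tuple[int, int]] = {}
        for call in calls:
            if call.category != "coding":
                continue
            cohort = cohort_of[call.variant.sample_id]
            tot, syn = groups.get(cohort, (0, 0))
            groups[cohort] = (tot + 1, syn + (call.effect == "synonymous"))
        if groups:
            stats = pbstats.synonymous_enrichment(groups)
            syn_df = pd.DataFrame(
                [
                    {
                        "group": g,
                        "n_coding": groups[g][0],
                        "n_synonymous": groups[g][1],
                        "neglog10": s.neglog10,
                        "significant": s.significant,
                    }
                    for g, s in stats.items()
                ]
            )
            _write_tsv(syn_df, outdir / "synonymous_enrichment.tsv", cfg)

        stage = "report"
        top = scan[scan["cohort"] == cfg.focal_cohort].head(5)
        summary["top_bin"] = (
            f"{top.iloc[0]['chrom']}:{int(top.iloc[0]['start'])}-{int(top.iloc[0]['end'])}"
            if len(top)
            else ""
        )
        summary["top_bin_neglog10p"] = float(top.iloc[0]["neglog10p"]) if len(top) else np.nan
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return summary
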