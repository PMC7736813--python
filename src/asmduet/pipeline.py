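"""End-to-end orchestration of the two-assembly comparison.

``run_compare`` executes the separable analyses in dependency order —
structural calls, consensus-error profiling, coding impact, chromosome
features — on files named in a :class:`RunConfig`, writes one TSV per
stage plus a JSON/text report, and cross-checks every reported count
against the rows it wrote. Optional inputs (methylation table, centromere
consensus, depth tracks, self-alignments) switch their analyses to
"skipped" rather than failing the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import edlib
import yaml

from . import (
    alignment_projection as ap,
    chromosome_features as cf,
    coding_impact as ci,
    error_analysis as ea,
    formats_io as fio,
    structural_comparison as sc,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("structural", "errors", "coding", "features")


class ConfigError(Exception):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """Paths and thresholds for one comparison run.

    Required inputs: the contiguous assembly A, fragmented assembly B, the
    B-onto-A PAF, a single-sample VCF of read-backed calls against A, and a
    GFF3 of gene models on A. Everything else is optional and skips its
    analysis when absent.
    """

    assembly_a: str = ""
    assembly_b: str = ""
    paf: str = ""
    vcf: str = ""
    gff3: str = ""
    self_paf: str | None = None
    methylation: str | None = None
    centromere_consensus: str | None = None
    depth_shotgun_a: str | None = None
    depth_consensus_b: str | None = None
    outdir: str = "out"
    seed: int = 0
    # thresholds
    min_gap_bp: int = sc.DEFAULT_MIN_GAP_BP
    min_reciprocal_bp: int = 1_000_000
    local_mismatch_bp: int = ap.LOCAL_MISMATCH_THRESHOLD_BP
    redundancy_min_similarity: float = 0.97
    redundancy_max_total_depth: float = 60.0
    redundancy_max_each_depth: float = 40.0
    min_called_sites: int = 10
    window_bp: int = ea.WINDOW_BP
    step_bp: int = ea.STEP_BP
    enrichment_min_errors: int = ea.ENRICHMENT_MIN_ERRORS
    depth_cutoff: int = 5
    include_missense: bool = True
    telomere_motif: str = cf.TELOMERE_MOTIF
    telomere_min_units: int = 10
    centromere_min_identity: float = 0.8
    t2t_require_centromere: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self, stages: Sequence[str] = ALL_STAGES) -> None:
        required = {"assembly_a": self.assembly_a}
        if "structural" in stages:
            required["assembly_b"] = self.assembly_b
            required["paf"] = self.paf
            required["gff3"] = self.gff3
        if "errors" in stages or "coding" in stages:
            required["vcf"] = self.vcf
        if "coding" in stages:
            required["gff3"] = self.gff3
        for name, value in required.items():
            if not value:
                raise ConfigError(f"config key {name!r} is required")
            if not Path(value).exists():
                raise ConfigError(f"{name}: no such file {value!r}")
        for name in ("self_paf", "methylation", "centromere_consensus",
                     "depth_shotgun_a", "depth_consensus_b"):
            value = getattr(self, name)
            if value and not Path(value).exists():
                raise ConfigError(f"{name}: no such file {value!r}")

    @property
    def redundancy_criteria(self) -> sc.RedundancyCriteria:
        return sc.RedundancyCriteria(
            self.redundancy_min_similarity,
            self.redundancy_max_total_depth,
            self.redundancy_max_each_depth,
        )


def copy_similarity(seq1: str, seq2: str) -> float:
    """Alignment identity between two candidate copies (matches over columns)."""
    if not seq1 or not seq2:
        return 0.0
    result = edlib.align(seq1, seq2, mode="NW", task="distance")
    return max(0.0, 1.0 - result["editDistance"] / max(len(seq1), len(seq2)))


def _query_interval(record: fio.AlignmentRecord, t0: int, t1: int) -> tuple[int, int]:
    """Approximate query-coordinate interval for a target sub-span."""
    t0 = max(t0, record.target_start)
    t1 = min(t1, record.target_end)
    scale = record.query_span / record.target_span
    if record.strand == "+":
        q0 = record.query_start + round((t0 - record.target_start) * scale)
        q1 = record.query_start + round((t1 - record.target_start) * scale)
    else:
        q1 = record.query_end - round((t0 - record.target_start) * scale)
        q0 = record.query_end - round((t1 - record.target_start) * scale)
    return max(record.query_start, q0), min(record.query_end, max(q1, q0 + 1))


@dataclass
class _Inputs:
    assembly_a: list[fio.SequenceRecord] = field(default_factory=list)
    assembly_b: list[fio.SequenceRecord] = field(default_factory=list)
    alignments: list[fio.AlignmentRecord] = field(default_factory=list)
    self_alignments: list[fio.AlignmentRecord] | None = None
    variants: list[fio.VariantRecord] = field(default_factory=list)
    genes: list[fio.GeneModel] = field(default_factory=list)
    methylation: list[fio.MethylationSite] | None = None
    centromere_unit: str | None = None
    shotgun_depth: fio.DepthTrack | None = None
    consensus_depth_b: fio.DepthTrack | None = None

    @property
    def seqs_a(self) -> dict[str, str]:
        return {r.id: r.seq for r in self.assembly_a}

    @property
    def seqs_b(self) -> dict[str, str]:
        return {r.id: r.seq for r in self.assembly_b}


def _load_inputs(config: RunConfig, stages: Sequence[str]) -> _Inputs:
    inputs = _Inputs()
    inputs.assembly_a = fio.read_fasta(config.assembly_a)
    if "structural" in stages:
        inputs.assembly_b = fio.read_fasta(config.assembly_b)
        inputs.alignments = fio.read_paf(config.paf)
        if config.self_paf:
            inputs.self_alignments = fio.read_paf(config.self_paf)
    if ("errors" in stages or "coding" in stages) and config.vcf:
        inputs.variants = fio.read_vcf(config.vcf)
    if config.gff3 and ("structural" in stages or "coding" in stages):
        inputs.genes = fio.read_gff3(config.gff3)
    if config.methylation:
        inputs.methylation = fio.read_methylation_table(
            config.methylation, config.min_called_sites
        )
    if config.centromere_consensus:
        units = fio.read_fasta(config.centromere_consensus)
        inputs.centromere_unit = units[0].seq if units else None
    if config.depth_shotgun_a:
        inputs.shotgun_depth = fio.read_depth_track(config.depth_shotgun_a)
    if config.depth_consensus_b:
        inputs.consensus_depth_b = fio.read_depth_track(config.depth_consensus_b)
    return inputs


def stage_structural(config: RunConfig, inputs: _Inputs) -> tuple[dict, list[sc.StructuralCall]]:
    """Gap/overlap/redundancy/loss calling plus gene gain/loss accounting."""
    primary = ap.select_primary(inputs.alignments)
    by_record = {r.query_id: r for r in primary}
    calls: list[sc.StructuralCall] = []
    for target in inputs.assembly_a:
        target_records = [r for r in primary if r.target_id == target.id]
        projections = ap.project_to_target(target_records)
        gaps = sc.call_gaps(projections, target.id, len(target.seq), config.min_gap_bp)
        overlaps = sc.call_overlaps(projections)
        calls.extend(gaps)
        for overlap in overlaps:
            similarity = depth_1 = depth_2 = None
            q_left = by_record.get(overlap.left_query)
            q_right = by_record.get(overlap.right_query)
            if q_left is not None and q_right is not None and inputs.assembly_b:
                l0, l1 = _query_interval(q_left, overlap.start, overlap.end)
                r0, r1 = _query_interval(q_right, overlap.start, overlap.end)
                seqs = inputs.seqs_b
                similarity = copy_similarity(
                    seqs[overlap.left_query][l0:l1], seqs[overlap.right_query][r0:r1]
                )
                if inputs.consensus_depth_b is not None:
                    depth_1 = inputs.consensus_depth_b.mean_depth(overlap.left_query, l0, l1)
                    depth_2 = inputs.consensus_depth_b.mean_depth(overlap.right_query, r0, r1)
            overlap.similarity = similarity
            overlap.depth_a = depth_1
            overlap.depth_b = depth_2
            calls.append(overlap)
            verdict = sc.classify_redundancy(
                overlap, similarity, depth_1, depth_2, config.redundancy_criteria
            )
            if verdict == "redundancy":
                calls.append(
                    sc.StructuralCall(
                        overlap.target_id, overlap.start, overlap.end, "redundancy",
                        left_query=overlap.left_query, right_query=overlap.right_query,
                        similarity=similarity, depth_a=depth_1, depth_b=depth_2,
                    )
                )
        calls.extend(sc.call_loss_and_double_cover(gaps, projections))
    if inputs.self_alignments is not None:
        for call in calls:
            sc.annotate_repeat_context(call, inputs.self_alignments)
    gene_summary = sc.count_gene_gain_loss(calls, inputs.genes)
    by_kind_counts: dict[str, int] = {}
    by_kind_bp: dict[str, int] = {}
    for call in calls:
        by_kind_counts[call.call_kind] = by_kind_counts.get(call.call_kind, 0) + 1
        by_kind_bp[call.call_kind] = by_kind_bp.get(call.call_kind, 0) + call.length
    summary = {
        "n_calls": len(calls),
        "calls_by_kind": by_kind_counts,
        "bp_by_kind": by_kind_bp,
        "redundancy_genes": gene_summary["redundancy_genes"],
        "loss_genes": gene_summary["loss_genes"],
    }
    return summary, calls


def stage_errors(config: RunConfig, inputs: _Inputs) -> tuple[dict, list, list]:
    """Hard filtering, 1/1 selection, and the error characterisation battery."""
    passing = ea.apply_hard_filters(inputs.variants)
    errors = ea.select_assembly_errors(passing)
    assembly_len = sum(len(r.seq) for r in inputs.assembly_a)
    primary = ap.select_primary(inputs.alignments) if inputs.alignments else []
    reciprocal = ap.filter_reciprocal_matches(primary, config.min_reciprocal_bp)
    reciprocal_bp = sum(r.target_span for r in reciprocal)
    rate_assembly = ea.error_rate_per_kb(len(errors), assembly_len)
    rate_reciprocal = (
        ea.error_rate_per_kb(len(errors), reciprocal_bp) if reciprocal_bp else None
    )
    distances = ea.adjacent_distances(errors)
    clustering = ea.clustering_test(distances, rate_assembly)
    windows = ea.window_error_scan(
        errors,
        {r.id: len(r.seq) for r in inputs.assembly_a},
        window_bp=config.window_bp,
        step_bp=config.step_bp,
        min_count=config.enrichment_min_errors,
        sequences=inputs.seqs_a,
        methylation_sites=inputs.methylation,
    )
    contrasts = ea.contrast_enriched_windows(windows)
    if inputs.shotgun_depth is not None:
        depth_summary = ea.error_site_depth_summary(
            errors, inputs.shotgun_depth, config.depth_cutoff
        )
    else:
        depth_summary = {"skipped": True, "reason": "no shotgun depth track"}
    n_sub = sum(1 for e in errors if not e.is_indel)
    summary = {
        "n_variants": len(inputs.variants),
        "n_passing_filters": len(passing),
        "n_errors": len(errors),
        "n_substitutions": n_sub,
        "n_indels": len(errors) - n_sub,
        "indel_stats": ea.indel_length_stats(errors),
        "error_rate_per_kb_assembly": rate_assembly,
        "error_rate_per_kb_reciprocal": rate_reciprocal,
        "reciprocal_match_bp": reciprocal_bp,
        "clustering": dataclasses.asdict(clustering),
        "n_windows": len(windows),
        "n_enriched_windows": sum(1 for w in windows if w.enriched),
        "window_contrasts": contrasts,
        "depth_at_errors": depth_summary,
    }
    return summary, errors, windows


def stage_coding(config: RunConfig, inputs: _Inputs, errors: list) -> tuple[dict, list]:
    """Translation-impact classification of errors against gene models."""
    result = ci.count_affected(
        errors, inputs.genes, inputs.seqs_a, include_missense=config.include_missense
    )
    impacts = result.pop("impacts")
    result["n_classified"] = len(impacts)
    return result, impacts


def stage_features(config: RunConfig, inputs: _Inputs) -> tuple[dict, list[cf.FeatureHit], list[dict]]:
    """Telomere/centromere detection and per-contig T2T verdicts on assembly A."""
    hits: list[cf.FeatureHit] = []
    t2t: list[dict] = []
    for rec in inputs.assembly_a:
        telomeres = cf.find_telomere_arrays(
            rec.seq, motif=config.telomere_motif,
            min_units=config.telomere_min_units, contig=rec.id,
        )
        centromeres = cf.find_centromere(
            rec.seq, inputs.centromere_unit,
            min_identity=config.centromere_min_identity, contig=rec.id,
        )
        hits.extend(telomeres)
        hits.extend(centromeres)
        t2t.append(
            cf.assess_t2t(rec, telomeres, centromeres,
                          require_centromere=config.t2t_require_centromere)
        )
    summary = {
        "n_telomere_hits": sum(1 for h in hits if h.feature == "telomere"),
        "n_centromere_regions": sum(1 for h in hits if h.feature == "centromere"),
        "centromere_search": "skipped: no consensus" if inputs.centromere_unit is None else "done",
        "n_t2t_contigs": sum(1 for t in t2t if t["is_t2t"]),
        "n_contigs": len(t2t),
    }
    return summary, hits, t2t


# ---------------------------------------------------------------------------
# output writing
# ---------------------------------------------------------------------------


def _fmt(value: Any) -> str:
    if value is None:
        return "."
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def _write_tsv(path: Path, header: Sequence[str], rows: Sequence[Sequence[Any]]) -> int:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")
    return len(rows)


def run_compare(config: RunConfig, stages: Sequence[str] = ALL_STAGES) -> dict:
    """Run the requested stages and write artifacts + report under outdir."""
    config.validate(stages)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
    inputs = _load_inputs(config, stages)
    report: dict[str, Any] = {"stages": list(stages), "seed": config.seed}
    errors: list = []

    if "structural" in stages:
        logger.info("stage structural: %d alignments", len(inputs.alignments))
        summary, calls = stage_structural(config, inputs)
        n = _write_tsv(
            outdir / "structural_calls.tsv",
            ["contig", "start", "end", "call_kind", "left_query", "right_query",
             "similarity", "depth_a", "depth_b", "repeat_context"],
            [
                (c.target_id, c.start, c.end, c.call_kind, c.left_query, c.right_query,
                 c.similarity, c.depth_a, c.depth_b, c.repeat_context)
                for c in calls
            ],
        )
        assert n == summary["n_calls"]
        report["structural"] = summary
        logger.info("stage structural: %d calls", n)

    if "errors" in stages or "coding" in stages:
        logger.info("stage errors: %d variant records", len(inputs.variants))
        summary, errors, windows = stage_errors(config, inputs)
        if "errors" in stages:
            n = _write_tsv(
                outdir / "errors.tsv",
                ["contig", "pos", "error_kind", "length", "assembly_allele",
                 "evidence_allele"],
                [
                    (e.contig, e.pos, e.error_kind, e.length, e.assembly_allele,
                     e.evidence_allele)
                    for e in errors
                ],
            )
            assert n == summary["n_errors"]
            m = _write_tsv(
                outdir / "windows.tsv",
                ["contig", "start", "end", "error_count", "gc_fraction",
                 "methylation_level", "enriched", "truncated"],
                [
                    (w.contig, w.start, w.end, w.error_count, w.gc_fraction,
                     w.methylation_level, int(w.enriched), int(w.truncated))
                    for w in windows
                ],
            )
            assert m == summary["n_windows"]
            report["errors"] = summary
            logger.info("stage errors: %d errors, %d windows", n, m)

    if "coding" in stages:
        summary, impacts = stage_coding(config, inputs, errors)
        n = _write_tsv(
            outdir / "impacts.tsv",
            ["gene_id", "contig", "pos", "error_kind", "impact",
             "affected_exon_index", "splice_adjacent"],
            [
                (im.gene_id, im.error.contig, im.error.pos, im.error.error_kind,
                 im.impact, im.affected_exon_index, int(im.splice_adjacent))
                for im in impacts
            ],
        )
        assert n == summary["n_classified"]
        report["coding"] = summary
        logger.info("stage coding: %d classified error-gene pairs", n)

    if "features" in stages:
        summary, hits, t2t = stage_features(config, inputs)
        n = _write_tsv(
            outdir / "features.tsv",
            ["contig", "start", "end", "feature", "unit_count", "mean_identity",
             "contig_end", "orientation"],
            [
                (h.contig, h.start, h.end, h.feature, h.unit_count, h.mean_identity,
                 h.contig_end, h.orientation)
                for h in hits
            ],
        )
        assert n == summary["n_telomere_hits"] + summary["n_centromere_regions"]
        summary["per_contig"] = t2t
        report["features"] = summary
        logger.info("stage features: %d hits, %d/%d contigs T2T",
                    n, summary["n_t2t_contigs"], summary["n_contigs"])

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    with open(outdir / "report.txt", "w") as fh:
        fh.write(render_report(report))
    return report


def render_report(report: dict) -> str:
    """Human-readable summary of a comparison report."""
    lines = ["asmduet comparison report", "=" * 25, ""]
    if "structural" in report:
        s = report["structural"]
        lines.append("Structural comparison")
        for kind, count in sorted(s.get("calls_by_kind", {}).items()):
            bp = s.get("bp_by_kind", {}).get(kind, 0)
            lines.append(f"  {kind:14s} {count:6d} calls  {bp:>12,d} bp")
        lines.append(f"  genes in redundancies: {s['redundancy_genes']}")
        lines.append(f"  genes in losses:       {s['loss_genes']}")
        lines.append("")
    if "errors" in report:
        e = report["errors"]
        lines.append("Consensus errors")
        lines.append(f"  errors: {e['n_errors']} "
                     f"({e['n_substitutions']} substitutions, {e['n_indels']} InDels)")
        mean = e["indel_stats"]["mean_bp"]
        if mean is not None:
            lines.append(f"  mean InDel length: {mean:.2f} bp")
        lines.append(f"  rate (assembly denominator):   "
                     f"{e['error_rate_per_kb_assembly']:.3f} per kb")
        if e["error_rate_per_kb_reciprocal"] is not None:
            lines.append(f"  rate (reciprocal-match denom): "
                         f"{e['error_rate_per_kb_reciprocal']:.3f} per kb")
        lines.append(f"  clustering verdict: {e['clustering']['verdict']}")
        lines.append(f"  enriched windows: {e['n_enriched_windows']} / {e['n_windows']}")
        depth = e["depth_at_errors"]
        if not depth.get("skipped"):
            frac = depth["fraction_at_or_below"]
            if frac is not None:
                lines.append(
                    f"  errors at shotgun depth <= {depth['cutoff']}: {100 * frac:.1f}%"
                )
        lines.append("")
    if "coding" in report:
        c = report["coding"]
        lines.append("Coding impact")
        lines.append(f"  affected exons: {c['affected_exons']} "
                     f"(strict {c['affected_exons_strict']})")
        lines.append(f"  affected genes: {c['affected_genes']} "
                     f"(strict {c['affected_genes_strict']})")
        for impact, count in sorted(c.get("impact_counts", {}).items()):
            lines.append(f"    {impact:12s} {count}")
        lines.append("")
    if "features" in report:
        f = report["features"]
        lines.append("Chromosome features")
        lines.append(f"  telomere hits: {f['n_telomere_hits']}; "
                     f"centromere regions: {f['n_centromere_regions']}")
        lines.append(f"  T2T contigs: {f['n_t2t_contigs']} / {f['n_contigs']}")
        lines.append("")
    return "\n".join(lines)
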