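"""Gap, overlap, redundancy and loss calling between two assemblies.

Assembly B's contig projections onto assembly A define the structural
comparison: target intervals covered by no projection are uncovered gaps;
intervals claimed by two different query contigs are overlaps, which are
promoted to redundancies when the two candidate copies are near-identical
(similarity >= 97%) and their read depths betray a single true copy
(total depth < 60 with each copy < 40, at ~50x consensus-read coverage).
Gaps are further split into losses (no coverage at all) versus redundancies
(covered twice). Calls are annotated with repeat context from assembly-A
self-alignments, and genes overlapping redundancy/loss calls are tallied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .alignment_projection import ContigProjection, coverage_depth
from .formats_io import AlignmentRecord, GeneModel

DEFAULT_MIN_GAP_BP = 50


@dataclass
class RedundancyCriteria:
    """Thresholds for promoting an overlap to a redundancy call."""

    min_similarity: float = 0.97
    max_total_depth: float = 60.0
    max_each_depth: float = 40.0

    def __post_init__(self) -> None:
        if not 0.0 < self.min_similarity <= 1.0:
            raise ValueError("min_similarity must be in (0, 1]")
        if self.max_total_depth <= 0 or self.max_each_depth <= 0:
            raise ValueError("depth bounds must be > 0")


@dataclass
class StructuralCall:
    """A gap, overlap, redundancy or loss interval on assembly A."""

    target_id: str
    start: int
    end: int
    call_kind: str  # gap_uncovered | overlap | redundancy | loss
    left_query: str | None = None
    right_query: str | None = None
    similarity: float | None = None
    depth_a: float | None = None
    depth_b: float | None = None
    repeat_context: str = "unknown"  # tandem | dispersed | none | unknown

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError(f"call interval [{self.start}, {self.end}) is empty")
        if self.call_kind not in ("gap_uncovered", "overlap", "redundancy", "loss"):
            raise ValueError(f"bad call kind {self.call_kind!r}")
        if self.similarity is not None and not 0.0 <= self.similarity <= 1.0:
            raise ValueError("similarity outside [0, 1]")

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end

    @property
    def length(self) -> int:
        return self.end - self.start


def call_gaps(
    projections: Sequence[ContigProjection],
    target_id: str,
    target_len: int,
    min_gap_bp: int = DEFAULT_MIN_GAP_BP,
) -> list[StructuralCall]:
    """Maximal uncovered target intervals of at least ``min_gap_bp``.

    The complement of the union of all projected intervals, with the nearest
    covering query recorded on each side (one-sided for terminal gaps).
    Sub-threshold holes are suppressed as boundary jitter.
    """
    covered: list[tuple[int, int, str]] = []
    for proj in projections:
        if proj.target_id != target_id:
            continue
        for start, end in proj.intervals:
            covered.append((start, end, proj.query_id))
    covered.sort()
    calls: list[StructuralCall] = []

    def emit(start: int, end: int, left: str | None, right: str | None) -> None:
        if end - start >= min_gap_bp:
            calls.append(
                StructuralCall(target_id, start, end, "gap_uncovered",
                               left_query=left, right_query=right)
            )

    cursor = 0
    left_query: str | None = None
    for start, end, query in covered:
        if start > cursor:
            emit(cursor, start, left_query, query)
        if end > cursor:
            cursor = end
            left_query = query
    if cursor < target_len:
        emit(cursor, target_len, left_query, None)
    return calls


def call_overlaps(projections: Sequence[ContigProjection]) -> list[StructuralCall]:
    """Target intervals claimed by projections of two distinct query contigs.

    Each intersecting pair yields one call per intersection interval; three
    mutually overlapping queries yield three pairwise calls.
    """
    calls: list[StructuralCall] = []
    projs = list(projections)
    for i in range(len(projs)):
        for j in range(i + 1, len(projs)):
            a, b = projs[i], projs[j]
            if a.target_id != b.target_id or a.query_id == b.query_id:
                continue
            for s1, e1 in a.intervals:
                for s2, e2 in b.intervals:
                    start, end = max(s1, s2), min(e1, e2)
                    if end > start:
                        calls.append(
                            StructuralCall(
                                a.target_id, start, end, "overlap",
                                left_query=a.query_id, right_query=b.query_id,
                            )
                        )
    calls.sort(key=lambda c: (c.target_id, c.start, c.end))
    return calls


def classify_redundancy(
    candidate: StructuralCall,
    similarity: float | None,
    depth_a: float | None,
    depth_b: float | None,
    criteria: RedundancyCriteria | None = None,
) -> str:
    """Decide whether an overlap is a redundancy: ``redundancy``,
    ``not_redundancy`` or ``unknown``.

    A redundancy requires both copies near-identical (similarity >= 97% by
    default) and depth evidence that reads were split between two assembled
    copies of a single true locus: total depth below 60 with each copy below
    40. Missing similarity or depth never silently classifies as redundancy.
    """
    criteria = criteria or RedundancyCriteria()
    if candidate.call_kind != "overlap":
        raise ValueError("classify_redundancy expects an overlap call")
    if similarity is None or depth_a is None or depth_b is None:
        return "unknown"
    if (
        similarity >= criteria.min_similarity
        and depth_a + depth_b < criteria.max_total_depth
        and depth_a < criteria.max_each_depth
        and depth_b < criteria.max_each_depth
    ):
        return "redundancy"
    return "not_redundancy"


def call_loss_and_double_cover(
    gaps: Sequence[StructuralCall],
    projections: Sequence[ContigProjection],
) -> list[StructuralCall]:
    """Split gap intervals into losses and redundancies by projection coverage.

    Within each gap, maximal sub-intervals covered by zero projections become
    ``loss`` calls and sub-intervals covered by two or more become
    ``redundancy`` calls; single coverage is left uncalled. The projections
    passed here may be a wider set than the one that defined the gaps (e.g.
    including short contigs excluded from primary gap calling).
    """
    calls: list[StructuralCall] = []
    by_target: dict[str, list[ContigProjection]] = {}
    for proj in projections:
        by_target.setdefault(proj.target_id, []).append(proj)
    depth_cache: dict[str, list[tuple[int, int, int]]] = {}
    for gap in gaps:
        if gap.call_kind != "gap_uncovered":
            raise ValueError("call_loss_and_double_cover expects gap_uncovered calls")
        if gap.target_id not in depth_cache:
            projs = by_target.get(gap.target_id, [])
            target_len = max(
                [gap.end] + [e for p in projs for _, e in p.intervals]
            )
            depth_cache[gap.target_id] = coverage_depth(projs, gap.target_id, target_len)
        for run_start, run_end, depth in depth_cache[gap.target_id]:
            start, end = max(run_start, gap.start), min(run_end, gap.end)
            if end <= start:
                continue
            kind = "loss" if depth == 0 else ("redundancy" if depth >= 2 else None)
            if kind is not None:
                calls.append(
                    StructuralCall(
                        gap.target_id, start, end, kind,
                        left_query=gap.left_query, right_query=gap.right_query,
                    )
                )
    # coalesce adjacent same-kind calls within a gap
    merged: list[StructuralCall] = []
    for call in calls:
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and prev.target_id == call.target_id
            and prev.call_kind == call.call_kind
            and prev.end == call.start
        ):
            prev.end = call.end
        else:
            merged.append(call)
    return merged


def annotate_repeat_context(
    call: StructuralCall,
    self_alignments: Sequence[AlignmentRecord] | None,
    tandem_max_dist_bp: int = 100_000,
    min_dispersed_identity: float = 0.95,
    flank_bp: int = 5_000,
) -> StructuralCall:
    """Label a call tandem / dispersed / none from assembly-A self-alignments.

    ``tandem``: a non-identity self-alignment on the call's own contig pairs
    sequence at the call (or its immediate flanks) with a second copy within
    ``tandem_max_dist_bp``. ``dispersed``: the call's interval matches at
    >= ``min_dispersed_identity`` on a different contig or farther away than
    ``tandem_max_dist_bp``. ``none`` when self-alignments exist but show
    neither; ``unknown`` when none were provided.
    """
    if self_alignments is None:
        call.repeat_context = "unknown"
        return call
    window = (call.start - flank_bp, call.end + flank_bp)
    context = "none"
    for rec in self_alignments:
        same_query = rec.query_id == call.target_id
        same_target = rec.target_id == call.target_id
        if same_query and same_target:
            if rec.query_start == rec.target_start and rec.query_end == rec.target_end:
                continue  # identity alignment
            q_hits = rec.query_start < window[1] and rec.query_end > window[0]
            t_hits = rec.target_start < window[1] and rec.target_end > window[0]
            if q_hits or t_hits:
                other = (rec.target_start, rec.target_end) if q_hits else (rec.query_start, rec.query_end)
                dist = max(0, max(call.start - other[1], other[0] - call.end))
                if dist <= tandem_max_dist_bp:
                    context = "tandem"
                    break
                if rec.identity >= min_dispersed_identity:
                    context = "dispersed"
        elif same_query or same_target:
            span = (
                (rec.query_start, rec.query_end) if same_query
                else (rec.target_start, rec.target_end)
            )
            if (
                span[0] < call.end and span[1] > call.start
                and rec.identity >= min_dispersed_identity
            ):
                context = "dispersed"
    call.repeat_context = context
    return call


def count_gene_gain_loss(
    calls: Sequence[StructuralCall],
    gene_models: Sequence[GeneModel],
    whole_gene: bool = False,
) -> dict:
    """Count genes gained through redundancies and lost through losses.

    A gene counts toward a call when at least 1 bp of its CDS overlaps the
    call interval (or, with ``whole_gene``, when the whole CDS span is
    contained). Each gene is counted once per call kind, deduplicated across
    calls of that kind.
    """
    trees: dict[str, IntervalTree] = {}
    for idx, gene in enumerate(gene_models):
        tree = trees.setdefault(gene.contig, IntervalTree())
        for s, e in gene.cds_intervals:
            tree[s:e] = idx
    genes_by_kind: dict[str, set[str]] = {"redundancy": set(), "loss": set()}
    per_call: list[dict] = []
    for call in calls:
        hit_ids: set[str] = set()
        tree = trees.get(call.target_id)
        if tree is not None:
            hit_idx = {iv.data for iv in tree.overlap(call.start, call.end)}
            for idx in hit_idx:
                gene = gene_models[idx]
                if whole_gene:
                    span = gene.span
                    if not (call.start <= span[0] and span[1] <= call.end):
                        continue
                hit_ids.add(gene.gene_id)
        per_call.append(
            {
                "target_id": call.target_id,
                "start": call.start,
                "end": call.end,
                "call_kind": call.call_kind,
                "genes": sorted(hit_ids),
            }
        )
        if call.call_kind in genes_by_kind:
            genes_by_kind[call.call_kind] |= hit_ids
    return {
        "redundancy_genes": len(genes_by_kind["redundancy"]),
        "loss_genes": len(genes_by_kind["loss"]),
        "redundancy_gene_ids": sorted(genes_by_kind["redundancy"]),
        "loss_gene_ids": sorted(genes_by_kind["loss"]),
        "per_call": per_call,
    }
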