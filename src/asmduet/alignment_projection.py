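"""Selection, filtering and target-projection of assembly-to-assembly alignments.

The comparison of two assemblies starts from whole-genome alignments of the
fragmented assembly (B, the query) onto the contiguous one (A, the target).
This module keeps one primary alignment per query contig, restricts the
comparison to long reciprocal matches, projects the retained blocks onto
target coordinates, and recovers per-base differences from cg-style
difference strings — binning them into small-scale mismatches (SNVs, small
InDels) versus local mismatches longer than 85 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .formats_io import AlignmentRecord, parse_cigar

LOCAL_MISMATCH_THRESHOLD_BP = 85


@dataclass
class ContigProjection:
    """Target-coordinate footprint of one query contig's retained alignments."""

    query_id: str
    target_id: str
    intervals: list[tuple[int, int]]
    identities: list[float]

    def __post_init__(self) -> None:
        if len(self.intervals) != len(self.identities):
            raise ValueError("one identity per interval required")
        for (s, e), ident in zip(self.intervals, self.identities):
            if e <= s:
                raise ValueError(f"empty projected interval [{s}, {e})")
            if not 0.0 <= ident <= 1.0:
                raise ValueError(f"identity {ident} outside [0, 1]")
        if any(
            self.intervals[i][1] > self.intervals[i + 1][0]
            for i in range(len(self.intervals) - 1)
        ):
            raise ValueError("projected intervals overlap or are unsorted")

    @property
    def covered_bp(self) -> int:
        return sum(e - s for s, e in self.intervals)


@dataclass
class Mismatch:
    """One non-match run between the assemblies, on target coordinates."""

    target_pos: int
    kind: str  # substitution | insertion | deletion
    length: int
    category: str = field(init=False)
    local_threshold_bp: int = LOCAL_MISMATCH_THRESHOLD_BP

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("mismatch length must be >= 1")
        if self.kind not in ("substitution", "insertion", "deletion"):
            raise ValueError(f"bad mismatch kind {self.kind!r}")
        self.category = "local" if self.length > self.local_threshold_bp else "small_scale"


@dataclass
class MismatchScan:
    """Mismatches from one alignment, plus whether substitutions were recoverable.

    Plain ``M`` runs do not encode substitutions; when an alignment carries
    only M/I/D ops, ``substitutions_available`` is False and the scan holds
    insertions/deletions only.
    """

    mismatches: list[Mismatch]
    substitutions_available: bool


def select_primary(records: Iterable[AlignmentRecord]) -> list[AlignmentRecord]:
    """Keep the primary hit for each query contig.

    Alignments flagged primary are retained as-is. For a query with no
    flagged alignment, the single best hit is kept instead: largest
    block_len, ties broken by larger n_matches, then lowest target_start.
    """
    by_query: dict[str, list[AlignmentRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.query_id not in by_query:
            order.append(rec.query_id)
        by_query.setdefault(rec.query_id, []).append(rec)
    kept: list[AlignmentRecord] = []
    for query_id in order:
        hits = by_query[query_id]
        primary = [r for r in hits if r.is_primary]
        if primary:
            kept.extend(primary)
        else:
            kept.append(
                min(hits, key=lambda r: (-r.block_len, -r.n_matches, r.target_start))
            )
    return kept


def filter_reciprocal_matches(
    records: Iterable[AlignmentRecord], min_len_bp: int = 1_000_000
) -> list[AlignmentRecord]:
    """Keep alignments whose query span AND target span are each >= min_len_bp.

    This is the reciprocal-match restriction applied before mismatch
    counting: only blocks at least 1 Mb long on both assemblies enter the
    comparison by default.
    """
    if min_len_bp < 0:
        raise ValueError("min_len_bp must be >= 0")
    return [
        r for r in records
        if r.query_span >= min_len_bp and r.target_span >= min_len_bp
    ]


def _merge_intervals(
    spans: Sequence[tuple[int, int, int, int]], merge_gap_bp: int
) -> tuple[list[tuple[int, int]], list[float]]:
    """Merge (start, end, n_matches, block_len) spans closer than merge_gap_bp."""
    merged: list[list[int]] = []  # [start, end, n_matches, block_len]
    for start, end, nm, bl in sorted(spans):
        if merged and start <= merged[-1][1] + merge_gap_bp:
            merged[-1][1] = max(merged[-1][1], end)
            merged[-1][2] += nm
            merged[-1][3] += bl
        else:
            merged.append([start, end, nm, bl])
    intervals = [(s, e) for s, e, _, _ in merged]
    identities = [nm / bl if bl else 0.0 for _, _, nm, bl in merged]
    return intervals, identities


def project_to_target(
    records: Iterable[AlignmentRecord], merge_gap_bp: int = 0
) -> list[ContigProjection]:
    """Project each query's retained alignments onto merged target intervals.

    Adjacent or overlapping target spans from the same query are merged
    (strict adjacency by default; ``merge_gap_bp`` widens the tolerance).
    Minus-strand alignments contribute their target span unchanged — the
    projection lives entirely in target coordinates. A query aligned to more
    than one target contig is an error at this stage: projection groups are
    per (query, target).
    """
    by_query: dict[str, list[AlignmentRecord]] = {}
    order: list[str] = []
    for rec in records:
        if rec.query_id not in by_query:
            order.append(rec.query_id)
        by_query.setdefault(rec.query_id, []).append(rec)
    projections: list[ContigProjection] = []
    for query_id in order:
        hits = by_query[query_id]
        targets = {r.target_id for r in hits}
        if len(targets) > 1:
            raise ValueError(
                f"query {query_id!r} aligns to multiple targets {sorted(targets)}; "
                "split projection groups per target first"
            )
        spans = [(r.target_start, r.target_end, r.n_matches, r.block_len) for r in hits]
        intervals, identities = _merge_intervals(spans, merge_gap_bp)
        projections.append(
            ContigProjection(
                query_id=query_id,
                target_id=hits[0].target_id,
                intervals=intervals,
                identities=identities,
            )
        )
    return projections


def coverage_depth(
    projections: Iterable[ContigProjection], target_id: str, target_len: int
) -> list[tuple[int, int, int]]:
    """Stepwise count of projecting queries per target position.

    Returns maximal runs (start, end, depth) tiling [0, target_len) exactly.
    """
    events: list[tuple[int, int]] = []
    for proj in projections:
        if proj.target_id != target_id:
            continue
        for start, end in proj.intervals:
            if not 0 <= start < end <= target_len:
                raise ValueError(
                    f"projected interval [{start}, {end}) outside target of length {target_len}"
                )
            events.append((start, +1))
            events.append((end, -1))
    if not events:
        return [(0, target_len, 0)] if target_len > 0 else []
    events.sort()
    runs: list[tuple[int, int, int]] = []
    depth = 0
    prev = 0
    i = 0
    while i < len(events):
        pos = events[i][0]
        if pos > prev:
            runs.append((prev, pos, depth))
        while i < len(events) and events[i][0] == pos:
            depth += events[i][1]
            i += 1
        prev = pos
    if prev < target_len:
        runs.append((prev, target_len, depth))
    # coalesce equal-depth neighbours
    out: list[tuple[int, int, int]] = []
    for run in runs:
        if out and out[-1][2] == run[2] and out[-1][1] == run[0]:
            out[-1] = (out[-1][0], run[1], run[2])
        else:
            out.append(run)
    return out


def extract_mismatches(
    record: AlignmentRecord, local_threshold_bp: int = LOCAL_MISMATCH_THRESHOLD_BP
) -> MismatchScan:
    """Recover per-base differences from an alignment's difference string.

    Emits one Mismatch per non-match run with its target coordinate:
    ``X`` runs become substitutions, ``I`` runs (query-only bases) become
    insertions anchored at the target position where they occur, ``D``/``N``
    runs become deletions. Runs longer than ``local_threshold_bp`` are
    categorised ``local``, the rest ``small_scale``. When the string uses
    plain ``M`` (match-or-mismatch) runs, substitutions cannot be recovered
    and the scan says so.
    """
    if record.cigar is None:
        raise ValueError("alignment has no difference string")
    runs = parse_cigar(record.cigar)
    substitutions_available = all(op != "M" for _, op in runs)
    mismatches: list[Mismatch] = []
    tpos = record.target_start
    for length, op in runs:
        if op in "M=":
            tpos += length
        elif op == "X":
            mismatches.append(
                Mismatch(target_pos=tpos, kind="substitution", length=length,
                         local_threshold_bp=local_threshold_bp)
            )
            tpos += length
        elif op == "I":
            mismatches.append(
                Mismatch(target_pos=tpos, kind="insertion", length=length,
                         local_threshold_bp=local_threshold_bp)
            )
        elif op in "DN":
            mismatches.append(
                Mismatch(target_pos=tpos, kind="deletion", length=length,
                         local_threshold_bp=local_threshold_bp)
            )
            tpos += length
        else:
            raise ValueError(f"unsupported cigar op {op!r}")
    return MismatchScan(mismatches=mismatches, substitutions_available=substitutions_available)
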