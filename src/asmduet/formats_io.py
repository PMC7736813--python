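"""Readers and writers for the external formats the pipeline consumes.

Every coordinate is normalised to a single internal convention: 0-based,
half-open, on the forward strand of the sequence it refers to. The only
places 1-based closed coordinates survive are the GFF3/VCF boundaries,
where they are converted on the way in.

Formats handled: multi-record FASTA, PAF (with optional ``cg:Z`` difference
strings and ``tp:A`` primary/secondary tags), single-sample VCF v4.x, GFF3
with gene/mRNA/CDS features, a 4-column methylation TSV (contig, position,
called_sites, methylated_frequency) and a 4-column BED-like depth TSV
(contig, start, end, depth).
"""

from __future__ import annotations

import logging
import re
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

VALID_BASES = set("ACGTN")
ANNOTATION_KEYS = ("QD", "FS", "SOR", "MQ", "MQRankSum", "ReadPosRankSum")

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SequenceRecord:
    """A named nucleotide sequence over the alphabet {A, C, G, T, N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AlignmentRecord:
    """One pairwise alignment block between a query contig and a target contig.

    Coordinates are 0-based half-open on both sides, as in PAF. ``cigar``,
    when present, is the ``cg:Z`` difference string (ops over M/I/D/=/X,
    query-vs-target orientation).
    """

    query_id: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_id: str
    target_len: int
    target_start: int
    target_end: int
    n_matches: int
    block_len: int
    mapq: int = 60
    is_primary: bool = True
    cigar: str | None = None

    def __post_init__(self) -> None:
        for name, start, end, length in (
            ("query", self.query_start, self.query_end, self.query_len),
            ("target", self.target_start, self.target_end, self.target_len),
        ):
            if not (0 <= start < end <= length):
                raise ValueError(
                    f"{name} span [{start}, {end}) out of bounds for length {length} "
                    f"({self.query_id} -> {self.target_id})"
                )
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.n_matches > self.block_len:
            raise ValueError("n_matches exceeds block_len")
        if self.cigar is not None:
            q, t = cigar_consumed(self.cigar)
            if q != self.query_end - self.query_start:
                raise ValueError(
                    f"cigar consumes {q} query bp but query span is "
                    f"{self.query_end - self.query_start}"
                )
            if t != self.target_end - self.target_start:
                raise ValueError(
                    f"cigar consumes {t} target bp but target span is "
                    f"{self.target_end - self.target_start}"
                )

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start

    @property
    def identity(self) -> float:
        return self.n_matches / self.block_len if self.block_len else 0.0


@dataclass
class VariantRecord:
    """One bi-allelic variant call against an assembly (multi-allelics are split).

    ``pos`` keeps the 1-based convention of the source VCF; downstream code
    converts when it builds 0-based error objects. ``site_annotations`` holds
    whichever of QD/FS/SOR/MQ/MQRankSum/ReadPosRankSum the caller emitted;
    a missing key means "annotation unavailable", never zero.
    """

    contig: str
    pos: int
    ref_allele: str
    alt_allele: str
    genotype: str  # "0/0", "0/1", "1/1" or "missing"
    site_annotations: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for allele in (self.ref_allele, self.alt_allele):
            if not allele or set(allele) - set("ACGT"):
                raise ValueError(f"bad allele {allele!r} at {self.contig}:{self.pos}")

    @property
    def variant_class(self) -> str:
        if len(self.ref_allele) == len(self.alt_allele):
            return "substitution"
        return "insertion" if len(self.alt_allele) > len(self.ref_allele) else "deletion"

    @property
    def is_indel(self) -> bool:
        return self.variant_class != "substitution"


@dataclass
class GeneModel:
    """One mRNA's coding structure: ordered, genomic-order CDS intervals.

    Intervals are 0-based half-open, sorted ascending regardless of strand;
    ``strand`` records transcription direction. ``frame_complete`` flags
    whether the total CDS length is a multiple of three (it is recorded, not
    required).
    """

    gene_id: str
    contig: str
    strand: str
    cds_intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        ivs = self.cds_intervals
        if not ivs or any(e <= s for s, e in ivs):
            raise ValueError(f"gene {self.gene_id}: empty or inverted CDS interval")
        if any(ivs[i][1] > ivs[i + 1][0] for i in range(len(ivs) - 1)):
            raise ValueError(f"gene {self.gene_id}: CDS intervals overlap or are unsorted")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    @property
    def frame_complete(self) -> bool:
        return self.cds_length % 3 == 0

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]


@dataclass
class MethylationSite:
    """One called methylation site (0-based position, per-site read support)."""

    contig: str
    pos: int
    called_sites: int
    methylated_fraction: float

    def __post_init__(self) -> None:
        if self.called_sites < 0:
            raise ValueError("called_sites must be >= 0")
        if not 0.0 <= self.methylated_fraction <= 1.0:
            raise ValueError(
                f"methylated fraction {self.methylated_fraction} outside [0, 1] "
                f"at {self.contig}:{self.pos}"
            )


class DepthTrack:
    """Interval-valued integer read depth per contig, with explicit missingness.

    Backed by sorted, non-overlapping (start, end, depth) runs; positions not
    covered by any run query as ``None``.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int, int]] = ()):
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        by_contig: dict[str, list[tuple[int, int, int]]] = {}
        for contig, start, end, depth in intervals:
            if depth < 0:
                raise ValueError(f"negative depth at {contig}:{start}-{end}")
            if end <= start:
                raise ValueError(f"empty depth interval {contig}:{start}-{end}")
            by_contig.setdefault(contig, []).append((start, end, depth))
        for contig, runs in by_contig.items():
            runs.sort()
            for (s0, e0, _), (s1, _, _) in zip(runs, runs[1:]):
                if s1 < e0:
                    raise ValueError(f"overlapping depth intervals on {contig}")
            starts, ends, depths = (np.array(col, dtype=np.int64) for col in zip(*runs))
            self._runs[contig] = (starts, ends, depths)

    @property
    def contigs(self) -> list[str]:
        return sorted(self._runs)

    def depth_at(self, contig: str, pos: int) -> int | None:
        runs = self._runs.get(contig)
        if runs is None:
            return None
        starts, ends, depths = runs
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return int(depths[i])
        return None

    def mean_depth(self, contig: str, start: int, end: int) -> float | None:
        """Mean depth over [start, end); None if nothing in the span is covered.

        Uncovered sub-spans are excluded from the mean (explicitly partial
        coverage rather than an implicit zero).
        """
        runs = self._runs.get(contig)
        if runs is None or end <= start:
            return None
        starts, ends, depths = runs
        lo = max(0, int(np.searchsorted(ends, start, side="right")))
        total = 0.0
        covered = 0
        for i in range(lo, len(starts)):
            if starts[i] >= end:
                break
            s = max(start, int(starts[i]))
            e = min(end, int(ends[i]))
            if e > s:
                total += float(depths[i]) * (e - s)
                covered += e - s
        if covered == 0:
            return None
        return total / covered


# ---------------------------------------------------------------------------
# CIGAR helpers
# ---------------------------------------------------------------------------


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Split a cg-style difference string into (length, op) runs."""
    runs = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if "".join(f"{n}{op}" for n, op in runs) != cigar:
        raise ValueError(f"malformed cigar {cigar!r}")
    if any(n <= 0 for n, _ in runs):
        raise ValueError(f"zero-length cigar run in {cigar!r}")
    return runs


def cigar_consumed(cigar: str) -> tuple[int, int]:
    """Return (query bp, target bp) consumed by a difference string."""
    q = t = 0
    for n, op in parse_cigar(cigar):
        if op in "M=X":
            q += n
            t += n
        elif op == "I":
            q += n
        elif op in "DN":
            t += n
        else:
            raise ValueError(f"unsupported cigar op {op!r}")
    return q, t


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA; sequences are uppercased and validated."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(f"invalid characters {sorted(bad)} in FASTA record {rec.id!r}")
        records.append(SequenceRecord(rec.id, seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 80) -> None:
    bio = (_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# PAF
# ---------------------------------------------------------------------------


def read_paf(path: str | Path) -> list[AlignmentRecord]:
    """Read a PAF file into AlignmentRecords.

    The twelve mandatory columns are required; ``cg:Z`` (difference string)
    and ``tp:A`` (P/S → primary flag) tags are honoured when present. A line
    without a ``tp`` tag is treated as primary.
    """
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(f"{path}:{lineno}: expected >=12 PAF columns, got {len(cols)}")
            try:
                qlen, qs, qe = int(cols[1]), int(cols[2]), int(cols[3])
                tlen, ts, te = int(cols[6]), int(cols[7]), int(cols[8])
                nmatch, blen, mapq = int(cols[9]), int(cols[10]), int(cols[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer mandatory column ({exc})") from None
            cigar = None
            is_primary = True
            for tag in cols[12:]:
                if tag.startswith("cg:Z:"):
                    cigar = tag[5:]
                elif tag.startswith("tp:A:"):
                    is_primary = tag[5:] == "P"
            try:
                records.append(
                    AlignmentRecord(
                        query_id=cols[0], query_len=qlen, query_start=qs, query_end=qe,
                        strand=cols[4],
                        target_id=cols[5], target_len=tlen, target_start=ts, target_end=te,
                        n_matches=nmatch, block_len=blen, mapq=mapq,
                        is_primary=is_primary, cigar=cigar,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return records


def write_paf(records: Iterable[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            cols = [
                r.query_id, r.query_len, r.query_start, r.query_end, r.strand,
                r.target_id, r.target_len, r.target_start, r.target_end,
                r.n_matches, r.block_len, r.mapq,
                f"tp:A:{'P' if r.is_primary else 'S'}",
            ]
            if r.cigar is not None:
                cols.append(f"cg:Z:{r.cigar}")
            fh.write("\t".join(str(c) for c in cols) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _split_genotype(gt: tuple[int | None, ...] | None, alt_index: int) -> str:
    """Per-allele genotype after splitting a multi-allelic line."""
    if gt is None or all(a is None for a in gt):
        return "missing"
    alleles = [a for a in gt if a is not None]
    n_alt = sum(1 for a in alleles if a == alt_index)
    if n_alt == len(alleles) and n_alt > 0:
        return "1/1"
    if n_alt > 0:
        return "0/1"
    return "0/0"


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a single-sample VCF into VariantRecords.

    Multi-allelic lines are split into one record per alternate allele, each
    inheriting its per-allele genotype. Symbolic alternates (``<...>``) and
    spanning-deletion placeholders (``*``) are dropped with a counter.
    Annotations absent from INFO are stored as absent, never as zero.
    """
    records: list[VariantRecord] = []
    n_symbolic = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            annotations: dict[str, float] = {}
            for key in ANNOTATION_KEYS:
                if key in rec.info:
                    value = rec.info[key]
                    if isinstance(value, tuple):
                        value = value[0]
                    if value is not None:
                        annotations[key] = float(value)
            gt = rec.samples[samples[0]].get("GT") if samples else None
            for alt_index, alt in enumerate(rec.alts or (), start=1):
                if alt is None or alt.startswith("<") or alt == "*":
                    n_symbolic += 1
                    continue
                records.append(
                    VariantRecord(
                        contig=rec.chrom,
                        pos=rec.pos,
                        ref_allele=rec.ref.upper(),
                        alt_allele=alt.upper(),
                        genotype=_split_genotype(gt, alt_index),
                        site_annotations=dict(annotations),
                    )
                )
    if n_symbolic:
        logger.warning("dropped %d symbolic/star alternate alleles from %s", n_symbolic, path)
    return records


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from a GFF3 file, one GeneModel per mRNA.

    CDS intervals are converted from 1-based closed to 0-based half-open and
    kept in genomic order; minus-strand models record their strand instead of
    being flipped. CDS features without a resolvable mRNA parent are skipped
    with a logged count.
    """
    import gffutils
    from gffutils.exceptions import EmptyInputError

    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except EmptyInputError:
        return []
    models: list[GeneModel] = []
    n_orphan = 0
    mrna_ids = {f.id for f in db.features_of_type("mRNA")}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [])
        if not any(p in mrna_ids for p in parents):
            n_orphan += 1
    for mrna in db.features_of_type("mRNA"):
        intervals = sorted(
            (cds.start - 1, cds.end) for cds in db.children(mrna, featuretype="CDS")
        )
        if not intervals:
            continue
        models.append(
            GeneModel(
                gene_id=mrna.id,
                contig=mrna.seqid,
                strand=mrna.strand,
                cds_intervals=intervals,
            )
        )
    if n_orphan:
        logger.warning("skipped %d CDS features without an mRNA parent in %s", n_orphan, path)
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path, source: str = "asmduet") -> None:
    """Write gene models as gene/mRNA/CDS features (inverse of read_gff3)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            start, end = m.span
            gid = f"gene:{m.gene_id}"
            fh.write(
                f"{m.contig}\t{source}\tgene\t{start + 1}\t{end}\t.\t{m.strand}\t.\tID={gid}\n"
            )
            fh.write(
                f"{m.contig}\t{source}\tmRNA\t{start + 1}\t{end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id};Parent={gid}\n"
            )
            for s, e in m.cds_intervals:
                fh.write(
                    f"{m.contig}\t{source}\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t0\t"
                    f"ID=cds:{m.gene_id};Parent={m.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# Methylation and depth tables
# ---------------------------------------------------------------------------

METHYLATION_COLUMNS = ["contig", "position", "called_sites", "methylated_frequency"]


def read_methylation_table(path: str | Path, min_called_sites: int = 10) -> list[MethylationSite]:
    """Read a per-site methylation TSV, dropping weakly supported sites.

    Rows with ``called_sites`` below ``min_called_sites`` are excluded
    (the support filter applied to nanopore methylation calls).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in METHYLATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing methylation columns {missing}")
    sites = []
    for row in df.itertuples(index=False):
        if row.called_sites < min_called_sites:
            continue
        sites.append(
            MethylationSite(
                contig=str(row.contig),
                pos=int(row.position),
                called_sites=int(row.called_sites),
                methylated_fraction=float(row.methylated_frequency),
            )
        )
    return sites


def write_methylation_table(sites: Iterable[MethylationSite], path: str | Path) -> None:
    df = pd.DataFrame(
        [(s.contig, s.pos, s.called_sites, s.methylated_fraction) for s in sites],
        columns=METHYLATION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_depth_track(path: str | Path) -> DepthTrack:
    """Read a 4-column BED-like TSV (contig, start, end, depth) into a DepthTrack."""
    df = pd.read_csv(path, sep="\t", header=None, names=["contig", "start", "end", "depth"],
                     comment="#")
    return DepthTrack(
        (str(r.contig), int(r.start), int(r.end), int(r.depth))
        for r in df.itertuples(index=False)
    )


def write_depth_track(intervals: Iterable[tuple[str, int, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for contig, start, end, depth in intervals:
            fh.write(f"{contig}\t{start}\t{end}\t{depth}\n")
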