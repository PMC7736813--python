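"""Translation impact of assembly errors on annotated coding sequence.

Each error overlapping a gene's CDS is applied in genomic coordinates and
the coding sequence rebuilt on both versions: ``protein_before`` comes from
the error-bearing assembly, ``protein_after`` from the corrected sequence
(evidence allele applied). A frame-breaking InDel (length not divisible by
three inside CDS) is a frameshift regardless of downstream sequence; a
substitution creating a premature stop is a stop gain, one destroying the
annotated stop a stop loss; remaining amino-acid changes are missense and
silent changes synonymous. Errors outside CDS are noncoding, with a flag
for intronic errors within 2 bp of a splice junction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq
from intervaltree import IntervalTree

from .error_analysis import AssemblyError
from .formats_io import GeneModel

DISRUPTIVE = ("frameshift", "stop_gain", "stop_loss")
AFFECTING = DISRUPTIVE + ("missense",)

SPLICE_WINDOW_BP = 2


@dataclass
class TranslationResult:
    protein: str  # truncated at first stop
    first_stop_codon: int | None  # codon index of first stop, None if none
    has_terminal_stop: bool
    has_internal_stop: bool
    partial_codon: bool


@dataclass
class TranslationImpact:
    gene_id: str
    error: AssemblyError
    impact: str  # frameshift | stop_gain | stop_loss | missense | synonymous | noncoding
    affected_exon_index: int | None
    protein_before: str
    protein_after: str
    splice_adjacent: bool = False


def build_cds(gene: GeneModel, contig_seq: str) -> str:
    """Concatenate a gene's CDS exons; minus-strand genes are
    reverse-complemented as one unit after splicing in genomic order."""
    if gene.cds_intervals[-1][1] > len(contig_seq):
        raise ValueError(
            f"gene {gene.gene_id} CDS extends past contig end "
            f"({gene.cds_intervals[-1][1]} > {len(contig_seq)})"
        )
    spliced = "".join(contig_seq[s:e] for s, e in gene.cds_intervals)
    if gene.strand == "-":
        return str(Seq(spliced).reverse_complement())
    return spliced


def translate(cds: str) -> TranslationResult:
    """Standard-code translation, truncated at the first stop codon."""
    if len(cds) < 3:
        raise ValueError("coding sequence shorter than one codon")
    n_codons = len(cds) // 3
    full = str(Seq(cds[: n_codons * 3]).translate())
    stop = full.find("*")
    if stop == -1:
        protein, first_stop = full, None
    else:
        protein, first_stop = full[:stop], stop
    return TranslationResult(
        protein=protein,
        first_stop_codon=first_stop,
        has_terminal_stop=stop == n_codons - 1,
        has_internal_stop=0 <= stop < n_codons - 1,
        partial_codon=len(cds) % 3 != 0,
    )


def _shift_coord(c: int, pos: int, len_ref: int, len_alt: int) -> int:
    """Map a coordinate through the edit replacing [pos, pos+len_ref) by len_alt bases.

    Coordinates at or before the anchor are unchanged; coordinates past the
    replaced span shift by the length delta; the rare endpoint inside the
    span is clamped to the replacement.
    """
    if c <= pos:
        return c
    if c >= pos + len_ref:
        return c + (len_alt - len_ref)
    return min(c, pos + len_alt)


def _edited(contig_seq: str, error: AssemblyError) -> tuple[str, int, int]:
    """Apply the evidence allele; returns (edited sequence, len_ref, len_alt)."""
    pos = error.pos
    ref, alt = error.assembly_allele, error.evidence_allele
    if contig_seq[pos : pos + len(ref)] != ref:
        raise ValueError(
            f"assembly allele {ref!r} absent at {error.contig}:{pos} "
            f"(found {contig_seq[pos:pos + len(ref)]!r}) — coordinate mismatch"
        )
    return contig_seq[:pos] + alt + contig_seq[pos + len(ref):], len(ref), len(alt)


def _changed_region(error: AssemblyError) -> tuple[int, int]:
    """Genomic half-open span whose bases actually change under the edit.

    For anchored InDels the shared anchor base is excluded: a deletion of k
    bases changes [pos+1, pos+1+k), an insertion changes the single junction
    point after the anchor.
    """
    if error.error_kind == "substitution":
        return error.pos, error.pos + len(error.assembly_allele)
    longer = max(len(error.assembly_allele), len(error.evidence_allele))
    if len(error.assembly_allele) > len(error.evidence_allele):
        return error.pos + 1, error.pos + longer  # bases present only in assembly
    return error.pos + 1, error.pos + 1  # insertion point (empty span)


def _in_cds(gene: GeneModel, error: AssemblyError) -> int | None:
    """Index of the CDS interval the error changes, or None if noncoding."""
    lo, hi = _changed_region(error)
    for idx, (s, e) in enumerate(gene.cds_intervals):
        if lo == hi:  # insertion after the anchor: coding iff the anchor base is exonic
            if s <= error.pos < e:
                return idx
        elif lo < e and hi > s:
            return idx
    return None


def _splice_adjacent(gene: GeneModel, error: AssemblyError) -> bool:
    lo, hi = _changed_region(error)
    probe = (lo, max(hi, lo + 1))
    for s, e in gene.cds_intervals:
        for junction in (s, e):
            if probe[0] < junction + SPLICE_WINDOW_BP and probe[1] > junction - SPLICE_WINDOW_BP:
                span = gene.span
                if span[0] <= lo <= span[1]:
                    return True
    return False


def classify_error_impact(
    error: AssemblyError, gene: GeneModel, contig_seq: str
) -> TranslationImpact:
    """Classify one error's effect on one gene's translation.

    Raises ValueError when the assembly allele does not match the contig at
    the error position (a coordinate-frame mismatch, never ignorable).
    """
    if error.pos >= len(contig_seq):
        raise ValueError(f"error position {error.pos} beyond contig end")
    edited_seq, len_ref, len_alt = _edited(contig_seq, error)
    exon_index = _in_cds(gene, error)
    if exon_index is None:
        return TranslationImpact(
            gene_id=gene.gene_id,
            error=error,
            impact="noncoding",
            affected_exon_index=None,
            protein_before="",
            protein_after="",
            splice_adjacent=_splice_adjacent(gene, error),
        )
    cds_before = build_cds(gene, contig_seq)
    shifted = [
        (
            _shift_coord(s, error.pos, len_ref, len_alt),
            _shift_coord(e, error.pos, len_ref, len_alt),
        )
        for s, e in gene.cds_intervals
    ]
    after_gene = GeneModel(gene.gene_id, gene.contig, gene.strand, shifted)
    cds_after = build_cds(after_gene, edited_seq)
    before = translate(cds_before)
    after = translate(cds_after)
    # frame disruption is judged on the coding-sequence length change, so an
    # InDel straddling an exon boundary contributes only its exonic bases
    delta = len(cds_after) - len(cds_before)
    if delta != 0 and abs(delta) % 3 != 0:
        impact = "frameshift"
    else:
        impact = _compare_translations(before, after)
    return TranslationImpact(
        gene_id=gene.gene_id,
        error=error,
        impact=impact,
        affected_exon_index=exon_index,
        protein_before=before.protein,
        protein_after=after.protein,
    )


def _compare_translations(before: TranslationResult, after: TranslationResult) -> str:
    """In-frame comparison: stop position first, then residue identity."""
    inf = float("inf")
    stop_b = before.first_stop_codon if before.first_stop_codon is not None else inf
    stop_a = after.first_stop_codon if after.first_stop_codon is not None else inf
    if before.protein == after.protein and stop_b == stop_a:
        return "synonymous"
    if stop_b < stop_a:
        return "stop_gain"  # the error truncates translation early
    if stop_b > stop_a:
        return "stop_loss"  # the error destroys the corrected sequence's stop
    return "missense"


def count_affected(
    errors: Sequence[AssemblyError],
    genes: Sequence[GeneModel],
    contig_seqs: Mapping[str, str],
    include_missense: bool = True,
) -> dict:
    """Count exons and genes whose translation the errors disrupt.

    An exon/gene is affected when it carries at least one error whose impact
    prevents correct translation. Two criteria are reported: the inclusive
    one counts missense alongside frameshift/stop changes, the strict one
    counts frame and stop disruptions only. Each exon and gene is counted
    once under each criterion.
    """
    trees: dict[str, IntervalTree] = {}
    for idx, gene in enumerate(genes):
        span = gene.span
        trees.setdefault(gene.contig, IntervalTree())[span[0]:span[1]] = idx
    tallies: dict[str, int] = {}
    affected_exons: set[tuple[str, int]] = set()
    affected_genes: set[str] = set()
    strict_exons: set[tuple[str, int]] = set()
    strict_genes: set[str] = set()
    impacts: list[TranslationImpact] = []
    for err in errors:
        tree = trees.get(err.contig)
        if tree is None:
            continue
        for iv in tree.overlap(err.pos, err.pos + max(len(err.assembly_allele), 1)):
            gene = genes[iv.data]
            impact = classify_error_impact(err, gene, contig_seqs[err.contig])
            impacts.append(impact)
            tallies[impact.impact] = tallies.get(impact.impact, 0) + 1
            if impact.impact in AFFECTING:
                affected_exons.add((gene.gene_id, impact.affected_exon_index))
                affected_genes.add(gene.gene_id)
            if impact.impact in DISRUPTIVE:
                strict_exons.add((gene.gene_id, impact.affected_exon_index))
                strict_genes.add(gene.gene_id)
    chosen_exons = affected_exons if include_missense else strict_exons
    chosen_genes = affected_genes if include_missense else strict_genes
    return {
        "affected_exons": len(chosen_exons),
        "affected_genes": len(chosen_genes),
        "affected_exons_inclusive": len(affected_exons),
        "affected_genes_inclusive": len(affected_genes),
        "affected_exons_strict": len(strict_exons),
        "affected_genes_strict": len(strict_genes),
        "impact_counts": tallies,
        "impacts": impacts,
    }
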