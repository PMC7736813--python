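import numpy as np
import pytest

from asmduet import coding_impact as ci
from asmduet.error_analysis import AssemblyError
from asmduet.formats_io import GeneModel

from helpers import CODON_TABLE, oracle_classify, revcomp


# ---------------------------------------------------------------------------
# build_cds / translate
# ---------------------------------------------------------------------------


def test_build_cds_single_exon_plus_strand():
    gene = GeneModel("g", "c1", "+", [(0, 6)])
    assert ci.build_cds(gene, "ATGTAACC") == "ATGTAA"


def test_build_cds_minus_strand_reverse_complements():
    gene = GeneModel("g", "c1", "-", [(0, 6)])
    assert ci.build_cds(gene, "ATGTAACC") == "TTACAT"


def test_build_cds_two_exon_splice():
    gene = GeneModel("g", "c1", "+", [(0, 3), (6, 9)])
    assert ci.build_cds(gene, "ATGxxxTAA".replace("x", "C")) == "ATGTAA"


def test_build_cds_out_of_bounds():
    gene = GeneModel("g", "c1", "+", [(0, 50)])
    with pytest.raises(ValueError, match="past contig end"):
        ci.build_cds(gene, "ATGTAA")


def test_translate_stops_and_flags():
    result = ci.translate("ATGTAA")
    assert (result.protein, result.has_terminal_stop) == ("M", True)
    result = ci.translate("ATGGCC")
    assert (result.protein, result.first_stop_codon) == ("MA", None)
    result = ci.translate("ATGTAGGGG")
    assert result.protein == "M"
    assert result.has_internal_stop
    assert ci.translate("ATGGCCA").partial_codon
    with pytest.raises(ValueError):
        ci.translate("AT")


# ---------------------------------------------------------------------------
# classify_error_impact on constructed cases
# ---------------------------------------------------------------------------


def _sub(contig_seq, pos, evidence):
    return AssemblyError("c1", pos, "substitution", 1, contig_seq[pos], evidence)


def test_one_base_cds_deletion_is_frameshift():
    # assembly lost one base: evidence allele restores it
    seq = "ATGGCCGGATAA" + "C" * 10
    gene = GeneModel("g", "c1", "+", [(0, 12)])
    err = AssemblyError("c1", 3, "insertion", 1, seq[3], seq[3] + "T")
    impact = ci.classify_error_impact(err, gene, seq)
    assert impact.impact == "frameshift"


def test_extra_base_in_cds_is_frameshift():
    seq = "ATGTGCCGGATAA" + "C" * 10  # assembly carries one extra base at pos 3
    gene = GeneModel("g", "c1", "+", [(0, 13)])
    err = AssemblyError("c1", 2, "deletion", 1, seq[2:4], seq[2])
    assert ci.classify_error_impact(err, gene, seq).impact == "frameshift"


def test_stop_gain_truncates_protein():
    # TGG (W) read as TGA (*) in the assembly: premature stop
    correct = "ATG" + "TGG" + "GCCGCC" + "TAA"
    assembly = "ATG" + "TGA" + "GCCGCC" + "TAA"
    gene = GeneModel("g", "c1", "+", [(0, len(assembly))])
    err = _sub(assembly, 5, correct[5])
    impact = ci.classify_error_impact(err, gene, assembly)
    assert impact.impact == "stop_gain"
    assert impact.protein_before == "M"
    assert impact.protein_after == "MWAA"


def test_stop_loss_reads_through():
    correct = "ATGGCC" + "TAA" + "GGGCCC"
    assembly = "ATGGCC" + "TCA" + "GGGCCC"  # annotated stop destroyed in assembly
    gene = GeneModel("g", "c1", "+", [(0, 9)])
    err = _sub(assembly, 7, correct[7])
    assert ci.classify_error_impact(err, gene, assembly).impact == "stop_loss"


def test_synonymous_third_position():
    correct = "ATG" + "GCT" + "TAA"  # GCT and GCC both code alanine
    assembly = "ATG" + "GCC" + "TAA"
    gene = GeneModel("g", "c1", "+", [(0, 9)])
    err = _sub(assembly, 5, correct[5])
    impact = ci.classify_error_impact(err, gene, assembly)
    assert impact.impact == "synonymous"
    assert impact.protein_before == impact.protein_after


def test_missense_changes_residue():
    assembly = "ATG" + "GAC" + "TAA"  # D where evidence says E
    gene = GeneModel("g", "c1", "+", [(0, 9)])
    err = _sub(assembly, 5, "A")  # GAC -> GAA
    assert ci.classify_error_impact(err, gene, assembly).impact == "missense"


def test_intronic_error_is_noncoding_with_splice_flag():
    seq = "ATG" + "GTCCCCAG" + "GCCTAA" + "C" * 5
    gene = GeneModel("g", "c1", "+", [(0, 3), (11, 17)])
    deep = _sub(seq, 7, "T")
    impact = ci.classify_error_impact(deep, gene, seq)
    assert impact.impact == "noncoding"
    assert not impact.splice_adjacent
    near = _sub(seq, 4, "A")  # 1 bp into the intron
    impact = ci.classify_error_impact(near, gene, seq)
    assert impact.impact == "noncoding"
    assert impact.splice_adjacent


def test_allele_mismatch_raises():
    seq = "ATGGCCTAA"
    gene = GeneModel("g", "c1", "+", [(0, 9)])
    err = AssemblyError("c1", 4, "substitution", 1, "T", "A")  # seq[4] is C, not T
    with pytest.raises(ValueError, match="coordinate mismatch"):
        ci.classify_error_impact(err, gene, seq)


def test_minus_strand_stop_gain():
    # CDS on the minus strand: plant a stop in CDS codon 2
    cds_correct = "ATG" + "TGG" + "GCC" + "TAA"
    cds_assembly = "ATG" + "TGA" + "GCC" + "TAA"
    genomic = "CC" + revcomp(cds_assembly) + "CC"
    gene = GeneModel("g", "c1", "-", [(2, 2 + len(cds_assembly))])
    # CDS index 5 maps to genomic position 2 + (len - 1 - 5)
    gpos = 2 + len(cds_assembly) - 6
    err = AssemblyError("c1", gpos, "substitution", 1, genomic[gpos],
                        revcomp(cds_correct[5]))
    assert ci.classify_error_impact(err, gene, genomic).impact == "stop_gain"


# ---------------------------------------------------------------------------
# agreement with the brute-force rebuild oracle
# ---------------------------------------------------------------------------


def _random_gene_and_contig(rng):
    n_codons = int(rng.integers(20, 60))
    cds = (
        "ATG"
        + "".join(rng.choice([c for c in CODON_TABLE if CODON_TABLE[c] != "*"],
                             size=n_codons - 2))
        + str(rng.choice(["TAA", "TAG", "TGA"]))
    )
    n_exons = int(rng.integers(1, 4))
    cuts = sorted(rng.choice(np.arange(3, len(cds) - 3), size=n_exons - 1, replace=False))
    pieces = [cds[a:b] for a, b in zip([0] + cuts, cuts + [len(cds)])]
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        pieces = [revcomp(p) for p in pieces[::-1]]
    flank = "".join(rng.choice(list("ACGT"), size=50))
    parts = [flank]
    intervals = []
    pos = len(flank)
    for i, piece in enumerate(pieces):
        intervals.append((pos, pos + len(piece)))
        parts.append(piece)
        pos += len(piece)
        intron = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 60))))
        parts.append(intron)
        pos += len(intron)
    contig = "".join(parts) + flank
    return GeneModel("g", "c1", strand, intervals), contig


def _random_error(rng, gene, contig):
    span = gene.span
    pos = int(rng.integers(max(0, span[0] - 10), min(len(contig) - 30, span[1] + 10)))
    roll = rng.random()
    if roll < 0.4:
        base = contig[pos]
        return AssemblyError("c1", pos, "substitution", 1, base,
                             str(rng.choice([b for b in "ACGT" if b != base])))
    length = int(rng.integers(1, 7))
    if roll < 0.7:  # assembly has extra bases
        return AssemblyError("c1", pos, "deletion", length,
                             contig[pos:pos + 1 + length], contig[pos])
    return AssemblyError(  # assembly lost bases
        "c1", pos, "insertion", length, contig[pos],
        contig[pos] + "".join(rng.choice(list("ACGT"), size=length)),
    )


def test_classifier_agrees_with_rebuild_oracle():
    rng = np.random.default_rng(2024)
    n_checked = 0
    for _ in range(60):
        gene, contig = _random_gene_and_contig(rng)
        for _ in range(5):
            err = _random_error(rng, gene, contig)
            got = ci.classify_error_impact(err, gene, contig).impact
            expected = oracle_classify(gene.cds_intervals, gene.strand, contig,
                                       err.pos, err.assembly_allele, err.evidence_allele)
            assert got == expected, (err, gene.strand, gene.cds_intervals)
            n_checked += 1
    assert n_checked == 300


def test_reverse_edit_inverts_stop_relationship():
    """Correcting the error and re-classifying the reverse edit swaps gain/loss."""
    correct = "ATG" + "TGG" + "GCCGCC" + "TAA"
    assembly = "ATG" + "TGA" + "GCCGCC" + "TAA"
    gene = GeneModel("g", "c1", "+", [(0, len(assembly))])
    forward = AssemblyError("c1", 5, "substitution", 1, assembly[5], correct[5])
    assert ci.classify_error_impact(forward, gene, assembly).impact == "stop_gain"
    backward = AssemblyError("c1", 5, "substitution", 1, correct[5], assembly[5])
    assert ci.classify_error_impact(backward, gene, correct).impact == "stop_loss"


# ---------------------------------------------------------------------------
# count_affected
# ---------------------------------------------------------------------------


def _multi_exon_setup():
    # three-exon gene; CDS = ATG TGG GCT ... TAA
    exon1, exon2, exon3 = "ATGTGG", "GCTGCA", "GCGTAA"
    introns = "CCCC"
    contig = exon1 + introns + exon2 + introns + exon3
    intervals = [(0, 6), (10, 16), (20, 26)]
    gene = GeneModel("g1", "c1", "+", intervals)
    return gene, contig


def test_count_affected_deduplicates_exons_and_genes():
    gene, contig = _multi_exon_setup()
    # TGG read as TAG in exon 0 (stop loss on correction side), GCT -> GTT in exon 1
    stop_loss = AssemblyError("c1", 4, "substitution", 1, contig[4], "A")
    missense = AssemblyError("c1", 11, "substitution", 1, contig[11], "T")
    result = ci.count_affected([stop_loss, missense], [gene], {"c1": contig})
    assert result["affected_exons"] == 2
    assert result["affected_genes"] == 1


def test_count_affected_synonymous_only_counts_nothing():
    gene, contig = _multi_exon_setup()
    # GCT -> GCC and GCA -> GCG are synonymous (alanine)
    syn1 = AssemblyError("c1", 12, "substitution", 1, contig[12], "C")
    result = ci.count_affected([syn1], [gene], {"c1": contig})
    assert (result["affected_exons"], result["affected_genes"]) == (0, 0)
    assert result["impact_counts"] == {"synonymous": 1}


def test_count_affected_strict_excludes_missense():
    gene, contig = _multi_exon_setup()
    missense = AssemblyError("c1", 11, "substitution", 1, contig[11], "T")
    inclusive = ci.count_affected([missense], [gene], {"c1": contig})
    strict = ci.count_affected([missense], [gene], {"c1": contig}, include_missense=False)
    assert inclusive["affected_genes"] == 1
    assert strict["affected_genes"] == 0
    assert strict["affected_genes_inclusive"] == 1
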