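"""Independent oracles used across tests.

The translation oracle rebuilds both genome versions by token surgery and
translates with a literal codon table, sharing no code with the package's
interval-shift + Biopython path.
"""

from __future__ import annotations

# fmt: off
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
# fmt: on

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def translate_table(cds: str) -> tuple[str, int | None]:
    """Codon-by-codon translation; returns (protein to first stop, stop index)."""
    protein = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        aa = CODON_TABLE[cds[i:i + 3]]
        if aa == "*":
            return "".join(protein), i // 3
        protein.append(aa)
    return "".join(protein), None


def oracle_classify(
    cds_intervals: list[tuple[int, int]],
    strand: str,
    contig_seq: str,
    pos: int,
    assembly_allele: str,
    evidence_allele: str,
) -> str:
    """Brute-force impact classification by full sequence rebuild.

    Applies the correction as token surgery on a per-base list, reassembles
    the coding sequence from prefix-length coordinates, and compares
    codon-by-codon translations.
    """
    ref, alt = assembly_allele, evidence_allele
    assert contig_seq[pos:pos + len(ref)] == ref, "oracle given inconsistent coordinates"
    tokens = list(contig_seq)
    for i in range(pos, pos + len(ref)):
        tokens[i] = ""
    tokens[pos] = alt
    prefix = [0]
    for t in tokens:
        prefix.append(prefix[-1] + len(t))
    edited = "".join(tokens)

    cds_before = "".join(contig_seq[s:e] for s, e in cds_intervals)
    cds_after = "".join(edited[prefix[s]:prefix[e]] for s, e in cds_intervals)
    if strand == "-":
        cds_before, cds_after = revcomp(cds_before), revcomp(cds_after)
    if cds_before == cds_after:
        return "noncoding"
    delta = len(cds_after) - len(cds_before)
    if delta != 0 and abs(delta) % 3 != 0:
        return "frameshift"
    prot_before, stop_before = translate_table(cds_before)
    prot_after, stop_after = translate_table(cds_after)
    inf = float("inf")
    sb = stop_before if stop_before is not None else inf
    sa = stop_after if stop_after is not None else inf
    if prot_before == prot_after and sb == sa:
        return "synonymous"
    if sb < sa:
        return "stop_gain"
    if sb > sa:
        return "stop_loss"
    return "missense"


def interval_overlap_fraction(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Intersection over the longer interval."""
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    return inter / max(a[1] - a[0], b[1] - b[0])


def match_calls(planted, called, kind: str, min_overlap: float = 0.9):
    """Precision/recall of called intervals vs planted intervals of one kind."""
    p = [(c.target_id, c.start, c.end) for c in planted if c.call_kind == kind]
    c = [(x.target_id, x.start, x.end) for x in called if x.call_kind == kind]
    tp_planted = sum(
        1 for pi in p
        if any(ci[0] == pi[0] and interval_overlap_fraction(ci[1:], pi[1:]) >= min_overlap
               for ci in c)
    )
    tp_called = sum(
        1 for ci in c
        if any(ci[0] == pi[0] and interval_overlap_fraction(ci[1:], pi[1:]) >= min_overlap
               for pi in p)
    )
    recall = tp_planted / len(p) if p else 1.0
    precision = tp_called / len(c) if c else 1.0
    return precision, recall, len(p), len(c)
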