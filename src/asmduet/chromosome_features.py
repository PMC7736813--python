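"""Telomere and centromere detection and telomere-to-telomere assessment.

Plant telomeres are tandem arrays of a short motif (AAACCCT in rice) at
contig ends; centromeres are arrays of a satellite family unit (RCS2-like,
~155 bp). Telomere arrays are found by exact-seed, mismatch-tolerant
tandem extension of the motif and its reverse complement; centromeres by
approximate full-unit matching of a consensus sequence (edlib), merging
nearby unit hits into regions. A contig is telomere-to-telomere when it
carries a telomere array near each end and contains no N characters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import edlib

from .formats_io import SequenceRecord

TELOMERE_MOTIF = "AAACCCT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class FeatureHit:
    """One detected telomere array or centromere region."""

    contig: str
    start: int
    end: int
    feature: str  # telomere | centromere
    unit_count: int
    mean_identity: float
    contig_end: str  # five_prime | three_prime | internal
    orientation: str = "+"  # motif strand for telomeres

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _classify_end(start: int, end: int, seq_len: int, end_window_bp: int) -> str:
    near_5 = start < end_window_bp
    near_3 = seq_len - end < end_window_bp
    if near_5 and near_3:
        return "five_prime" if start <= seq_len - end else "three_prime"
    if near_5:
        return "five_prime"
    if near_3:
        return "three_prime"
    return "internal"


def find_telomere_arrays(
    seq: str,
    motif: str = TELOMERE_MOTIF,
    min_units: int = 10,
    max_mismatch_fraction: float = 0.1,
    end_window_bp: int = 10_000,
    contig: str = "",
) -> list[FeatureHit]:
    """Maximal tandem runs of the telomere motif (either strand).

    Exact motif occurrences seed runs that are extended unit-by-unit in both
    directions, tolerating up to ``floor(max_mismatch_fraction * len(motif))``
    mismatches per unit. Runs of at least ``min_units`` copies are reported
    and classified by proximity to the contig ends.
    """
    if len(motif) < 4:
        raise ValueError("motif length must be >= 4")
    m = len(motif)
    allowed = int(max_mismatch_fraction * m)
    hits: list[FeatureHit] = []
    for unit, orientation in ((motif, "+"), (reverse_complement(motif), "-")):
        claimed_until = -1
        pos = seq.find(unit)
        while pos != -1:
            if pos <= claimed_until:
                pos = seq.find(unit, pos + 1)
                continue
            # extend right
            end = pos + m
            mismatches = 0
            while end + m <= len(seq) and _hamming(seq[end:end + m], unit) <= allowed:
                mismatches += _hamming(seq[end:end + m], unit)
                end += m
            # extend left
            start = pos
            while start - m >= 0 and _hamming(seq[start - m:start], unit) <= allowed:
                mismatches += _hamming(seq[start - m:start], unit)
                start -= m
            units = (end - start) // m
            if units >= min_units:
                hits.append(
                    FeatureHit(
                        contig=contig, start=start, end=end, feature="telomere",
                        unit_count=units,
                        mean_identity=1.0 - mismatches / (units * m),
                        contig_end=_classify_end(start, end, len(seq), end_window_bp),
                        orientation=orientation,
                    )
                )
            claimed_until = end - 1
            pos = seq.find(unit, max(pos + 1, end - m + 1))
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def find_centromere(
    seq: str,
    unit_consensus: str | None,
    min_identity: float = 0.8,
    min_full_units: int = 1,
    merge_gap_bp: int = 10_000,
    end_window_bp: int = 10_000,
    contig: str = "",
) -> list[FeatureHit]:
    """Centromere regions as clusters of full-length satellite-unit matches.

    The consensus unit is matched approximately (edit distance, both
    strands) across the contig; only full-unit matches at identity
    >= ``min_identity`` count, so a lone half-length fragment never seeds a
    centromere. Matches within ``merge_gap_bp`` are merged, and merged
    regions need at least ``min_full_units`` unit hits.
    """
    if unit_consensus is None:
        return []
    unit_len = len(unit_consensus)
    if unit_len < 50:
        raise ValueError("centromere consensus unit must be >= 50 bp")
    max_dist = int(round((1.0 - min_identity) * unit_len))
    matches: list[tuple[int, int, float]] = []
    for unit in (unit_consensus, reverse_complement(unit_consensus)):
        i = 0
        window = int(unit_len * 1.3)
        while i + unit_len <= len(seq):
            res = edlib.align(unit, seq[i:i + window], mode="HW", task="locations", k=max_dist)
            if res["editDistance"] >= 0 and res["locations"]:
                loc = res["locations"][0]
                start, end = i + loc[0], i + loc[1] + 1
                matches.append((start, end, 1.0 - res["editDistance"] / unit_len))
                i = end
            else:
                i += max(unit_len // 3, 25)
    if not matches:
        return []
    matches.sort()
    # drop duplicate strand hits over the same span
    deduped: list[tuple[int, int, float]] = []
    for m in matches:
        if deduped and m[0] < deduped[-1][1]:
            if m[2] > deduped[-1][2]:
                deduped[-1] = m
            continue
        deduped.append(m)
    regions: list[list] = []  # [start, end, [identities]]
    for start, end, ident in deduped:
        if regions and start - regions[-1][1] <= merge_gap_bp:
            regions[-1][1] = max(regions[-1][1], end)
            regions[-1][2].append(ident)
        else:
            regions.append([start, end, [ident]])
    hits = [
        FeatureHit(
            contig=contig, start=start, end=end, feature="centromere",
            unit_count=len(idents),
            mean_identity=sum(idents) / len(idents),
            contig_end=_classify_end(start, end, len(seq), end_window_bp),
        )
        for start, end, idents in regions
        if len(idents) >= min_full_units
    ]
    return hits


def assess_t2t(
    record: SequenceRecord,
    telomere_hits: Sequence[FeatureHit],
    centromere_hits: Sequence[FeatureHit] = (),
    require_centromere: bool = False,
) -> dict:
    """Telomere-to-telomere verdict for one contig.

    True when a five-prime and a three-prime telomere array are both present
    and the sequence contains no N characters; centromere presence is
    reported, and required only when ``require_centromere`` is set.
    """
    has_5 = any(h.contig_end == "five_prime" for h in telomere_hits)
    has_3 = any(h.contig_end == "three_prime" for h in telomere_hits)
    n_count = record.seq.count("N")
    has_cen = len(centromere_hits) > 0
    reasons: list[str] = []
    if not has_5:
        reasons.append("no five_prime telomere")
    if not has_3:
        reasons.append("no three_prime telomere")
    if n_count > 0:
        reasons.append(f"contains N ({n_count})")
    if require_centromere and not has_cen:
        reasons.append("no centromere")
    return {
        "contig": record.id,
        "is_t2t": not reasons,
        "reasons": reasons,
        "has_five_prime_telomere": has_5,
        "has_three_prime_telomere": has_3,
        "n_count": n_count,
        "has_centromere": has_cen,
    }
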