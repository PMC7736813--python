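"""Synthetic truth genomes with planted events, replacing the study's raw data.

The generator emulates the situation the pipeline analyses: a plant-like
truth genome carrying telomere motif arrays, a satellite centromere array,
long tandem repeats and cross-chromosome dispersed duplications (14-48 kb,
longer than a consensus-read span), plus multi-exon gene models. From the
truth it derives

* **assembly A** — one contiguous contig per chromosome with planted
  homozygous consensus errors (substitutions and small InDels at a
  configurable rate, half of them clustered inside designated
  high-methylation / low-shotgun-depth windows), heterozygous decoy sites
  and filter-failing decoy records to exercise the variant filters; and
* **assembly B** — chromosomes fragmented at every repeat longer than the
  read-length proxy, each break planted either as an uncovered gap (the
  repeat omitted) or as an overlap redundancy (the repeat duplicated onto
  both flanking contigs), with exact base-level alignments of B onto A
  emitted from construction.

Every planted event is recorded in ledgers (structural calls, errors,
repeats) against which the callers are scored; applying the planted errors'
evidence alleles back onto assembly A restores the truth genome exactly.
All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .error_analysis import AssemblyError
from .formats_io import (
    AlignmentRecord,
    GeneModel,
    MethylationSite,
    SequenceRecord,
    VariantRecord,
    write_depth_track,
    write_fasta,
    write_gff3,
    write_methylation_table,
    write_paf,
)
from .structural_comparison import StructuralCall

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_NON_STOP_CODONS = [
    a + b + c
    for a in _BASES for b in _BASES for c in _BASES
    if a + b + c not in _STOPS
]
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

TELOMERE_MOTIF = "AAACCCT"

PASSING_ANNOTATIONS = {
    "QD": 25.0, "MQ": 60.0, "FS": 1.0, "SOR": 1.0,
    "MQRankSum": 0.0, "ReadPosRankSum": 0.0,
}


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults mirror the emulated study system.

    Rates are per kb of truth sequence; repeat lengths are the unit lengths
    of the planted arrays (each tandem entry is planted once per chromosome,
    each dispersed entry once as a cross-chromosome pair). The read-length
    proxy separates repeats an assembly built from ~20 kb consensus reads
    can span from those it cannot.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_len_bp: int = 2_000_000
    gc_target: float = 0.44
    gene_density: float = 30.0  # genes per Mb
    tandem_repeat_lengths: tuple[int, ...] = (14_000, 23_000, 48_000)
    tandem_copies: int = 2
    dispersed_dup_lengths: tuple[int, ...] = (15_000, 48_000)
    telomere_units: int = 100
    centromere_units: int = 40
    centromere_unit_bp: int = 155
    error_rate_per_kb: float = 1.06
    substitution_fraction: float = 0.5
    clustered_error_fraction: float = 0.5
    cluster_errors_per_window: float = 20.0
    het_site_rate_per_kb: float = 0.5
    failing_record_fraction: float = 0.05
    indel_mean_bp: float = 1.39
    max_indel_bp: int = 25
    read_len_proxy_bp: int = 20_000
    gap_mode_weight: float = 0.5  # probability a break is a gap (else overlap)
    shotgun_depth: int = 30
    shotgun_depth_in_clusters: int = 2
    ont_depth: int = 100
    consensus_depth: int = 50

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chromosome_len_bp < 200_000:
            raise ValueError("need >=1 chromosome of >=200 kb")
        for name in ("error_rate_per_kb", "het_site_rate_per_kb", "gene_density"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "gc_target", "substitution_fraction", "clustered_error_fraction",
            "failing_record_fraction", "gap_mode_weight",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if min(self.tandem_repeat_lengths + self.dispersed_dup_lengths, default=1) <= 0:
            raise ValueError("repeat lengths must be > 0")


@dataclass
class PlantedRepeat:
    chrom: str
    start: int
    end: int
    kind: str  # telomere | centromere | tandem | dispersed
    unit_len: int
    pair_id: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class _PlantedEdit:
    """One planted error in truth coordinates (anchored alleles)."""

    pos: int  # truth coordinate of the anchor
    truth_seg: str  # correct (evidence) sequence at the anchor
    assembly_seg: str  # erroneous sequence written into assembly A

    @property
    def delta(self) -> int:
        return len(self.assembly_seg) - len(self.truth_seg)


class CoordinateLift:
    """Maps truth coordinates to assembly-A coordinates through planted edits."""

    def __init__(self, edits: Sequence[_PlantedEdit]):
        self._pos = [e.pos for e in edits]
        self._len_t = [len(e.truth_seg) for e in edits]
        self._len_a = [len(e.assembly_seg) for e in edits]
        cum = [0]
        for e in edits:
            cum.append(cum[-1] + e.delta)
        self._cum = cum

    def lift(self, c: int) -> int:
        i = bisect_left(self._pos, c)
        if i == 0:
            return c
        j = i - 1
        if c >= self._pos[j] + self._len_t[j]:
            return c + self._cum[i]
        return min(c - self._pos[j], self._len_a[j]) + self._pos[j] + self._cum[j]


@dataclass
class SyntheticTruth:
    """The complete planted-event ledger plus all derived artifacts."""

    config: SimulationConfig
    genome: list[SequenceRecord]
    gene_models: list[GeneModel]
    planted_repeats: list[PlantedRepeat]
    centromere_consensus: str
    feature_ledger: dict = field(default_factory=dict)
    # derive_assembly_a
    assembly_a: list[SequenceRecord] | None = None
    gene_models_a: list[GeneModel] | None = None
    planted_errors: list[AssemblyError] | None = None
    planted_het_sites: list[VariantRecord] | None = None
    truth_vcf: list[VariantRecord] | None = None
    methylation_sites: list[MethylationSite] | None = None
    depth_tracks: dict[str, list[tuple[str, int, int, int]]] = field(default_factory=dict)
    cluster_windows: list[tuple[str, int, int]] = field(default_factory=list)
    lifts: dict[str, CoordinateLift] = field(default_factory=dict)
    # derive_assembly_b
    assembly_b: list[SequenceRecord] | None = None
    true_alignments: list[AlignmentRecord] | None = None
    planted_structural: list[StructuralCall] | None = None

    def chromosome(self, name: str) -> SequenceRecord:
        for rec in self.genome:
            if rec.id == name:
                return rec
        raise KeyError(name)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)
    return arr.tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute bases at the given per-base rate (keeps length)."""
    arr = bytearray(seq, "ascii")
    n = rng.binomial(len(arr), rate)
    for i in rng.choice(len(arr), size=n, replace=False):
        current = chr(arr[i])
        arr[i] = ord(rng.choice([b for b in _BASES if b != current]))
    return arr.decode()


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class _Placer:
    """Non-overlapping feature placement with margins on one chromosome."""

    def __init__(self, rng: np.random.Generator, length: int, end_margin: int = 50_000):
        self.rng = rng
        self.length = length
        self.end_margin = end_margin
        self.occupied: list[tuple[int, int]] = []

    def reserve(self, start: int, end: int) -> None:
        self.occupied.append((start, end))

    def place(self, length: int, margin: int = 2_000) -> int:
        lo, hi = self.end_margin, self.length - self.end_margin - length
        if hi <= lo:
            raise ValueError("requested features exceed chromosome length")
        for _ in range(2_000):
            start = int(self.rng.integers(lo, hi))
            end = start + length
            if all(
                end + margin <= s or start - margin >= e for s, e in self.occupied
            ):
                self.reserve(start, end)
                return start
        raise ValueError("requested features exceed chromosome length")


def generate_truth_genome(config: SimulationConfig) -> SyntheticTruth:
    """Build the truth genome with planted repeats, features and gene models."""
    rng = np.random.default_rng([config.seed, 1])
    unit = _random_seq(rng, config.centromere_unit_bp, 0.5)
    chrom_names = [f"chr{i + 1:02d}" for i in range(config.n_chromosomes)]
    sequences: dict[str, bytearray] = {}
    repeats: list[PlantedRepeat] = []
    placers: dict[str, _Placer] = {}

    for name in chrom_names:
        length = config.chromosome_len_bp
        seq = bytearray(_random_seq(rng, length, config.gc_target), "ascii")
        placer = _Placer(rng, length)
        # telomeres at both ends
        tel_len = config.telomere_units * len(TELOMERE_MOTIF)
        seq[0:tel_len] = (TELOMERE_MOTIF * config.telomere_units).encode()
        seq[length - tel_len:length] = (
            _revcomp(TELOMERE_MOTIF) * config.telomere_units
        ).encode()
        placer.reserve(0, tel_len)
        placer.reserve(length - tel_len, length)
        repeats.append(PlantedRepeat(name, 0, tel_len, "telomere", len(TELOMERE_MOTIF)))
        repeats.append(
            PlantedRepeat(name, length - tel_len, length, "telomere", len(TELOMERE_MOTIF))
        )
        # one centromere array
        array = "".join(
            _mutate(rng, unit, 0.02) for _ in range(config.centromere_units)
        )
        start = placer.place(len(array))
        seq[start:start + len(array)] = array.encode()
        repeats.append(
            PlantedRepeat(name, start, start + len(array), "centromere",
                          config.centromere_unit_bp)
        )
        # tandem repeat arrays, one per configured unit length
        for unit_len in config.tandem_repeat_lengths:
            tr_unit = _random_seq(rng, unit_len, config.gc_target)
            array = tr_unit * config.tandem_copies
            start = placer.place(len(array), margin=5_000)
            seq[start:start + len(array)] = array.encode()
            repeats.append(
                PlantedRepeat(name, start, start + len(array), "tandem", unit_len)
            )
        sequences[name] = seq
        placers[name] = placer

    # dispersed duplications: source on one chromosome, mutated copy on the next
    for pair_id, dlen in enumerate(config.dispersed_dup_lengths):
        src = chrom_names[pair_id % len(chrom_names)]
        dst = chrom_names[(pair_id + 1) % len(chrom_names)]
        src_start = placers[src].place(dlen, margin=5_000)
        segment = sequences[src][src_start:src_start + dlen].decode()
        copy = _mutate(rng, segment, 0.01)  # >= 97% mutual identity
        dst_start = placers[dst].place(dlen, margin=5_000)
        sequences[dst][dst_start:dst_start + dlen] = copy.encode()
        repeats.append(PlantedRepeat(src, src_start, src_start + dlen, "dispersed",
                                     dlen, pair_id))
        repeats.append(PlantedRepeat(dst, dst_start, dst_start + dlen, "dispersed",
                                     dlen, pair_id))

    # gene models in repeat-free space
    genes: list[GeneModel] = []
    for name in chrom_names:
        n_genes = int(round(config.gene_density * config.chromosome_len_bp / 1e6))
        for g in range(n_genes):
            n_codons = int(rng.integers(100, 401))
            cds = (
                "ATG"
                + "".join(rng.choice(_NON_STOP_CODONS, size=n_codons - 2))
                + str(rng.choice(_STOPS))
            )
            n_exons = int(rng.integers(2, 6))
            cuts = sorted(rng.choice(np.arange(10, len(cds) - 10), size=n_exons - 1,
                                     replace=False))
            pieces = [cds[a:b] for a, b in zip([0] + cuts, cuts + [len(cds)])]
            introns = [int(rng.integers(100, 501)) for _ in range(n_exons - 1)]
            span = len(cds) + sum(introns)
            try:
                start = placers[name].place(span, margin=500)
            except ValueError:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            lengths = [len(p) for p in pieces]
            if strand == "-":
                lengths = lengths[::-1]
            intervals: list[tuple[int, int]] = []
            pos = start
            for k, exon_len in enumerate(lengths):
                intervals.append((pos, pos + exon_len))
                pos += exon_len + (introns[k] if k < len(introns) else 0)
            seq = sequences[name]
            for k, (s, e) in enumerate(intervals):
                piece = (
                    pieces[k] if strand == "+"
                    else _revcomp(pieces[len(pieces) - 1 - k])
                )
                seq[s:e] = piece.encode()
            genes.append(GeneModel(f"{name}_g{g:04d}", name, strand, intervals))

    genome = [SequenceRecord(name, sequences[name].decode()) for name in chrom_names]
    feature_ledger = {
        "telomere": [(r.chrom, r.start, r.end) for r in repeats if r.kind == "telomere"],
        "centromere": [(r.chrom, r.start, r.end) for r in repeats if r.kind == "centromere"],
    }
    return SyntheticTruth(
        config=config,
        genome=genome,
        gene_models=genes,
        planted_repeats=repeats,
        centromere_consensus=unit,
        feature_ledger=feature_ledger,
    )


def _break_repeats(truth: SyntheticTruth) -> dict[str, list[PlantedRepeat]]:
    """Repeats long enough to fragment an assembly built from proxy-length reads."""
    proxy = truth.config.read_len_proxy_bp
    by_chrom: dict[str, list[PlantedRepeat]] = {rec.id: [] for rec in truth.genome}
    for rep in truth.planted_repeats:
        if rep.kind in ("tandem", "dispersed") and rep.length > proxy:
            by_chrom[rep.chrom].append(rep)
    for reps in by_chrom.values():
        reps.sort(key=lambda r: r.start)
    return by_chrom


def _boundary_exclusions(truth: SyntheticTruth, chrom: str, margin: int = 100) -> list[tuple[int, int]]:
    zones = [(0, margin), (len(truth.chromosome(chrom)) - margin, len(truth.chromosome(chrom)))]
    for rep in _break_repeats(truth)[chrom]:
        zones.append((rep.start - margin, rep.start + margin))
        zones.append((rep.end - margin, rep.end + margin))
    return sorted(zones)


def _in_zones(pos: int, zones: list[tuple[int, int]]) -> bool:
    return any(s <= pos < e for s, e in zones)


def derive_assembly_a(truth: SyntheticTruth, config: SimulationConfig | None = None) -> SyntheticTruth:
    """Plant consensus errors into a contiguous copy of each chromosome.

    Fills assembly A, the planted-error ledger (in A coordinates), the truth
    VCF (errors as 1/1 with passing annotations, decoy 1/1 records with
    failing annotations, heterozygous 0/1 sites), the methylation table
    (high inside designated cluster windows), and shotgun/ONT depth tracks
    (shotgun depth <= 5 inside cluster windows).
    """
    config = config or truth.config
    rng = np.random.default_rng([config.seed, 2])
    geom_p = 1.0 / config.indel_mean_bp

    assembly_a: list[SequenceRecord] = []
    gene_models_a: list[GeneModel] = []
    all_errors: list[AssemblyError] = []
    all_hets: list[VariantRecord] = []
    truth_vcf: list[VariantRecord] = []
    meth_sites: list[MethylationSite] = []
    shotgun: list[tuple[str, int, int, int]] = []
    ont: list[tuple[str, int, int, int]] = []
    cluster_windows_a: list[tuple[str, int, int]] = []

    for rec in truth.genome:
        chrom, seq, length = rec.id, rec.seq, len(rec.seq)
        zones = _boundary_exclusions(truth, chrom)
        n_total = rng.poisson(config.error_rate_per_kb * length / 1000.0)
        n_clustered = int(round(config.clustered_error_fraction * n_total))
        n_windows = (
            int(np.ceil(n_clustered / config.cluster_errors_per_window))
            if n_clustered else 0
        )
        # designated high-methylation, low-shotgun-depth windows (1 kb, truth coords)
        window_starts: list[int] = []
        grid = np.arange(2_000, length - 3_000, 1_000)
        rng.shuffle(grid)
        for cand in grid:
            if len(window_starts) == n_windows:
                break
            cand = int(cand)
            if _in_zones(cand, zones) or _in_zones(cand + 1_000, zones):
                continue
            if any(abs(cand - w) < 2_000 for w in window_starts):
                continue
            window_starts.append(cand)
        window_starts.sort()
        windows = [(w, w + 1_000) for w in window_starts]

        # error anchor positions: slotted inside cluster windows (keeps a
        # minimum spacing so anchored edits never overlap), rejection-sampled
        # background fill so the realized count equals the Poisson draw
        min_sep = 30
        slot_pool: list[int] = []
        for ws, we in windows:
            slot_pool.extend(
                ws + min_sep * i + int(rng.integers(0, 4))
                for i in range((we - ws - 4) // min_sep)
            )
        n_clustered = min(n_clustered, len(slot_pool))
        clustered_pos = (
            [int(p) for p in rng.choice(slot_pool, size=n_clustered, replace=False)]
            if n_clustered else []
        )
        filtered = sorted(clustered_pos)
        deficit = n_total - len(filtered)
        for _ in range(60):
            if deficit <= 0:
                break
            for p in rng.integers(50, length - 50, size=max(deficit, 16)):
                p = int(p)
                if _in_zones(p, zones):
                    continue
                i = bisect_left(filtered, p - min_sep + 1)
                if i < len(filtered) and filtered[i] < p + min_sep:
                    continue
                filtered.insert(bisect_left(filtered, p), p)
                deficit -= 1
                if deficit == 0:
                    break
        edits: list[_PlantedEdit] = []
        for p in filtered:
            if rng.random() < config.substitution_fraction:
                base = seq[p]
                other = str(rng.choice([b for b in _BASES if b != base]))
                edits.append(_PlantedEdit(p, base, other))
            else:
                k = int(min(rng.geometric(geom_p), config.max_indel_bp))
                if rng.random() < 0.5:  # assembly carries extra bases
                    extra = _random_seq(rng, k, 0.5)
                    edits.append(_PlantedEdit(p, seq[p], seq[p] + extra))
                else:  # assembly lost bases present in the truth
                    edits.append(_PlantedEdit(p, seq[p:p + 1 + k], seq[p]))

        # build assembly A and per-error A coordinates
        pieces: list[str] = []
        cursor = 0
        a_positions: list[int] = []
        a_len = 0
        for e in edits:
            pieces.append(seq[cursor:e.pos])
            a_len += e.pos - cursor
            a_positions.append(a_len)
            pieces.append(e.assembly_seg)
            a_len += len(e.assembly_seg)
            cursor = e.pos + len(e.truth_seg)
        pieces.append(seq[cursor:])
        a_seq = "".join(pieces)
        assembly_a.append(SequenceRecord(chrom, a_seq))
        lift = CoordinateLift(edits)
        truth.lifts[chrom] = lift

        for e, a_pos in zip(edits, a_positions):
            if len(e.truth_seg) == len(e.assembly_seg) == 1:
                kind, elen = "substitution", 1
            elif len(e.truth_seg) > len(e.assembly_seg):
                kind, elen = "insertion", len(e.truth_seg) - len(e.assembly_seg)
            else:
                kind, elen = "deletion", len(e.assembly_seg) - len(e.truth_seg)
            all_errors.append(
                AssemblyError(chrom, a_pos, kind, elen, e.assembly_seg, e.truth_seg)
            )
            truth_vcf.append(
                VariantRecord(chrom, a_pos + 1, e.assembly_seg, e.truth_seg, "1/1",
                              dict(PASSING_ANNOTATIONS))
            )

        # heterozygous sites and filter-failing decoys at error-free positions
        taken = set(filtered)
        taken_sorted = sorted(taken)

        def _free_positions(n: int) -> list[int]:
            out: list[int] = []
            attempts = 0
            while len(out) < n and attempts < 50 * (n + 1):
                attempts += 1
                p = int(rng.integers(1_000, length - 1_000))
                if _in_zones(p, zones):
                    continue
                i = bisect_left(taken_sorted, p - 30)
                if i < len(taken_sorted) and taken_sorted[i] < p + 30:
                    continue
                taken_sorted.insert(bisect_left(taken_sorted, p), p)
                out.append(p)
            return out

        n_het = rng.poisson(config.het_site_rate_per_kb * length / 1000.0)
        for p in _free_positions(int(n_het)):
            base = seq[p]
            other = str(rng.choice([b for b in _BASES if b != base]))
            het = VariantRecord(chrom, lift.lift(p) + 1, base, other, "0/1",
                                dict(PASSING_ANNOTATIONS))
            all_hets.append(het)
            truth_vcf.append(het)
        n_decoy = int(round(config.failing_record_fraction * len(edits)))
        for i, p in enumerate(_free_positions(n_decoy)):
            base = seq[p]
            other = str(rng.choice([b for b in _BASES if b != base]))
            annotations = dict(PASSING_ANNOTATIONS)
            if i % 2 == 0:
                annotations["QD"] = 1.0  # fails the SNP and InDel QD condition
                vrec = VariantRecord(chrom, lift.lift(p) + 1, base, other, "1/1",
                                     annotations)
            else:
                annotations["FS"] = 250.0  # fails the InDel FS condition
                vrec = VariantRecord(chrom, lift.lift(p) + 1, seq[p:p + 2], base, "1/1",
                                     annotations)
            truth_vcf.append(vrec)

        # methylation: high inside cluster windows, low outside
        n_sites = length // 200
        site_pos = np.sort(rng.choice(length, size=n_sites, replace=False))
        in_window = np.zeros(length, dtype=bool)
        for s, e in windows:
            in_window[s:e] = True
        for p in site_pos:
            p = int(p)
            frac = float(rng.beta(8, 2) if in_window[p] else rng.beta(2, 8))
            meth_sites.append(
                MethylationSite(chrom, lift.lift(p), int(rng.poisson(15)), frac)
            )

        # shotgun depth: baseline, dropping to <=5 inside cluster windows
        cursor = 0
        for s, e in windows:
            s_a, e_a = lift.lift(s), lift.lift(e)
            if s_a > cursor:
                shotgun.append((chrom, cursor, s_a, config.shotgun_depth))
            shotgun.append((chrom, s_a, e_a, config.shotgun_depth_in_clusters))
            cursor = e_a
        if cursor < len(a_seq):
            shotgun.append((chrom, cursor, len(a_seq), config.shotgun_depth))
        ont.append((chrom, 0, len(a_seq), config.ont_depth))
        cluster_windows_a.extend(
            (chrom, lift.lift(s), lift.lift(e)) for s, e in windows
        )

        # gene models lifted onto A
        for gene in truth.gene_models:
            if gene.contig != chrom:
                continue
            gene_models_a.append(
                GeneModel(
                    gene.gene_id, chrom, gene.strand,
                    [(lift.lift(s), lift.lift(e)) for s, e in gene.cds_intervals],
                )
            )

    truth_vcf.sort(key=lambda v: (v.contig, v.pos))
    truth.assembly_a = assembly_a
    truth.gene_models_a = gene_models_a
    truth.planted_errors = sorted(all_errors, key=lambda e: e.sort_key())
    truth.planted_het_sites = all_hets
    truth.truth_vcf = truth_vcf
    truth.methylation_sites = meth_sites
    truth.depth_tracks["shotgun_a"] = shotgun
    truth.depth_tracks["ont_a"] = ont
    truth.cluster_windows = cluster_windows_a
    return truth


def _contig_alignment(
    truth: SyntheticTruth, chrom: str, name: str, cs: int, ce: int,
    query_len: int, target_len: int,
) -> AlignmentRecord:
    """Exact alignment of B contig (truth[cs:ce]) onto assembly A."""
    lift = truth.lifts.get(chrom)
    edits = _edits_for(truth, chrom, cs, ce)
    runs: list[tuple[int, str]] = []

    def push(n: int, op: str) -> None:
        if n <= 0:
            return
        if runs and runs[-1][1] == op:
            runs[-1] = (runs[-1][0] + n, op)
        else:
            runs.append((n, op))

    cursor = cs
    for e in edits:
        push(e.pos - cursor, "=")
        lt, la = len(e.truth_seg), len(e.assembly_seg)
        if lt == la:
            push(lt, "X")
        elif la > lt:  # assembly has extra bases: target-only
            push(1, "=")
            push(la - lt, "D")
        else:  # assembly lost bases: query-only
            push(1, "=")
            push(lt - la, "I")
        cursor = e.pos + len(e.truth_seg)
    push(ce - cursor, "=")
    cigar = "".join(f"{n}{op}" for n, op in runs)
    n_matches = sum(n for n, op in runs if op == "=")
    block_len = sum(n for n, op in runs if op in "=XID")
    t_start = lift.lift(cs) if lift else cs
    t_span = sum(n for n, op in runs if op in "=XD")
    return AlignmentRecord(
        query_id=name, query_len=query_len, query_start=0, query_end=ce - cs,
        strand="+",
        target_id=chrom, target_len=target_len,
        target_start=t_start, target_end=t_start + t_span,
        n_matches=n_matches, block_len=block_len, mapq=60,
        is_primary=True, cigar=cigar,
    )


def _edits_for(truth: SyntheticTruth, chrom: str, cs: int, ce: int) -> list[_PlantedEdit]:
    """Planted edits whose anchored spans fall inside truth[cs:ce]."""
    if truth.planted_errors is None or chrom not in truth.lifts:
        return []
    lift = truth.lifts[chrom]
    seq = truth.chromosome(chrom).seq
    a_seq = next(r.seq for r in truth.assembly_a if r.id == chrom)
    edits = []
    lo = bisect_left(lift._pos, cs)
    for idx in range(lo, len(lift._pos)):
        p = lift._pos[idx]
        if p + lift._len_t[idx] > ce:
            break
        truth_seg = seq[p:p + lift._len_t[idx]]
        a_pos = lift.lift(p)
        assembly_seg = a_seq[a_pos:a_pos + lift._len_a[idx]]
        edits.append(_PlantedEdit(p, truth_seg, assembly_seg))
    return edits


def derive_assembly_b(truth: SyntheticTruth, config: SimulationConfig | None = None) -> SyntheticTruth:
    """Fragment the truth at long repeats into assembly B with planted events.

    Each repeat longer than the read-length proxy breaks its chromosome; per
    break the repeat is either omitted (an uncovered gap — scored as a loss)
    or duplicated onto both flanking contigs (an overlap — scored as a
    redundancy when the copies pass the similarity/depth criteria). True
    alignments of every B contig onto assembly A are emitted from
    construction with exact difference strings; a consensus-read depth track
    over B halves the depth across duplicated copies.
    """
    config = config or truth.config
    rng = np.random.default_rng([config.seed, 3])
    a_lengths = {
        rec.id: len(rec.seq)
        for rec in (truth.assembly_a if truth.assembly_a is not None else truth.genome)
    }
    contigs: list[SequenceRecord] = []
    alignments: list[AlignmentRecord] = []
    structural: list[StructuralCall] = []
    depth_b: list[tuple[str, int, int, int]] = []
    breaks = _break_repeats(truth)

    for rec in truth.genome:
        chrom = rec.id
        lift = truth.lifts.get(chrom)

        def to_a(c: int) -> int:
            return lift.lift(c) if lift else c

        events: list[dict] = []
        pending: list[tuple[int, int, str]] = []  # contig truth-intervals + name
        cursor = 0
        idx = 0

        def contig_name() -> str:
            return f"b_{chrom}_{len(pending):02d}"

        for rep in breaks[chrom]:
            mode = "gap" if rng.random() < config.gap_mode_weight else "overlap"
            if mode == "gap":
                left = contig_name()
                pending.append((cursor, rep.start, left))
                cursor = rep.end
            else:
                left = contig_name()
                pending.append((cursor, rep.end, left))
                cursor = rep.start
            events.append({"repeat": rep, "mode": mode, "left": left})
        pending.append((cursor, len(rec.seq), contig_name()))

        for cs, ce, name in pending:
            contigs.append(SequenceRecord(name, rec.seq[cs:ce]))
        names = [name for _, _, name in pending]
        for k, event in enumerate(events):
            event["right"] = names[k + 1]
        for cs, ce, name in pending:
            alignments.append(
                _contig_alignment(truth, chrom, name, cs, ce, ce - cs, a_lengths[chrom])
            )
        # consensus depth over B: halved across duplicated repeat copies
        dup_local: dict[str, list[tuple[int, int]]] = {name: [] for _, _, name in pending}
        for event in events:
            if event["mode"] != "overlap":
                continue
            rep = event["repeat"]
            for cs, ce, name in pending:
                if name in (event["left"], event["right"]):
                    dup_local[name].append((rep.start - cs, rep.end - cs))
        for cs, ce, name in pending:
            cursor_b = 0
            for s, e in sorted(dup_local[name]):
                if s > cursor_b:
                    depth_b.append((name, cursor_b, s, config.consensus_depth))
                depth_b.append((name, s, e, int(rng.integers(22, 30))))
                cursor_b = e
            if cursor_b < ce - cs:
                depth_b.append((name, cursor_b, ce - cs, config.consensus_depth))
        # structural ledger in assembly-A coordinates
        for event in events:
            rep = event["repeat"]
            start_a, end_a = to_a(rep.start), to_a(rep.end)
            base = {"gap": ("gap_uncovered", "loss"), "overlap": ("overlap", "redundancy")}
            for kind in base[event["mode"]]:
                structural.append(
                    StructuralCall(
                        chrom, start_a, end_a, kind,
                        left_query=event["left"], right_query=event["right"],
                        repeat_context=rep.kind if rep.kind in ("tandem", "dispersed") else "none",
                    )
                )

    truth.assembly_b = contigs
    truth.true_alignments = alignments
    truth.planted_structural = structural
    truth.depth_tracks["consensus_b"] = depth_b
    return truth


def simulate(config: SimulationConfig) -> SyntheticTruth:
    """Full deterministic simulation: truth genome, assembly A, assembly B."""
    truth = generate_truth_genome(config)
    derive_assembly_a(truth, config)
    derive_assembly_b(truth, config)
    return truth


# ---------------------------------------------------------------------------
# Fixture writing
# ---------------------------------------------------------------------------

VCF_HEADER_KEYS = ("QD", "MQ", "FS", "SOR", "MQRankSum", "ReadPosRankSum")


def write_vcf(records: Sequence[VariantRecord], contig_lengths: dict[str, int],
              path: str | Path) -> None:
    """Write a minimal single-sample VCF (for fixtures, not a general writer)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig, length in contig_lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        for key in VCF_HEADER_KEYS:
            fh.write(f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for rec in records:
            info = ";".join(f"{k}={v:g}" for k, v in rec.site_annotations.items()) or "."
            gt = "./." if rec.genotype == "missing" else rec.genotype
            fh.write(
                f"{rec.contig}\t{rec.pos}\t.\t{rec.ref_allele}\t{rec.alt_allele}"
                f"\t.\t.\t{info}\tGT\t{gt}\n"
            )


def write_fixtures(truth: SyntheticTruth, outdir: str | Path) -> dict[str, Path]:
    """Write the complete synthetic dataset and ledgers into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def p(name: str) -> Path:
        paths[name] = outdir / name
        return paths[name]

    write_fasta(truth.genome, p("truth.fasta"))
    write_fasta([SequenceRecord("centromere_unit", truth.centromere_consensus)],
                p("centromere_consensus.fasta"))
    if truth.assembly_a is not None:
        write_fasta(truth.assembly_a, p("assembly_a.fasta"))
        write_gff3(truth.gene_models_a, p("genes_a.gff3"))
        write_vcf(truth.truth_vcf, {r.id: len(r.seq) for r in truth.assembly_a},
                  p("calls.vcf"))
        write_methylation_table(truth.methylation_sites, p("methylation.tsv"))
        write_depth_track(truth.depth_tracks["shotgun_a"], p("depth_shotgun_a.tsv"))
        write_depth_track(truth.depth_tracks["ont_a"], p("depth_ont_a.tsv"))
    if truth.assembly_b is not None:
        write_fasta(truth.assembly_b, p("assembly_b.fasta"))
        write_paf(truth.true_alignments, p("alignments_b_on_a.paf"))
        write_depth_track(truth.depth_tracks["consensus_b"], p("depth_consensus_b.tsv"))
    # ledgers
    import json

    with open(p("ledger_structural.tsv"), "w") as fh:
        fh.write("target_id\tstart\tend\tcall_kind\tleft_query\tright_query\trepeat_context\n")
        for call in truth.planted_structural or []:
            fh.write(
                f"{call.target_id}\t{call.start}\t{call.end}\t{call.call_kind}"
                f"\t{call.left_query}\t{call.right_query}\t{call.repeat_context}\n"
            )
    with open(p("ledger_errors.tsv"), "w") as fh:
        fh.write("contig\tpos\terror_kind\tlength\tassembly_allele\tevidence_allele\n")
        for err in truth.planted_errors or []:
            fh.write(
                f"{err.contig}\t{err.pos}\t{err.error_kind}\t{err.length}"
                f"\t{err.assembly_allele}\t{err.evidence_allele}\n"
            )
    with open(p("ledger_repeats.tsv"), "w") as fh:
        fh.write("chrom\tstart\tend\tkind\tunit_len\tpair_id\n")
        for rep in truth.planted_repeats:
            fh.write(
                f"{rep.chrom}\t{rep.start}\t{rep.end}\t{rep.kind}"
                f"\t{rep.unit_len}\t{rep.pair_id}\n"
            )
    summary = {
        "config": {f.name: getattr(truth.config, f.name) for f in fields(truth.config)},
        "n_chromosomes": len(truth.genome),
        "n_genes": len(truth.gene_models),
        "n_planted_errors": len(truth.planted_errors or []),
        "n_planted_structural": len(truth.planted_structural or []),
        "n_b_contigs": len(truth.assembly_b or []),
    }
    with open(p("ledger.json"), "w") as fh:
        json.dump(summary, fh, indent=2, default=list)
    return paths


def restore_truth(truth: SyntheticTruth) -> list[SequenceRecord]:
    """Apply every planted error's evidence allele back onto assembly A.

    Returns sequences that must equal the truth genome byte-for-byte — the
    generator's reversibility guarantee.
    """
    if truth.assembly_a is None or truth.planted_errors is None:
        raise ValueError("assembly A not derived")
    restored: list[SequenceRecord] = []
    by_contig: dict[str, list[AssemblyError]] = {}
    for err in truth.planted_errors:
        by_contig.setdefault(err.contig, []).append(err)
    for rec in truth.assembly_a:
        errors = sorted(by_contig.get(rec.id, []), key=lambda e: e.pos)
        pieces: list[str] = []
        cursor = 0
        for err in errors:
            pieces.append(rec.seq[cursor:err.pos])
            pieces.append(err.evidence_allele)
            cursor = err.pos + len(err.assembly_allele)
        pieces.append(rec.seq[cursor:])
        restored.append(SequenceRecord(rec.id, "".join(pieces)))
    return restored
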