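"""Consensus-error definition and characterisation for the error-prone assembly.

High-accuracy consensus reads (HiFi) mapped onto the nanopore assembly yield
variant calls; after GATK-style hard filtering, homozygous-alternate (1/1)
sites are the assembly's consensus errors — heterozygous calls reflect true
heterozygosity of the diploid sample, not errors. The surviving error set is
then characterised: InDel length distribution, spacing of adjacent errors
against a homogeneous-Poisson null (errors cluster rather than scatter),
1 kb sliding-window enrichment (>= 5 errors per window), GC/methylation
contrast between enriched and other windows, and read depth at error sites
(low shotgun depth explains why polishing failed there).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .formats_io import DepthTrack, MethylationSite, VariantRecord

WINDOW_BP = 1_000
STEP_BP = 500
ENRICHMENT_MIN_ERRORS = 5

# GATK-style hard filters: a record FAILS if any condition holds for its
# class; a missing annotation passes that condition.
SNP_FILTERS = {
    "QD": ("lt", 2.0),
    "MQ": ("lt", 40.0),
    "FS": ("gt", 60.0),
    "SOR": ("gt", 3.0),
    "MQRankSum": ("lt", -12.5),
    "ReadPosRankSum": ("lt", -8.0),
}
INDEL_FILTERS = {
    "QD": ("lt", 2.0),
    "FS": ("gt", 200.0),
    "SOR": ("gt", 10.0),
    "MQRankSum": ("lt", -12.5),
    "ReadPosRankSum": ("lt", -8.0),
}


@dataclass
class FilterThresholds:
    """Hard-filter conditions per variant class (fail when any holds)."""

    snp: dict[str, tuple[str, float]] = field(default_factory=lambda: dict(SNP_FILTERS))
    indel: dict[str, tuple[str, float]] = field(default_factory=lambda: dict(INDEL_FILTERS))


@dataclass
class AssemblyError:
    """One surviving consensus error on the error-prone assembly.

    ``pos`` is 0-based; ``assembly_allele`` is the erroneous sequence present
    in the assembly (the VCF REF), ``evidence_allele`` the read-backed
    correction (the VCF ALT). For InDels both alleles share the anchor base
    and ``length`` is the absolute size difference.
    """

    contig: str
    pos: int
    error_kind: str  # substitution | insertion | deletion
    length: int
    assembly_allele: str
    evidence_allele: str

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("error length must be >= 1")
        if self.error_kind == "substitution":
            if (
                len(self.assembly_allele) != len(self.evidence_allele)
                or self.assembly_allele == self.evidence_allele
            ):
                raise ValueError("substitution alleles must differ and have equal length")

    @property
    def is_indel(self) -> bool:
        return self.error_kind != "substitution"

    def sort_key(self) -> tuple[str, int]:
        return self.contig, self.pos


@dataclass
class ErrorWindow:
    """One sliding window with its error count, GC, methylation and flag."""

    contig: str
    start: int
    end: int
    error_count: int
    gc_fraction: float
    methylation_level: float | None
    enriched: bool
    truncated: bool = False  # final short window at a contig end


@dataclass
class ClusteringResult:
    ks_statistic: float | None
    p_value: float | None
    verdict: str  # clustered | not_clustered | undetermined
    n_distances: int
    observed_median_bp: float | None = None
    null_median_bp: float | None = None


def _fails(annotations: Mapping[str, float], rules: Mapping[str, tuple[str, float]]) -> bool:
    for key, (op, threshold) in rules.items():
        if key not in annotations:
            continue  # missing annotation passes the condition
        value = annotations[key]
        if op == "lt" and value < threshold:
            return True
        if op == "gt" and value > threshold:
            return True
    return False


def apply_hard_filters(
    records: Iterable[VariantRecord], thresholds: FilterThresholds | None = None
) -> list[VariantRecord]:
    """Drop variant records failing the class-appropriate hard filters."""
    thresholds = thresholds or FilterThresholds()
    passing = []
    for rec in records:
        rules = thresholds.indel if rec.is_indel else thresholds.snp
        if not _fails(rec.site_annotations, rules):
            passing.append(rec)
    return passing


def select_assembly_errors(records: Iterable[VariantRecord]) -> list[AssemblyError]:
    """Keep homozygous-alternate (1/1) calls as assembly errors, 0-based.

    Heterozygous (0/1) and reference (0/0) genotypes — true sample
    heterozygosity or noise — and missing genotypes are excluded.
    """
    errors = []
    for rec in records:
        if rec.genotype != "1/1":
            continue
        cls = rec.variant_class
        length = (
            1 if cls == "substitution"
            else abs(len(rec.ref_allele) - len(rec.alt_allele))
        )
        errors.append(
            AssemblyError(
                contig=rec.contig,
                pos=rec.pos - 1,
                error_kind=cls,
                length=length,
                assembly_allele=rec.ref_allele,
                evidence_allele=rec.alt_allele,
            )
        )
    return errors


def indel_length_stats(
    errors: Iterable[AssemblyError], max_length: int = 20
) -> dict:
    """Mean InDel length and a histogram with an overflow bucket.

    Lengths above ``max_length`` are tallied separately (overflow), mirroring
    how long-tail InDels are reported apart from the main distribution.
    """
    lengths = [e.length for e in errors if e.is_indel]
    histogram = Counter()
    overflow = 0
    for length in lengths:
        if length > max_length:
            overflow += 1
        else:
            histogram[length] += 1
    return {
        "n_indels": len(lengths),
        "mean_bp": float(np.mean(lengths)) if lengths else None,
        "histogram": dict(sorted(histogram.items())),
        "overflow_count": overflow,
        "overflow_threshold_bp": max_length,
    }


def adjacent_distances(errors: Sequence[AssemblyError]) -> np.ndarray:
    """Distances between successive errors within each contig (bp)."""
    by_contig: dict[str, list[int]] = {}
    for err in errors:
        by_contig.setdefault(err.contig, []).append(err.pos)
    out: list[np.ndarray] = []
    for positions in by_contig.values():
        arr = np.sort(np.asarray(positions, dtype=np.int64))
        if arr.size > 1:
            out.append(np.diff(arr))
    if not out:
        return np.array([], dtype=np.int64)
    return np.concatenate(out)


def random_placement_null(
    rate_per_kb: float, genome_len_bp: int, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, dict]:
    """Adjacent distances under uniform random (Poisson) error placement.

    Errors are dropped as a homogeneous Poisson process at ``rate_per_kb``;
    consecutive spacings are exponential with mean 1000/rate bp, which is the
    ~1 kb peak expected at 1.06 errors per kb if errors did not cluster.
    """
    if rate_per_kb <= 0:
        raise ValueError("rate_per_kb must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = rng.poisson(rate_per_kb * genome_len_bp / 1000.0)
    positions = np.sort(rng.integers(0, genome_len_bp, size=n))
    distances = np.diff(positions)
    mean = float(distances.mean()) if distances.size else None
    return distances, {
        "n_errors": int(n),
        "mean_bp": mean,
        "analytic_mean_bp": 1000.0 / rate_per_kb,
    }


def clustering_test(
    distances: Sequence[int] | np.ndarray,
    rate_per_kb: float,
    alpha: float = 0.05,
    min_distances: int = 10,
) -> ClusteringResult:
    """One-sample KS test of adjacent distances against the exponential null.

    Under uniform placement at ``rate_per_kb``, spacings are exponential with
    mean 1000/rate bp. The verdict is ``clustered`` when the test rejects at
    ``alpha`` AND the observed median falls below the exponential median —
    rejection with longer-than-null spacings would indicate over-dispersion,
    not clustering.
    """
    distances = np.asarray(distances, dtype=float)
    if distances.size < min_distances:
        return ClusteringResult(None, None, "undetermined", int(distances.size))
    scale = 1000.0 / rate_per_kb
    ks = stats.kstest(distances, "expon", args=(0, scale))
    null_median = scale * math.log(2)
    observed_median = float(np.median(distances))
    if ks.pvalue < alpha and observed_median < null_median:
        verdict = "clustered"
    else:
        verdict = "not_clustered"
    return ClusteringResult(
        ks_statistic=float(ks.statistic),
        p_value=float(ks.pvalue),
        verdict=verdict,
        n_distances=int(distances.size),
        observed_median_bp=observed_median,
        null_median_bp=null_median,
    )


def _gc_fraction(seq: str) -> float:
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / acgt


def window_error_scan(
    errors: Sequence[AssemblyError],
    contig_lengths: Mapping[str, int],
    window_bp: int = WINDOW_BP,
    step_bp: int = STEP_BP,
    min_count: int = ENRICHMENT_MIN_ERRORS,
    sequences: Mapping[str, str] | None = None,
    methylation_sites: Sequence[MethylationSite] | None = None,
) -> list[ErrorWindow]:
    """Tile each contig with sliding windows and profile errors/GC/methylation.

    Windows are ``window_bp`` wide with ``step_bp`` stride (1 kb / 500 bp by
    default, so interior errors fall in exactly two windows); the final short
    window at a contig end is kept and flagged. A window is enriched when it
    holds at least ``min_count`` errors. Methylation level is the mean
    methylated fraction of the sites inside the window, missing when none.
    """
    if not (window_bp >= step_bp > 0):
        raise ValueError("require window_bp >= step_bp > 0")
    err_pos: dict[str, np.ndarray] = {}
    for contig in contig_lengths:
        positions = sorted(e.pos for e in errors if e.contig == contig)
        err_pos[contig] = np.asarray(positions, dtype=np.int64)
    meth_pos: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if methylation_sites:
        by_contig: dict[str, list[tuple[int, float]]] = {}
        for site in methylation_sites:
            by_contig.setdefault(site.contig, []).append((site.pos, site.methylated_fraction))
        for contig, pairs in by_contig.items():
            pairs.sort()
            pos = np.asarray([p for p, _ in pairs], dtype=np.int64)
            frac = np.asarray([f for _, f in pairs], dtype=float)
            meth_pos[contig] = (pos, frac)
    windows: list[ErrorWindow] = []
    for contig, length in contig_lengths.items():
        positions = err_pos[contig]
        seq = sequences.get(contig) if sequences else None
        meth = meth_pos.get(contig)
        for start in range(0, max(length, 1), step_bp):
            if start >= length:
                break
            end = min(start + window_bp, length)
            count = int(
                np.searchsorted(positions, end, side="left")
                - np.searchsorted(positions, start, side="left")
            )
            gc = _gc_fraction(seq[start:end]) if seq is not None else float("nan")
            level: float | None = None
            if meth is not None:
                lo = np.searchsorted(meth[0], start, side="left")
                hi = np.searchsorted(meth[0], end, side="left")
                if hi > lo:
                    level = float(meth[1][lo:hi].mean())
            windows.append(
                ErrorWindow(
                    contig=contig, start=start, end=end,
                    error_count=count, gc_fraction=gc, methylation_level=level,
                    enriched=count >= min_count,
                    truncated=end - start < window_bp,
                )
            )
            if end >= length:
                break
    return windows


def contrast_enriched_windows(windows: Sequence[ErrorWindow]) -> dict:
    """Mann-Whitney U contrast of GC and methylation, enriched vs other windows.

    Two-sided tests with medians and effect direction; a metric is skipped
    (with the reason) when either group has fewer than two usable windows.
    """
    enriched = [w for w in windows if w.enriched]
    other = [w for w in windows if not w.enriched]
    results: dict[str, dict] = {}
    for metric, getter in (
        ("gc_test", lambda w: w.gc_fraction),
        ("methylation_test", lambda w: w.methylation_level),
    ):
        a = [getter(w) for w in enriched]
        b = [getter(w) for w in other]
        a = [x for x in a if x is not None and not math.isnan(x)]
        b = [x for x in b if x is not None and not math.isnan(x)]
        if len(a) < 2 or len(b) < 2:
            results[metric] = {
                "skipped": True,
                "reason": f"need >=2 windows per group, got {len(a)} enriched / {len(b)} other",
            }
            continue
        test = stats.mannwhitneyu(a, b, alternative="two-sided")
        med_a, med_b = float(np.median(a)), float(np.median(b))
        results[metric] = {
            "skipped": False,
            "statistic": float(test.statistic),
            "p_value": float(test.pvalue),
            "median_enriched": med_a,
            "median_other": med_b,
            "direction": (
                "higher_in_enriched" if med_a > med_b
                else "lower_in_enriched" if med_a < med_b else "equal"
            ),
            "n_enriched": len(a),
            "n_other": len(b),
        }
    return results


def error_site_depth_summary(
    errors: Sequence[AssemblyError], depth_track: DepthTrack, cutoff: int = 5
) -> dict:
    """Fraction of error sites at read depth <= cutoff (inclusive).

    Sites with no depth information are counted separately, never folded into
    either side of the cutoff.
    """
    n_at_or_below = 0
    n_missing = 0
    n_with_depth = 0
    for err in errors:
        depth = depth_track.depth_at(err.contig, err.pos)
        if depth is None:
            n_missing += 1
        else:
            n_with_depth += 1
            if depth <= cutoff:
                n_at_or_below += 1
    return {
        "fraction_at_or_below": (n_at_or_below / n_with_depth) if n_with_depth else None,
        "cutoff": cutoff,
        "n_at_or_below": n_at_or_below,
        "n_with_depth": n_with_depth,
        "n_missing": n_missing,
    }


def error_rate_per_kb(n_errors: int, denominator_bp: int) -> float:
    """Errors per kb over an explicit denominator (assembly or matched span)."""
    if denominator_bp <= 0:
        raise ValueError("denominator_bp must be > 0")
    return 1000.0 * n_errors / denominator_bp
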