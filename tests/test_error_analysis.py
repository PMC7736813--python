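import math

import numpy as np
import pytest

from asmduet import error_analysis as ea
from asmduet.formats_io import DepthTrack, MethylationSite, VariantRecord


def _var(ref="A", alt="G", gt="1/1", pos=100, contig="c1", **annotations):
    return VariantRecord(contig, pos, ref, alt, gt, dict(annotations))


# ---------------------------------------------------------------------------
# hard filters
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "record,passes",
    [
        (_var(QD=1.5), False),  # SNP QD below 2.0 fails
        (_var(QD=5.0, MQ=60.0, FS=10.0, SOR=1.0, MQRankSum=0.0, ReadPosRankSum=0.0), True),
        (_var(MQ=35.0), False),  # SNP MQ condition
        (_var(FS=65.0), False),  # SNP FS > 60
        (_var(ref="A", alt="AG", FS=250.0), False),  # InDel FS > 200
        (_var(ref="A", alt="AG", FS=150.0, SOR=9.0), True),  # within InDel bounds
        (_var(ref="A", alt="AG", MQ=10.0), True),  # MQ not part of the InDel filter
        (_var(ref="ACC", alt="A", SOR=11.0), False),  # InDel SOR > 10
        (_var(MQRankSum=-13.0), False),
        (_var(ReadPosRankSum=-9.0), False),
        (_var(), True),  # all annotations missing: every condition passes
    ],
)
def test_hard_filter_conditions(record, passes):
    assert (ea.apply_hard_filters([record]) == [record]) is passes


def test_snp_boundary_values_pass():
    # the conditions are strict inequalities
    rec = _var(QD=2.0, MQ=40.0, FS=60.0, SOR=3.0, MQRankSum=-12.5, ReadPosRankSum=-8.0)
    assert ea.apply_hard_filters([rec]) == [rec]


# ---------------------------------------------------------------------------
# error selection
# ---------------------------------------------------------------------------


def test_select_errors_keeps_only_homozygous_alternate():
    records = [
        _var(gt="1/1", pos=10),
        _var(gt="0/1", pos=20),
        _var(gt="0/0", pos=30),
        _var(gt="missing", pos=40),
    ]
    (err,) = ea.select_assembly_errors(records)
    assert err.pos == 9  # converted to 0-based
    assert err.error_kind == "substitution"
    assert ea.select_assembly_errors([]) == []


def test_select_errors_indel_length_and_alleles():
    (err,) = ea.select_assembly_errors([_var(ref="ACCT", alt="A", gt="1/1")])
    assert (err.error_kind, err.length) == ("deletion", 3)
    assert (err.assembly_allele, err.evidence_allele) == ("ACCT", "A")


# ---------------------------------------------------------------------------
# indel stats and distances
# ---------------------------------------------------------------------------


def _err(pos, contig="c1", kind="substitution", length=1):
    ref = "A" * (length + 1) if kind == "insertion" else "A"
    alt = "A" * (length + 1) if kind == "deletion" else "A"
    if kind == "substitution":
        ref, alt = "A", "G"
    return ea.AssemblyError(contig, pos, kind, length, alt, ref)


def test_indel_length_stats_mean_and_overflow():
    errors = [
        _err(0, kind="insertion", length=1),
        _err(50, kind="deletion", length=1),
        _err(100, kind="insertion", length=2),
        _err(150, kind="deletion", length=25),
        _err(200),  # substitution: excluded from InDel stats
    ]
    stats = ea.indel_length_stats(errors, max_length=20)
    assert stats["n_indels"] == 4
    assert stats["mean_bp"] == pytest.approx((1 + 1 + 2 + 25) / 4)
    assert stats["histogram"] == {1: 2, 2: 1}
    assert stats["overflow_count"] == 1


def test_indel_length_stats_substitutions_only():
    assert ea.indel_length_stats([_err(0)])["mean_bp"] is None


@pytest.mark.parametrize(
    "positions,expected",
    [
        ([0, 1000, 2000], [1000, 1000]),
        ([5, 8, 20], [3, 12]),
    ],
)
def test_adjacent_distances_within_contig(positions, expected):
    errors = [_err(p) for p in positions]
    assert list(ea.adjacent_distances(errors)) == expected


def test_adjacent_distances_never_cross_contigs():
    errors = [_err(100, contig="c1"), _err(500, contig="c2")]
    assert list(ea.adjacent_distances(errors)) == []


# ---------------------------------------------------------------------------
# random placement null and clustering test
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("rate,expected_mean", [(1.0, 1000.0), (2.0, 500.0)])
def test_random_placement_null_mean(rate, expected_mean):
    distances, summary = ea.random_placement_null(rate, 50_000_000, seed=1)
    se = expected_mean / math.sqrt(len(distances))
    assert abs(summary["mean_bp"] - expected_mean) < 3 * se


def test_random_placement_null_analytic_mean_at_study_rate():
    _, summary = ea.random_placement_null(1.06, 10_000_000, seed=2)
    assert summary["analytic_mean_bp"] == pytest.approx(943.396, abs=0.001)


def test_random_placement_null_mean_stable_over_seeds():
    means = []
    for seed in range(100):
        _, summary = ea.random_placement_null(1.0, 2_000_000, seed=seed)
        means.append(summary["mean_bp"])
    se = 1000.0 / math.sqrt(2_000_000 / 1000)
    assert abs(np.mean(means) - 1000.0) < 3 * se / math.sqrt(len(means))


def test_clustering_test_extreme_clustering():
    result = ea.clustering_test([10] * 100, rate_per_kb=1.0)
    assert result.verdict == "clustered"
    assert result.p_value < 1e-6


def test_clustering_test_too_few_distances():
    result = ea.clustering_test([10] * 5, rate_per_kb=1.0)
    assert result.verdict == "undetermined"
    assert result.p_value is None


def test_clustering_test_matching_exponential_not_clustered():
    rng = np.random.default_rng(0)
    distances = rng.exponential(1000.0, size=2000)
    assert ea.clustering_test(distances, rate_per_kb=1.0).verdict == "not_clustered"


def test_clustering_test_overdispersed_is_not_clustered():
    # uniformly spaced errors reject the exponential but are the opposite of clusters
    result = ea.clustering_test([1000] * 500, rate_per_kb=1.0)
    assert result.p_value < 0.05
    assert result.verdict == "not_clustered"


# ---------------------------------------------------------------------------
# window scan
# ---------------------------------------------------------------------------


def test_window_enrichment_boundary():
    errors = [_err(p) for p in (100, 200, 300, 400)]
    windows = ea.window_error_scan(errors, {"c1": 2_000})
    first = windows[0]
    assert first.error_count == 4 and not first.enriched
    errors.append(_err(500))
    windows = ea.window_error_scan(errors, {"c1": 2_000})
    assert windows[0].error_count == 5 and windows[0].enriched


def test_window_membership_with_step():
    errors = [_err(990), _err(1010)]
    windows = {(w.start, w.end): w for w in ea.window_error_scan(errors, {"c1": 3_000})}
    assert windows[(0, 1000)].error_count == 1
    assert windows[(500, 1500)].error_count == 2
    assert windows[(1000, 2000)].error_count == 1
    assert windows[(1500, 2500)].error_count == 0


def test_window_scan_matches_brute_force_counter():
    rng = np.random.default_rng(23)
    length = 100_000
    errors = [_err(int(p)) for p in np.sort(rng.integers(0, length, size=400))]
    windows = ea.window_error_scan(errors, {"c1": length})
    positions = [e.pos for e in errors]
    start = 0
    expected = []
    while start < length:
        end = min(start + 1000, length)
        expected.append(sum(1 for p in positions if start <= p < end))
        if end >= length:
            break
        start += 500
    assert [w.error_count for w in windows] == expected
    # each error lands in exactly window/step = 2 windows, except near contig ends
    total = sum(w.error_count for w in windows)
    interior = sum(1 for p in positions if 500 <= p < length - 500)
    edges = sum(1 for p in positions if p < 500 or p >= length - 500)
    assert total == 2 * interior + edges


def test_window_scan_gc_and_methylation_profiles():
    seq = "G" * 1000 + "A" * 800
    sites = [MethylationSite("c1", 100, 20, 0.9), MethylationSite("c1", 1500, 20, 0.1)]
    windows = ea.window_error_scan([], {"c1": 1800}, sequences={"c1": seq},
                                   methylation_sites=sites)
    by_start = {w.start: w for w in windows}
    assert by_start[0].gc_fraction == pytest.approx(1.0)
    assert by_start[0].methylation_level == pytest.approx(0.9)
    assert by_start[500].gc_fraction == pytest.approx(0.5)
    assert by_start[1000].methylation_level == pytest.approx(0.1)
    assert by_start[1000].truncated  # final short window kept and flagged
    assert by_start[1000].end == 1800


# ---------------------------------------------------------------------------
# enriched-window contrasts
# ---------------------------------------------------------------------------


def _window(start, enriched, gc=0.5, meth=None):
    return ea.ErrorWindow("c1", start, start + 1000, 5 if enriched else 0,
                          gc, meth, enriched)


def test_contrast_detects_methylation_difference():
    windows = [_window(i * 1000, True, meth=0.9) for i in range(10)]
    windows += [_window((i + 10) * 1000, False, meth=0.1) for i in range(10)]
    result = ea.contrast_enriched_windows(windows)
    meth = result["methylation_test"]
    assert meth["p_value"] < 0.05
    assert meth["direction"] == "higher_in_enriched"


def test_contrast_identical_groups_not_significant():
    windows = [_window(i * 1000, i < 10, meth=0.5, gc=0.4) for i in range(20)]
    result = ea.contrast_enriched_windows(windows)
    assert result["methylation_test"]["p_value"] > 0.9


def test_contrast_skipped_with_tiny_group():
    windows = [_window(0, True, meth=0.9)] + [
        _window((i + 1) * 1000, False, meth=0.1) for i in range(5)
    ]
    result = ea.contrast_enriched_windows(windows)
    assert result["methylation_test"]["skipped"]
    assert "reason" in result["methylation_test"]


# ---------------------------------------------------------------------------
# depth at error sites
# ---------------------------------------------------------------------------


def test_error_depth_summary_fraction_and_missing():
    track = DepthTrack([("c1", 0, 100, 3), ("c1", 100, 200, 10), ("c1", 200, 300, 5)])
    errors = [_err(50), _err(150), _err(250), _err(5_000)]
    summary = ea.error_site_depth_summary(errors, track, cutoff=5)
    assert summary["fraction_at_or_below"] == pytest.approx(2 / 3)  # depth 5 is inclusive
    assert summary["n_missing"] == 1


def test_error_depth_summary_all_zero():
    track = DepthTrack([("c1", 0, 1000, 0)])
    summary = ea.error_site_depth_summary([_err(10), _err(500)], track)
    assert summary["fraction_at_or_below"] == 1.0


def test_error_rate_both_denominators():
    assert ea.error_rate_per_kb(1060, 1_000_000) == pytest.approx(1.06)
    with pytest.raises(ValueError):
        ea.error_rate_per_kb(10, 0)
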