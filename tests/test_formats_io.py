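import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asmduet import formats_io as fio


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def test_fasta_roundtrip_uppercases_and_validates(tmp_path):
    path = tmp_path / "toy.fasta"
    path.write_text(">c1\nacgtn\n>c2\nGGGG\n")
    records = fio.read_fasta(path)
    assert [(r.id, r.seq) for r in records] == [("c1", "ACGTN"), ("c2", "GGGG")]
    out = tmp_path / "out.fasta"
    fio.write_fasta(records, out)
    assert [(r.id, r.seq) for r in fio.read_fasta(out)] == [("c1", "ACGTN"), ("c2", "GGGG")]


def test_fasta_rejects_bad_characters_and_duplicates(tmp_path):
    path = tmp_path / "bad.fasta"
    path.write_text(">c1\nACGU\n")
    with pytest.raises(ValueError, match="invalid characters"):
        fio.read_fasta(path)
    path.write_text(">c1\nACGT\n>c1\nACGT\n")
    with pytest.raises(ValueError, match="duplicate"):
        fio.read_fasta(path)


# ---------------------------------------------------------------------------
# PAF
# ---------------------------------------------------------------------------


def test_read_paf_empty_file(tmp_path):
    path = tmp_path / "empty.paf"
    path.write_text("")
    assert fio.read_paf(path) == []


def test_read_paf_single_line_fields(tmp_path):
    path = tmp_path / "one.paf"
    path.write_text("q\t100\t0\t100\t+\tt\t200\t50\t150\t95\t100\t60\n")
    (rec,) = fio.read_paf(path)
    assert (rec.query_start, rec.query_end) == (0, 100)
    assert (rec.target_start, rec.target_end) == (50, 150)
    assert rec.n_matches == 95 and rec.block_len == 100
    assert rec.is_primary is True  # tp absent defaults to primary
    assert rec.cigar is None


def test_read_paf_parses_tags_and_roundtrips(tmp_path):
    path = tmp_path / "tags.paf"
    path.write_text(
        "q\t100\t0\t100\t-\tt\t200\t50\t150\t95\t100\t60\ttp:A:S\tcg:Z:95=1X4=\n"
    )
    (rec,) = fio.read_paf(path)
    assert rec.is_primary is False
    assert rec.cigar == "95=1X4="
    out = tmp_path / "out.paf"
    fio.write_paf([rec], out)
    assert fio.read_paf(out) == [rec]


def test_read_paf_rejects_inconsistent_cigar(tmp_path):
    path = tmp_path / "bad.paf"
    # cigar consumes 101 target bp but the target span is 100
    path.write_text("q\t101\t0\t101\t+\tt\t200\t50\t150\t95\t101\t60\tcg:Z:101=\n")
    with pytest.raises(ValueError, match="cigar consumes"):
        fio.read_paf(path)


def test_read_paf_reports_line_number_on_malformed_input(tmp_path):
    path = tmp_path / "short.paf"
    path.write_text("q\t100\t0\t100\t+\tt\t200\n")
    with pytest.raises(ValueError, match=":1:"):
        fio.read_paf(path)


def test_alignment_record_rejects_inverted_coordinates():
    with pytest.raises(ValueError, match="out of bounds"):
        fio.AlignmentRecord("q", 100, 50, 40, "+", "t", 200, 0, 100, 10, 10)


@st.composite
def _alignment_records(draw):
    qlen = draw(st.integers(10, 10_000))
    qs = draw(st.integers(0, qlen - 1))
    qe = draw(st.integers(qs + 1, qlen))
    tlen = draw(st.integers(10, 10_000))
    ts = draw(st.integers(0, tlen - 1))
    te = draw(st.integers(ts + 1, tlen))
    block = max(qe - qs, te - ts)
    return fio.AlignmentRecord(
        query_id=draw(st.text("abc", min_size=1, max_size=5)),
        query_len=qlen, query_start=qs, query_end=qe,
        strand=draw(st.sampled_from("+-")),
        target_id="t", target_len=tlen, target_start=ts, target_end=te,
        n_matches=draw(st.integers(0, block)), block_len=block,
        mapq=draw(st.integers(0, 255)),
        is_primary=draw(st.booleans()),
    )


@settings(derandomize=True, max_examples=50)
@given(st.lists(_alignment_records(), max_size=6))
def test_paf_roundtrip_identity_on_mandatory_fields(tmp_path_factory, records):
    path = tmp_path_factory.mktemp("paf") / "rt.paf"
    fio.write_paf(records, path)
    assert fio.read_paf(path) == records


@settings(derandomize=True, max_examples=50)
@given(st.data())
def test_gff3_coordinate_conversion_is_an_exact_inverse(tmp_path_factory, data):
    n_exons = data.draw(st.integers(1, 4))
    bounds = sorted(
        data.draw(
            st.lists(st.integers(0, 5_000), min_size=2 * n_exons,
                     max_size=2 * n_exons, unique=True)
        )
    )
    intervals = [(bounds[2 * i], bounds[2 * i + 1]) for i in range(n_exons)]
    model = fio.GeneModel("m1", "c1", data.draw(st.sampled_from("+-")), intervals)
    path = tmp_path_factory.mktemp("gff") / "rt.gff3"
    fio.write_gff3([model], path)
    (back,) = fio.read_gff3(path)
    assert back.cds_intervals == intervals
    assert back.strand == model.strand


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=c1,length=1000>\n"
    '##INFO=<ID=QD,Number=1,Type=Float,Description="x">\n'
    '##INFO=<ID=FS,Number=1,Type=Float,Description="x">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="x">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
)


def _write_vcf(tmp_path, body: str):
    path = tmp_path / "calls.vcf"
    path.write_text(VCF_HEADER + body)
    return path


def test_read_vcf_genotypes_and_annotations(tmp_path):
    path = _write_vcf(
        tmp_path,
        "c1\t10\t.\tA\tG\t.\t.\tQD=3.0\tGT\t1/1\n"
        "c1\t20\t.\tC\tT\t.\t.\t.\tGT\t0/1\n",
    )
    hom, het = fio.read_vcf(path)
    assert hom.genotype == "1/1" and hom.site_annotations["QD"] == 3.0
    assert het.genotype == "0/1"
    assert "FS" not in hom.site_annotations  # absent, not zero


def test_read_vcf_header_only(tmp_path):
    assert fio.read_vcf(_write_vcf(tmp_path, "")) == []


def test_read_vcf_splits_multiallelic_with_per_allele_genotypes(tmp_path):
    path = _write_vcf(tmp_path, "c1\t10\t.\tA\tG,T\t.\t.\t.\tGT\t1/2\n")
    rec_g, rec_t = fio.read_vcf(path)
    assert (rec_g.alt_allele, rec_g.genotype) == ("G", "0/1")
    assert (rec_t.alt_allele, rec_t.genotype) == ("T", "0/1")


def test_read_vcf_missing_genotype_and_symbolic_alt(tmp_path):
    path = _write_vcf(
        tmp_path,
        "c1\t10\t.\tA\tG\t.\t.\t.\tGT\t./.\n"
        "c1\t30\t.\tA\t<DEL>\t.\t.\t.\tGT\t1/1\n",
    )
    records = fio.read_vcf(path)
    assert len(records) == 1  # symbolic alt dropped
    assert records[0].genotype == "missing"


@pytest.mark.parametrize(
    "ref,alt,expected",
    [("A", "G", "substitution"), ("A", "AGG", "insertion"), ("ACC", "A", "deletion")],
)
def test_variant_class_follows_allele_lengths(ref, alt, expected):
    rec = fio.VariantRecord("c1", 5, ref, alt, "1/1")
    assert rec.variant_class == expected


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

GFF_HEADER = "##gff-version 3\n"


def test_read_gff3_converts_coordinates(tmp_path):
    path = tmp_path / "g.gff3"
    path.write_text(
        GFF_HEADER
        + "c1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1\n"
        + "c1\tsrc\tmRNA\t101\t200\t.\t+\t.\tID=m1;Parent=g1\n"
        + "c1\tsrc\tCDS\t101\t200\t.\t+\t0\tID=cds1;Parent=m1\n"
    )
    (model,) = fio.read_gff3(path)
    assert model.cds_intervals == [(100, 200)]  # 1-based closed -> 0-based half-open
    assert model.strand == "+"


def test_read_gff3_minus_strand_keeps_genomic_order(tmp_path):
    path = tmp_path / "g.gff3"
    path.write_text(
        GFF_HEADER
        + "c1\tsrc\tgene\t11\t100\t.\t-\t.\tID=g1\n"
        + "c1\tsrc\tmRNA\t11\t100\t.\t-\t.\tID=m1;Parent=g1\n"
        + "c1\tsrc\tCDS\t61\t100\t.\t-\t0\tID=cds1a;Parent=m1\n"
        + "c1\tsrc\tCDS\t11\t30\t.\t-\t0\tID=cds1b;Parent=m1\n"
    )
    (model,) = fio.read_gff3(path)
    assert model.cds_intervals == [(10, 30), (60, 100)]  # ascending despite minus strand
    assert model.strand == "-"


def test_read_gff3_empty_file(tmp_path):
    path = tmp_path / "empty.gff3"
    path.write_text(GFF_HEADER)
    assert fio.read_gff3(path) == []


def test_gff3_roundtrip_is_identity(tmp_path, small_truth):
    models = [g for g in small_truth.gene_models_a if g.contig == "chr01"][:20]
    path = tmp_path / "rt.gff3"
    fio.write_gff3(models, path)
    back = {m.gene_id: m for m in fio.read_gff3(path)}
    assert len(back) == len(models)
    for model in models:
        other = back[model.gene_id]
        assert other.cds_intervals == model.cds_intervals
        assert other.strand == model.strand


# ---------------------------------------------------------------------------
# Methylation and depth tables
# ---------------------------------------------------------------------------


def test_methylation_support_threshold(tmp_path):
    path = tmp_path / "meth.tsv"
    path.write_text(
        "contig\tposition\tcalled_sites\tmethylated_frequency\n"
        "c1\t100\t9\t0.5\n"  # below support threshold: excluded
        "c1\t200\t10\t0.8\n"  # at the boundary: retained
    )
    sites = fio.read_methylation_table(path, min_called_sites=10)
    assert [(s.pos, s.methylated_fraction) for s in sites] == [(200, 0.8)]


def test_methylation_empty_and_invalid(tmp_path):
    path = tmp_path / "meth.tsv"
    path.write_text("contig\tposition\tcalled_sites\tmethylated_frequency\n")
    assert fio.read_methylation_table(path) == []
    path.write_text(
        "contig\tposition\tcalled_sites\tmethylated_frequency\nc1\t1\t20\t1.5\n"
    )
    with pytest.raises(ValueError, match="outside"):
        fio.read_methylation_table(path)


def test_depth_track_point_interval_and_missing(tmp_path):
    path = tmp_path / "depth.tsv"
    path.write_text("c1\t0\t100\t30\nc1\t100\t200\t10\nc2\t0\t50\t5\n")
    track = fio.read_depth_track(path)
    assert track.depth_at("c1", 99) == 30
    assert track.depth_at("c1", 100) == 10
    assert track.depth_at("c1", 500) is None
    assert track.depth_at("cX", 0) is None
    assert track.mean_depth("c1", 50, 150) == pytest.approx(20.0)
    assert track.mean_depth("c1", 400, 500) is None
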