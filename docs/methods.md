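# Methods

This note documents the models, thresholds and design choices behind
`asmduet`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Setting and coordinate conventions

The package arbitrates between two assemblies of one diploid individual:
assembly **A**, contiguous but consensus-error-prone (ultralong-read
style), and assembly **B**, accurate at base level but fragmented at long
repeats (consensus-long-read style). All internal coordinates are 0-based
half-open on the forward strand; 1-based closed coordinates exist only at
the GFF3/VCF boundaries and are converted on read. PAF is parsed directly
(twelve mandatory columns plus `cg:Z` difference strings and `tp:A`
primary tags); FASTA goes through Biopython, VCF through pysam, GFF3
through gffutils, tabular tracks through pandas.

## Structural comparison

B-onto-A alignments are reduced to one primary hit per query contig
(flagged primary, or the largest block with deterministic tie-breaks),
projected to merged target intervals (strict adjacency by default — gap
calling downstream must see true discontinuities), and compared:

* **Gaps**: maximal uncovered target intervals ≥ `min_gap_bp` (default
  50 bp; sub-50 bp holes are alignment boundary jitter, not structure).
* **Overlaps**: pairwise intersections of two queries' projections.
* **Redundancy promotion**: an overlap is a redundancy iff the two
  candidate copies have similarity ≥ 0.97 AND depth_1 + depth_2 < 60 AND
  each depth < 40. Similarity is computed as alignment identity between
  the two copy sequences (edlib global alignment, matches over aligned
  columns) — the natural reading of a "similarity score" between copies.
  Depths are means of a user-supplied consensus-read depth track over each
  copy; which read class to use is a configuration choice, defaulting to
  the high-accuracy long-read track. The depth bounds assume ~50×
  consensus coverage (reads split between two false copies yield ~25×
  each); they are exposed as configuration for other coverages. Missing
  similarity or depth classifies as `unknown`, never silently as
  redundancy.
* **Loss vs double cover**: within each gap, sub-intervals covered by zero
  projections are losses, by two or more are redundancies; single
  coverage is left uncalled (the defined dichotomy).
* **Repeat context**: from non-identity self-alignments of assembly A —
  `tandem` when a self-alignment pairs the call's flanks on the same
  contig within 100 kb, `dispersed` when the interval matches at ≥ 95%
  identity on another contig or farther than 100 kb, `none` otherwise,
  `unknown` without self-alignments. The 100 kb flank distance is this
  package's choice; the distinction is qualitative in the underlying
  analysis.
* **Gene accounting**: a gene counts toward a call when ≥ 1 bp of its CDS
  overlaps the call interval (whole-gene containment available as a
  stricter option), deduplicated per call kind.

## Consensus errors

Variant calls of high-accuracy reads against assembly A pass GATK-style
hard filters (SNP: QD < 2.0, MQ < 40.0, FS > 60.0, SOR > 3.0,
MQRankSum < −12.5, ReadPosRankSum < −8.0; InDel: QD < 2.0, FS > 200.0,
SOR > 10.0 and the same rank sums; a record fails if *any* condition
holds). Missing INFO annotations pass the corresponding condition — the
GATK convention; dropping such records would bias toward well-annotated
sites. Heterozygous (0/1) calls represent genuine heterozygosity of the
diploid sample and are removed; homozygous-alternate (1/1) survivors are
the assembly errors. Filtering before or after the genotype split is
observationally equivalent for the final set; the package filters first.
InDels are anchored at the VCF POS base (converted to 0-based) with
length |len(ref) − len(alt)|.

Characterisation:

* **Error rate** is reported per kb under two denominators — the full
  assembly length and the ≥ 1 Mb reciprocal-match span (alignments whose
  query *and* target spans are ≥ 1 Mb) — because the appropriate
  denominator is ambiguous when assemblies only partially correspond.
* **Clustering**: observed adjacent-error distances are tested against
  the homogeneous-Poisson null (exponential spacings, mean 1000/rate bp;
  at 1.06/kb the mean is 943.4 bp, a peak near ~1 kb) with a one-sample
  Kolmogorov–Smirnov test. The verdict is `clustered` only when the test
  rejects at α = 0.05 *and* the observed median lies below the
  exponential median — rejection with long spacings is over-dispersion,
  not clustering. The KS formalisation is this package's choice; a
  normal(1000, 200) overlay is reproducible for plotting but plays no
  inferential role. Fewer than 10 distances → `undetermined`.
* **Windows**: 1,000 bp windows at 500 bp steps tile each contig
  independently; the final short window is kept and flagged. A window
  with ≥ 5 errors is error-enriched. GC is computed over A/C/G/T bases;
  methylation level is the mean methylated fraction of sites with
  ≥ 10 supporting reads (the support filter applied on read-in).
  Enriched-vs-other contrasts use two-sided Mann–Whitney U with medians
  and direction; the underlying analysis reports significance without
  naming a test, and a rank test is the conservative choice for bounded,
  non-normal fractions.
* **Depth at errors**: the fraction of error sites at shotgun depth ≤ 5
  (inclusive); sites without depth information are counted separately,
  never folded into either side.

## Coding impact

`protein_before` is translated from the error-bearing assembly,
`protein_after` from the corrected sequence (evidence allele applied), so
impact labels describe what the error does to the assembly's annotation.
Edits are applied in genomic coordinates; CDS interval endpoints are
shifted through the edit (endpoints inside a replaced span clamp to the
replacement). Frame disruption is judged on the **coding-sequence length
change** — an InDel straddling an exon boundary contributes only its
exonic bases — with any non-multiple-of-three change a frameshift
regardless of downstream sequence. In-frame changes compare first-stop
codon positions (earlier stop in the assembly → stop gain; later → stop
loss), then residue identity (missense vs synonymous). Errors outside all
CDS are noncoding; intronic errors within 2 bp of a splice junction carry
a `splice_adjacent` flag but remain noncoding — splice sites are not
modelled, matching an analysis pipeline based on protein-to-genome
alignment rather than splice prediction. Affected exon/gene counts are
reported under both criteria (inclusive of missense, and frame/stop
disruptions only) because "fails to translate correctly" admits either
reading. Standard genetic code only.

## Chromosome features

Telomeres: maximal tandem runs of the motif (default `AAACCCT`) or its
reverse complement, found by exact-seed extension tolerating a per-unit
mismatch fraction (default 0.1 — zero mismatches for a 7-mer), requiring
≥ 10 units, classified five-prime/three-prime within 10 kb of a contig
end. Centromeres: approximate full-length matches of a satellite
consensus unit (≥ 50 bp) at edit-distance identity ≥ 0.8, both strands,
merged within 10 kb; a half-length fragment never seeds a region. These
cutoffs are this package's declared approximations of a workflow that
used Tandem Repeats Finder and a read aligner, neither of which defines
portable thresholds. T2T: a contig with a five-prime and a three-prime
telomere array and zero N characters; centromere presence is reported and
optionally required. The consensus unit is an input file, so no accession
download is needed.

## Synthetic truth generator

The generator's defaults are the study conditions the pipeline targets:

* error rate 1.06/kb, split evenly between substitutions and InDels (the
  emulated error set was ~50/50); InDel lengths geometric with mean
  1.39 bp (only the mean is reported by the emulated study, so the law is
  a declared modelling choice), capped at 25 bp;
* clustered error fraction 0.5, placed in designated 1 kb windows (~20
  errors each) that also receive methylated fractions drawn from
  Beta(8, 2) (vs Beta(2, 8) elsewhere) and shotgun depth 2 (vs 30) — so
  the enrichment, methylation-contrast and depth analyses have a planted
  signal to recover;
* heterozygous sites at 0.5/kb (0/1, never applied to the sequence) and
  filter-failing decoy records at 5% of the error count (1/1 with a
  violated annotation, never applied), to exercise the genotype and hard
  filters;
* tandem arrays of 14/23/48 kb units (two copies each, per chromosome)
  and 15/48 kb dispersed duplication pairs across chromosomes at ≥ 97%
  mutual identity, telomere arrays of 100 motif units at both ends, one
  centromere array of 40 × 155 bp units per chromosome at ~98% identity;
* a 20 kb read-length proxy: every repeat longer than it fragments
  assembly B, drawn into gap mode (repeat omitted) or overlap mode
  (repeat duplicated onto both flanking contigs) with equal probability;
* GC target 0.44 and ~30 genes/Mb of 100–400 codons in 2–5 exons,
  ATG-initiated, internally stop-free, placed in repeat-free space.

Error anchors keep ≥ 30 bp separation (slotted placement inside cluster
windows, rejection-sampled background) so anchored edits never overlap
and the realised count equals the Poisson draw — the configured rate is
recovered within sampling error. True B-onto-A alignments are emitted
from construction with exact `=`/`X`/`I`/`D` difference strings that
encode the planted errors; no aligner runs in tests. All outputs are pure
functions of (config, seed); seeds feed `numpy.random.default_rng`
streams keyed per stage.

What the generator does **not** emulate: read-level noise and mapping
artefacts (alignments are exact), segmental-duplication mosaicism, repeat
families with internal structure, genes inside repeats (so gene gain/loss
counts on synthetic runs are typically zero and that logic is verified on
constructed cases), N-gaps, and base-composition biases beyond a global
GC target. Passing tests therefore demonstrate the decision logic —
filters, thresholds, coordinate handling, statistics — not robustness to
aligner or caller noise.

## Numerical and degenerate-input choices

Ties in primary-hit selection break by n_matches then leftmost target
position. Overlap→query coordinate mapping is proportional within the
alignment block (exact inversion through the difference string is
unnecessary at the ≥ 97% similarity scale). Empty groups skip statistical
tests with an explicit reason rather than returning NaN. An error whose
assembly allele does not match the contig raises (a coordinate-frame
mismatch is never ignorable). GC is undefined (NaN) for all-N windows;
windows without methylation sites report a missing level. The
double-cover check coalesces adjacent same-kind segments within a gap.

## Problem sizes in tests

The test suite runs entirely on generated data: a shared 2 × 1 Mb truth
for module tests, 2 × 10 Mb for structural planted-truth recovery,
2 × 2 Mb for error recovery, ≥ 1,000 random gene/error pairs for the
translation oracle, 200 null and 60 clustered replicates for clustering
calibration and power, and 1 Mb instances for window-scan exactness and
feature recovery. These sizes give the planted-event counts (tens of
thousands of errors, multiple structural events per chromosome) needed
for the statistical checks while keeping the full suite under a minute
of simulation time.

## Known limitations

Redundancy similarity uses whole-copy global alignment identity, which
can dip below threshold for copies with large internal rearrangements.
The double-cover redundancy branch is exercised on constructed
projections only (the generator's break modes produce uncovered gaps and
overlaps). QUAST-style misassembly taxonomy (relocations, inversions) is
out of scope; only the 85 bp small-scale/local mismatch boundary is
reproduced. Splice-site disruption and non-standard genetic codes are not
modelled.
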